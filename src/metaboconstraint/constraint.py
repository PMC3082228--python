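"""Selective-constraint (omega = Ka/Ks) estimation on codon alignments.

The built-in estimator is a pairwise Nei–Gojobori-style counting method:
synonymous and nonsynonymous sites and differences are counted with
equal-weight pathway averaging, the per-site proportions are Jukes–Cantor
corrected, and omega is pooled as mean(Ka)/mean(Ks) over all taxon pairs.
It is deterministic and dependency-free, suitable for simulation studies
and small datasets.  For maximum-likelihood fits (model M0 for a single
omega; M1a/M2a for positive selection) an adapter around an external
``codeml`` binary (PAML) is provided; the positive-selection decision rule
compares twice the M2a-vs-M1a log-likelihood difference to the chi-square
critical value 5.99 (P < 0.05 at 2 degrees of freedom).
"""

from __future__ import annotations

import math
import re
import subprocess
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import Phylo

from . import _codons
from .alignment_qc import GAP, ProteinAlignment
from .errors import ExternalToolError, FormatError, TranslationError

#: chi-square 95th percentile at 2 df, the M1a-vs-M2a rejection threshold
POSITIVE_SELECTION_CRITICAL = 5.99

_GAP_CODON = GAP * 3


@dataclass
class CodonAlignment:
    """A codon-preserving nucleotide alignment keyed by taxon."""

    rows: dict[str, str]
    tree: str | None = None
    set_id: str = ""

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError(f"unequal row lengths: {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise FormatError("alignment length not divisible by 3")
        for taxon, seq in self.rows.items():
            for k in range(0, len(seq), 3):
                if seq[k : k + 3].upper() in _codons.STOP_CODONS:
                    raise FormatError(f"internal stop codon in {taxon} at codon {k // 3}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.rows.values()))) // 3 if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def codon(self, taxon: str, k: int) -> str:
        return self.rows[taxon][3 * k : 3 * k + 3].upper()


@dataclass
class OmegaRecord:
    """Result of one omega estimation for an ortholog set."""

    set_id: str
    omega: float
    ka: float
    ks: float
    lnl_m0: float | None = None
    lnl_m1a: float | None = None
    lnl_m2a: float | None = None
    positive_selection: bool | None = None
    estimator: str = "builtin"
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.flag is None and math.isfinite(self.omega)


def backtranslate(aa_aln: ProteinAlignment, cds: dict[str, str]) -> CodonAlignment:
    """Thread each CDS through its aligned protein row (gap -> ``---``).

    A trailing stop codon on the CDS is tolerated and dropped; any
    translation mismatch raises naming the taxon and protein position.
    """
    rows: dict[str, str] = {}
    for taxon, aa_row in aa_aln.rows.items():
        if taxon not in cds:
            raise TranslationError(f"no CDS for taxon {taxon}")
        seq = cds[taxon].upper()
        if len(seq) % 3 != 0:
            raise TranslationError(f"CDS length for {taxon} not divisible by 3")
        codons = [seq[k : k + 3] for k in range(0, len(seq), 3)]
        if codons and codons[-1] in _codons.STOP_CODONS:
            codons = codons[:-1]
        out: list[str] = []
        i = 0
        for pos, aa in enumerate(aa_row):
            if aa == GAP:
                out.append(_GAP_CODON)
                continue
            if i >= len(codons):
                raise TranslationError(f"CDS for {taxon} shorter than protein row")
            codon = codons[i]
            if _codons.translate_codon(codon) == "*":
                raise TranslationError(
                    f"internal stop codon in CDS of {taxon} at codon {i}"
                )
            if _codons.translate_codon(codon) != aa.upper():
                raise TranslationError(
                    f"translation mismatch for {taxon} at column {pos}: "
                    f"codon {codon} vs residue {aa}"
                )
            out.append(codon)
            i += 1
        if i != len(codons):
            raise TranslationError(f"CDS for {taxon} longer than protein row")
        rows[taxon] = "".join(out)
    return CodonAlignment(rows)


def drop_gap_codons(aln: CodonAlignment) -> CodonAlignment:
    """Remove codon columns containing a gap in any row."""
    taxa = aln.taxa
    keep = [
        k
        for k in range(aln.n_codons)
        if all(GAP not in aln.codon(t, k) for t in taxa)
    ]
    rows = {t: "".join(aln.codon(t, k) for k in keep) for t in taxa}
    return CodonAlignment(rows, tree=aln.tree, set_id=aln.set_id)


def _jukes_cantor(p: float) -> float | None:
    """JC69 distance from a proportion of differing sites; None if saturated."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _pair_ka_ks(idx1: np.ndarray, idx2: np.ndarray) -> tuple[float, float] | None:
    s_sites, n_sites = _codons.site_counts()
    sd_tab, nd_tab = _codons.pathway_tables()
    usable = (idx1 >= 0) & (idx2 >= 0)
    if not usable.any():
        return None
    i1, i2 = idx1[usable], idx2[usable]
    s = 0.5 * (s_sites[i1].sum() + s_sites[i2].sum())
    n = 0.5 * (n_sites[i1].sum() + n_sites[i2].sum())
    sd = sd_tab[i1, i2].sum()
    nd = nd_tab[i1, i2].sum()
    if s <= 0 or n <= 0:
        return None
    ks = _jukes_cantor(sd / s)
    ka = _jukes_cantor(nd / n)
    if ks is None or ka is None:
        return None  # saturated pair
    return ka, ks


def _codon_indices(aln: CodonAlignment, taxon: str) -> np.ndarray:
    """Codon index per column; -1 marks gaps and ambiguous codons."""
    return np.array(
        [_codons.CODON_INDEX.get(aln.codon(taxon, k), -1) for k in range(aln.n_codons)],
        dtype=np.int64,
    )


def ng86_omega(codon_aln: CodonAlignment) -> OmegaRecord:
    """Pairwise counting estimate of omega pooled over all taxon pairs.

    omega = mean(Ka) / mean(Ks); a record is flagged ``undefined`` when the
    pooled Ks is zero (no synonymous divergence) and ``saturated`` when the
    Jukes–Cantor correction fails for every pair.  Invariant to row order
    and taxon labels.
    """
    taxa = sorted(codon_aln.taxa)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    indices = {t: _codon_indices(codon_aln, t) for t in taxa}
    kas: list[float] = []
    kss: list[float] = []
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            result = _pair_ka_ks(indices[t1], indices[t2])
            if result is not None:
                kas.append(result[0])
                kss.append(result[1])
    if not kas:
        return OmegaRecord(codon_aln.set_id, math.nan, math.nan, math.nan, flag="saturated")
    mean_ka = float(np.mean(kas))
    mean_ks = float(np.mean(kss))
    if mean_ks == 0.0:
        return OmegaRecord(
            codon_aln.set_id, math.nan, mean_ka, mean_ks, flag="undefined"
        )
    return OmegaRecord(codon_aln.set_id, mean_ka / mean_ks, mean_ka, mean_ks)


def positive_selection_call(lnl_m1a: float, lnl_m2a: float) -> bool:
    """True iff 2*(lnL_M2a - lnL_M1a) exceeds 5.99 (strict inequality).

    A negative difference (the richer model fitting worse) indicates an
    optimizer anomaly and yields False with a warning.
    """
    if not (math.isfinite(lnl_m1a) and math.isfinite(lnl_m2a)):
        raise ValueError("log-likelihoods must be finite")
    stat = 2.0 * (lnl_m2a - lnl_m1a)
    if stat < 0:
        warnings.warn(
            f"M2a log-likelihood below M1a (2*dlnL = {stat:.4g}); "
            "treating as no positive selection",
            stacklevel=2,
        )
        return False
    return stat > POSITIVE_SELECTION_CRITICAL


# --- external codeml adapter -------------------------------------------------

_MODEL_CODES = {"M0": (0, 0), "M1a": (0, 1), "M2a": (0, 2)}


def write_phylip_sequential(aln: CodonAlignment, path: Path) -> None:
    """PAML-style sequential PHYLIP with full taxon names."""
    lines = [f" {len(aln.rows)} {len(next(iter(aln.rows.values())))}"]
    for taxon in sorted(aln.rows):
        lines.append(f"{taxon}  {aln.rows[taxon]}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_codeml_output(text: str, model: str, source: str = "<string>") -> dict:
    """Extract lnL (and omega for M0) from a codeml main output file."""
    out: dict[str, float] = {}
    lnl = re.search(r"lnL\(.*?\):\s*(-?\d+\.\d+)", text)
    if lnl is None:
        raise FormatError(f"could not parse lnL from codeml output: {source}")
    out["lnl"] = float(lnl.group(1))
    if model == "M0":
        om = re.search(r"omega \(dN/dS\)\s*=\s*([0-9.]+)", text)
        if om is None:
            raise FormatError(f"could not parse omega from codeml output: {source}")
        out["omega"] = float(om.group(1))
    return out


def codeml_adapter(
    codon_aln: CodonAlignment,
    tree: str,
    model: str,
    workdir: Path,
    codeml_path: str = "codeml",
    options: dict | None = None,
) -> OmegaRecord:
    """Run codeml (PAML) on one alignment and parse omega / lnL.

    ``tree`` is a newick string; ``model`` one of M0, M1a, M2a.  Extra
    control-file options may be supplied via ``options`` (codeml defaults
    otherwise).  Raises :class:`ExternalToolError` when the binary is
    missing.
    """
    if model not in _MODEL_CODES:
        raise ValueError(f"unknown model {model!r}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seqfile = workdir / "seqs.phy"
    treefile = workdir / "tree.nwk"
    outfile = workdir / "mlc.out"
    ctlfile = workdir / "codeml.ctl"
    write_phylip_sequential(codon_aln, seqfile)
    treefile.write_text(tree.strip() + "\n")
    nsmodel, nssites = _MODEL_CODES[model]
    ctl = {
        "seqfile": seqfile.name,
        "treefile": treefile.name,
        "outfile": outfile.name,
        "noisy": 0,
        "verbose": 0,
        "runmode": 0,
        "seqtype": 1,
        "CodonFreq": 2,
        "model": nsmodel,
        "NSsites": nssites,
        "icode": 0,
        "fix_kappa": 0,
        "kappa": 2,
        "fix_omega": 0,
        "omega": 0.4,
    }
    ctl.update(options or {})
    ctlfile.write_text("".join(f"{k} = {v}\n" for k, v in ctl.items()))
    try:
        result = subprocess.run(
            [codeml_path, ctlfile.name],
            cwd=workdir,
            capture_output=True,
            timeout=3600,
        )
    except FileNotFoundError as exc:
        raise ExternalToolError(f"external tool unavailable: {codeml_path}") from exc
    if result.returncode != 0 or not outfile.exists():
        raise ExternalToolError(
            f"codeml failed in {workdir}: {result.stderr.decode(errors='replace')[:500]}"
        )
    parsed = parse_codeml_output(outfile.read_text(), model, source=str(outfile))
    record = OmegaRecord(
        codon_aln.set_id,
        omega=parsed.get("omega", math.nan),
        ka=math.nan,
        ks=math.nan,
        estimator="external",
    )
    if model == "M0":
        record.lnl_m0 = parsed["lnl"]
    elif model == "M1a":
        record.lnl_m1a = parsed["lnl"]
    else:
        record.lnl_m2a = parsed["lnl"]
    return record


def read_tree(newick: str):
    """Parse a newick string into a Bio.Phylo tree (raises FormatError)."""
    try:
        tree = Phylo.read(StringIO(newick), "newick")
    except Exception as exc:
        raise FormatError(f"unreadable newick tree: {exc}") from exc
    if tree.count_terminals() < 2:
        raise FormatError("tree needs at least two leaves")
    return tree
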