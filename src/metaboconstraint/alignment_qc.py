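"""Protein alignment quality control.

Ortholog sets are aligned at the amino-acid level and pushed through an
iterative filter cascade: every sequence pair must reach a minimum percent
identity (default 40%), offenders are removed guided by their identity to a
consensus sequence, gap columns are stripped, and alignments that end up
shorter than a minimum column count (default 50) lose their worst row and
are realigned from the original sequences.  Sets that cannot satisfy all
thresholds with at least ``min_rows`` sequences are rejected.

The aligner is pluggable: any callable mapping ``{taxon: sequence}`` to a
:class:`ProteinAlignment` works.  A dependency-free center-star progressive
aligner is built in; adapters for external MUSCLE/MAFFT binaries are
provided for production use.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ExternalToolError

GAP = "-"

Aligner = Callable[[Mapping[str, str]], "ProteinAlignment"]


@dataclass
class ProteinAlignment:
    """A multiple protein alignment keyed by taxon."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)


@dataclass
class QCReport:
    """Audit trail of a quality-control run."""

    removed_taxa: list[tuple[str, str, int]] = field(default_factory=list)
    realignment_rounds: int = 0
    accepted: bool = False


def percent_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns where neither row is a gap.

    Symmetric and insensitive to alignment padding; returns 0.0 when the two
    rows share no ungapped column.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    matches = 0
    denom = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        denom += 1
        if x == y:
            matches += 1
    return matches / denom if denom else 0.0


def consensus(aln: ProteinAlignment) -> str:
    """Per-column plurality residue; gaps do not vote; ties break alphabetically."""
    if not aln.rows:
        raise ValueError("empty alignment")
    cols = []
    rows = list(aln.rows.values())
    for k in range(aln.n_columns):
        counts = Counter(r[k] for r in rows if r[k] != GAP)
        if not counts:
            cols.append(GAP)
            continue
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        cols.append(best[0])
    return "".join(cols)


def strip_gap_columns(aln: ProteinAlignment) -> ProteinAlignment:
    """Remove every column containing at least one gap (row order preserved)."""
    rows = list(aln.rows.values())
    keep = [k for k in range(aln.n_columns) if all(r[k] != GAP for r in rows)]
    return ProteinAlignment(
        {t: "".join(s[k] for k in keep) for t, s in aln.rows.items()}
    )


def _protein_pairwise_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def center_star_align(sequences: Mapping[str, str]) -> ProteinAlignment:
    """Progressive center-star multiple alignment.

    The center sequence maximizes the summed pairwise alignment score to all
    others (ties broken by taxon name); remaining sequences are merged onto
    the center one at a time under the once-a-gap-always-a-gap rule.
    Adequate for closely related orthologs; not a MUSCLE substitute for
    deeply diverged sets.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    taxa = sorted(sequences)
    if len(taxa) == 1:
        return ProteinAlignment({taxa[0]: sequences[taxa[0]]})
    pa = _protein_pairwise_aligner()
    score = {t: 0.0 for t in taxa}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            s = pa.score(sequences[t1], sequences[t2])
            score[t1] += s
            score[t2] += s
    center = max(taxa, key=lambda t: (score[t], t))

    # master holds the center row with accumulated gaps; rows follow it
    master = list(sequences[center])
    rows: dict[str, list[str]] = {center: list(sequences[center])}
    for taxon in taxa:
        if taxon == center:
            continue
        best = pa.align(sequences[center], sequences[taxon])[0]
        c_aln, s_aln = str(best[0]), str(best[1])
        master, rows = _merge_onto_center(master, rows, c_aln, s_aln, taxon)
    return ProteinAlignment({t: "".join(r) for t, r in rows.items()})


def _merge_onto_center(
    master: list[str],
    rows: dict[str, list[str]],
    c_aln: str,
    s_aln: str,
    taxon: str,
) -> tuple[list[str], dict[str, list[str]]]:
    """Merge one pairwise (center, new sequence) alignment into the master.

    Both ``master`` and ``c_aln`` spell the center sequence with different
    gap patterns; the merged master carries the union of the gaps.
    """
    new_master: list[str] = []
    new_rows: dict[str, list[str]] = {t: [] for t in rows}
    new_row: list[str] = []
    i = j = 0  # i over master, j over c_aln/s_aln
    while i < len(master) or j < len(c_aln):
        m_gap = i < len(master) and master[i] == GAP
        c_gap = j < len(c_aln) and c_aln[j] == GAP
        if i < len(master) and j < len(c_aln) and not m_gap and not c_gap:
            new_master.append(master[i])
            for t in rows:
                new_rows[t].append(rows[t][i])
            new_row.append(s_aln[j])
            i += 1
            j += 1
        elif m_gap:
            # gap already in master: existing rows keep their residue here
            new_master.append(GAP)
            for t in rows:
                new_rows[t].append(rows[t][i])
            new_row.append(GAP)
            i += 1
        else:
            # new gap introduced by this pairwise alignment
            new_master.append(GAP)
            for t in rows:
                new_rows[t].append(GAP)
            new_row.append(s_aln[j])
            j += 1
    new_rows[taxon] = new_row
    return new_master, new_rows


def make_external_aligner(program: str = "mafft") -> Aligner:
    """Adapter running an external multiple aligner (``mafft`` or ``muscle``)."""
    if shutil.which(program) is None:
        raise ExternalToolError(f"external tool unavailable: {program}")

    def _align(sequences: Mapping[str, str]) -> ProteinAlignment:
        with tempfile.TemporaryDirectory() as tmp:
            infile = Path(tmp) / "in.fasta"
            outfile = Path(tmp) / "out.fasta"
            infile.write_text(
                "".join(f">{t}\n{s}\n" for t, s in sorted(sequences.items()))
            )
            if program == "mafft":
                with open(outfile, "w") as out:
                    res = subprocess.run(
                        [program, "--auto", "--amino", str(infile)],
                        stdout=out,
                        stderr=subprocess.PIPE,
                    )
            else:  # muscle-style -in/-out interface
                res = subprocess.run(
                    [program, "-in", str(infile), "-out", str(outfile)],
                    capture_output=True,
                )
            if res.returncode != 0:
                raise ExternalToolError(
                    f"{program} failed: {res.stderr.decode(errors='replace')[:500]}"
                )
            rows = {
                rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(outfile), "fasta")
            }
        return ProteinAlignment(rows)

    return _align


def _lowest_consensus_pid_row(aln: ProteinAlignment) -> str:
    cons = consensus(aln)
    # ties broken by taxon name for a deterministic audit trail
    return min(aln.taxa, key=lambda t: (percent_identity(aln.rows[t], cons), t))


def qc_filter(
    sequences: Mapping[str, str],
    aligner: Aligner = center_star_align,
    pid_floor: float = 0.40,
    min_cols: int = 50,
    min_rows: int = 6,
) -> tuple[ProteinAlignment | None, QCReport]:
    """Iterative alignment quality control.

    Aligns, removes rows while any sequence pair falls below ``pid_floor``
    (always the row with the lowest identity to the consensus), strips gap
    columns, and — if fewer than ``min_cols`` columns survive — drops the
    worst row and realigns the original (unaligned) sequences.  Returns the
    gap-free accepted alignment, or ``None`` with ``report.accepted`` False
    once fewer than ``min_rows`` sequences would remain.
    """
    if len(sequences) < min_rows:
        raise ValueError(
            f"need at least {min_rows} sequences, got {len(sequences)}"
        )
    report = QCReport()
    current = dict(sequences)

    while True:
        if len(current) < min_rows:
            return None, report
        try:
            aln = aligner(current)
        except Exception as exc:  # wrap with context per contract
            raise ExternalToolError(f"aligner failed on {sorted(current)}") from exc

        # PID phase: drop rows until every pair clears the floor
        pid_ok = False
        while True:
            taxa = aln.taxa
            worst_pair = min(
                (
                    percent_identity(aln.rows[t1], aln.rows[t2])
                    for i, t1 in enumerate(taxa)
                    for t2 in taxa[i + 1 :]
                ),
                default=1.0,
            )
            if worst_pair >= pid_floor:
                pid_ok = True
                break
            victim = _lowest_consensus_pid_row(aln)
            del current[victim]
            report.realignment_rounds += 1
            report.removed_taxa.append(
                (victim, "low_pairwise_pid", report.realignment_rounds)
            )
            if len(current) < min_rows:
                return None, report
            aln = aligner(current)
        assert pid_ok

        stripped = strip_gap_columns(aln)
        if stripped.n_columns >= min_cols:
            report.accepted = True
            return stripped, report

        # too short once gap columns are removed: drop the row with the
        # lowest consensus identity and realign the original sequences
        victim = _lowest_consensus_pid_row(aln)
        del current[victim]
        report.realignment_rounds += 1
        report.removed_taxa.append(
            (victim, "short_alignment", report.realignment_rounds)
        )
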