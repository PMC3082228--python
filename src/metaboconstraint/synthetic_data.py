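"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate (i) genome pairs with planted ortholog, tandem-duplicate
and gene-family structure plus noise homology hits, (ii) codon alignments
evolved on a phylogeny at a known omega, (iii) compartmentalized metabolic
reconstructions with planted modules and currency metabolites, (iv) omega
tables drawn per group from named distribution families, and (v) expression
matrices whose per-gene maxima are rank-coupled to omega at a requested
strength.  Each generator returns a :class:`SyntheticTruth` sufficient to
score the downstream stage (ortholog precision/recall, currency recovery,
omega recovery, test power) without inspecting generator internals, and all
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm

from . import _codons
from .constraint import CodonAlignment, read_tree
from .errors import FormatError, InvalidParameterError
from .metabolic_network import Metabolite, Reaction, Reconstruction
from .orthology import Gene, HomologyHit

#: Eight-taxon eutherian species tree used throughout; branch lengths are in
#: expected substitutions per codon, scaled to roughly mammalian divergences.
MAMMAL_TREE = (
    "((((human:0.06,chimpanzee:0.06):0.03,macaque:0.09):0.09,"
    "(mouse:0.21,rat:0.21):0.12):0.03,((horse:0.15,dog:0.15):0.045,cow:0.18):0.03);"
)

MAMMAL_GENOMES = (
    "human",
    "chimpanzee",
    "macaque",
    "mouse",
    "rat",
    "horse",
    "dog",
    "cow",
)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every synthetic dataset."""

    true_ortholog_pairs: set[tuple[str, str]] = field(default_factory=set)
    tandem_groups: list[list[str]] = field(default_factory=list)
    currency_metabolites: set[str] = field(default_factory=set)
    module_labels: dict[str, int] = field(default_factory=dict)
    true_omega: dict[str, float] = field(default_factory=dict)
    group_params: dict[str, tuple] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_ortholog_pairs": sorted(map(list, self.true_ortholog_pairs)),
            "tandem_groups": self.tandem_groups,
            "currency_metabolites": sorted(self.currency_metabolites),
            "module_labels": self.module_labels,
            "true_omega": self.true_omega,
            "group_params": {k: list(v) for k, v in self.group_params.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise InvalidParameterError(f"{name} must be in [0, 1], got {value}")


# --- genome pairs -------------------------------------------------------------

def gen_genome_pair(
    n_genes: int,
    tandem_rate: float = 0.0,
    family_expansion_rate: float = 0.0,
    noise_hit_rate: float = 0.0,
    seed: int = 0,
    genome1: str = "human",
    genome2: str = "other",
) -> tuple[list[Gene], list[Gene], list[HomologyHit], SyntheticTruth]:
    """A pair of single-chromosome genomes with planted orthologs.

    Every ancestral gene yields one ortholog pair whose homology hit passes
    the orthology filters (E-value, identity, Ks).  With probability
    ``tandem_rate`` a gene gains an immediately adjacent tandem duplicate in
    one genome (recorded in ``tandem_groups``); with probability
    ``family_expansion_rate`` a gene gains a cross-genome hit to a dispersed
    paralog (ordinal distance > 1), breaking one-to-one seeding; with
    probability ``noise_hit_rate`` a spurious hit is added whose E-value is
    log-uniform in [1e-12, 1e-6] and identity in [0.35, 0.7], straddling the
    filter thresholds.
    """
    if n_genes < 10:
        raise InvalidParameterError("n_genes must be at least 10")
    for name, rate in (
        ("tandem_rate", tandem_rate),
        ("family_expansion_rate", family_expansion_rate),
        ("noise_hit_rate", noise_hit_rate),
    ):
        _check_rate(name, rate)
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    ids1 = [f"{genome1}_{i:04d}" for i in range(n_genes)]
    ids2 = [f"{genome2}_{i:04d}" for i in range(n_genes)]
    hits: list[HomologyHit] = []

    def passing_hit(g1: str, g2: str, ks_lo=0.05, ks_hi=0.4) -> HomologyHit:
        return HomologyHit(
            g1,
            g2,
            e_value=float(10.0 ** rng.uniform(-50, -15)),
            pid=float(rng.uniform(0.6, 0.95)),
            ks=float(rng.uniform(ks_lo, ks_hi)),
        )

    for a, b in zip(ids1, ids2):
        truth.true_ortholog_pairs.add((a, b))
        hits.append(passing_hit(a, b))

    # tandem duplicates: adjacent copy in one genome, homologous to both its
    # template and the template's ortholog
    order1: list[str] = list(ids1)
    order2: list[str] = list(ids2)
    for i in range(n_genes):
        if rng.random() >= tandem_rate:
            continue
        in_first = bool(rng.random() < 0.5)
        template = ids1[i] if in_first else ids2[i]
        partner = ids2[i] if in_first else ids1[i]
        dup = f"{template}t"
        target = order1 if in_first else order2
        target.insert(target.index(template) + 1, dup)
        truth.tandem_groups.append([template, dup])
        hits.append(passing_hit(template, dup, ks_lo=0.01, ks_hi=0.1))
        hits.append(passing_hit(dup, partner))

    # dispersed family expansions: an extra cross-genome hit at ordinal
    # distance > 1, with an old-paralog Ks above the seeding ceiling
    for i in range(n_genes):
        if rng.random() >= family_expansion_rate:
            continue
        candidates = [j for j in range(n_genes) if abs(j - i) > 1]
        j = int(rng.choice(candidates))
        hits.append(
            HomologyHit(
                ids1[i],
                ids2[j],
                e_value=float(10.0 ** rng.uniform(-30, -15)),
                pid=float(rng.uniform(0.5, 0.7)),
                ks=float(rng.uniform(0.8, 1.5)),
            )
        )

    for i in range(n_genes):
        if rng.random() >= noise_hit_rate:
            continue
        j = int(rng.integers(n_genes))
        hits.append(
            HomologyHit(
                ids1[i],
                ids2[j],
                e_value=float(10.0 ** rng.uniform(-12, -6)),
                pid=float(rng.uniform(0.35, 0.7)),
                ks=float(rng.uniform(0.1, 2.0)),
            )
        )

    genes1 = [
        Gene(gid, genome1, "1", pos) for pos, gid in enumerate(order1)
    ]
    genes2 = [
        Gene(gid, genome2, "1", pos) for pos, gid in enumerate(order2)
    ]
    # deduplicate hits that may have been drawn twice (canonical keys)
    unique = {}
    for h in hits:
        unique.setdefault(h.key, h)
    return genes1, genes2, sorted(unique.values(), key=lambda h: h.key), truth


# --- codon alignments ---------------------------------------------------------

def gen_codon_alignments(
    tree: str = MAMMAL_TREE,
    omega: float = 0.2,
    kappa: float = 2.0,
    n_sets: int = 1,
    n_codons: int = 300,
    seed: int = 0,
) -> tuple[list[CodonAlignment], SyntheticTruth]:
    """Codon alignments evolved on ``tree`` under a GY-style process.

    The root sequence is uniform over the 61 sense codons; each branch
    applies the matrix exponential of the omega/kappa rate matrix for its
    length (expected substitutions per codon).  Sequences are gap-free,
    stop-free, and of length ``3 * n_codons``.
    """
    if omega < 0:
        raise InvalidParameterError("omega must be nonnegative")
    if kappa <= 0:
        raise InvalidParameterError("kappa must be positive")
    if n_codons < 30:
        raise InvalidParameterError("n_codons must be at least 30")
    phylo = read_tree(tree)
    if phylo.count_terminals() < 3:
        raise FormatError("tree needs at least three leaves")

    rng = np.random.default_rng(seed)
    q = _codons.rate_matrix(omega, kappa)
    p_cache: dict[float, np.ndarray] = {}

    def transition(bl: float) -> np.ndarray:
        key = round(bl, 12)
        if key not in p_cache:
            p = expm(q * bl)
            np.clip(p, 0.0, None, out=p)
            p /= p.sum(axis=1, keepdims=True)
            p_cache[key] = np.cumsum(p, axis=1)
        return p_cache[key]

    def evolve(states: np.ndarray, bl: float) -> np.ndarray:
        if bl == 0:
            return states.copy()
        cum = transition(bl)
        u = rng.random(states.size)
        return (cum[states] > u[:, None]).argmax(axis=1)

    alignments: list[CodonAlignment] = []
    truth = SyntheticTruth()
    for s in range(n_sets):
        set_id = f"set{s:04d}"
        rows: dict[str, str] = {}

        def walk(clade, states: np.ndarray) -> None:
            for child in clade.clades:
                bl = child.branch_length or 0.0
                child_states = evolve(states, bl)
                if child.is_terminal():
                    rows[child.name] = "".join(
                        _codons.SENSE_CODONS[k] for k in child_states
                    )
                else:
                    walk(child, child_states)

        root_states = rng.integers(_codons.N_CODONS, size=n_codons)
        walk(phylo.root, root_states)
        alignments.append(CodonAlignment(rows, tree=tree, set_id=set_id))
        truth.true_omega[set_id] = omega
    return alignments, truth


# --- metabolic reconstructions ------------------------------------------------

_COMPARTMENT_ORDER = ("c", "m", "n", "r", "g", "e", "l", "x")


def gen_reconstruction(
    n_compartments: int = 4,
    reactions_per_module: int = 6,
    modules_per_compartment: int = 3,
    n_currency: int = 3,
    currency_coverage: float = 0.8,
    transport_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[Reconstruction, SyntheticTruth]:
    """A compartmentalized reconstruction with planted modules and currency.

    Each compartment holds ``modules_per_compartment`` modules whose
    reactions are chained by module-private metabolites and densified by a
    module hub metabolite joined to every reaction of the module (a local
    cofactor).  Each of the ``n_currency`` currency compounds exists as one
    instance per compartment (ids carry compartment suffixes, e.g.
    ``cur0_c``) attached to ``currency_coverage`` of the compartment's
    reactions on a random side.  Transport reactions span two compartments.
    Truth records currency *base* names and a module label per reaction
    (transport reactions get label -1).
    """
    if currency_coverage <= 0 or currency_coverage > 1:
        raise InvalidParameterError("currency_coverage must be in (0, 1]")
    if n_currency < 0:
        raise InvalidParameterError("n_currency must be nonnegative")
    if not 1 <= n_compartments <= len(_COMPARTMENT_ORDER):
        raise InvalidParameterError(
            f"n_compartments must be in [1, {len(_COMPARTMENT_ORDER)}]"
        )
    _check_rate("transport_fraction", transport_fraction)
    rng = np.random.default_rng(seed)
    codes = _COMPARTMENT_ORDER[:n_compartments]

    metabolites: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    truth = SyntheticTruth()
    gene_counter = 0

    def add_met(name: str, code: str) -> str:
        mid = f"{name}_{code}"
        metabolites.setdefault(mid, Metabolite(mid, name, code))
        return mid

    module_index = 0
    module_met_ids: dict[str, list[str]] = {code: [] for code in codes}
    for code in codes:
        for mj in range(modules_per_compartment):
            chain = [
                add_met(f"m{code}{mj}chain{k}", code)
                for k in range(reactions_per_module + 1)
            ]
            hub = add_met(f"m{code}{mj}hub0", code)
            module_met_ids[code].extend(chain)
            # alternating hub side and reversibility give every module the
            # same internal edge structure (degree-balanced communities)
            for i in range(reactions_per_module):
                rid = f"R_{code}{mj}_{i}"
                subs = [chain[i]]
                prods = [chain[i + 1]]
                (subs if i % 2 == 0 else prods).append(hub)
                genes: set[str] = set()
                if rng.random() < 0.9:
                    for _ in range(int(rng.integers(1, 3))):
                        genes.add(f"g{gene_counter:04d}")
                        gene_counter += 1
                reactions[rid] = Reaction(
                    rid, subs, prods, reversible=bool(i % 2), genes=genes
                )
                truth.module_labels[rid] = module_index
            module_index += 1

    # currency instances per compartment, attached to an exact fraction of
    # that compartment's reactions
    for t in range(n_currency):
        base = f"cur{t}"
        truth.currency_metabolites.add(base)
        for code in codes:
            mid = add_met(base, code)
            rids = sorted(r for r in reactions if reactions[r].substrates and
                          metabolites[reactions[r].substrates[0]].compartment == code)
            n_attach = max(1, round(currency_coverage * len(rids)))
            chosen = rng.choice(len(rids), size=n_attach, replace=False)
            for k in chosen:
                rxn = reactions[rids[int(k)]]
                (rxn.substrates if rng.random() < 0.5 else rxn.products).append(mid)

    n_core = len(reactions)
    n_transport = round(transport_fraction * n_core)
    for t in range(n_transport):
        c1, c2 = rng.choice(len(codes), size=2, replace=False)
        m1 = module_met_ids[codes[int(c1)]]
        m2 = module_met_ids[codes[int(c2)]]
        rid = f"T_{t}"
        genes = {f"g{gene_counter:04d}"}
        gene_counter += 1
        reactions[rid] = Reaction(
            rid,
            substrates=[m1[int(rng.integers(len(m1)))]],
            products=[m2[int(rng.integers(len(m2)))]],
            reversible=bool(rng.random() < 0.5),
            genes=genes,
        )
        truth.module_labels[rid] = -1

    return Reconstruction(metabolites, reactions), truth


# --- omega tables and expression ---------------------------------------------

_OMEGA_FAMILIES = ("weibull", "gamma", "exponential")


def gen_omega_table(
    group_specs: dict[str, tuple[str, tuple[float, ...], int]],
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-group omega draws from a named family.

    ``group_specs`` maps a group label to (family, params, n); supported
    families are ``weibull`` (shape, scale), ``gamma`` (shape, scale) and
    ``exponential`` (scale,).  Returns a table with columns
    (set_id, group, omega) and the truth's ``group_params``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = SyntheticTruth()
    for group in sorted(group_specs):
        family, params, n = group_specs[group]
        if n < 2:
            raise InvalidParameterError(f"group {group!r} needs n >= 2")
        if family == "weibull":
            shape, scale = params
            draws = scale * rng.weibull(shape, size=n)
        elif family == "gamma":
            shape, scale = params
            draws = rng.gamma(shape, scale, size=n)
        elif family == "exponential":
            (scale,) = params
            draws = rng.exponential(scale, size=n)
        else:
            raise InvalidParameterError(f"unknown family {family!r}")
        truth.group_params[group] = (family, tuple(params))
        for i, omega in enumerate(draws):
            set_id = f"{group}_{i:05d}"
            rows.append((set_id, group, float(omega)))
            truth.true_omega[set_id] = float(omega)
    return pd.DataFrame(rows, columns=["set_id", "group", "omega"]), truth


def gen_expression(
    n_tissues: int,
    coupling: float = 0.0,
    omega_table: pd.DataFrame | None = None,
    n_genes: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nonnegative expression matrix whose per-gene maximum tracks omega.

    With ``coupling`` != 0 the per-gene maximum is rank-coupled to the omega
    column of ``omega_table`` at the requested strength (Gaussian scores of
    the omega ranks mixed with independent noise); each gene's remaining
    tissue values are uniform fractions of its maximum.
    """
    if abs(coupling) > 1:
        raise InvalidParameterError("coupling must be in [-1, 1]")
    if n_tissues < 1:
        raise InvalidParameterError("n_tissues must be at least 1")
    if omega_table is None:
        if coupling != 0:
            raise InvalidParameterError("coupling requires an omega table")
        if n_genes is None:
            raise InvalidParameterError("need n_genes or an omega table")
        genes = [f"g{i:05d}" for i in range(n_genes)]
        n = n_genes
        z_omega = None
    else:
        genes = list(omega_table["set_id"])
        n = len(genes)
        ranks = stats.rankdata(omega_table["omega"].to_numpy())
        z_omega = stats.norm.ppf((ranks - 0.5) / n)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    if coupling != 0 and z_omega is not None:
        z = coupling * z_omega + math.sqrt(1.0 - coupling**2) * noise
    else:
        z = noise
    maxima = np.maximum(0.0, 100.0 + 30.0 * z)

    values = maxima[:, None] * rng.uniform(0.1, 1.0, size=(n, n_tissues))
    peak = rng.integers(n_tissues, size=n)
    values[np.arange(n), peak] = maxima
    return pd.DataFrame(
        values, index=genes, columns=[f"tissue{j}" for j in range(n_tissues)]
    )

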