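"""End-to-end orchestration with seeded reproducibility.

``run_all`` executes the full analysis in order — orthology, alignment QC +
omega estimation, network construction, currency-metabolite removal, and
the statistical battery (group tests, distribution fits, compartment
clustering, centrality and expression correlations) — either on a fully
synthetic bundle (default) or on a user-supplied reconstruction / omega
table.  Every stage writes a TSV into the output directory and the run ends
with a ``summary.json`` carrying the seed and a hash of the configuration;
two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    alignment_qc,
    constraint,
    evostats,
    metabolic_network as net,
    modularity_currency as modul,
    orthology,
    synthetic_data as synth,
)
from ._codons import translate_codon
from .errors import MetaboconstraintError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of an end-to-end run; defaults give a desk-scale bundle."""

    seed: int = 0
    # orthology stage
    n_genes: int = 80
    tandem_rate: float = 0.05
    family_expansion_rate: float = 0.1
    noise_hit_rate: float = 0.05
    min_others: int = 5
    # alignment / omega stage
    n_demo_sets: int = 10
    n_codons: int = 120
    demo_omega: float = 0.2
    kappa: float = 2.0
    pid_floor: float = 0.40
    min_cols: int = 50
    min_rows: int = 6
    # network / currency stage
    n_compartments: int = 4
    reactions_per_module: int = 6
    modules_per_compartment: int = 3
    n_currency: int = 3
    currency_coverage: float = 0.8
    transport_fraction: float = 0.1
    variant: str = "noncompartmentalized"
    max_removals: int = 6
    n_random: int = 30
    # statistics stage
    group_specs: dict = field(
        default_factory=lambda: {
            "metabolic": ("weibull", (2.0, 0.13), 400),
            "non_metabolic": ("weibull", (2.0, 0.15), 2000),
        }
    )
    n_reps: int = 2000
    alpha: float = 0.01
    omega_aggregation: str = "mean"  # per-reaction omega over its genes
    # expression stage
    with_expression: bool = True
    n_tissues: int = 19
    expression_coupling: float = -0.1
    # optional user inputs (override the synthetic generators)
    sbml_path: str | None = None
    omega_table_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "group_specs" in data:
            data["group_specs"] = {
                k: (v[0], tuple(v[1]), int(v[2]))
                for k, v in data["group_specs"].items()
            }
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def _translate_rows(codon_aln: constraint.CodonAlignment) -> dict[str, str]:
    return {
        t: "".join(
            translate_codon(codon_aln.codon(t, k)) for k in range(codon_aln.n_codons)
        )
        for t in codon_aln.taxa
    }


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order and return the summary dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _subseeds(config.seed, 8)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                summary["stages"][name] = fn()
            except MetaboconstraintError:
                raise
            except Exception as exc:
                raise MetaboconstraintError(f"stage '{name}' failed: {exc}") from exc
            return fn

        return deco

    # ---- orthology ------------------------------------------------------
    @stage("orthology")
    def _orthology():
        pairwise: dict[str, list[orthology.OrthologPair]] = {}
        genome_of: dict[str, str] = {}
        truth_pairs: set[tuple[str, str]] = set()
        all_pairs_rows = []
        for k, companion in enumerate(synth.MAMMAL_GENOMES[1:]):
            primate = companion in ("chimpanzee", "macaque")
            thr = (
                orthology.PRIMATE_THRESHOLDS if primate else orthology.DEFAULT_THRESHOLDS
            )
            g1, g2, hits, truth = synth.gen_genome_pair(
                config.n_genes,
                config.tandem_rate,
                config.family_expansion_rate,
                config.noise_hit_rate,
                seed=seeds[0] + k,
                genome1="human",
                genome2=companion,
            )
            pairs = orthology.find_orthologs(g1 + g2, hits, **thr)
            pairwise[companion] = pairs
            genome_of.update({g.id: g.genome for g in g1 + g2})
            truth_pairs |= truth.true_ortholog_pairs
            all_pairs_rows += [
                (companion, p.gene1, p.gene2, p.provenance) for p in pairs
            ]
        sets = orthology.assemble_sets(
            pairwise, "human", genome_of, min_others=config.min_others
        )
        pd.DataFrame(
            all_pairs_rows, columns=["genome", "gene1", "gene2", "provenance"]
        ).to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
        orthology.write_sets(sets, out / "ortholog_sets.tsv")
        found = {
            tuple(sorted(p)) for pairs in pairwise.values() for p in
            ((q.gene1, q.gene2) for q in pairs)
        }
        truth_sorted = {tuple(sorted(t)) for t in truth_pairs}
        tp = len(found & truth_sorted)
        return {
            "n_pairs": sum(len(p) for p in pairwise.values()),
            "n_sets": len(sets),
            "precision": tp / len(found) if found else float("nan"),
            "recall": tp / len(truth_sorted),
        }

    # ---- alignment QC + omega -------------------------------------------
    @stage("omega")
    def _omega():
        alns, truth = synth.gen_codon_alignments(
            omega=config.demo_omega,
            kappa=config.kappa,
            n_sets=config.n_demo_sets,
            n_codons=config.n_codons,
            seed=seeds[1],
        )
        records = []
        n_accepted = 0
        for aln in alns:
            proteins = _translate_rows(aln)
            cds = {t: aln.rows[t] for t in aln.taxa}
            qc_aln, report = alignment_qc.qc_filter(
                proteins,
                pid_floor=config.pid_floor,
                min_cols=config.min_cols,
                min_rows=config.min_rows,
            )
            if qc_aln is None:
                continue
            n_accepted += 1
            codon_aln = constraint.backtranslate(qc_aln, cds)
            codon_aln.set_id = aln.set_id
            records.append(constraint.ng86_omega(constraint.drop_gap_codons(codon_aln)))
        df = pd.DataFrame(
            [(r.set_id, r.omega, r.ka, r.ks, r.flag or "") for r in records],
            columns=["set_id", "omega", "ka", "ks", "flag"],
        )
        df.to_csv(out / "omega_estimates.tsv", sep="\t", index=False)
        defined = df[df.flag == ""]["omega"]
        return {
            "n_sets": len(alns),
            "n_accepted": n_accepted,
            "true_omega": config.demo_omega,
            "median_omega_estimate": float(defined.median()) if len(defined) else None,
        }

    # ---- network + currency ---------------------------------------------
    if config.sbml_path:
        recon = net.parse_reconstruction(config.sbml_path)
    else:
        recon, _net_truth = synth.gen_reconstruction(
            config.n_compartments,
            config.reactions_per_module,
            config.modules_per_compartment,
            config.n_currency,
            config.currency_coverage,
            config.transport_fraction,
            seed=seeds[2],
        )
        net.write_sbml(recon, out / "reconstruction.xml")
        recon = net.parse_reconstruction(out / "reconstruction.xml")

    @stage("currency")
    def _currency():
        trajectory = modul.currency_scan(
            recon,
            variant=config.variant,
            max_removals=config.max_removals,
            n_random=config.n_random,
            seed=seeds[3],
        )
        trajectory.to_frame().to_csv(out / "currency_trajectory.tsv", sep="\t", index=False)
        return {
            "argmax_step": trajectory.argmax_step,
            "removed_metabolites": sorted(trajectory.removed_set),
            "max_delta_q": max(s.delta_q for s in trajectory.steps),
        }

    # downstream analyses always run on the compartmentalized network; when
    # the scan merged compartments, its removed base names map back to every
    # compartment-specific instance
    removed = set(summary["stages"]["currency"]["removed_metabolites"])
    graph_recon = recon
    excluded = {
        mid
        for mid, met in recon.metabolites.items()
        if mid in removed or met.name in removed
    }
    graph = net.build_reaction_graph(graph_recon, excluded_metabolites=excluded)

    @stage("network")
    def _network():
        table = net.node_table(graph, graph_recon)
        table.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        net.write_edge_list(graph, out / "network_edges.tsv")
        return {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_gene_nodes": int((table["genes"] != "").sum()),
        }

    # ---- statistics -------------------------------------------------------
    if config.omega_table_path:
        omega_table = pd.read_csv(config.omega_table_path, sep="\t", comment="#")
    else:
        omega_table, _ = synth.gen_omega_table(config.group_specs, seed=seeds[4])
    omega_table.to_csv(out / "omega_table.tsv", sep="\t", index=False)

    groups = {
        g: omega_table.loc[omega_table.group == g, "omega"].to_numpy()
        for g in sorted(omega_table.group.unique())
    }
    met_label = sorted(groups)[0] if "metabolic" not in groups else "metabolic"
    other_label = next(g for g in sorted(groups) if g != met_label)
    met, non = groups[met_label], groups[other_label]

    # pair metabolic omega values with reconstruction genes for the
    # centrality analysis
    recon_genes = sorted(graph_recon.genes)
    gene_omega = dict(zip(recon_genes, met))

    @stage("stats")
    def _stats():
        pool = np.concatenate([met, non])
        mw = evostats.mann_whitney(met, non, alternative="less")
        boot_mean = evostats.bootstrap_mean_test(
            non, n_sub=len(met), n_reps=config.n_reps,
            observed_mean=float(met.mean()), tail="less", seed=seeds[5],
        )
        boot_diff = evostats.bootstrap_diff_test(
            pool, n1=len(met), n2=len(non), n_reps=config.n_reps,
            observed_diff=float(met.mean() - non.mean()), seed=seeds[5] + 1,
        )
        ranking = evostats.rank_distributions(pool)
        ranking.drop(columns="params").to_csv(
            out / "distribution_ranking.tsv", sep="\t", index=False
        )
        lrt = {
            fam: evostats.two_group_lrt(met, non, fam)
            for fam in ("weibull", "gamma", "exponential")
        }
        median_split = evostats.chisq_2x2(
            [
                [(met <= np.median(pool)).sum(), (met > np.median(pool)).sum()],
                [(non <= np.median(pool)).sum(), (non > np.median(pool)).sum()],
            ]
        )
        return {
            "median_metabolic": float(np.median(met)),
            "median_non_metabolic": float(np.median(non)),
            "mean_metabolic": float(met.mean()),
            "mean_non_metabolic": float(non.mean()),
            "mann_whitney_p": mw.p_value,
            "bootstrap_mean_p": boot_mean.p_value,
            "bootstrap_diff_p": boot_diff.p_value,
            "best_family": ranking.family.iloc[0],
            "lrt": {f: {"stat": t.statistic, "p": t.p_value} for f, t in lrt.items()},
            "chisq_median_split": {
                "stat": median_split.statistic,
                "p": median_split.p_value,
            },
        }

    @stage("compartments")
    def _compartments():
        group_values: dict[str, list[float]] = {}
        reaction_omega: dict[str, float] = {}
        for rid, rxn in graph_recon.reactions.items():
            omegas = [gene_omega[g] for g in rxn.genes if g in gene_omega]
            if not omegas:
                continue
            reaction_omega[rid] = float(np.mean(omegas))
            label = net.classify_compartment(rxn, graph_recon.metabolites)
            group_values.setdefault(label.value, []).append(reaction_omega[rid])
        usable = {k: v for k, v in group_values.items() if len(v) >= 2}
        if len(usable) < 2:
            return {"note": "fewer than two compartments with data; skipped"}
        newick, comparisons = evostats.upgma_nested_tests(usable, alpha=config.alpha)
        (out / "compartment_tree.nwk").write_text(newick + "\n")
        pd.DataFrame(
            [
                (
                    "+".join(c.left),
                    "+".join(c.right),
                    c.test.p_value,
                    c.significant,
                )
                for c in comparisons
            ],
            columns=["left", "right", "p_value", "significant"],
        ).to_csv(out / "compartment_tests.tsv", sep="\t", index=False)

        # centrality vs omega on the currency-removed network
        btw = net.betweenness(graph)
        deg = net.degree(graph)
        agg = config.omega_aggregation
        rows = []
        for rid, om in reaction_omega.items():
            if agg == "mean":
                rows.append((btw[rid], deg[rid], om))
            else:  # one observation per (reaction, gene) pair
                for g in graph_recon.reactions[rid].genes:
                    if g in gene_omega:
                        rows.append((btw[rid], deg[rid], gene_omega[g]))
        b, d, o = (np.array(v, dtype=float) for v in zip(*rows))
        result = {
            "compartment_means": {k: float(np.mean(v)) for k, v in usable.items()},
            "n_comparisons": len(comparisons),
            "spearman_betweenness": evostats.correlate(b, o, "spearman").statistic,
            "spearman_degree": evostats.correlate(d, o, "spearman").statistic,
        }
        positive = b > 0
        if positive.sum() >= 3:
            result["pearson_log10_betweenness"] = evostats.correlate(
                b[positive], o[positive], "pearson", x_transform="log10"
            ).statistic
        return result

    # ---- expression -------------------------------------------------------
    if config.with_expression:

        @stage("expression")
        def _expression():
            expr = synth.gen_expression(
                n_tissues=config.n_tissues,
                coupling=config.expression_coupling,
                omega_table=omega_table,
                seed=seeds[6],
            )
            expr.to_csv(out / "expression.tsv", sep="\t")
            maxima = evostats.max_expression(expr)
            omega = omega_table.set_index("set_id").loc[maxima.index, "omega"]
            corr = evostats.correlate(maxima.to_numpy(), omega.to_numpy(), "pearson")
            met_ids = omega_table.loc[omega_table.group == met_label, "set_id"]
            corr_met = evostats.correlate(
                maxima.loc[met_ids].to_numpy(),
                omega.loc[met_ids].to_numpy(),
                "pearson",
            )
            return {
                "pearson_max_expression": corr.statistic,
                "pearson_max_expression_p": corr.p_value,
                "pearson_max_expression_metabolic": corr_met.statistic,
            }

    else:
        summary["stages"]["expression"] = {"note": "no expression table; skipped"}
        logger.info("expression stage skipped (with_expression=False)")

    # every tabular output records the provenance of the run
    header = f"# seed={config.seed} config_hash={config.digest()}\n"
    for tsv in sorted(out.glob("*.tsv")):
        body = tsv.read_text()
        if not body.startswith("# seed="):
            tsv.write_text(header + body)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float)
    )
    return summary
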