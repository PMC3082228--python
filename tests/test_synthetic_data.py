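"""Generators: planted structure, parameter validation, reproducibility."""

import numpy as np
import pytest

from metaboconstraint import _codons, evostats
from metaboconstraint import synthetic_data as synth
from metaboconstraint.errors import FormatError, InvalidParameterError
from metaboconstraint.metabolic_network import classify_compartment


class TestGenGenomePair:
    def test_too_few_genes_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_genome_pair(5)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_genome_pair(50, tandem_rate=1.5)

    def test_no_confounders_gives_unique_reciprocal_hits(self):
        g1, g2, hits, truth = synth.gen_genome_pair(50, 0, 0, 0, seed=1)
        assert len(hits) == 50
        assert len(truth.true_ortholog_pairs) == 50
        assert {h.key for h in hits} == {
            tuple(sorted(p)) for p in truth.true_ortholog_pairs
        }

    def test_tandem_group_count_near_binomial_mean(self):
        _, _, _, truth = synth.gen_genome_pair(100, tandem_rate=0.1, seed=7)
        # binomial(100, 0.1): allow +-3 sd around the mean of 10
        assert 1 <= len(truth.tandem_groups) <= 19

    def test_family_expansion_creates_multi_hit_genes(self):
        _, _, hits, _ = synth.gen_genome_pair(
            100, family_expansion_rate=0.2, seed=3
        )
        counts: dict[str, int] = {}
        for h in hits:
            counts[h.gene1] = counts.get(h.gene1, 0) + 1
            counts[h.gene2] = counts.get(h.gene2, 0) + 1
        assert sum(1 for c in counts.values() if c >= 2) > 0

    def test_noise_evalues_straddle_filter_thresholds(self):
        _, _, hits, truth = synth.gen_genome_pair(
            200, noise_hit_rate=0.5, seed=5
        )
        truth_keys = {tuple(sorted(p)) for p in truth.true_ortholog_pairs}
        noise = [h for h in hits if h.key not in truth_keys]
        evals = np.array([h.e_value for h in noise])
        assert ((evals >= 1e-12) & (evals <= 1e-6)).all()
        assert (evals < 1e-9).any() and (evals > 1e-9).any()

    def test_ortholog_pairs_join_distinct_genomes(self):
        g1, g2, _, truth = synth.gen_genome_pair(40, 0.2, 0.2, 0.2, seed=2)
        genome_of = {g.id: g.genome for g in g1 + g2}
        for a, b in truth.true_ortholog_pairs:
            assert genome_of[a] != genome_of[b]

    def test_bit_reproducible(self):
        a = synth.gen_genome_pair(60, 0.1, 0.1, 0.1, seed=4)
        b = synth.gen_genome_pair(60, 0.1, 0.1, 0.1, seed=4)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_positions_contiguous(self):
        g1, g2, _, _ = synth.gen_genome_pair(30, tandem_rate=0.3, seed=6)
        for genes in (g1, g2):
            assert [g.position for g in genes] == list(range(len(genes)))


class TestGenCodonAlignments:
    def test_omega_zero_forbids_nonsynonymous_change(self):
        tree = "((a:0.3,b:0.3):0.1,c:0.4);"
        alns, _ = synth.gen_codon_alignments(
            tree=tree, omega=0.0, kappa=2.0, n_sets=2, n_codons=50, seed=1
        )
        for aln in alns:
            proteins = {
                "".join(
                    _codons.translate_codon(aln.codon(t, k))
                    for k in range(aln.n_codons)
                )
                for t in aln.taxa
            }
            assert len(proteins) == 1  # all rows translate identically

    def test_rows_gap_free_and_triplet_length(self):
        alns, truth = synth.gen_codon_alignments(n_sets=1, n_codons=40, seed=2)
        aln = alns[0]
        assert set(aln.rows) == set(synth.MAMMAL_GENOMES)
        for row in aln.rows.values():
            assert len(row) == 120 and "-" not in row
        assert truth.true_omega == {"set0000": 0.2}

    def test_too_short_sequences_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_codon_alignments(n_codons=0)

    def test_negative_omega_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_codon_alignments(omega=-0.1)

    def test_unreadable_tree_rejected(self):
        with pytest.raises(FormatError):
            synth.gen_codon_alignments(tree="((broken")

    def test_bit_reproducible(self):
        a, _ = synth.gen_codon_alignments(n_sets=2, n_codons=40, seed=3)
        b, _ = synth.gen_codon_alignments(n_sets=2, n_codons=40, seed=3)
        assert [x.rows for x in a] == [x.rows for x in b]


class TestGenReconstruction:
    def test_invalid_coverage_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_reconstruction(currency_coverage=0.0)

    def test_negative_currency_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_reconstruction(n_currency=-1)

    def test_currency_attached_to_requested_fraction(self):
        recon, truth = synth.gen_reconstruction(
            n_currency=2, currency_coverage=0.8, seed=1
        )
        core = [r for r in recon.reactions.values() if r.id.startswith("R_")]
        for base in truth.currency_metabolites:
            using = sum(
                1
                for r in core
                if any(recon.metabolites[m].name == base for m in r.metabolites)
            )
            assert using >= 0.8 * len(core) - len(core) ** 0.5

    def test_module_labels_cover_all_reactions(self):
        recon, truth = synth.gen_reconstruction(seed=2)
        assert set(truth.module_labels) == set(recon.reactions)
        transports = {r for r in recon.reactions if r.startswith("T_")}
        assert all(truth.module_labels[r] == -1 for r in transports)

    def test_transport_reactions_span_two_compartments(self):
        recon, _ = synth.gen_reconstruction(transport_fraction=0.2, seed=3)
        transports = [r for r in recon.reactions.values() if r.id.startswith("T_")]
        assert transports
        for rxn in transports:
            comps = {recon.metabolites[m].compartment for m in rxn.metabolites}
            assert len(comps) == 2

    def test_metabolite_ids_carry_compartment_suffix(self):
        recon, _ = synth.gen_reconstruction(seed=4)
        for met in recon.metabolites.values():
            assert met.id == f"{met.name}_{met.compartment}"

    def test_bit_reproducible(self):
        a, _ = synth.gen_reconstruction(seed=5)
        b, _ = synth.gen_reconstruction(seed=5)
        assert a.reactions == b.reactions and a.metabolites == b.metabolites


class TestGenOmegaTable:
    def test_sample_sizes_exact(self):
        table, truth = synth.gen_omega_table(
            {
                "A": ("weibull", (2.0, 0.13), 1190),
                "B": ("weibull", (2.0, 0.15), 12738),
            },
            seed=2,
        )
        assert (table.group == "A").sum() == 1190
        assert (table.group == "B").sum() == 12738
        assert (table.omega > 0).all()
        assert truth.group_params["A"] == ("weibull", (2.0, 0.13))

    def test_unknown_family_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_omega_table({"A": ("zeta", (1.0,), 10)})

    def test_tiny_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_omega_table({"A": ("gamma", (2.0, 0.1), 1)})


@pytest.fixture(scope="module")
def omega_table():
    table, _ = synth.gen_omega_table(
        {"all": ("weibull", (2.0, 0.14), 4000)}, seed=1
    )
    return table


class TestGenExpression:

    def test_uncoupled_expression_uncorrelated(self, omega_table):
        expr = synth.gen_expression(10, 0.0, omega_table, seed=2)
        r = evostats.correlate(
            expr.max(axis=1).to_numpy(), omega_table.omega.to_numpy()
        )
        assert abs(r.statistic) < 0.05

    def test_negative_coupling_recovered(self, omega_table):
        expr = synth.gen_expression(10, -0.5, omega_table, seed=3)
        r = evostats.correlate(
            expr.max(axis=1).to_numpy(), omega_table.omega.to_numpy()
        )
        assert r.statistic == pytest.approx(-0.5, abs=0.1)

    def test_single_tissue_max_is_the_value(self, omega_table):
        expr = synth.gen_expression(1, -0.2, omega_table, seed=4)
        assert expr.shape[1] == 1
        assert (expr >= 0).all().all()

    def test_invalid_coupling_rejected(self, omega_table):
        with pytest.raises(InvalidParameterError):
            synth.gen_expression(5, -1.5, omega_table)

    def test_values_nonnegative(self, omega_table):
        expr = synth.gen_expression(19, -0.3, omega_table, seed=5)
        assert (expr.to_numpy() >= 0).all()
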