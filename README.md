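# metaboconstraint

Selective constraint on mammalian enzyme-coding genes versus their position
in the metabolic network, their cellular compartment, and their expression
level — as a tested, reusable pipeline.

## The scientific problem

The ratio of nonsynonymous to synonymous substitution rates, ω = Ka/Ks,
measures the purifying selection acting on a protein-coding gene: ω near 0
means strong constraint, ω > 1 directional selection. Work in bacteria,
yeast and *Drosophila* suggests that an enzyme's importance in the metabolic
network (its degree or betweenness centrality in a reaction graph) predicts
its constraint. Testing this in mammals requires a chain of non-trivial
steps, each implemented here as a separate module:

1. **`orthology`** — synteny-propagating ortholog identification across
   eight mammal genomes (human anchor plus chimpanzee, macaque, mouse, rat,
   horse, dog, cow). Homology hits are filtered by E-value and identity,
   tandem duplicates collapse into single loci, unique reciprocal hits with
   Ks below a ceiling seed ortholog pairs, and orthology then propagates
   along chromosomes: homologous immediate neighbors of an accepted pair
   become a pair themselves, their other homology edges are deleted, and
   one-to-one seeding repeats until convergence.
2. **`alignment_qc`** — protein alignments must have all pairwise identities
   ≥ 40%; offenders are removed guided by consensus identity, gap columns
   stripped, alignments shorter than 50 columns lose their worst row and are
   realigned; sets keep at least 6 of their 8 taxa or are rejected.
3. **`constraint`** — codon-preserving back-translation and ω estimation.
   The built-in estimator is pairwise Nei–Gojobori-style counting
   (equal-weight pathway averaging, Jukes–Cantor correction, ω pooled as
   mean Ka / mean Ks over taxon pairs); an adapter for external
   `codeml` (PAML models M0, M1a, M2a) preserves the maximum-likelihood
   route where the binary is available. A gene is called positively
   selected when 2·(lnL_M2a − lnL_M1a) > 5.99 (χ², 2 df, P < 0.05).
4. **`metabolic_network`** — reaction-node graphs from a compartmentalized
   SBML reconstruction: reactions sharing a compartment-specific metabolite
   are joined unless both are irreversible and the metabolite lies on the
   same side of each; transport reactions (reactants and products in
   different compartments) form their own category.
5. **`modularity_currency`** — currency metabolites (H⁺, ATP, water …)
   spuriously link unrelated reactions. They are identified structurally:
   metabolites are removed in order of edge frequency and the effective
   modularity ΔQ = Q − mean Q(rewired graphs) is tracked; the removal count
   maximizing ΔQ defines the currency set.
6. **`evostats`** — the statistical battery: ML distribution fits with Q-Q
   ranking, shared-vs-separate two-group likelihood-ratio tests, subsampling
   bootstraps on means, Mann-Whitney U (exact by enumeration for small
   tie-free samples), 2×2 χ², UPGMA clustering of compartments by mean ω
   with nested comparisons, and Pearson/Spearman correlations.
7. **`synthetic_data`** — generates every input with known planted truth
   (orthologs, tandem arrays, currency metabolites, true ω, group
   distribution parameters) so each stage is verifiable end to end without
   downloads.
8. **`pipeline`** — seeded, config-driven orchestration of all stages with
   per-stage TSV outputs and a byte-reproducible `summary.json`.

## Worked example

```python
from metaboconstraint import synthetic_data as synth, constraint
from metaboconstraint import modularity_currency as mc
import numpy as np

# recover omega from codon alignments simulated on the 8-taxon mammal tree
alns, truth = synth.gen_codon_alignments(omega=0.1, kappa=1.0,
                                         n_sets=50, n_codons=500, seed=11)
estimates = [constraint.ng86_omega(a).omega for a in alns]
print(round(float(np.median(estimates)), 4))        # 0.0964

# recover planted currency metabolites by effective-modularity maximization
recon, truth = synth.gen_reconstruction(n_currency=3, currency_coverage=0.8,
                                        seed=8)
traj = mc.currency_scan(recon, "noncompartmentalized",
                        max_removals=5, n_random=30, seed=8)
print(traj.argmax_step, sorted(traj.removed_set))   # 3 ['cur0', 'cur1', 'cur2']
```

The first number is the median counting-estimator ω over 50 simulated
500-codon ortholog sets whose true ω was 0.1 — within 4% of truth. The
second line shows the ΔQ trajectory peaking after exactly the three planted
currency compounds have been removed.

The same analyses run from the shell:

```bash
metaboconstraint simulate reconstruction --seed 8 --out-dir demo/
metaboconstraint currency --sbml demo/reconstruction.xml \
    --variant noncompartmentalized --n-random 50 --seed 8 --out demo/traj.tsv
metaboconstraint run --seed 42 --out-dir demo/full_run/
```

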