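# Methods

This note records the models, conventions and design choices behind the
package, the way a simulation or statistics library documents itself. The
numbers quoted are computed by the test suite and `scripts/acceptance.py`;
nothing here states a result the code does not reproduce.

## Orthology identification

Gene order and pairwise homology hits (E-value, amino-acid identity, Ks)
are the inputs; the algorithm never runs a homology search itself.
Filter thresholds follow divergence: E ≤ 1e-10 and identity ≥ 50% for the
close primate comparisons (human vs chimpanzee or macaque), E ≤ 1e-9 and
identity ≥ 45% otherwise; the Ks ceiling for seeding is 0.5 (primates) or
0.75. Filters are applied once, up front; edge deletion during propagation
does not re-trigger them.

Conventions where the procedure is underdetermined:

- **Tandem collapsing** merges maximal runs of immediately adjacent,
  pairwise-homologous genes transitively; the lowest-position gene
  represents the locus and positions are renumbered contiguously.
- **Immediate neighbor** means ordinal distance 1 on the same chromosome
  after collapsing; chromosome ends have a single neighbor.
- **Propagation order**: anchors are scanned in ascending (chromosome,
  position) of the first-genome gene. Conflicts within a sweep (one gene
  proposed for two partners) resolve first-come; later proposals are
  dropped. The deleted-edge set never includes an edge underlying an
  accepted pair.
- **Multi-genome sets** are anchor-centric: pairwise runs of the anchor
  genome against each companion, joined on the anchor gene; anchor genes
  with orthologs in fewer than 5 companion genomes are excluded, so sets
  have 6–8 members with seven companions.

## Alignment quality control

The QC loop aligns, removes rows while any pair identity falls below the
floor (0.40), strips gap columns, and — if fewer than 50 columns remain —
drops the worst row and realigns the *original* sequences, rejecting once
fewer than 6 rows would remain. Percent identity uses as denominator the
columns where neither sequence is gapped, making it insensitive to
alignment padding. The consensus is the per-column plurality residue, gaps
not voting, ties broken alphabetically. "Gap column" means any column with
at least one gap, because the downstream codon counting needs gap-free
columns.

The aligner is a pluggable contract. The built-in center-star progressive
aligner (BLOSUM62, gap open −11 / extend −1, center chosen by summed
pairwise score, merged under once-a-gap-always-a-gap) keeps the test suite
free of external binaries and is adequate for the closely related ortholog
sets this pipeline targets; adapters for MUSCLE or MAFFT binaries are
provided for production alignments of deeply diverged sets.

## Selective constraint (ω)

The built-in estimator is pairwise counting in the Nei–Gojobori style:
synonymous site counts per codon give changes to stop codons nonsynonymous
status; differences between codons differing at multiple positions are
averaged over all substitution orders with equal weight, excluding pathways
through stop codons unless all pathways are blocked. Proportions are
Jukes–Cantor corrected (flagged saturated at p ≥ 3/4) and ω is pooled as
mean(Ka)/mean(Ks) over all taxon pairs; a record is flagged undefined when
pooled Ks is 0, e.g. identical sequences. Ambiguous codons are ineligible
per pair. The estimator is invariant to row order and taxon labels.

Genome-scale maximum-likelihood fits are out of desk-scale reach, so the
counting estimator is the built-in route and a `codeml` (PAML) adapter —
control-file writer, sequential-PHYLIP writer, output parser — preserves
the ML route (M0 single-ω; M1a/M2a for positive selection) when the binary
exists. The positive-selection call is strict:
2·(lnL_M2a − lnL_M1a) > 5.99, the χ² 95th percentile at 2 df; negative
differences are optimizer anomalies and yield "no positive selection" with
a warning. Run options beyond the model choice are exposed as a config dict
with codeml defaults.

One subtlety the tests document: under simulation at ω = 0 the leaf
*proteins* are identical, but equal-weight pathway averaging can attribute
a small nonsynonymous fraction to codons hit by two synonymous
substitutions (an alternative pathway passes through a different amino
acid), so the counting Ka is near-zero (≈3e-4 at mammalian divergences)
rather than exactly zero.

## The codon simulator

Sequences evolve on a fixed eight-taxon eutherian tree
(((((human, chimpanzee), macaque), (mouse, rat)), ((horse, dog), cow)))
under a Goldman–Yang-style 61-state process with equal codon frequencies:
single-nucleotide codon changes have rate κ for transitions and factor ω
for nonsynonymous changes, the matrix scaled so a branch length of 1 equals
one expected substitution per codon. Branch lengths are set to roughly
mammalian relative divergences (human–mouse path ≈ 0.5 substitutions per
codon ≈ 0.17 per site), deep enough for informative Ks yet far from
saturation. Per-branch transition matrices are matrix exponentials, cached
by branch length. Root codons are uniform over the 61 sense codons; no
indels or rate variation among sites are simulated. Recovery under these
conditions: the counting estimator's median over 50 sets of 500 codons is
within 5–10% of the simulated ω at both ω = 0.1 and ω = 1.0 (the
acceptance bound is 25%).

## Reaction graphs

Reactions are nodes. A compartment-specific metabolite shared by two
reactions supports an edge unless both reactions are irreversible and the
metabolite is a substrate in both or a product in both ("semi-directed":
direction filters edge support, but the final graph is undirected because
degree, betweenness and the rewiring null all operate on a simple
undirected graph). Multiple supporting metabolites collapse to one edge
whose supporting set is retained — it is what the currency scan counts. A
metabolite on both sides of one reaction creates no self-edge. Transport
reactions (reactant and product compartments differ) form their own
category among the nine compartment labels. Betweenness is Brandes'
algorithm (networkx), reported unnormalized as the per-node sum over
endpoint pairs of the fraction of shortest paths through the node, and is
checked exactly against a brute-force all-shortest-paths enumeration.

SBML I/O is Level 2 via libsbml; species flagged as boundary are ignored
and gene associations are read from `GENE_ASSOCIATION` notes.

## Modularity and currency metabolites

Newman's Q = Σᵢ(eᵢᵢ/m − aᵢ²) scores a partition. Community detection is
greedy agglomeration (Clauset–Newman–Moore) through igraph's C
implementation; when no subdivision beats the single community the trivial
partition (Q = 0) is returned. The null model is degree-preserving
double-edge swapping with 10× the edge count attempted swaps per null
graph; swaps creating self-loops or parallel edges are skipped, so node
set, edge count and degree sequence are preserved exactly. Effective
modularity ΔQ is Q minus the mean Q of `n_random` rewired copies
(default 1000; the simulation studies use 50, which keeps the null-mean
standard error near 0.003 — small against the ΔQ signal).

The currency scan removes the currently most edge-frequent metabolite
(frequency = number of edges whose supporting set includes it, re-ranked
after every removal; ties break lexicographically), rebuilds the graph and
records ΔQ; the full trajectory is scanned to `max_removals` and the
argmax taken afterwards, rather than stopping at the first dip, because
trajectories show local dips. Null graphs are regenerated (seeded) at every
step. Three variants: compartmentalized (metabolite instances distinct per
compartment), noncompartmentalized (instances merged by compound name), and
per-compartment (each non-transport compartment's sub-reconstruction
scanned separately).

## The synthetic reconstruction

Each compartment holds a fixed number of modules; a module's reactions are
chained by private metabolites and densified by one module-hub metabolite
joined to every reaction, with hub side and reversibility alternating
deterministically so all modules are structurally identical
(degree-balanced). That balance matters: with randomly attached hubs,
trimming the largest-degree module could genuinely *raise* Q, blurring the
ΔQ peak. Currency compounds exist as one instance per compartment and
attach to an exact fraction (default 0.8) of each compartment's reactions
on a random side; truth records their base names, so recovery is scored
with the noncompartmentalized scan, the variant able to remove a compound
across all compartments at once. Transport reactions link module
metabolites of two random compartments. Under the default conditions
(4 compartments × 3 modules × 6 reactions, 3 currency compounds) the scan
recovers exactly the planted set at the trajectory argmax in 30/30 probe
seeds, and with no planted currency the argmax sits at zero removals.

What the generator does not emulate: realistic stoichiometric
coefficients, genome-scale reaction counts, hub-degree heterogeneity of
real metabolism (H⁺ alone supports half the edges in a real
reconstruction), or shared isoenzymes across compartments. Passing
recovery tests therefore demonstrates the scan's correctness, not its
behavior on genome-scale networks, where peaks are broader and igraph
tie-breaking may shift the argmax by small counts.

## Statistics

- **Distribution fitting** is maximum likelihood via scipy (Nelder-Mead
  style numerical optimization for multi-parameter families; the
  exponential rate is the closed-form 1/mean). Positive-support families
  (Weibull, gamma, exponential, log-normal) fix location at 0 and require
  positive data. The free-parameter counts are Weibull/gamma/logistic/
  normal/log-normal/Cauchy 2, exponential 1, and 3 for the generalized
  extreme value. Fit quality is ranked by the Pearson correlation between
  theoretical quantiles at plotting positions (i − 0.5)/n and the sorted
  data; ties break by log-likelihood so the top family is unique.
- **Two-group LRT**: the null pools both groups into one fit, the
  alternative fits each separately; 2·(lnL_x + lnL_y − lnL_pooled) is
  referred to χ² with k degrees of freedom (k = the family's parameter
  count). Type-I error at α = 0.05 is calibrated within the binomial 99%
  band over 1000 null replicates, and Weibull scale 0.13 vs 0.15 at group
  sizes 1190/12738 rejects at α = 1e-6 in 20/20 seeds.
- **Bootstraps** sample *without* replacement within a replicate
  (subsampling from a finite gene set; a with-replacement switch exists)
  and report p = (count at-or-beyond + 1)/(n_reps + 1), so "no case as
  extreme" over 1e6 replicates reports p < 1e-6.
- **Mann-Whitney U** is exact by full enumeration when the combined sample
  is ≤ 12 and tie-free (verified identical to an independent exact
  implementation), otherwise the normal approximation with tie correction.
- **UPGMA compartment clustering** uses average linkage on absolute
  differences of group mean ω, labels sorted for determinism. Tests then
  walk the merges from the leaves: one two-sided Mann-Whitney per internal
  node between the pooled raw values of its child clades — g − 1
  comparisons for g groups instead of all pairs — each flagged at α = 0.01.
  Pooled raw values (not means of means) are used because the rank test
  needs samples.
- **Correlations** are Pearson or Spearman (average ranks on ties) with
  two-sided p; betweenness is log10-transformed for the Pearson variant,
  restricted to nodes with positive betweenness.

## Synthetic ω and expression tables

Group ω values are drawn from named families; the two-group study
conditions are Weibull(shape 2, scale 0.13) for the metabolic group versus
Weibull(2, 0.15) for the rest at sizes 1190 and 12738 — scales chosen so
group means sit near the 0.13/0.15 region of the ω scale with the
right-skewed shape such data show. Expression matrices couple the per-gene
maximum to ω through Gaussian scores of the ω ranks mixed with independent
noise at the requested correlation; remaining tissue values are uniform
fractions of the maximum. The default pipeline coupling is −0.1, a weak
negative association.

## Pipeline and reproducibility

`run_all` derives one sub-seed per stage from the master seed, writes
per-stage TSVs and a `summary.json` carrying the seed and a SHA-256 hash of
the configuration; identical configs produce byte-identical summaries. The
desk-scale defaults (80 genes per genome pair, 10 demo codon sets,
4-compartment reconstruction, 2000 bootstrap replicates, 30 rewired nulls)
complete in a few seconds; all sizes are configuration, chosen to keep the
full battery interactive while remaining large enough for every test's
tolerance.

## Known limitations

- The built-in ω estimator is a counting method; it ignores transition/
  transversion bias in site counting (κ enters only the simulator), codon
  frequency bias, and among-site rate variation. The codeml adapter is the
  fidelity route.
- The center-star aligner has no iterative refinement; deep divergences
  should use the MAFFT/MUSCLE adapters.
- Greedy modularity is a heuristic; argmax positions on large real networks
  can shift by small counts between implementations.
- The orthology module handles a single rearrangement-free gene order per
  chromosome and does not reconcile paralog trees.
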