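# Methods

This note documents the models and procedures `myconet` implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical choices that matter for reproducibility.

## The analysis chain

### Rarefaction and alpha diversity

Samples are subsampled **without replacement** to a common depth
(`multivariate_hypergeometric`), default the minimum column sum. Samples
shallower than the requested depth are dropped with a logged warning, never
kept silently. Chao1 uses the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))`, which stays defined when a sample has no
doubletons; Shannon uses natural logarithms (the convention of the common R
ecology tooling). Consequences asserted in tests: Chao1 ≥ observed richness
with equality iff F1 ≤ 1; Shannon ≤ ln(richness) with equality iff uniform.

### Ordination and group separation

Bray–Curtis dissimilarity `BC_jk = Σ|x_ij − x_ik| / Σ(x_ij + x_ik)` on
counts; a pair of all-zero samples is defined as distance 0 with a warning.
PCoA is classical metric scaling: double-centre −½D², eigendecompose, order
axes by descending eigenvalue, report proportion explained over the positive
eigenvalues only. The sign of each axis is fixed by making its first
non-zero loading positive, so coordinates are bit-reproducible; the axis
pair to plot is the caller's choice. PERMANOVA partitions the squared
distances into among- and within-group sums (one-way, unrestricted label
permutations — the split-plot structure of a field layout is deliberately
not modelled, matching how such tests are usually reported), with
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` and a seeded permutation
stream. Note a degenerate corner: with internally identical, fully separated
groups, F = ∞ and every partition-preserving permutation ties, so the
attainable minimum p is the fraction of such permutations, not
1/(1 + n_perm).

### Guilds

Guild assignment is a longest-match lookup: reference patterns are
rank-prefixed lineage fragments (`g__Mortierella`, `f__Nectriaceae`, …) and
a more specific rank always beats a less specific one (species > genus >
family > order > class > phylum > kingdom). Unmatched or malformed lineages
become `Unassigned`, so per-sample guild proportions plus `Unassigned` sum
to one. The bundled `FIXTURE_GUILD_REFERENCE` maps six common rhizosphere
genera to plausible guilds for tests and examples only — it is a synthetic
fixture, not curated biology; real analyses must supply their own reference.
Confidence grades of database-driven guild predictors are out of scope.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤10 tie-free observations (so the n=4 vs 4
fully separated case gives exactly p = 2/70), normal approximation with tie
correction otherwise.

### Co-occurrence networks

Within each treatment group, taxa are pre-filtered (default: present in
≥50% of the group's samples and mean relative abundance ≥ 1e−4 — the
filtering step is a practical necessity the analysis exposes explicitly),
then all pairwise Spearman correlations are computed (average ranks, Pearson
on ranks). P-values use the t approximation with n−2 degrees of freedom;
exact permutation enumeration is available for n ≤ 9 samples and is the
default for n ≤ 7 (beyond that, n! is prohibitive and the t approximation
is adequate). Zero-variance taxa make a pair untestable: such pairs are
excluded from the Bonferroni factor m (counting them would inflate the
correction arbitrarily) and logged. An edge requires |ρ| > 0.8 **and**
Bonferroni-corrected p < 0.05; isolated taxa are dropped, so node counts
mean "connected taxa".

**Power note.** The joint gate is severe: at n = 15 samples with m ≈ 10³
pairs it only admits observed |ρ| ≳ 0.87, and at n = 4–6 (common field
replication) *no* pair can pass. Synthetic replication defaults to 15 per
group for exactly this reason; users of the defaults should treat n as a
power parameter, not a formality.

### Topology panel

Average degree 2E/N and density 2E/(N(N−1)) by closed form; mean local
clustering with C_i = 0 for degree < 2; characteristic path length and
diameter on the largest connected component, reported **both raw (hops) and
normalised by node count** — published tables sometimes print sub-1 values
for these metrics, which are only interpretable as normalised, so both
conventions are emitted and the reporting choice is explicit. Modularity is
Q of the Clauset–Newman–Moore greedy partition computed on a
sorted-node-order copy of the graph: determinism was preferred over the
marginal Q gains of stochastic methods. Q ∈ [−0.5, 1] always.

### Cohesion and the stability ratio

For samples i and taxa j with relative abundances a_ij:

1. observed pairwise correlations r_jk across samples (Pearson on relative
   abundances by default — the convention of the cohesion literature;
   Spearman available to mirror the network stage);
2. a null expectation E₀[r_jk] from B randomisations in which **every
   taxon's abundance vector is independently permuted across samples**; for
   any pair this induces the same null as permuting one member, it is
   symmetric in (j,k), and it vectorises;
3. corrected correlations r′ = r − E₀[r], removing abundance- and
   compositionally-driven baseline correlation;
4. connectedness⁺(j) = mean of the positive r′_jk (0 if none), and
   connectedness⁻(j) likewise over the negative values;
5. cohesion⁺(i) = Σ_j a_ij · connectedness⁺(j) ≥ 0, cohesion⁻(i) ≤ 0
   analogously; stability ratio = |cohesion⁻| / cohesion⁺ per sample
   (undefined and flagged when cohesion⁺ ≤ 0).

Default B = 200 null iterations. Monte-Carlo convergence: on the standard
fixture (45 samples × 40 taxa) doubling B moves r′ by ~0.013 RMS; at n = 15
samples the same check gives ~0.024, because the permutation-null dispersion
scales as n^{−1/2} — with few samples, raise B and expect a noisier ratio.
A corrected-correlation noise floor of order E|r_null| remains in
connectedness at any B; it shrinks with replication, not with null
iterations, so with independent taxa the ratio tends to 1 in distribution
(positive and negative parts are symmetric) rather than to 0.

### Robustness

Remove ⌊fraction·N⌋ nodes (default 50%), either uniformly at random
(replicated, seeded) or in descending degree order with ties broken by node
id (deterministic, one replicate). The default metric is the size of the
largest connected component divided by the number of *surviving* nodes.
**Caveat:** that normalisation has a small-graph floor (an edgeless
five-node remnant still scores 1/5), which inflates tiny sparse networks and
makes cross-network comparison misleading at small scale; for comparing
differently sized networks the alternative metric, natural connectivity
ln(mean eᵏ) over adjacency eigenvalues k, is recommended and is what the
end-to-end ordering checks use. "Targeted" means degree-ordered — the
cheapest defensible reading; betweenness ordering would cost more and is
not implemented.

### Guild–stability link

Pearson R (with two-sided p) between each guild's relative abundance and
the per-sample stability ratio, pooled over groups and aligned strictly by
sample id. Pearson because the association is reported as a fitted line
with R; a Spearman option exists for consistency with the rank-based tests
elsewhere. Constant guilds are flagged, not dropped. Per-sample ratios (not
per-network values broadcast to samples) are the default x-variable.

### Reporting statistics

Significance stars: `*` p<0.05, `**` p<0.01, `***` p<0.001, `****`
p<0.0001, `ns` otherwise, strict inequalities (p = 0.05 is ns). The
multi-group path is Kruskal–Wallis (tie-corrected) followed by pairwise
comparisons: the table carries both Holm-adjusted Dunn z-tests and the
rank-scale Fisher-LSD t-tests; the compact letter display is built from the
LSD family, protected by a significant omnibus test. Rationale: at n = 4–6
replication the Dunn+Holm family cannot separate any pair (adjacent-group
z ≈ 1.6 even under complete separation), whereas the protected rank-LSD —
the procedure behind the letter displays of the standard R agronomy tooling
— separates fully distinct groups. Letters are assigned by greedy
insert-and-absorb with ties broken by group order.

## The synthetic generator

`SimulationDesign` draws, per dataset:

* per-taxon lognormal baseline abundances (μ = 0, σ = `baseline_sigma`,
  default 1.5 — a typical ITS rank-abundance skew);
* planted modules: the first `n_modules × module_size` taxa form blocks; in
  a sample, block members share a latent factor with loading √s (s =
  `module_strength`), giving within-block latent correlation exactly s at
  any block count (a latent-factor construction is positive-definite by
  construction, unlike hand-built covariance matrices). A fraction
  `anti_fraction` of each block loads negatively, planting the
  anti-correlated pairs the cohesion analysis measures — without them a
  design could never move the negative:positive ratio;
* per-group guild reweighting: taxa carry guild labels sampled from the
  average design mix; each group's expected guild shares are rescaled to its
  `guild_mix` row exactly;
* multinomial sampling at `sequencing_depth` per sample, so column sums are
  exact and the data are compositional.

`module_strength`, `anti_fraction`, `guild_mix` and `active_modules` accept
per-group values, which is how treatment effects are planted. A master seed
spawns named substreams (baseline / guilds / factors / sampling), so the
whole dataset is bit-reproducible and stages can be re-run independently.

`plant_group_effect` scales one guild's expected relative abundance in one
group by a fold f and redraws those samples at their original depth. After
renormalisation the *proportion* ratio is f/(1−(1−f)p₀), not f — but the
per-sample odds shift by exactly f, so fold recovery is estimated on the
log-odds scale (geometric-mean odds ratio), which is exact in expectation
and robust to the heavy right tail of the odds.

**What the generator does not emulate:** read-level noise, chimeras,
taxonomy-classifier error, spatial/temporal autocorrelation between
replicates, and genuinely compositional interactions (the planted
correlations live on latent abundances; closure effects enter only through
the multinomial). Passing tests therefore demonstrate that the *algorithms*
recover planted statistical structure under realistic depth and skew — not
that any particular field result is correct.

### Standard fixture

`treatment_effect_design()` (seed 0 is the committed reference dataset) uses
40 taxa, all inside 4 modules of 10, 15 replicates per group at depth 10⁴,
`baseline_sigma = 0.8`, and plants: CK s = 0.93 / anti 0.35, CF s = 0.98 /
anti 0.50, BF s = 0.80 / anti 0.0, with saprotrophs and symbiotrophs
depleted in the BF mix. The choices are power-driven: module taxa dominate
so cohesion responds to planted structure rather than the noise floor; the
three strengths straddle the edge-gate detection boundary at n = 15 so the
edge ordering CF > CK > BF is structural; BF keeps *positive* structure
(strong but sub-threshold) because a low |C⁻|/C⁺ ratio requires genuine
positive cohesion, not absence of signal. Module recovery uses a graph
thresholded at |ρ| > 0.6 without multiplicity gating — recovering planted
blocks is a different task from controlling false edges, and the full
reporting gate cannot see blocks planted near strength 0.8 at n = 15.

## Problem sizes used by the test-suite and acceptance script

Simulations run at desk scale by design: 10–60 taxa, 4–30 replicates per
group, depths 2–10 × 10³, 500 PERMANOVA null datasets with 199 permutations,
50-seed recovery loops, 20-graph robustness sweeps. The full suite runs in
well under a minute; these sizes were chosen as the smallest at which every
property is comfortably identified.

## Known limitations

* Plain Spearman on rarefied relative abundances is not
  compositionally-aware; SparCC/SPIEC-EASI-style corrections are explicit
  non-goals.
* The Bonferroni-gated 0.8 threshold makes edge discovery a function of
  replication; networks from different n are not comparable.
* Cohesion's positive/negative split inherits a replication-dependent noise
  floor (see above); comparing ratios across groups is safe, comparing
  absolute ratios across studies with different n is not.
* The robustness giant-component metric is survivor-normalised per the
  common convention and is scale-sensitive; use natural connectivity for
  cross-network claims.
* Phylogenetic diversity metrics, keystone/Zi-Pi analyses and figure
  rendering are out of scope.
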