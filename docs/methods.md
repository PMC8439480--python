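# Methods

## The conservation statistic

For a CpG with k beta-value measurements A₁…A_k, the pairwise difference is
PWD = (1/C(k,2)) Σ_{i<j} |A_i − A_j| ∈ [0, 1]. It is permutation-invariant,
reduces to |A₁ − A₂| at k = 2, is invariant under adding a constant to all
measurements and scales linearly under multiplication — properties the test
suite checks against a brute-force all-pairs oracle. A gene's PWD is the
*unweighted* mean over its annotated CpG sites (not pair-count-weighted);
a multimapped CpG contributes to every gene it is annotated to.

Missing beta values are dropped per CpG: a CpG needs at least two
non-missing measurements within a comparison group to contribute, and a
gene with no computable CpG is omitted rather than reported as 0.

**Grouped designs.** When replicates are nested in groups (four crypts per
individual, replicate pairs per cell line), the gene PWD is computed within
each group and then averaged across groups with equal weights. Pooling all
samples into one comparison would conflate between-group (e.g.
inter-individual) differences with within-group drift, which is the
quantity of interest; a `pooled` strategy is retained for sensitivity
analysis. A group of 4 samples and a group of 2 contribute equally.

## Essentiality and classifier diagnostics

A gene is essential when its mean gene-effect score (log-fold proliferation
change after disruption, averaged over selected cell lines, missing scores
skipped) is strictly below −0.4. Conservation is evaluated as a classifier
via predicted-essential = (gene PWD < cutoff), strict, at cutoffs 0.05 /
0.10 / 0.15 by default, over the intersection of genes that have both a PWD
and an essentiality call. Sensitivity, specificity, PPV and NPV are
reported with their defining count fractions; percentages round half-up to
one decimal; a zero denominator yields "undefined" (NaN), never 0. Both
cutoffs use strict inequality, so a gene exactly at the boundary is called
negative. Raising the PWD cutoff can only add predicted positives, so
sensitivity is non-decreasing and specificity non-increasing in the cutoff
(a property test enforces this).

Class comparisons use Welch's unequal-variances t-test (two-sided,
α = 0.05), implemented from the formula with Welch–Satterthwaite degrees of
freedom and cross-checked against SciPy to 1e−10. Trend tests are Pearson
correlations of mean gene PWD against time, likewise written out and
cross-checked; a constant series has an undefined r. Two-sided p-values are
used uniformly, including for directional recovery claims, to keep one
convention throughout.

## Tissue comparison

A gene is preferentially conserved in tissue A when PWD_A < 0.05 and
PWD_B > 0.1 (configurable). The pair (0.05, 0.1) matches the cutoffs used
everywhere else in the package; a "conserved" bound as high as 0.5 would
label nearly every gene conserved and make the call uninformative. The
rule is antisymmetric in the two tissues, and tightening the conserved
bound can only shrink the called set. Gene-family enrichment is left to
the user; the package only tags symbols by prefix (e.g. HOXA, HOXB).

## Drug-sensitivity correlation

Per cell line, target-gene conservation is the PWD between the line's
replicate samples. Across lines, Pearson r is computed between target-gene
PWD and drug sensitivity per (drug, target) pair — multi-target drugs give
one row per target — requiring at least 3 lines with both values. Both
axes are oriented negative-is-more (conserved / sensitive), so positive r
means conservation tracks sensitivity. z-scoring is applied for reporting
and plotting; Pearson r is invariant under it (tested). p-values are
two-sided and uncorrected.

## The simulator

The generative model is a haploid Wright–Fisher population of `n_cells`
cells, each carrying a binary methylation state at
`n_genes × cpgs_per_gene` CpG sites. Per generation:

1. **Drift:** every site of every cell flips with probability ε
   (`error_rate`), a symmetric two-state replication-error model.
2. **Selection:** cell fitness w = exp(−s·h), where h is the Hamming
   distance between the cell's essential sites and the optimum
   configuration (essential genes are the first `essential_fraction` of
   genes; the optimum is fully methylated by default so a demethylating
   shock is deleterious). Multiplicative and always positive; the simplest
   monotone penalty for a disrupted essential epigenome.
3. **Reproduction:** constant-size resampling with probabilities
   proportional to fitness.

Measurement reports the per-site methylated fraction plus Gaussian noise
(sd `measurement_noise_sd`), truncated to [0, 1] — an array-style beta
value. A demethylating shock switches each methylated site of each cell
off with probability `shock_prob`, emulating transient exposure to a
hypomethylating agent.

**Neutral closed form.** For two populations split from a clonal founder t
generations ago, the expected cell-level cross-population PWD (mean
mismatch over cross pairs of cells; for binary states |a−b| is a mismatch
indicator, so this is f_a + f_b − 2 f_a f_b per site) equals
½(1 − (1−2ε)^(2t)) *exactly*, for any population size: every cross pair of
lineages is separated by exactly 2t independent flip opportunities because
the populations were identical at the split. This is the quantity
`cross_population_pwd` computes and the acceptance check compares against
the closed form (within 3 Monte-Carlo standard errors over sites). Note
that the *beta-level* statistic |f_a − f_b| is a different quantity — it
shrinks toward 0 as n_cells → ∞ under neutrality because both fractions
concentrate on the same deterministic trajectory — so the closed form is
checked at the cell level, where it is exact.

**Default configuration** (chosen once; minutes on one CPU): 200 cells,
100 genes × 5 CpGs, 20% essential, ε = 0.002 per site per generation,
s = 2, 500 generations, measurement noise sd 0.005, 3 replicates. Time is
measured in generations; sample sheets map generations to months at 25
divisions/month (≈1/day in culture), so the clonal checkpoints 62/350/500
correspond to ≈2.5/14/20 months. The shock scenario burns in 100
generations, shocks with d = 0.5 and measures control/treated pairs at
days 5/15/30/50/68 (one generation per day). The drug panel uses smaller
per-line populations (60 cells, 30 genes × 3 CpGs, 30 lines with
divergence times spread over 30–230 generations): a panel needs many
independent lines, and per-line population detail adds cost without
changing the cross-line correlation structure under study. Sensitivity
scores are constructed as effect·z(target divergence) + √(1−effect²)·noise,
so the planted Pearson correlation equals the effect size in expectation
and effect 0 is an exact null.

All randomness descends from a single seed through spawned child streams:
identical configuration ⇒ bit-identical outputs.

### What the simulator does and does not emulate

It reproduces the mechanistic skeleton: clonal founding, gradual
divergence of replicate populations, selective pinning of essential-gene
methylation, shock-then-recovery under selection, and an r-shaped gene-PWD
distribution (most essential genes near 0, a long non-essential tail). It
does **not** model: maintenance/de-novo methyltransferase kinetics or
hemimethylation; correlated errors along a chromosome; probe-specific
array artefacts; cell-type mixtures within a sample; or active global
remethylation after a shock. Consequently, after a shock only genes under
selection are driven back toward the control configuration — non-essential
genes recover only through the slow symmetric-flip reversion toward
equilibrium and keep drifting, so the per-class recovery trend is reliably
negative for the essential class and for the all-genes average, but not
for the non-essential class on its own. Real tissue data show weak
recovery of non-essential genes too, presumably via remethylation
machinery this model omits. Passing tests on synthetic data therefore
demonstrate that the pipeline detects the drift/selection signal when the
mechanism is as modelled, not that real arrays behave this simply.

## Numerical choices and degenerate inputs

* PWD pair sums use the sorted-order identity Σ_{i<j}|x_i−x_j| =
  Σ_i (2i−k−1)x_(i) (O(k log k), matches brute force to ≤1e−12).
* Histogram bins are right-open with the final bin closed at 1.0.
* Percentages round half-up (0.05 → 0.1), matching printed diagnostic
  tables; internal comparisons always use the unrounded proportions.
* Undefined statistics (constant input to z-score or Pearson, zero
  denominators) propagate as NaN with a flag, never as 0.
* Selection weights subtract the minimum Hamming distance before
  exponentiating, so fitness never underflows even for large s·h.
* Fewer than 2 usable measurements per CpG, empty gene intersections,
  unmatched control/treated pairs and unknown scenario names raise
  descriptive errors rather than producing empty results silently.

## Problem sizes used in checks

The automated checks use the default configuration above; the neutral-drift
check enlarges the population to 1000 cells (drift variance shrinks, the
lineage argument is size-free) and evaluates t = 50/200/500; the
selection-ordering check uses 5 seeds with s = 2 and 10 with s = 0; the
shock-recovery check 5 seeds; the drug panel 10 seeds at effect 0.5 and a
100-seed null at effect 0.

## Known limitations

* The CpG→gene annotation is a required user input; no array manifest is
  bundled and no promoter/gene-body distinction is made.
* Gene symbols are normalized by trim+uppercase only; no alias resolution.
* No beta-value preprocessing (normalization, probe QC, M-values): values
  are consumed as provided.
* The essentiality cutoff (−0.4) and PWD cutoffs are conventions, not
  fitted quantities; drift (ε) and selection (s) defaults are model
  choices, not estimates from real data.
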