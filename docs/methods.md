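# Methods

This note documents the models and numerical choices behind `replicaging`:
what each stage computes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Cohort simulation

Each founder (mother) cell divides through a homogeneous Poisson process.
By default the per-cell rate is drawn from a gamma distribution with mean
0.5 h⁻¹ and CV 0.2 (`rate_cv`), so the replicative-age distribution of the
cohort widens over time — the reason harvests are scheduled geometrically
rather than linearly (`harvest_schedule`, default 12 points from 7.8 h to
72 h). The phrase "cells divide at a random rate following a Poisson
distribution" admits two readings — rate heterogeneity across cells versus
the event process itself — and we expose both: `rate_model="heterogeneous"`
(default; reproduces the widening) and `rate_model="shared"` (pure
counting-process spread, variance equal to the mean).

Mortality is optional and additive: each cell draws a replicative-lifespan
limit from a logistic distribution (default midpoint 34 divisions, scale 5)
and dies — division count frozen — when its count reaches the limit. The
defaults put cohort viability at 72 h near 45%, in the range observed for
column-aged populations whose last harvest still contains roughly
two-fifths viable cells. Both parameters are plain dataclass fields
(`DeathModel`) because the underlying biology (Gompertz-like hazard vs
threshold) is not settled by the data this package targets.

## Ground-truth trajectories and mixed samples

`generate_molecular_truth` plants per-gene protein and transcript
trajectories for three cell types. Mother trajectories are linear in log2
space, `log2 FC(t) = s·u(t)` with `u` time normalized to [0, 1]; the sign
pattern of the protein/transcript slopes defines five archetypes (coupled
up/down, uncoupled protein-up "Q2-type", uncoupled protein-down "Q4-type",
flat). Slope magnitudes are uniform on [0.5, 2.5] log2 units — terminal
two-fold to ~5.7-fold changes, the range where a census at a two-fold
threshold is informative. Daughters are attenuated copies of the mother
trends (default factor 0.5, partial rejuvenation); dead cells carry a
fixed, time-independent lognormal signature. Protein and transcript
baselines share the gene-abundance hierarchy with log-scale correlation
0.78, which puts the young-reference proteome–transcriptome Spearman
correlation near 0.75, the value typical of single-study comparisons.

Complexes are disjoint member sets whose protein slopes are overridden:
"coordinated" complexes share one slope (stoichiometry-loss IQR stays 0),
"drifting" complexes get a fan of slopes from 0.2 to 1.8 (IQR grows
linearly in time, since all trajectories are linear in `t`).

Mixed samples are composition-weighted sums of the pure profiles,
multiplied by unit-mean lognormal noise (`noise_cv`, default 0.10 — chosen
so replicate CVs stay mostly below the 0.3 reproducibility filter).
Protein channels of bead-containing mixes are additionally multiplied by
per-protein bead-loss factors uniform on [0.5, 1]. The default mix design
mirrors the harvest layout: mix 2 mother-enriched (84–99% mothers), mix 3
effluent-like (daughter-dominated), mix 1 intermediate, and a dead
fraction growing linearly to 0.30 at 72 h. Measured compositions can be
perturbed by a Dirichlet resampling about the truth (concentration
configurable), which keeps them on the simplex.

What the generator does **not** emulate: count noise of sequencing,
peptide-level missingness of shotgun proteomics, batch drift between
replicate campaigns, or nonlinear (saturating) trajectories. Passing tests
therefore demonstrate correctness of the algorithms under multiplicative
noise and linear-in-log2 dynamics, not robustness to every artifact of
real data.

## Un-mixing

`unmix_timepoint` performs the exact square solve of `W·a = a_mix` per
gene (`numpy.linalg.solve`), never a constrained fit: negative components
are physically impossible and are *flagged* rather than clamped, because
silently constraining would hide composition errors. A time point whose
composition matrix has condition number above 1e8 is wholly unsolvable.
Early time points without dead cells reduce to a 2×2 (mother, daughter)
system; `unmix_series` switches automatically when the dead column is
numerically zero. Traces with fewer than 5 solved time points are dropped;
remaining gaps are linearly interpolated in time, with boundary gaps
taking the nearest solved value (extrapolation could go negative).
Finalized series are normalized so each time-point column sums to 10⁶.

Error anatomy worth knowing: the accuracy of each un-mixed component is
governed by the corresponding row of `W⁻¹`. Under the aging design the
dead population is never dominant in any mix, so its inverse row is large
and dead-cell estimates are noise-amplified — which is exactly why the
trace-quality rules exist. Mother and daughter rows are well conditioned
(each has a dominant mix) and recover to ~15% average error at 10%
measurement noise. A validation-style design in which each population
dominates one mix (`VALIDATION_WEIGHTS`) recovers all three populations to
~13% average error at the same noise, consistent with the sub-16% accuracy
reported for such validations.

## Preprocessing

* **Bead correction**: factor = mean(without-beads)/mean(with-beads) per
  protein, applied multiplicatively to bead-containing samples before
  un-mixing. Factor-of-means rather than mean-of-factors; with two
  replicates the difference is second order. Tables carry a
  `bead_corrected` flag and refuse double application.
* **Reference standardization**: log2 FC against the first harvest
  (default 7.8 h); the offset between the reference and an unprocessed
  sample is stored as metadata, not applied, so recovery from the loading
  procedure is not mislabeled as aging.
* **Replicate fusion**: LOWESS over the pooled replicate points (span
  0.75), evaluated at the experimental harvest times. Fitting is in linear
  abundance space by default (log-space available via config). Genes with
  fewer than 4 pooled points are unfittable; genes whose fit dips negative
  are removed by default (mirroring the removal of the handful of such
  profiles in practice) or clamped to 1e-6 × the column median when
  `drop_negative_fits=False`.
* **CV filter**: per gene, the CV across replicates at each shared time
  point (sample SD, n−1 denominator), averaged over time; retain CV
  strictly below 0.3. The per-time-point-then-average definition was
  chosen over a pooled-residual definition because it is symmetric in the
  replicates and insensitive to the trend itself.

## Coupling statistics

Quadrant assignment is by strict fold-change signs; exact zeros sit on an
axis and are excluded from quadrant fractions (with their count reported)
— immaterial for continuous data, but it makes the invariant "fractions
sum to 1" exact. Overabundance quadrant sums group genes by their
final-time assignment so the per-quadrant curves partition the total at
every time point. The two-fold census counts a gene as "previously
changed" if any earlier time crossed the same two-fold threshold in the
same direction, making "new + previous = total changers" exact by
construction.

## Complex stoichiometry

IQR uses linear-interpolation quantiles (the common scientific-computing
default; configurable since box-plot conventions differ). Complexes with
fewer than two quantified members are skipped, not scored 0 — a singleton
IQR would claim perfect coordination from no evidence. Cross-level
comparisons (proteome vs transcriptome) are restricted to genes quantified
on both levels so member sets match.

## Directional network

* **Signal filter**: per profile, the log marginal-likelihood ratio of a
  Gaussian process (squared-exponential kernel plus independent noise,
  maximized over a fixed grid of lengthscales {0.1, 0.25, 0.5, 1.0} ×
  range and signal fractions {0.5, 0.9, 0.99}) against an iid-noise null
  of equal total variance. Threshold 2.0, set from the null distribution
  of white-noise profiles (95th percentile ≈ 0.8, 99th ≈ 2.0 at 12 time
  points) so at least 95% — in practice ≈ 99% — of pure-noise profiles
  are removed.
* **Shrinkage**: the analytic variance-minimizing intensity
  `λ* = Σ Var(r_ij) / Σ r_ij²` toward the identity, guaranteeing a
  positive-definite correlation matrix with far fewer samples than genes.
* **Partial correlations**: `−P_ij/√(P_ii P_jj)` with `P` the inverse of
  the shrunk correlation matrix; edges where |pcor| ≥ cutoff; isolated
  nodes dropped.
* **Orientation**: SPV per node = residual variance after regressing the
  profile on its graph neighbors, divided by its marginal variance, both
  degrees-of-freedom corrected (RSS/(n−1−k) over TSS/(n−1)). Without the
  df correction the raw residual of a high-degree node shrinks
  mechanically with its degree and hubs always look responsive. When a
  node's degree approaches the sample count the regression is ridge
  regularized (penalty 1e-2) and the node flagged. Edges orient from
  higher SPV to lower; |log SPV ratio| below 0.85 is a tie (left
  undirected, excluded from causal counts), the 95th percentile of the
  ratio on simulated null edges (siblings equally tied to a shared
  parent, 12 time points × 2 replicates). Note that an *isolated* pair
  can never be oriented: both endpoints have SPV = 1 − r², so orientation
  information exists only in network context.
* **Clustering and ranking**: maximum-modularity clustering of the
  undirected skeleton — exact (all partitions enumerated) for graphs of
  ≤ 10 nodes, greedy agglomerative above, with nodes pre-sorted for
  determinism. Clusters rank by outgoing/incoming inter-cluster arrows;
  a cluster with no incoming arrows ranks first among its peers by
  outgoing count.
* **Cutoff grid**: with tens of genes per sample, shrinkage compresses
  partial correlations to a few hundredths, so the default sensitivity
  grid is (0.02, 0.03, 0.04) — the sparse-to-dense transition for this
  data class. Stability across the grid is the rank correlation of
  cluster causal orderings after matching clusters by maximal overlap.

### Known limitation: cluster-level causal recovery at scale

The driver/responder generator plants causality as *lagged* transmission:
responders are sparse linear maps of time-delayed drivers plus noise. In
this regime the node-level statistics behave as designed — drivers retain
systematically higher SPV than responders, and directed driver↔responder
edges point driver→responder at every default cutoff (verified across
seeds). Cluster-level recovery is weaker: with ~200 genes observed at 12
time points (two replicate series, ≤ 24 samples), partial-correlation
estimates cannot separate true parent–child edges from the estimation
noise floor — near-deterministic transmission makes siblings "explain
away" each other's parents in the population limit, and raising responder
noise to restore edge identifiability erodes the orientation asymmetry.
Modularity clusters consequently mix drivers and responders, and the
ranking of the most driver-enriched cluster is not reliably first at this
scale. Users should read the cluster ranking as a coarse, sweep-validated
summary, and the SPV/arrow statistics as the better-supported causal
readout; the corresponding end-to-end test records this limitation.

## Determinism

Every stochastic routine takes a mandatory seed and uses an isolated
`numpy` generator; outputs are reproducible bit-for-bit. The CLI writes a
run manifest with config, stage list and SHA-256 digests of all outputs.

## Problem sizes

Packaged tests and the acceptance script run on 200–1000 genes, 12 harvest
times, 2 replicates and 3 mixes per time point — the full structure of the
emulated study at a gene count that keeps any single check in seconds
while leaving every algorithmic path exercised.
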