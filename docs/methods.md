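# Methods

This note records the modelling choices behind `delaynet`: what is
computed, under which conventions, which knobs matter, and what the
synthetic cohorts do and do not establish about real data.

## Delayed correlation and the anti-symmetric split

For regions × timepoints data X and lag d ≥ 0, the delayed correlation
is the Pearson correlation of the leader segment x_i(1..T−d) with the
follower segment x_j(1+d..T). Conventions:

- **Overlap.** Only the T−d overlapping samples enter; no padding or
  wrap-around. Truncation is the standard estimator and keeps the
  zero-lag case identical to the ordinary correlation matrix.
- **Direction.** Row = earlier/source, column = later/target. Every
  writer records this in a JSON sidecar.
- **Degenerate segments.** A zero-variance overlap segment yields
  correlation 0 with a logged warning rather than an error: one flat
  region must not abort a cohort run.
- **Clipping.** Entries are clipped to [−1, 1] only to absorb floating
  rounding.

The split C = S + K with S = (C+Cᵀ)/2, K = (C−Cᵀ)/2 is unique; the
implementation asserts reconstruction to 1e−12 in its tests. K is
exactly zero at delay 0, which is why the pipeline refuses delay 0
instead of silently computing an empty network. Directed weights are
W = max(K, 0); a matrix is accepted as anti-symmetric when
max|K + Kᵀ| ≤ 1e−8.

Group-representative networks are element-wise means of individual W
matrices. Because supports are subject-specific, the average may carry
weight in both directions of a pair; it is therefore returned as a plain
matrix, not a directed network. Weight histograms exclude exact zeros —
they are structural absences created by negativity-zeroing, not small
weights.

## Graph measures over the density sweep

Binarisation is proportional: at density D, the m = round(D·n(n−1))
largest positive weights become edges, ties at the cut broken by
ascending (row, column) index for bit-reproducibility. If fewer
positive weights exist, all are kept and the achieved density is
recorded with a warning (an anti-symmetric support can fill at most half
of the ordered pairs). Rank thresholding makes edge sets nested across
densities, which in turn makes global efficiency monotone along the
sweep — both are asserted in tests.

- **Clustering** is Fagiolo's binary directed coefficient: per node,
  t_i = ½[(A+Aᵀ)³]_ii closed patterns against d_i(d_i−1) − 2d_i↔
  possible ones, zero where the denominator vanishes, averaged over
  nodes. Reciprocal edges cannot occur on pipeline inputs (d_i↔ = 0)
  but the formula handles them for generality.
- **Global efficiency** is the mean of 1/ℓ_ij over ordered pairs with
  BFS hop-count distances; unreachable pairs contribute 0. Disconnected
  graphs are expected at low densities and are not an error.

Both measures are pinned to brute-force oracles (triple-loop pattern
counting, Floyd–Warshall) exhaustively over all 4-node digraphs.

The per-subject summary is the trapezoidal AUC of the measure against
density *as a fraction* (default 0.05…0.50 in 0.01 steps, 46 points).
The abscissa convention cancels in group comparisons but is fixed for
reproducibility; with values in [0, 1] the AUC is bounded by 0.45.

## Statistics

- **Permutation test.** Statistic = difference of group means; labels
  permuted uniformly; two-tailed add-one p-value
  (1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm), which is never 0 and is
  exact under exchangeability. An `exact=True` mode enumerates all
  label splits for small groups. Default 10,000 replicates.
- **FDR.** Benjamini–Hochberg step-up at q = 0.05, applied across the
  whole family: all contrasts × measures × delays for group
  comparisons, all outcomes × delays for association models.
- **Outlier screen.** Subjects whose *outcome* lies outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are dropped per analysis (quartiles by
  linear interpolation). Which variable the screen targets is a design
  choice; it is configurable (`iqr_on`) with "outcome" as the
  documented default. Samples with fewer than 4 values skip the screen
  with a warning.
- **Quadratic models.** OLS of outcome on [intercept, AUC terms,
  their squares, covariates], with categorical covariates expanded to
  indicators (reference = first level in canonical group order).
  Association models run over amyloid-positive subjects with cognitive
  status (group) as a covariate, CN Aβ+ as reference; APOE ε4 copies
  can be added as a numeric covariate via a flag.
- **AIC selection.** AIC = n·ln(RSS/n) + 2k (k mean parameters
  including intercept; constant offsets cancel at fixed n). Candidate
  term sets over {CC, CC², GE, GE²} obey a hierarchy rule — a square
  only together with its linear term — giving 9 subsets including the
  covariates-only model; covariates are always present. The minimum-AIC
  fit wins; exact ties break toward fewer terms, then enumeration
  order. Candidates that are collinear or too large for the sample are
  skipped as unfittable rather than aborting the selection. Minimum-AIC
  selection retains the generating terms essentially always under
  strong signal, but admits a spurious extra term in roughly a fifth of
  replicates (the familiar P(χ²₁ > 2) ≈ 0.16 per parameter); exact
  true-set recovery therefore plateaus around 75–85% and model choice
  should be read accordingly.

## Synthetic cohorts

The generator emulates the statistical shape of an amyloid-staged
ageing cohort, not its biology:

- **Signals.** Stable VAR processes x(t) = Σ_l B_l x(t−l) + ε(t) with
  Gaussian innovations, 200 burn-in steps, and stability checked via
  the companion-matrix spectral radius (< 1 required). Defaults: 200
  regions, 197 timepoints at TR 3 s; desk-scale analyses use 30 regions
  and 10 subjects per group to keep runtimes in seconds.
- **Topology.** Each group shares a directed ring backbone (every
  region drives its 3 clockwise neighbours at lag 1, strength 0.22,
  self-coupling 0.10) with a group-specific fraction of couplings
  rewired to random targets: 0.30 (CN Aβ−), 0.02 (CN Aβ+), 0.80
  (MCI Aβ+), 0.00 (AD Aβ+). Shortcuts raise recovered global
  efficiency, so these probabilities plant the nonlinear trajectory
  decrease → increase → decrease across the Aβ+ groups; lattice-like
  groups show correspondingly higher clustering. Parameters live in
  `data/default_design.yaml`, not code.
- **Heterogeneity.** Per-subject multiplicative Gaussian jitter on
  coupling strengths (sd 10%, truncated at ±3 sd). Truncation makes
  stability provable by a row-sum budget: 0.10 + 3·0.22·1.3 = 0.958 < 1.
  The jitter magnitude is a free parameter of the generator, not an
  inference about any real cohort.
- **Covariates and outcomes.** Age ~ N(76, 7), education ~ N(16, 3),
  sex ~ Bernoulli(0.5), APOE ε4 copies group-dependent categorical;
  amyloid SUVR uniform below (0.9–1.11) or above (1.12–1.6) the 1.11
  cut-off with strict-inequality classification; tau and cognitive
  scores group-dependent Gaussians loosely matched to published
  medians. Only realistic variance matters for model testing, not
  exact replication. Outcomes with known quadratic links (plus
  covariate effects and Gaussian noise) can be attached to any measure
  for recovery checks.

What passing tests show: the estimator orients planted directed
couplings correctly, the graph measures and statistics are exact or
calibrated, and the full pipeline recovers planted group effects of
realistic size. What they do not show: robustness to haemodynamic
convolution, scanner noise and drift, spatial correlation of
parcellation errors, or longitudinal dynamics — none of which the
generator models.

## Numerical and degenerate-input conventions

- Determinism everywhere: every stochastic routine is a pure function
  of (inputs, seed); the pipeline spawns per-task seeds from one root
  seed, and reruns are byte-identical.
- Densities are generated floating-point-safely so the 5%..50%/1% sweep
  has exactly 46 points.
- Empty graphs score 0 on both measures; single-node graphs score 0
  efficiency.
- Zero outcome variance and rank-deficient designs are rejected with
  the offending columns named.
- Cohort TSV/CSV round-trips are bit-exact (full-precision printing,
  round-trip float parsing).

## Problem sizes used by the checks

The verification suite runs at sizes chosen for seconds-scale feedback:
exhaustive 4-node graph enumeration (4096 adjacencies), 1000 random
matrices for decomposition exactness, 100 seeds for direction recovery
(5 regions, T = 500), 2000 null replicates at 500 permutations for
type-I calibration, 50 seeds for quadratic recovery (n = 150) and AIC
selection (n = 200), and ten 40-subject/30-region cohorts for the
end-to-end planted-contrast check. The full-scale design (166 subjects,
200 regions, 46-density sweep, 10,000 permutations) runs through the
same code paths via the CLI.
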