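# Methods

This note documents the models and numerical choices behind `fluidconn`:
what each stage computes, the defaults and why, what the synthetic data do
and do not emulate, and the package's behaviour in degenerate cases.

## Signal processing

**Filtering.** Band-pass filtering uses an order-2 Butterworth *band-pass*
design (`scipy.signal.butter(2, (low, high), btype="bandpass")`) in
second-order-sections form, applied forward and backward
(`sosfiltfilt`) for exactly zero phase. We chose the band-pass transform
over a high-pass + low-pass cascade deliberately: the two are not
equivalent, and the band-pass design concentrates energy much more tightly
(e.g. 99.8 % of white-noise output power within 3–7 Hz for the 4–6 Hz theta
band, versus 80 % for the cascade) while remaining numerically stable in SOS
form even for the 0.1 Hz delta edge at 1 kHz sampling. Shipped bands:
delta 0.1–4, theta 4–6, alpha 6–12, beta 12–30 Hz, broadband 0.5–60 Hz. The
theta/alpha edges are intentionally atypical so that a pathologically slowed
alpha peak (below 8 Hz) is not split across two bands.

**Phase.** Instantaneous phase is the angle of the analytic signal (Hilbert
transform) per region, wrapped to (−π, π]. Zero-variance channels are an
error by default, or recorded as excluded channels (their rows/columns of
the PLI graph are zeroed) when requested. Filter and Hilbert edge
transients motivate the pipeline's `edge_seconds` option (default 1 s
trimmed from each end of the phase series before windowing; PLI uses the
full series, matching its full-length definition). Note that the delta
band's 0.1 Hz pole rings for tens of seconds — analyses that require
machine-level stationarity should trim accordingly.

**Alpha peak.** Welch spectrum (2 s Hann segments, 50 % overlap), averaged
over the supplied channels; the peak is the maximum inside a 4–14 Hz search
range and must be a local maximum strictly inside the range, else NaN. The
wide default range leaves room for disease-related slowing; channel
selection (e.g. posterior electrodes) is the caller's responsibility.

## Dynamic connectivity and fluidity

Windows start at sample 0, advance by `step` (defaults 1 s / 0.1 s),
fractional sample counts round down, and incomplete tail windows are
dropped — 7 min at 1 kHz gives exactly 4,191 windows. Within each window the
circular correlation uses the *circular* mean (argument of the mean unit
phasor), not the arithmetic mean of wrapped angles, which would break wrap
invariance. The dFC recurrence matrix is the Pearson correlation between
strict upper triangles of window matrices; fluidity is the *population*
variance (divide by m) of the dFC strict upper triangle — "variance" without
correction, and the choice only rescales all subjects identically.

Degenerate cases are excluded, not imputed: a window in which some region
has zero sine-deviation energy is flagged; a window whose FC pattern has
(numerically) zero variance across region pairs is dropped with a log
record, because a Pearson correlation with a near-constant vector is noise.
A fully phase-locked network is the canonical way to hit this: all its
window matrices are exactly all-ones. The clean stationary *limit* of
fluidity is instead exhibited by window-commensurate periodic signals
(tones at odd-integer frequencies with a 1.5 s window and 1 s step, so
circular means stay well conditioned): their windows repeat exactly and
fluidity is zero to filter-transient precision. The test suite uses this
construction for the stationarity contract.

## Static connectivity

PLI follows the standard sign convention with sign(0) = 0, so identical
(zero-lag) signals score 0 — by design the index ignores instantaneous
coupling of the kind volume conduction produces. Graph metrics:

* average node strength — mean row sum of the weight matrix;
* modularity — Louvain (networkx) followed by iterative single-node
  fine-tuning (moves to any community or to a fresh singleton, plus a
  community-merge pass) until Q stops improving (ΔQ < 1e−10, ≤ 100 passes).
  Restarts alternate Louvain seedings with random initial partitions —
  random initializations reach optima that greedy aggregation cannot — and
  the best Q wins. Default 10 restarts; 16 recover the exhaustive-search
  optimum on every random ≤ 8-node graph we test.
* clustering — Onnela weighted clustering (geometric mean of triangle
  weights, weights normalized by the graph maximum), matrix-vectorized and
  cross-checked against networkx in tests;
* characteristic path length — mean shortest-path distance with edge length
  1/weight over ordered pairs; for disconnected graphs the mean runs over
  reachable pairs only, with a warning and a flag.

**Null models.** NormCluster and NormPath divide the raw values by the means
over 100 randomized networks (seeded, default). A null network preserves the
binary degree sequence (degree-preserving double-edge swaps; a no-op for the
complete graphs dense PLI matrices produce), the weight multiset exactly,
and node strengths approximately, in two stages: (1) rank-matched
reassignment — pick a random unassigned edge, give it the weight whose rank
matches the edge's rank by product of residual strengths; (2)
strength-matching acceptance — propose random weight swaps between edges and
accept only those that reduce the summed squared node-strength error
(40 proposals per edge). Stage 2 brings the per-node strength correlation
with the original graph above 0.99 on dense random graphs while leaving the
weight-to-topology assignment random.

## Statistics

* **Residualization** is OLS on an intercept plus covariates; incomplete
  rows are dropped from the fit and returned as NaN so alignment is kept.
* **Mahalanobis distances** use the pooled all-subject covariance after
  age residualization; a numerically singular covariance is an error (no
  silent pseudo-inverse) prompting feature reduction.
* **PERMANOVA** computes Anderson's pseudo-F from squared distances
  (SS via within-group submatrix sums), with free whole-label permutation
  and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); 20,000 permutations by
  default, vectorized in blocks, seed-controlled. Pairwise post-hocs re-test
  each pair on its submatrix of the full distance matrix (re-deriving
  distances per pair is available as an option) and are BH-adjusted across
  pairs. scikit-bio's PERMANOVA serves as an independent cross-check in the
  tests, never as the implementation — it offers neither seeding nor
  post-hocs.
* **Partial Spearman** correlations residualize both variables on the
  covariates and use the t-approximation with explicit sidedness
  (one-sided tests halve the p on the hypothesized side); FDR is applied
  after sidedness, within each analysis family.
* **The LC × reserve model** residualizes fluidity, LC signal, and the
  reserve score on age, median-splits the residualized reserve
  (≤ median → lower), and fits OLS of fluidity on an orthogonal degree-2
  polynomial basis of LC fully interacted with the subgroup indicator. The
  basis follows R's `poly()` convention — columns centered, mutually
  orthogonal, unit norm, positive leading coefficients — verified against an
  R `lm(y ~ poly(x, 2) * g)` fit frozen into the tests. The low-reserve
  subgroup is the reference level, so `poly2` is directly the low-reserve
  curvature.
* Sex can be added as a second covariate (off by default). All analyses are
  complete-case with the effective n reported.

## LC contrast ratio

Intensities are multiplicatively normalized so the pontine-tegmentum (PT)
mask mean hits a common target (the CR is scale-invariant regardless — a
tested invariant). Per side and slice, the peak voxel inside the search mask
is found with a lexicographic tie-break; the signal is the mean of the
five-voxel in-plane cross (center + 4 neighbors). If the cross intersects
the fourth-ventricle mask, the center shifts one in-plane voxel in the
direction maximizing distance from the ventricle while staying in the search
mask (ties again lexicographic), and the shift is flagged; ventricle voxels
never enter the sampled mean. Three slices are measured; the middle slice is
caller-supplied, either directly or as an inferior-colliculus landmark minus
a 7 mm offset — anatomical landmark *detection* is out of scope. Rostral and
caudal default to ±1 slice. The PT reference is the volume-wide mask mean by
default ("slice" scope available). Unsampleable slices are reported missing,
never imputed. Downstream statistics default to the right caudal CR.

## Synthetic data: what it emulates, what it does not

**Signals** are Kuramoto–Sakaguchi phase oscillators per frequency band:
natural frequencies uniform in the band, sinusoidal coupling with
frustration angle α = 0.4 rad, Euler integration at the sampling rate, 5 s
burn-in discarded. The coupling matrix switches among `n_states` recurring
random modular templates with exponential dwell times (semi-Markov, mean
5 s by default — kept above the 1 s analysis window so states are
resolvable). Coupling strength c ∈ [0, 1] scales a gain of 2π × bandwidth,
calibrated so the PLI node strength responds monotonically over the whole
[0, 1] range rather than saturating. The observed signal sums sin(phase)
over bands, plus fixed per-region *observation phase shifts* (emulating
projection/dipole geometry — invisible to CCor because constant offsets
cancel in the sine deviations, but essential for PLI, which is blind to the
zero-lag synchrony an unshifted locked network would produce), plus white
Gaussian noise (default SD 0.5). Default group coupling places the
intermediate CN-CCF-like group delta-hyperconnected (0.8) relative to HC
(0.3) with MCI-LB between (0.5) — the nonlinear trajectory the analysis is
designed to detect; effect magnitudes are generator calibration choices, as
no raw-signal effect sizes exist to copy.

For test economy the default simulation is 250 Hz / 60 s (replicate-heavy
checks use 128 Hz / 20 s with 12 regions); full-scale settings (1 kHz, 7 min,
90 regions) remain configurable and run through the identical code path.

**Cohorts** (default 29/58/39 = HC/CN-CCF/MCI-LB, 126 subjects) attach age
(uniform 55–80), sex, premorbid intelligence with small group offsets,
clinical scales with group offsets, core-feature counts, and cognitive
scores built with configured rank correlations to designated connectivity
features. The LC→fluidity link is generated on standardized variables as
`a·LC² + b·LC + c` plus low-reserve-only slope (`interaction_gap`, default
0.25) and curvature (`quadratic_gap`, default −0.4) modifications and noise
(SD 0.5); dichotomization happens downstream via the median split, like the
analysis itself.

**Volumes** plant five-voxel crosses whose *mean* equals
PT × (1 + contrast) exactly, with a strictly maximal center (margin 5 % of
the PT level, comfortably above test noise), so zero-noise recovery is exact
and noisy recovery has a predictable cross-mean standard error. An optional
ventricle box (signal void) adjacent to a cross exercises the shift rule.

What passing tests therefore show: the implementation computes the stated
quantities correctly, the statistical layer is calibrated (type-I error at
nominal level) and has power against the planted effects at the study's
sample sizes. What they cannot show: anything about real EEG (no volume
conduction, artifacts, 1/f background, or anatomical realism), real
neuromelanin contrast distributions, or the clinical effect sizes of any
actual cohort.

## Reproducibility and degenerate inputs

Every stochastic component takes an explicit seed; per-subject and per-null
seeds derive from master seeds via `numpy.random.SeedSequence`. Cohort runs
echo their full materialized configuration, subject seeds, and per-analysis
ns into `manifest.json`; re-running the same configuration reproduces every
output byte-for-byte. Degenerate inputs follow one rule: fail or flag
loudly, never impute — constant channels, zero-variance FC windows, singular
covariances, constant distances, all-equal reserve scores, and unsampleable
slices each raise or produce logged NaN sentinels.
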