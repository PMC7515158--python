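# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `connrep`, and what the synthetic validation does and
does not establish.

## Study design and data model

The analysis targets a scan-rescan cohort: every subject contributes 4
resting-state scans (2 sessions on different days × 2 scans per session),
each scan being a T × N matrix of node time series (defaults N = 15 nodes,
T = 1200 time points, TR = 0.72 s — the dimensions of widely used public
scan-rescan node time-series releases). The pipeline consumes whitespace-
delimited text matrices named `<subject>_<scan>.txt`; parcellation and
denoising are assumed done upstream.

## Synthetic cohort generator

Real scan-rescan data provide no ground truth for either the coupling
structure or the intra/inter variance ratio, so validation runs on synthetic
cohorts with a known generative model. We use a stable sparse VAR(p):

* **Population coupling.** Off-diagonal directed edges are drawn i.i.d.
  with density 0.2; each edge gets one coefficient of magnitude 0.2–0.4
  (random sign) at a random lag 1..p (default p = 3); lag-1 self-terms of
  0.3–0.6 provide node autocorrelation. Scaling lag-l coefficients by s^l
  scales every companion-matrix eigenvalue by s, so one such rescaling pins
  the spectral radius exactly at 0.8 (comfortably stationary yet strongly
  autocorrelated, as resting-state signals are).
* **Subject and scan levels.** Each subject adds Gaussian noise of SD 0.10
  to the nonzero coefficients; each scan adds further Gaussian jitter of
  SD 0.025 (a quarter of the subject spread) plus fresh innovations.
  Non-stationary draws are rejection-resampled (≤ 100 attempts). These two
  scales are the only knobs controlling the intra/inter variance ratio; no
  public estimate of that ratio exists, so the default 4:1 split encodes the
  qualitative assumption that individual differences dominate scan-level
  fluctuation without making intra pairs trivially identical.
* **Observation.** 200 burn-in steps are discarded; with `hrf_enabled` each
  node is convolved with the canonical double-gamma HRF (peak 6 s,
  undershoot 16 s, ratio 1/6) sampled at TR; every emitted series is
  z-scored. There is no separate observation-noise term — the VAR
  innovations (SD 1.0) are the only stochastic input. `hrf_enabled`
  defaults to off: the estimators are specified to run on deconvolved
  (neural-level) series, which the VAR emits directly; HRF-enabled configs
  exist to exercise the deconvolution stage.
* **Seeding.** One root seed fans out through `SeedSequence` spawn keys per
  subject and scan, so any scan is reproducible in isolation.

What the generator does **not** emulate: neurovascular coupling physiology,
physiological noise spectra, motion artifacts, non-Gaussian innovations,
spatially correlated parcellation error. Passing tests therefore demonstrate
correctness of the estimators and of the statistical machinery under a
linear Gaussian ground truth, not robustness to real acquisition artifacts.

## Preprocessing

* **Stationarity** is verified per node with the augmented Dickey–Fuller
  test (AIC lag selection); non-stationary series are flagged and logged,
  never dropped.
* **Standardization** is z-scoring with the sample (ddof = 1) standard
  deviation; zero-variance series raise a degenerate-input error.
* **Blind deconvolution** is a simplified point-process scheme: pseudo-
  events are local maxima above 1 SD of the standardized signal; the
  event-triggered mean over a `round_half_up(10 s / TR)`-point window
  (14 points at TR 0.72 s) is fit to a double-gamma with a free onset (the
  onset absorbs the unknown event-to-peak delay — a pure-delay error in the
  kernel would time-shift the recovered activity); latent activity is
  recovered by Wiener deconvolution with a regularization floor of
  10⁻³ × the peak HRF spectral power, then re-standardized.
  Nodes with fewer than 3 events pass through unchanged, as do nodes whose
  triggered response is not HRF-like (double-gamma fit R² < 0.8 or kernel
  peaking at the window edge). The R² gate matters: on series with no real
  hemodynamic blur, unconstrained kernel fits inject node-specific phase
  shifts that destroy lagged-coupling structure. The 0.8 threshold sits in
  the gap between the R² of genuinely HRF-convolved responses (median ≈
  0.98, 5th percentile ≈ 0.81) and of plain-VAR autocorrelation bumps
  (95th percentile ≈ 0.78) measured on synthetic data.

## Connectivity estimators

All four estimators emit N × N nonnegative matrices with zero diagonal;
negative values (anticorrelations, numerical noise in GC/TE) are clipped to
zero so that the graph metrics' nonnegativity assumptions and the [0, 1]
bound of the matrix-level ND hold for every method.

* **Pearson / partial correlation.** Sample correlation, and the negated
  scaled inverse of the correlation matrix. With N = 15 and T = 1200 the
  inversion is well-posed; an optional ridge rescues near-singular inputs.
* **State-space mGC.** One full VAR fit per scan (OLS, no trend — series
  are standardized), order chosen by minimizing the median Schwarz/BIC
  score across all scans, each scan scored on a common effective sample so
  orders are comparable. Conditional GC from i to j is
  ln(reduced/full innovation variance of j), with the reduced variance
  obtained from the sub-process (all nodes except i) in innovations state-
  space form via the discrete algebraic Riccati equation — no reduced-model
  refits, avoiding their truncation bias. `scipy.linalg.solve_discrete_are`
  solves the filtering DARE (a fixed-point Riccati iteration is the
  fallback, tolerance 10⁻¹⁰). Natural logarithms throughout, so GC is in
  nats and the Gaussian identity TE = GC/2 holds. A dual-regression
  implementation (explicit reduced VAR refits) is kept solely as an
  independent cross-check.
* **mTE with non-uniform embedding.** Per target, candidate terms are all
  nodes' pasts at lags 1..5. Greedy selection minimizes the conditional
  entropy of the target's present under the linear-Gaussian estimator
  (CE = ½ ln 2πe σ²_resid), which reduces every evaluation to a Schur
  complement of one precomputed covariance matrix. Termination: the best
  candidate must lower CE more than the (1 − α) quantile of a permutation
  null, α = 0.05, 100 permutations of the target's current residual, each
  scored by the **maximum** gain over all open candidates. The max
  statistic corrects for selecting the best of ~N·5 candidates; testing
  only the chosen candidate's own permutations (a common convention) lets
  spurious terms through at far above α, and with the correction fully
  independent nodes select nothing. TE(i → j) is the CE gap between the
  embedding without i's selected terms and the full embedding, clipped at 0.

On Gaussian VAR data 2·TE and GC agree to a few percent on edges whose
sources are exogenous. On chain graphs they genuinely differ: the
state-space reduced model conditions on the *infinite* past of retained
nodes (absorbing indirect information about the excluded source), while the
embedding conditions on a finite selected set — so 2·TE exceeds GC on
chain edges. The equivalence test therefore uses a parallel-drive fixture.

## Graph metrics

Conventions (the silent degrees of freedom of weighted graph analysis):
path lengths are reciprocal weights; weights are max-normalized before the
cube-root-based metrics (clustering, efficiency, transitivity); strength is
total (in + out) strength for directed matrices; betweenness uses Brandes
accumulation with fractional shortest-path multiplicities (unordered pairs
for undirected graphs); clustering is Onnela (undirected) / Fagiolo
(directed); local efficiency is the cube-root-weighted inverse-distance sum
over a node's neighbours with distances computed in the neighbour-induced
subgraph; **global efficiency is defined as the average of the local
efficiencies** (the convention of the analysis this package reproduces, not
the classic inverse-shortest-path global efficiency); disconnected pairs
contribute zero inverse distance and isolated nodes get zero local metrics.
`metrics_reference_check` verifies strength, betweenness and clustering
against networkx; betweenness additionally has an exhaustive-enumeration
oracle in the tests.

## Variability and statistics

* ND(0, 0) = 0 (identical degenerate scans register no difference).
* Matrix ND is the ratio of squared Frobenius norms exactly as defined; a
  square-root variant (ratio of Frobenius distances) is available behind a
  flag — the two are monotonically related, so rank-based statistics are
  identical.
* Scalar ND pairs are oriented earlier-scan-position minus later, making
  runs reproducible; the Mann–Whitney comparison is orientation-robust
  because intra and inter pairs are constructed symmetrically.
* Inter-subject quadruples draw 4 distinct subjects per repeat (sampling
  without replacement within a repeat) and assign scan positions 1–4 by a
  random permutation; across repeats subjects recur, which is unavoidable
  when the number of repeats approaches the number of subjects.
* Mann–Whitney U tests are two-sided with tie correction;
  ES = median(inter) − median(intra). p-values are uncorrected by default
  (matching the decision rule of the analysis reproduced here), with
  opt-in Benjamini–Hochberg or Bonferroni adjustment. Kruskal–Wallis node
  tests pool 4 metrics × 4 estimators = 16 streams per node; missing
  streams warn and pool what is available. Post-hoc comparisons are
  pairwise Mann–Whitney tests.

## Problem sizes used in validation

The test suite and acceptance script validate at sizes chosen to give
stable statistics on a single core: counting identities at the full
1003-subject design (identity-only, no time series); estimator oracles at
T = 5000 (GC dual-regression agreement ≤ 10⁻²) and 20 random 5-node graphs
(betweenness, exact); order recovery and edge-detection AUC over 20 seeds;
the end-to-end discrimination on a 50-subject default cohort (600 ND values
per arm); test calibration with 1000 (Mann–Whitney type-I) and 200
(Kruskal–Wallis uniformity) replicates. The Kruskal–Wallis null calibration
uses exchangeable node-pooled ND samples directly rather than full cohort
replicates, which calibrates the same statistic at a feasible cost.

## Known limitations

* The TE entropy estimator is linear-Gaussian only; nonlinear (k-NN,
  binning) estimators are out of scope, so mTE here cannot detect purely
  nonlinear coupling.
* Dynamic (time-varying) connectivity and spectral GC are not implemented.
* The deconvolution stage is a simplified reimplementation of the
  point-process idea (event-triggered double-gamma fit + Wiener filter),
  not the full published toolbox; its parameter sensitivity is untested
  beyond the defaults.
* Effect sizes on synthetic cohorts depend directly on the chosen
  subject/scan jitter ratio and are not calibrated to any empirical
  dataset; only their sign and ordering are meaningful checks.
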