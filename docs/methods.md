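# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `actipred`. It is written for a reader who wants to know
exactly what the package computes and what its synthetic experiments do and
do not demonstrate.

## Problem setting

A body sensor network streams `N_s = 7` modalities — ambient temperature,
relative humidity, skin temperature, wrist and ankle 3-axis acceleration,
electrodermal activity (EDA) and EKG-based heart rate (HR) — to an
aggregator. The goal is to predict HR at time `t` from windowed features of
the other streams plus (optionally) HR history up to `t − δh`, and to use
the structure of the fitted model to decide which sensors can be duty-cycled
(idled) in each physical-activity state, trading a small loss of predictive
accuracy for a large cut in average current draw.

The predictor is activity-aware: an unsupervised activity-cluster function
`C(t)` maps ankle-accelerometer features to one of `K = 4` states, and a
separate sparse linear model is fitted per cluster.

## Pipeline

1. **Featurization.** Sliding 5 s windows with 1 s stride, ending at
   integer seconds on a 1 Hz analysis grid (the HR sampling rate). Windows
   are half-open `[t − w, t)`; accelerometer and EDA windows are framed on
   the sensor's native sampling grid because the spectral features need the
   full bandwidth. Groups and sizes: body temp (1, window mean), env temp
   (1), humidity (1), wrist accel (21), ankle accel (21), EDA (6), HR
   history (3); `p = 54`. Per accelerometer axis: mean, variance, skewness,
   excess kurtosis, peak periodogram magnitude and its frequency; plus the
   three pairwise covariances. The periodogram uses the mean-removed window
   with a rectangular taper; the peak is searched over bins in
   `(0, Nyquist]`, and a flat (zero) spectrum reports frequency 0.
   Zero-variance windows define skewness and excess kurtosis as 0. EDA:
   mean, least-squares slope vs time, variance, skewness, excess kurtosis,
   absolute range. HR history: `[y(t−δh), Δy, Δ²y]` on the 1 Hz grid;
   `δh = ∞` omits the group (`p = 51`).

   A row exists where both the feature window and the HR history fit inside
   the row's day: `t ≥ max(w, δh + 2)` relative to day start. The history
   is lagged from the window **end** `t`, matching the predictor's
   definition; rows with insufficient history are dropped, never imputed.

2. **Activity clustering.** The 21 ankle-accelerometer features are
   standardized, embedded to 3 dimensions with locality preserving
   projections, and clustered with k-means (`K = 4`, k-means++ with 20
   restarts, fixed seed). Cluster ids are relabelled in descending training
   size for reproducibility; semantic names are annotations only.

   LPP details: symmetrized 10-NN graph with heat-kernel weights
   `exp(−d²/σ²)`. The bandwidth default is the **mean** squared k-NN
   distance. The more common median heuristic degenerates here: rows are
   5 s windows at 1 s stride, so consecutive rows are near-duplicates whose
   tiny distances drag the median toward zero and disconnect the graph. The
   generalized eigenproblem `X'LX a = λ X'DX a` is regularized by adding the
   same ridge `ε = 10⁻⁸·tr(X'DX)/p` to both sides, so directions outside
   the data span receive generalized eigenvalue 1 and rank behind any real
   structure. Test-time assignment is nearest centroid in the embedded
   space, ties to the lowest cluster index.

3. **Group lasso per cluster.** On standardized features and response, the
   objective is

       ‖Y − Σ_k Z_k β_k‖₂² + λ Σ_k √c_k ‖β_k‖₂

   with `c_k = 1/M_k` (normalized scheme: every sensor weighted equally
   regardless of its feature count) or `c_k = P_k/M_k` (weighted scheme:
   `P_k` the sensor's incremental current in mA). The penalty is not
   divided by `N`; λ is therefore data-size dependent, which is harmless
   because the grid is always relative to
   `λ_max = max_k 2‖Z_k'Y‖₂/√c_k` (the smallest λ with an all-zero
   solution). The solver is block coordinate descent with exact block
   minimization: each group's subproblem (quadratic + Euclidean-norm
   penalty) is solved in the eigenbasis of its Gram block `Z_k'Z_k` via a
   monotone scalar root-find for the group norm — a single majorized
   proximal step per group converges impractically slowly on the collinear
   21-column accelerometer groups. Fits are computed in Gram form and
   warm-started along a 30-point log grid from `λ_max` down to
   `10⁻⁴·λ_max`. Convergence:
   max coefficient change `< 10⁻⁶` or 10 000 sweeps. Every fit satisfies
   the KKT certificate (relative violation `< 10⁻⁴` in the tests). The
   intercept is handled by centering and never penalized. Zero-variance
   columns (e.g. a constant humidity channel) are dropped with a warning;
   a group whose columns all vanish is excluded.

4. **λ selection.** Day-wise cross-validation: the training days are the
   folds; each fold fits the path on the other days' rows of the cluster
   and evaluates RMSE on the held-out day, on a common grid anchored at the
   full-training-set `λ_max`. Two deliberate choices on top of the plain
   "argmin of mean RMSE" rule:

   * **Relaxed validation (`relax=True`, default).** Each λ is scored by an
     *unpenalized* least-squares refit on that λ's active groups. With the
     penalized fit, the mean-RMSE curve keeps falling long past the point
     where the correct sensor set is complete — not because new groups add
     information but because the true groups' coefficients are still being
     un-shrunk — so the argmin systematically lands among models inflated
     with noise groups. Scoring the support instead of the shrunk fit
     removes that bias from the model-size comparison. The final predictor
     is still the group-lasso fit at the selected λ.
   * **One-standard-error rule (`rule="1se"`, default).** The mean-RMSE
     curve around its minimum is flat over one to two decades of λ relative
     to fold-to-fold noise, so an argmin inside the plateau is statistically
     arbitrary; we take the sparsest λ whose mean RMSE is within one
     standard error (across folds) of the minimum. `rule="min"` restores
     the plain argmin.

   A cluster absent from a fold's validation day skips that fold with a
   warning; a cluster absent from all training days is an error (the
   pipeline falls back to the unclustered model for such clusters at test
   time).

5. **Power accounting.** A sensor inactive in the running cluster's model
   is duty-cycled; the cluster's saving `ΔI_c` is the sum of the disabled
   sensors' incremental currents, and the average saving weights clusters
   by occupancy, `ΔI_avg = Σ N_c ΔI_c / Σ N_c` (test-day occupancy in the
   pipeline report). The default per-sensor current table
   (`data/power_table.json`) is reconstructed by solving the linear system
   that the published per-cluster reduction table defines over the
   sensor-inclusion sets, assuming the environmental-temperature and
   humidity increments are equal: body temp 0.312, env temp 0.263,
   humidity 0.263, EDA 0.312, HR/EKG 2.673 mA, with the implied system
   total 9.9455 mA (least squares over the printed mA/% pairs). The wrist
   accelerometer increment is set to 0.312 mA (the same-current assumption
   used for EDA and skin temperature) and the ankle accelerometer to
   2.70 mA (the chest-accelerometer increment from the bench measurements).
   The raw bench table ships as `data/power_table_measured.json`
   (wrist 0.32, chest accel 2.70, EKG 2.67 mA, total 10.02 mA); the bench
   measurements do **not** reproduce the published reduction table exactly,
   which is why the reconstructed table is the default. The weighted
   scheme's published reductions imply a wrist-accelerometer increment
   (≈3.19 mA) inconsistent with the bench wrist measurement; that
   discrepancy is documented, not resolved, and the weighted-scheme
   reduction table is not treated as reproducible.

6. **Evaluation.** MAE, RMSE, NRMSE = RMSE/(y_max − y_min), and R². The
   baselines are the constant predictor `ŷ(t) = y(t − δh)` (training-mean
   predictor when `δh = ∞`, flagged) and the unclustered model (`K = 1`),
   which re-selects its own λ. Test-time cluster assignment uses the
   training-fitted activity model. Clusters with fewer than 30 test rows
   are flagged small-sample. The accuracy–power trade-off lists, for each
   `λ ≥ λ*`, the test-RMSE increase over the optimum against the active
   set's percent current saving.

## Synthetic data

The generator reproduces the structure the method assumes, not physiology.
Each "day" is an independent realization (fresh seed stream) of an
8-segment protocol: 10 min walk; 20 min alternating walking (150 s) and
running (90 s) laps; 10 min rest; 15 min exercise; 5 min rest; 15 min
exercise; 10 min walk; 10 min walk. A semi-Markov alternative (transition
matrix + exponential dwells) is available.

* **Accelerometers.** Per state: a dominant sinusoid (ankle amplitude /
  frequency: rest 0.03 g / 0.25 Hz, walk 0.45 g / 1.8 Hz, run 1.1 g /
  2.8 Hz) with fixed per-axis scales (1.0, 0.6, 0.3) and phase lags, white
  sensor noise (0.01 g), and slow AR(1) wander of intensity (±10 %) and
  cadence (±5 %) emulating non-metronomic gait. Waveforms integrate the
  instantaneous frequency (cumulative phase), so cadence changes are smooth
  FM rather than chirps. Exercise is rhythmic bursts: a repeating 2.5 s
  amplitude profile of 0.5 s blocks alternating a 1.0 Hz primary and a
  weaker 2.2 Hz secondary component (ankle amplitude 1.3 g). The wrist
  scales the ankle amplitude per state (walk 0.55, run 0.75, exercise 1.6):
  arms swing less than the ankle moves during locomotion but dominate in
  upper-body exercise. These choices make the four states separable but
  diffuse blobs in feature space — the regime the clustering stage assumes.
* **Heart rate.** First-order relaxation to per-state setpoints (rest 70,
  walk 95, exercise 125, run 150 bpm) with τ = 30 s and 1.5 bpm/s½
  innovation noise, Euler-integrated at 1 Hz.
* **EDA.** Baseline 0.3 µS + slow drift (2·10⁻⁴ µS/s) + state-coupled
  component smoothed with τ = 60 s + noise; temperatures and humidity are
  constant means with small noise.

Ground-truth state labels are written for testing only; the pipeline never
reads them.

**What passing tests show and what they do not.** The synthetic states are
genuinely separable and the planted responses are exactly linear in the
features, so end-to-end successes here certify the machinery (featurization,
clustering, solver, selection, accounting) — not that real wrist-worn data
yields ARI ≈ 0.97 clusters or exact sensor recovery. Real data adds motion
artifacts, sensor drift, inter-day nonstationarity and nonlinear
HR dynamics that this generator deliberately omits.

## Support-recovery experiment design

The planted-truth harness replaces the target with
`Σ_k Z_k β_k + b₀ + ε` computed from the recording's raw windowed features;
when HR history is planted the target is generated recursively on the 1 Hz
grid so the downstream design reproduces the planted model exactly.
Planted coefficients apply to raw features (not standardized ones): the
HR-history group's standardization would otherwise depend on the target
being generated. Group support is invariant under per-group affine
reparameterization, so recovery checks are unaffected.

For the experiment the generator is configured so the non-planted sensors
are true decoys: EDA's state coupling and drift are switched off (with
them on, EDA legitimately proxies activity and time-of-day — the protocol
repeats daily — and *should* be selected). The planted groups carry
distinct signals — wrist: window variances (intensity); ankle: peak
frequencies (cadence); HR: a mild autoregressive term — because a support
is only identifiable if no planted group is predictively redundant given
the others. Noise is calibrated so the noiseless response variance is 10×
the noise variance (SNR 10).

## Numerical and degenerate-input conventions

* Ties in nearest-centroid assignment go to the lowest cluster index; ties
  in λ selection go to the larger (sparser) λ.
* The top of the λ grid is nudged `1 + 10⁻⁹` above `λ_max` so the first
  path point is exactly the empty model despite floating-point rounding.
* `λ = 0` reduces to least squares; a single group reduces to ridge-type
  norm shrinkage; singleton groups with unit weights reduce to the standard
  lasso (verified against independent solvers in the tests).
* Prediction accepts NaN in columns of inactive groups (the sensor is
  duty-cycled off); NaN in an active group's columns raises an error naming
  the sensor.
* Alignment to the 1 Hz grid averages faster channels over the forward
  window `[t, t + 1)` and linearly interpolates slower channels.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on minutes-long scaled versions of the
protocol (the segment structure is preserved; durations are scaled). The
clustering experiment uses the full default protocol. The support-recovery
experiment uses a protocol scaled to ≈2 040 s/day (≈2 000 design rows/day)
over 3 days and 20 seeds. The solver cross-checks use 50 random instances
with `N ≤ 40`, `p ≤ 12`.

## Known limitations

* The simulator is a structural emulator; none of its signal models are
  physiologically validated.
* LPP hyperparameters (10-NN, mean-distance bandwidth) are sensible
  defaults, not tuned values; clustering quality on real data will depend
  on them.
* The weighted penalty scheme is implemented and tested for its
  mathematical properties, but its published current-reduction table is
  internally inconsistent (see above) and is not a reproduction target.
* Day-wise CV assumes every cluster occurs on every training day; rare
  clusters fall back with warnings.
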