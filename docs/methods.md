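# Methods

This note documents the models, conventions, numerical choices and
limitations of the `serialdep` pipeline. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

* Orientations are in degrees on the half-open interval [0°, 180°);
  relative orientations are wrapped to (−90°, 90°], with the boundary
  difference of 90° mapping to +90°. Positive = counterclockwise.
* Time is in seconds, 0 at the lock event (stimulus, probe, or response);
  sample *i* covers the half-open interval [tᵢ, tᵢ + 1/f_s).
* Missing values are explicit (NaN in memory, `NA` on disk); nothing is
  imputed. Every filter logs how many trials it removed and why.
* All stochastic outputs are pure functions of (inputs, seed).

## Decoding model

At each time point the trailing `window_samples` samples (default 37 —
148 ms at 250 Hz; the scaled-down analyses use 4 samples at 25 Hz, the same
148 ms) of all sensors are concatenated into one feature vector per trial
and reduced by PCA to the smallest dimensionality reaching
`pca_variance = 0.90` cumulative explained variance. PCA is fit on all
eligible trials jointly — faithful to the published procedure rather than
leakage-free; `pca_per_fold=True` switches to fold-wise fitting. The
trailing (rather than centered) window alignment avoids using post-response
samples in response-locked analyses.

Each trial is held out in turn. Training trials are binned by their
orientation *relative to the held-out trial* into 10 half-open 18° bins
(edges −90°, −72°, …, +90°; a relative orientation of exactly +90° falls in
the top bin). The Mahalanobis distances from the held-out pattern to the 10
bin-mean patterns are sign-reversed and mean-centered, giving a tuning
curve whose similarities sum to zero. If any bin has no training trial the
curve is marked missing for that trial and time point (logged), never
imputed.

**Covariance.** The Mahalanobis metric uses a Ledoit–Wolf shrinkage
covariance of the training-fold residuals (each training trial minus its
bin mean), shrunk toward a scaled identity with the analytically optimal
intensity. The shrinkage formula is implemented in-package (so the
per-fold loop can be compiled with numba) and is unit-tested against
`sklearn.covariance.ledoit_wolf`. An `identity` option exists for oracle
tests, where the decoder reduces exactly to a Euclidean nearest-bin-mean
rule. The compiled fast path forms the within-group scatter by downdating
the precomputed total scatter; it is cross-checked against the direct
residual-matrix implementation to ~1e−15.

**Evidence.** Decoding evidence is the mean over bins of
similarity × cos(2 θ_bin). The doubled angle is the central interpretive
choice: orientation is 180°-periodic, and only cos(2θ) weights make flat
tuning map to exactly zero evidence (single-angle cosine weights would be
all-positive over (−90°, 90°] and could not index tuning).

**Response locking** re-epochs probe-locked data so time 0 is report
completion; trials with missing RT, RT outside `rt_bounds = (0.65, 11.85)` s,
or a span extending past the original epoch are excluded and counted.
Per-trial alignment is quantized to the nearest sample (< 1 sample error).

## Neural bias

The asymmetry index is the mean similarity of the three clockwise bins
(centers −63°, −45°, −27°) minus the three counterclockwise bins (+27°,
+45°, +63°); the two central and two extreme bins are excluded. It is
exactly invariant to mean-centering of the curve. Trials are sorted by the
sign of relative_orientation(inducer, target); trials at exactly 0° or
+90° are excluded from both groups (the closed sorting intervals would
otherwise double-count them) and the exclusion counts are logged. Group
order is average-then-difference: asymmetry is averaged across trials
within each inducer group per time point, then differenced, so

bias = asym(CW inducer) − asym(CCW inducer), positive = attraction.

A consequence of this bookkeeping, asserted by a test: mirror-reflecting
every orientation (θ → 180° − θ) swaps the groups *and* negates the
asymmetry, so an attractive bias remains positive — the index is
handedness-invariant. Only negating the underlying shift flips its sign.

For report-sorted analyses (the sensory-confound control), signed errors
are first corrected for stimulus-dependent bias: a sum of three sinusoids
of target orientation is fit per participant by deterministic multi-start —
every 3-subset of integer harmonics 1–8 cycles/180° solved by linear least
squares (amplitude/phase are linear given frequency), the best subset
refined by nonlinear least squares with free frequencies, the refinement
kept only if it lowers the RSS. The fit RSS therefore never exceeds the
zero-model RSS; non-convergence falls back to the grid fit (flagged).

**Windows.** Fixed windows average samples with t₀ ≤ t < t₁ (per trial
first, then across trials). Per-trial variable windows (e.g.
probe-onset-to-rotation-start) average each trial over its own
[event_start, rotation_start) span first; trials with empty windows are
dropped and counted.

## Inference

Cluster-based permutation test: one-sample t values per time point;
contiguous samples with |t| above the two-tailed `cluster_alpha = 0.05`
quantile form clusters; the statistic is the cluster mass (sum of t,
"maxsum" — the community default; the publication names only the test
family). The null flips the sign of whole participant time courses,
recording the maximum absolute cluster mass per permutation; positive and
negative clusters are pooled against it (two-tailed), and
p = (1 + #{null ≥ |mass|}) / (1 + n_perm), so p ≥ 1/(n_perm + 1). Default
100,000 iterations; the desk-scale analyses and tests use 1,000–10,000.
Windowed tests are two-tailed one-sample t tests; zero-variance input at
the null value returns t = 0, p = 1 rather than NaN.

## Synthetic data: what it emulates, and what it does not

**Task designs.** `meg`: 400 trials per participant — 200 with both
gratings (100 cued to each), 100 first-only, 100 second-only, randomly
mixed; the block count is not specified in the source design, so 8 blocks
of 50 is assumed. `eeg`: cued recall, 2 sessions × 6 blocks × 84 trials =
1,008 trials. Orientations are i.i.d. uniform on [0°, 180°);
previous-target links never cross block boundaries.

**Reports.** Signed error = DoG(Δ_prev) + DoG(Δ_s1, on trials where
sample 1 was shown but sample 2 cued) + cardinal term + Gaussian noise.
The DoG kernel is a·(δ/w)·exp(½ − δ²/2w²), so the amplitude *a* equals the
peak shift in degrees (an interpretable recovery target) occurring at
|δ| = w. Defaults: a_prev = +2°, a_s1 = −1°, w = 20°, noise SD 9° — typical
magnitudes for orientation working-memory reports. The cardinal bias is
amp·sin(2π·freq·θ/180) with amp 2°, freq 2 cycles/180° (90° period) — a
qualitative stand-in for repulsion from cardinal/oblique axes; its exact
shape is a free parameter. Swap errors (probability `swap_rate`, default 0)
re-center the report on the uncued item. RTs are log-normal
(μ = 0.9, σ = 0.45 log-s: median ≈ 2.5 s, 99 % ≈ 0.7–6.5 s, matching the
reported RT range); rotation start is a Beta(2,2) fraction of the RT, so
0 < rotation_start < rt always holds.

**Epochs.** Sensors sit on a unit-spaced grid on a disc (the real 306-
sensor geometry is not reproduced) with preferred orientations evenly
spread over [0°, 180°). Inside the signal window sensor s carries
gain·cos(2(θ_repr − φ_s)); θ_repr is the target shifted by each
`bias_schedule` entry along sign(relative_orientation(inducer, target)) —
positive shift = attraction. Windows get 50 ms cosine ramps to avoid step
artifacts, which keeps them well-defined for recovery tests. Noise is
Gaussian, white in time, with spatial covariance sd²·ρ^distance
(default ρ = 0.5 per grid unit) so Mahalanobis whitening genuinely matters;
a diagonal option exists for oracle tests. Defaults (gain 1, noise SD 1,
16 sensors) were calibrated once so that the full pipeline recovers an 8°
injected shift with power ≥ 0.9 at 20 participants × 400 trials, as the
package's recovery contract requires; they were not revisited afterwards.
`tuning_width` optionally replaces the cosine profile with a wrapped-
Gaussian bump; the default (None) is the cosine stated by the generator
contract.

**Not emulated:** biophysical forward models, eye/cardiac artifacts,
temporal autocorrelation of noise, probe-driven visual responses (so
report-sorted controls are exactly null only when the behavioral serial
bias is switched off — with it on, report sorting retains the small genuine
correlation with inducer sorting), masked-delay visual responses, and raw
preprocessing (filtering, ICA, interpolation). A green recovery test
therefore establishes that the *analysis chain* is sign-correct, localized
and calibrated — not that real recordings would show the effect.

## Degenerate inputs and tie-breaks

* Empty inducer groups or empty estimator sides raise
  `UndefinedEstimateError` naming the side; they are never silently zero.
* Searchlight neighborhoods are k nearest sensors by Euclidean distance,
  ties broken by sensor index (stable sort).
* The overlapping-bin visualization smoother averages exactly
  round(frac·N) trials per bin and is never used for inference.
* Orientations stored in [180°, 360°) are reduced mod 180° with a logged
  warning; values outside [0°, 360°) are rejected.

## Known limitations

* Joint PCA before cross-validation reproduces the published procedure but
  leaks marginal covariance across folds; the fold-wise switch is much
  slower and not the default.
* The trial-table validator requires the full column set; partial tables
  must be padded with `NA` columns.
* Per-trial response-locking quantizes to the sample grid; at 250 Hz this
  is ≤ 4 ms.
* The cluster test assumes exchangeability under sign flips
  (symmetric null); heavy-tailed participant effects inflate neither size
  (the permutation handles it) but can cost power.
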