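# Methods

This note records the models, conventions, and numerical choices behind
`covertbci`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

Epoched EEG lives in an `EpochSet`: `(n_trials, n_channels, n_samples)` in
microvolts, per-trial labels in {"yes", "no"}, a sampling rate `fs`, and
`t0_ms`, the time of the first sample relative to critical-word onset.
Sample `i` maps to `t0_ms + 1000·i/fs` ms; every cropping window is
half-open `[start, end)`, so adjacent subwindows of a tiling never share a
sample. The 29-channel montage carries 2-D unit-disc coordinates derived
from textbook 10–20/10–10 azimuth/inclination angles (radius =
inclination/90°, nose at +y). Positions are used only for channel grouping
and for the simulator's spatial effect footprints — nothing in the analysis
depends on a head model. Fixtures round-trip bit-exactly through a single
`.npz` archive (arrays plus a JSON metadata block).

"No" is treated as the positive class throughout (a "no" answer marks a
question that violates an autobiographical fact): sensitivity is the
correct-"no" rate, specificity the correct-"yes" rate.

## CSP estimation

Class covariances are per-trial channel covariances, each divided by its
trace before averaging. Trace normalization is the classic guard against
trial-amplitude confounds; it is a package choice (toggleable via
`trace_norm`) since either convention is defensible. The projection matrix
solves the symmetric generalized eigenproblem `Σ₁w = λ(Σ₁+Σ₂)w` via
`scipy.linalg.eigh`, which enforces `Wᵀ(Σ₁+Σ₂)W = I` and hence
`λ₁ₖ + λ₂ₖ = 1` per projection. Eigenvalues are sorted descending by λ₁
with a stable sort (deterministic tie-breaking). Numerical choices:

- If the composite covariance's condition number exceeds 1e10 (routine for
  2 Hz-band filtered data, which are nearly rank-deficient), a Tikhonov
  term `1e-9 · trace/C · I` is added before solving.
- Eigenvectors are sign-ambiguous; the entry of largest magnitude in each
  spatial-pattern column is forced positive, making filters, patterns, and
  all downstream topographies bit-reproducible.
- The pattern matrix is `(Wᵀ)⁻¹` (the mixing matrix for `Z = WᵀE`), so
  `patterns @ W.T = I` exactly; the discriminative topography is the last
  minus the first pattern column.

Features are `f_p = log(var(Z_p)/Σᵢ var(Zᵢ))` over the selected `2m`
projections (natural log; the base only rescales features uniformly), so
`Σ exp(f_p) = 1` by construction — an invariant the tests assert.

## Decoding pipeline

Band-pass filtering uses a 513-tap (order-512) linear-phase FIR designed by
the window method with unity gain at the band center; the symmetric kernel
is applied by centered convolution, which exactly cancels the 256-sample
group delay. The *full* −500…1300 ms epoch is filtered before cropping, so
filter transients never touch analyzed samples.

Cross-validation draws folds per class (balanced folds) from a seeded
generator; one seed fixes the partition, and the same partition serves
every subwindow of a subject's accuracy map and the combined decoder. CSP
and the classifier are fitted on the nine training folds only. Whether the
original analysis fitted CSP inside or outside the cross-validation loop is
not documented; fitting inside is the only leakage-safe reading, and a
dedicated test (many channels, few null trials) checks that the pipeline
cannot manufacture accuracy from test-fold information. A consequence is
that reported accuracies here are conservative relative to any
leakage-prone variant.

The classifier is a soft-margin RBF-kernel SVM (scikit-learn `SVC`). The
original work set its parameters "by trial-and-error" without reporting
them; defaults here are penalty `P = 1.0` and kernel width
`γ = 1/(p · median per-feature variance)` computed on the training fold —
conventional, reproducible, and deliberately not grid-searched.

Subwindow selection takes the group-mean accuracy map over all 138 tiles
and keeps windows strictly above mean + 2·SD (population SD over windows);
an optional absolute floor (the exact binomial chance threshold, 75% for 10
test trials per class) can be enabled. The combined decoder concatenates
the 4 features of each selected window per fold and trains a single SVM.

`chance_threshold(n, α)` returns the smallest `k/(2n)` with
`P(X ≥ k) < α`, `X ~ Binomial(2n, ½)`. For very small `n` no accuracy is
significant and the returned value exceeds 1 — a deliberate sentinel.

## ERSP

The wavelet is an analytic complex Morlet with `σ_t = n_cycles/(2πf)` and a
linear cycle schedule `n(f) = 4 + 9.5(f−1)/99` (4 cycles at 1 Hz, 13.5 at
100 Hz); wavelets are L2-normalized and zero-mean corrected. Transforms run
on the full epoch and only 0–1200 ms is reported, keeping edge effects out
of the analysis. Induced power averages single-trial power over trials, so
non-phase-locked oscillations survive (verified by an opposite-phase burst
test where the evoked average cancels exactly).

The analysis grid is 5 ms × 1 Hz over 0–1200 ms × 5–30 Hz — 241 × 26 bins
per channel, 181,714 over 29 channels. The bin counts are fixed by the
method; the steps (5 ms, 1 Hz, plain subsampling of the power envelope) are
inferred and configurable. Baseline normalization is relative change
`(P − B)/B` with `B` the mean power over −300…0 ms per channel and
frequency; the ratio variant `P/B` is a one-line config change. Normalized
maps are ≥ −1 and have zero baseline mean by construction.

## Cluster permutation statistics

Step 1 screens electrodes: paired t values over all
(channel, frequency, time) bins, averaged within the band of interest over
0–1200 ms, keep the top 10% (`ceil(0.1·C)`, = 3 of 29). The nominal theta
band 4–8 Hz intersects the 5 Hz-floored grid as 5–8 Hz. Step 2 averages
each subject's maps over the screened electrodes, thresholds paired t at
p < 0.05 (two-sided, df = n−1), clusters contiguous bins (4-neighbour
adjacency, positive and negative t clustered separately), drops components
without a run of ≥ 3 successive bins along time or frequency ("more than
two successive bins", read literally; the run length is configurable), and
scores each cluster by t_mass.

The null swaps each subject's two condition maps independently (sign-flips
of paired differences — the exchangeability-preserving scheme for a paired
design) and re-runs the *entire* analysis per surrogate, electrode screen
included, recording the maximum |t_mass| (0 when a surrogate yields no
cluster). Freezing the screen at the observed electrodes is available
(`freeze_electrodes`) but the nested default keeps the null honest.
Significance uses the permutation p-value `(1 + #{null ≥ |t_mass|})/(n_perm
+ 1) ≤ α`, the exact-valid form of "above the highest 5% of the null"; the
empirical 95% null quantile is also reported. With few subjects only `2ⁿ`
sign patterns exist and a warning flags the resolution limit.

## Synthetic cohorts

The generator emulates what the analysis assumes about the real data, not
the data themselves:

- Background: independent 1/f^1.0 noise per trial and channel
  (frequency-domain shaping), RMS 10 µV.
- Effects: band-limited white noise (4th-order Butterworth, zero-phase)
  with random per-trial phase — hence induced, not evoked — under a
  cosine-ramped (50 ms) time envelope, spread over channels by a Gaussian
  of scalp distance from the group centroid (width 0.35 disc units).
- Geometry (fixed to the reported findings): 9–12 Hz over right
  centroparietal channels (CP2, Pz, P4) at 300–1200 ms, and 6–10 Hz over
  right frontal channels (FC2, FC6, C4) at 200–800 ms, both stronger for
  "no".
- Cohort defaults: 23 subjects, 100 trials per class, 500 samples/s,
  −500…1300 ms epochs, log-normal per-subject effect-amplitude variability
  (SD 0.25).

No ground-truth effect sizes exist, so the class amplitudes are free
calibration parameters. They were calibrated once so the group-mean
accuracy in the best subwindow lands near 0.8 — comparable to the regime
the method was designed for — and then frozen: alpha 10.4 µV ("no") vs
2.6 µV ("yes") at the footprint peak, theta 9.4 vs 2.4 µV. A relevant
measurement made during calibration: with both classes carrying the
oscillation, accuracy in a single 200 ms × 2 Hz window saturates well below
1 even for large amplitude ratios, because each trial's narrowband variance
estimate has only a handful of effective degrees of freedom. Near-perfect
single-window decoding (≥ 0.95) requires an oscillation present in one
class only with amplitude ≳ 3× the background RMS, and that is the regime
the separability test exercises.

What the simulator does *not* model — and therefore what passing tests do
not establish about real recordings: volume-conduction mixing from a head
model, eye/muscle artifacts, phase-locked (evoked) components,
non-stationary noise, channel covariance structure beyond the planted
effects, and any quantitative match to the accuracies reported for the
real cohort (whose data are unavailable). Tests demonstrate internal
correctness and calibration of the machinery, not clinical performance.

## Problem sizes in tests and the acceptance script

Stochastic suites run at reduced sizes chosen to keep the full run in the
minutes range while preserving the statistical structure: null decoding
calibration pools 20 subjects × 40 trials; the family-wise-error simulation
uses 200 replicate cohorts (10 subjects, 6 trials/class, a 10-channel
montage, 250 samples/s, 12 frequencies, 200 surrogates); planted-effect
recovery uses 10 cohorts of 10 subjects. `scripts/acceptance.py` simulates
10 subjects × 40 trials/class at full channel/grid resolution with 500
surrogates. The generator's *defaults* remain the full study conditions;
only test problem sizes are reduced.

## Known limitations

- The per-subwindow decoder refits one CSP per fold per window; a 138-tile
  map over a 23-subject cohort at full trial counts is minutes-to-hours of
  CPU, not interactive.
- The simulator's Gaussian footprints make spatial patterns smooth and
  recoverable; real CSP patterns are noisier.
- Electrode screening inside each surrogate assumes the screen is part of
  the analysis; if the original analysis froze the screen, its null was
  slightly different (the frozen variant is available but not default).
- EDF/BrainVision import adapters are not implemented; the `.npz` fixture
  format and the simulator are the supported inputs. Real-data import
  would additionally need a stated re-referencing policy.
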