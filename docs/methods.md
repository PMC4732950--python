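# Methods

This note documents the models and numerical choices behind `respiro`: what
each index measures, how the synthetic breathing generator works, which
parameters matter, and where the design was genuinely open.

## Signals and preprocessing

The unit of analysis is a pair of breath-indexed series per subject: the
inter-breath interval (IBI, seconds, the time between consecutive breath
peaks) and the lung volume (LV, liters, the peak amplitude of each breath).
They are extracted from two-band respiratory inductive plethysmography:
ribcage and abdomen excursions are mapped to volume, peaks are detected, and
peak-to-peak intervals / peak amplitudes form the series.

* **Volume calibration** is an ordinary least-squares affine map from the
  two band signals to a reference volume channel.  A nonlinear (neural
  network) calibration is deliberately out of scope: the downstream indices
  are computed on z-normalized series and are insensitive to a monotone
  recalibration of amplitude; the linear map fills the pipeline slot and
  reports its R² so a poor fit is visible.
* **Peak detection** uses local maxima with a minimum separation of 1 s
  (below any physiologic inter-breath interval) and a minimum prominence of
  0.5 signal SD.  Both are configurable.
* **Artifact removal** drops interval values outside [0.5, 15] s, then
  values more than 5 robust SDs (1.4826·MAD) from the median.  The bounds
  rule runs first so a spike in an otherwise constant series is still
  caught when the MAD is zero.  Removing more than 20% of a series sets a
  warning flag.  These criteria are this package's own, chosen to be
  permissive; recordings in the field are typically cleaned by inspection.
* **Normalization**: all indices are computed on z-normalized series
  (mean 0, sample SD 1, n−1 denominator).  Using the sample SD makes the
  normalization contract exact and testable.
* The LV series has one more element than the IBI series (n peaks vs n−1
  intervals).  When the two are paired for cross-sample entropy, LV drops
  its first element; this alignment convention is recorded in the profile
  metadata.

## Complexity indices

**DFA.** The mean-subtracted series is integrated; for each box size n the
profile is split into ⌊N/n⌋ non-overlapping boxes and a least-squares line
(order 1, i.e. DFA-1) is removed per box; F(n) is the RMS residual.  The
scaling exponent α is the slope of log F(n) on log n over ~15 log-spaced
integer box sizes from 4 to N/4.  α = 0.5 for uncorrelated noise, 1.0 for
1/f (fractal) dynamics, 1.5 for an integrated random walk; the fit R² is
reported because the exponent is only meaningful when the log-log relation
is close to linear (R² ≥ 0.98 on synthetic fractal series of 1024 breaths).

**Sample entropy.** SampEn(m, r) = −ln(A/B), where B counts ordered pairs
of distinct m-point templates within Chebyshev distance r·SD and A the same
for m+1 points; both counts run over the same N−m template start indices and
self-matches are excluded.  Defaults m = 2, r = 0.2.  Counting uses a
KD-tree under the max norm and is exact (verified against O(N²) enumeration).
If A = 0 the statistic is +∞; `sample_entropy` returns `inf` rather than
raising so batch runs survive short, fully regular series.  For iid Gaussian
data the expected value is −ln(2Φ(r/√2)−1) ≈ 2.19 at r = 0.2, which the
estimator reproduces within 5% at N = 10⁴.

**Cross-sample entropy.** The same statistic with templates drawn from the
IBI series and matched in the LV series; there is no self-match concept.
The tolerance is r times the pooled SD of the two inputs, which equals r
for z-normalized series.  The statistic is direction-dependent; the
direction is recorded in the profile metadata and a symmetrized mean is
available (`symmetric=True`).  Lower values mean stronger IBI–LV
synchronization.  Note that the statistic has limited power against
*driver* correlation per se: two white-noise series with correlated
innovations match templates almost as often as independent ones, because
matches are dominated by unaligned index pairs.  It responds strongly when
the series share slowly varying structure (see the generator notes).

**Largest Lyapunov exponent.** Rosenstein's method: embed the series with
delay τ and dimension m, pair each embedded point with its nearest neighbor
at least a Theiler window apart, track the mean log-separation curve ⟨ln
d(i)⟩, and fit its slope over steps 1–10 (Δt = one breath, so the exponent
is per breath).  The Theiler window defaults to the mean period (reciprocal
of the power-weighted mean frequency), following Rosenstein's prescription.
The fit range is configurable; 1–10 covers the pre-saturation regime for
series of 10³–10⁴ points with near-neighbor separations well below the
attractor diameter.

* **Delay selection (AMI).** τ is the first local minimum of the
  histogram-estimated lagged mutual information.  Two guards matter in
  practice: (i) if I(1) is already below max(2·bias, 0.05·H) — where bias ≈
  (bins−1)²/2N is the histogram-MI bias for independent data and H the
  marginal entropy — the series is treated as immediately decorrelated and
  τ = 1; (ii) a "local minimum" at that same floor is decay, not rhythm,
  and also yields τ = 1.  Without guard (ii), monotonically decaying MI
  curves (chaotic maps, colored noise) would select an arbitrary large lag
  from noise on the floor.  Bins default to √(N/5).
* **Dimension selection (FNN).** m is the smallest dimension at which the
  false-nearest-neighbor fraction drops below 1%, with the Kennel criteria
  (distance-growth ratio > 15, or absolute growth > 2 series SD).  Exactly
  coincident neighbors (zero distance, as in integer-period signals) count
  as false only if they separate in the next dimension.  The cap (default
  10, reduced to N/50 for short series) is returned with a flag for
  noise-like series that never embed; a capped dimension on a ~10³-point
  breath series simply reports that no low-dimensional determinism was
  found, and the resulting exponent estimate is then interpreted as a
  divergence rate, not evidence of chaos.

Calibration: on logistic-map orbits at r = 4 the estimator is within 15% of
the analytic exponent ln 2 (orbit average of ln|r(1−2x)|); on a pure
sinusoid it is ≤ 0.05.

## Synthetic data generator

The generator exists so every stage can be tested against known ground
truth; no recordings ship with the package.

* **Colored noise** is synthesized in the frequency domain (independent
  complex-Gaussian coefficients with amplitude ∝ f^(−β/2), inverse FFT,
  standardized), giving exact spectral control; the expected DFA exponent
  is (β+1)/2.
* **Breath series**: per-breath interval and amplitude drivers are 1/f^β
  processes with correlation `coupling` between them; each driver is
  clipped at ±4 SD and passed through an exact lognormal link (σ² =
  ln(1+CV²), mean-corrected) so the target mean and CV are hit exactly for
  Gaussian drivers and intervals stay positive even at CV ≈ 0.5.  When
  coupled, the LV driver is a mixture and inherits a composite spectrum;
  this is acceptable because group contrasts, not per-series LV spectra,
  are the modeled quantity.
* **Waveform rendering**: each breath is a half-sine volume lobe whose peak
  sits exactly at the drawn peak time and amplitude, so the ground-truth
  breath table's peak-to-peak differences equal the interval draws.  The
  lobe is split across ribcage/abdomen channels with 60/40 mixing plus a
  small per-breath jitter in the split (so the two bands are not collinear
  and the calibration fit is identifiable); the reference volume is exactly
  0.6·ribcage + 0.4·abdomen.
* **Cohorts**: the default study design is four groups of ten subjects —
  healthy, controlled atopic asthma (CAA), uncontrolled atopic (UAA), and
  uncontrolled non-atopic (UNAA) — each recorded for 60 min.  Group
  interval/volume means and CVs follow values reported for such cohorts
  (e.g. healthy: mean IBI 3.51 s, CV 0.13, mean LV 0.64 L, CV 0.27).  The
  spectral exponents (1.0 / 0.7 / 0.4 / 0.1 for IBI) and couplings (0.1 →
  0.8) are *synthetic* choices that impose the qualitative ordering
  "healthy most fractal, uncontrolled non-atopic least, synchronization
  rising with severity"; no numeric group means of the complexity indices
  are available to match, so these defaults make no fidelity claim.  A
  second cohort mode draws features directly from per-group Gaussian
  tables, used for classifier tests.

What the generator does *not* emulate: movement/cough artifacts, sensor
physics, within-recording nonstationarity, apnea, or genuinely chaotic
respiratory dynamics (the drivers are stochastic, so synthetic LLE values
reflect noise-floor divergence rather than low-dimensional chaos).  Passing
tests therefore demonstrate that the estimators are correct and that the
pipeline discriminates groups whose structure differs as constructed — not
that real asthmatic breathing has these parameter values.

## Classification

The weighted sparse-representation classifier (WSRC) represents a test
vector y as a sparse combination of training columns A, with per-sample
penalties w_k equal to the Minkowski-p distance from y (default p = 2; the
order is not fixed by the source method) rescaled to [10⁻⁶, 1] — near
neighbors are cheap, far ones expensive; the direction "closer ⇒ smaller
penalty" follows the weighted-SRC literature.  When all distances are equal
to within 10⁻⁹ relative tolerance the weights collapse to uniform and the
classifier reduces to unweighted SRC.

The exact weighted ℓ₀ program is NP-hard.  The default solver is weighted
greedy matching pursuit: iteratively select the column maximizing
|correlation with the residual| / w_k, refit by least squares on the
support, stop at the sparsity budget (default min(10, ⌈n/4⌉)) or residual
10⁻¹⁰.  A coordinate-descent weighted-ℓ₁ solver is available behind
`solver="l1"`.  The predicted class minimizes the class-restricted
reconstruction residual ‖y − A·δ_c(x)‖₂, with each class residual capped at
‖y‖₂ (the empty representation is always available); ties break toward the
class with more coefficient mass, then lexicographically, so runs are
deterministic.

Evaluation is leave-one-out cross-validation; each fold standardizes
features using the n−1 training subjects only (no test leakage — the test
suite probes this with a constructed outlier).  Binary tasks mirror the
study questions: asthma (30) vs healthy (10); uncontrolled (20) vs
controlled (10); non-atopic (10) vs atopic (20) — the latter two exclude
healthy subjects.  Sequential forward selection ranks features by greedy
LOOCV-accuracy gain and returns the full trajectory, so overfitting shows
up as a peak before all features are included.

## Diagnostic evaluation

ROC curves sweep all unique thresholds; AUC is the trapezoid area, equal to
the concordant-pair fraction with ties counted half.  The AUC standard
error is Hanley–McNeil, the 95% CI is normal-approximation (clipped to
[0, 1]), and the p-value tests AUC = 0.5 on the same SE.  Score orientation
auto-flips so AUC ≥ 0.5, with the flip recorded.  The reported cut-off
maximizes the Youden index J = Se + Sp − 1, ties resolved toward higher
specificity (cut-off selection is not standardized across ROC software;
Youden is the default and the full curve is returned for any other rule).
Sensitivity / specificity / predictive values get exact Clopper–Pearson
intervals — the exact method, whose bounds for perfect rates at the group
sizes used here are 88–100% at k = n = 30, 69–100 at n = 10 and 83–100 at
n = 20 — and likelihood ratios get log-method
intervals, with division by zero reported as Inf/NaN flags rather than
errors.  Four-group comparisons use one-way ANOVA with Bonferroni-adjusted
pairwise t-tests when every group passes Shapiro normality at 0.05, else
Kruskal–Wallis with a hand-implemented Dunn post-test (rank z-tests with
tie correction, Bonferroni-adjusted).  A series with no variation at all
returns p = 1 with no flags.

## Problem sizes

Defaults reflect the study conditions: 60-minute recordings (≈10³ breaths
at a 3.5 s mean interval), 1 kHz waveform sampling, four groups of ten.
The test suite uses shorter recordings (5–20 min) where only structural
properties are asserted, and the full 60-minute, 40-subject design where
group recovery itself is the claim; a full cohort simulation plus profiling
runs in a few seconds.  Calibration checks use 2¹⁴-point noise series for
DFA and 5000-point logistic orbits for the Lyapunov estimator.

## Known limitations

* The ℓ₀ objective is solved greedily; no recovery guarantees are claimed.
* Histogram-based AMI is biased for small N; the bias-floor guard handles
  the selection problem but the reported MI values themselves are not
  debiased.
* Cross-sample entropy responds weakly to driver correlation below ≈0.95
  on stochastic series (see above); group-level synchronization contrasts
  in the default cohort come mainly from the smoother, more coupled
  drivers of the uncontrolled groups.
* The linear volume calibration cannot capture band nonlinearity; with the
  synthetic waveforms it is exact by construction.
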