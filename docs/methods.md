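# Methods

## The estimation problem

Beat-to-beat (RR) interval series recorded during exercise are
non-stationary on every time scale of interest: mean heart rate drifts with
workload, overall variability is suppressed at high intensity, and the
*correlation structure* of the intervals itself changes within tens of
seconds.  A single whole-recording DFA exponent, or even the conventional
short/long-scale split (α₁ over 4–16 beats, α₂ beyond), averages over these
changes.  `dynhrv` instead estimates correlation quantities *locally*, in
segments whose length is proportional to the scale or lag being probed, so
that every scale is estimated with comparable statistical accuracy and
temporal resolution degrades only as fast as the scale demands.

## Dynamic segmentation

For scale s (or lag τ), segments have ℓ(s) = a·s beats, rounded half away
from zero.  Defaults: a = 5 for DDFA, a = 10 for DPACF; both are exposed,
and a per-scale mapping can be supplied where finer control is wanted.
Segments overlap by 50% by default (`overlap` ∈ [0, 1)); the final segment
is anchored to the series end so trailing beats are never dropped.  A
segment's time index t is the mean beat time within it; its mean HR and HR
standard deviation are carried along for HR-binned aggregation and
robustness filtering.  Smaller a increases temporal resolution at the cost
of estimator noise.

## DDFA

Within each segment the DFA profile (cumulative sum of the mean-subtracted
intervals) is detrended with order-n polynomials in *maximally overlapping*
windows — every admissible start position, stride 1 — which substantially
reduces the variance of F(s) relative to disjoint tiling and makes the
fluctuation function smooth enough to differentiate directly.  The local
exponent is the second-order non-uniform finite difference of ln F with
respect to ln s evaluated from the three scales {s−1, s, s+1}:

    α(t,s) = [h₋² F̃(s+1) + (h₊² − h₋²) F̃(s) − h₊² F̃(s−1)] / [h₋ h₊ (h₊ + h₋)]

with F̃ = ln F, h₋ = ln s − ln(s−1), h₊ = ln(s+1) − ln s.  The scheme is
exact whenever ln F is affine in ln s (any pure power law), which the test
suite asserts to machine precision.

Defaults: n = 1 (DDFA-1).  Higher orders are supported but not default:
they inflate the short-scale bias, shift crossover scales, and need longer
segments for the same accuracy — short scales are precisely where the
dynamic analysis is most informative.  The minimum admissible scale is
n + 3, so that s − 1 still supports an order-n fit.  The default scale grid
is dense (every integer) from 5 to 20 beats and log-spaced up to 128; the
grid, like every parameter here, is configurable and analyses of long
recordings may extend it to thousands of beats.

Amplitude invariance (α unchanged under x → c·x + d, c > 0, for n ≥ 1) is
exact and tested; it is what allows arbitrary zero-mean test signals to be
embedded as positive RR series without affecting the estimate.

## DPACF

The lag-τ partial autocorrelation — the correlation between beats τ apart
with the linear dependence on intervening beats removed — is estimated per
dynamic segment: the *raw* intervals (not the profile) are detrended with
an order-m polynomial (m = 0, the default, subtracts the segment mean),
sample autocovariances are computed with the biased 1/ℓ estimator, and the
Levinson–Durbin recursion run to maximum order τ yields C(t,τ) as its final
reflection coefficient.  The biased estimator guarantees a nonnegative
definite autocovariance sequence, hence |C| ≤ 1 and a stable recursion even
on short segments; a numerically singular step (prediction-error variance
reaching zero) marks remaining orders NaN, and segments whose detrended
variance sits at the rounding level of the raw data are treated as zero
variance.  Because detrending acts on the raw series where DDFA detrends
the integrated profile, DPACF order m plays the role of DDFA order n = m+1;
the suite asserts the sign-structure agreement on constructed AR inputs.

Significance: C(t,τ) is flagged non-zero at the 5% level when
|C| ≥ 1.96/√ℓ(τ).  The band derives from the large-sample normal
approximation and is treated as valid only when ℓ(τ) ≥ 30 (τ ≥ 3 at
a = 10); the boundary is inclusive.  On white noise the measured
false-positive rate at valid lags is ≈ 3.7–3.8%, slightly below the nominal
5%: with mean detrending and the biased estimator the sampling variance of
the lag-τ PACF is ≈ (ℓ−τ)/ℓ², a little under the 1/ℓ the band assumes, so
the test errs on the conservative side at these segment lengths.  The band
is kept in its standard form rather than recalibrated.

## Conventional α₁

For comparison with the wider HRV literature, α₁ is computed as the
least-squares slope of ln F over scales 4–16 beats (every integer scale,
maximally overlapping windows, DFA-1) in moving 50-beat windows, stride 1
by default.  Natural logarithms are used throughout; slopes are
base-invariant.

## HR-binned aggregation

Dynamic-field values are averaged into heart-rate bins keyed by segment
mean HR: 0.1-BPM bins with linear interpolation across gaps up to 0.5 BPM
on the absolute axis; 0.001-wide bins with 0.005 gaps on the relative axis
(HR divided by the subject's maximum HR).  Gap width is measured in HR
units (bin width × empty-run length) and interpolation never extrapolates
beyond the outermost populated bins.  The α₁ curve uses 2-BPM (absolute) or
0.01 (relative) bins with per-bin mean, SD and SEM.  Probability-density
maps histogram each scale/lag row into 31 HR × 31 value bins and normalise
every populated HR column to unit mass, so the maps show how the *value
distribution* shifts with HR rather than how much time was spent at each
HR; the 99.5th-percentile density is reported as a colour-scale cap for
plotting and is never applied to the stored data.  The HR-stability filter
retains segments whose within-segment HR standard deviation lies below a
chosen quantile of the hr_std distribution, computed per scale/lag row by
default (a global variant is available) — per-row computation prevents the
long segments of large scales, which naturally accumulate more HR drift,
from dominating the threshold.  Multi-recording aggregation is by
concatenation of segment records, i.e. segment-weighted.

## Technical-artifact filtering

Only technical artifacts are addressed; no ectopic-beat physiology is
attempted.  Each interval is compared with the centred 11-beat rolling
median: an interval ≥ 1.75× the local median is tested as a missed-beat
merge (split into two equal halves when half the interval falls within
[0.75, 1.25]× the median, otherwise removed); an interval ≤ 0.4× the local
median is removed.  All thresholds are exposed.  The rolling median is
robust to isolated artifacts, and the filter is idempotent on series whose
artifacts are isolated; the suite also checks that recordings with up to
half the beats merged pairwise (a chest-strap failure mode) remain
analyzable after filtering.

## Synthetic processes and oracles

The generators define the validation conditions:

- **fGn** (Hurst H ∈ (0,1), DFA α = H): exact circulant (Davies–Harte)
  embedding of the target covariance γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H}
  + |k−1|^{2H}), so covariance oracles are sharp at every lag rather than
  asymptotic.
- **AR(p)**: Gaussian innovations, stationarity enforced via the
  characteristic roots, burn-in of max(10p, 100) samples discarded.
- **1/f noise** (α = 1): spectral synthesis with amplitudes ∝ f^{−1/2},
  random phases, zero DC, real Nyquist bin.
- **Random walk** (α = 1.5): cumulated iid Gaussians.
- **Interval session**: warm-up plus six 160-s high-intensity intervals
  separated by 90-s recovery jogs.  Recovery beats are AR(1) with φ = 0.6
  around 700 ms (≈ 86 BPM, recovery-jog level); intense beats are AR(1)
  with φ = −0.4 around 350 ms (≈ 171 BPM) with suppressed variability
  (SD 8 ms vs 20 ms) — capturing the two robust exercise signatures,
  shorter and anticorrelated intervals at intensity, without modelling
  respiration, stride coupling or Mayer waves.  Regime changes ramp the
  RR level linearly over 10 beats so steps do not dominate short-scale
  fluctuations.

The analytic oracle `theoretical_dfa_spectrum` computes, for any
stationary Gaussian autocovariance, the exact E[F²(s)]: within a window the
DFA residual is a fixed linear map M (cumulative sum followed by projection
off the polynomial subspace), so E[F²(s)] = tr(M Γ Mᵀ)/s with Γ the
Toeplitz covariance.  The implied α(s) uses the same finite-difference
scheme as DDFA on ½ ln E[F²].  Monte-Carlo agreement within 3 SE is
asserted for white noise, AR(1) φ = ±0.5 and fGn H ∈ {0.2, 0.8}.

What the synthetic conditions do *not* emulate: measurement jitter,
respiratory sinus arrhythmia, stride-cadence coupling, slow HR drift within
regimes, or subject-specific maximum-HR physiology.  Passing tests
therefore demonstrate estimator correctness on processes of known scaling,
not physiological validity on real recordings.

## Numerical choices

- ℓ(s) rounding: half away from zero; segment step max(1, round(ℓ·(1−overlap))).
- Window residuals are computed explicitly (w − Q Qᵀw with an orthonormal
  polynomial basis from QR) rather than via a difference of squared norms,
  avoiding catastrophic cancellation for strongly drifting profiles.
- fit_alpha and the finite difference return NaN, not exceptions, for
  undefined results (fewer than two usable scales, non-finite ln F).
- Scales, lags, thresholds, overlaps, a-factors and bin widths are exposed
  everywhere; defaults are stated above.
- All generators accept integer seeds or numpy Generators and are
  bit-reproducible under a fixed seed; the CLI writes TSV with a fixed
  float format so reruns are byte-identical.

## Study sizes used in validation

Scaling-law recovery uses series of 16384 (1/f, 20 seeds) or 20000 beats
(fGn and random walk, 10 seeds); significance-band calibration uses 100
white-noise series of 5000 beats; parameter recovery uses 5 seeds per
setting.  These sizes put Monte-Carlo error comfortably inside the
assertion bands (±0.1 on exponents, ±1.5 percentage points on the
false-positive rate, ±0.1 on AR coefficients).

One deliberate deviation from the module defaults: the lag-1 AR(1)
recovery check runs DPACF with a = 50.  At the default a = 10 a lag-1
segment has only ℓ = 10 beats, where the sample PACF carries an O(1/ℓ)
bias of roughly −(1 + 3φ)/ℓ (≈ −0.28 at φ = 0.6) — segments that short are
exactly what the ℓ ≥ 30 validity rule excludes.  At ℓ = 50 the residual
bias (≈ −0.06) sits inside the recovery band.  This is a property of short
sample PACFs, not of the dynamic estimator.

## Known limitations

- Segment-mean α(t,s) carries a small Jensen-type negative bias (the mean
  of ln F is below ln E[F]); it largely cancels in the three-point
  difference but a residual of ~0.02–0.03 remains at moderate segment
  lengths, visible when comparing against the analytic α(s).
- The significance band is slightly conservative at small ℓ (see above).
- The artifact filter is a heuristic for *technical* artifacts only;
  heavily corrupted recordings are made analyzable, not clean.
- The expectation oracle ignores the global mean subtraction of the
  profile; for detrending order ≥ 1 this is exact (the induced ramp lies
  in the removed subspace), for order 0 it is an approximation.
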