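# dynhrv

Dynamic, scale-dependent correlation analysis of beat-to-beat (RR) interval
series.

Heart-rate variability during exercise is strongly non-stationary: the
correlation structure of RR intervals changes with exercise intensity on a
time scale of seconds to minutes, which defeats conventional whole-recording
statistics.  `dynhrv` implements two estimators that resolve the correlation
structure in *time* as well as in scale or lag:

- **DDFA** — dynamic detrended fluctuation analysis.  For each scale *s* the
  series is divided into segments of length ℓ(s) = a·s beats (default a = 5,
  50% overlap).  In each segment the DFA-1 fluctuation function F is computed
  with maximally overlapping windows at scales {s−1, s, s+1}, and the local
  scaling exponent is the finite difference

      α(t,s) ≈ [h₋² ln F(s+1) + (h₊² − h₋²) ln F(s) − h₊² ln F(s−1)] / [h₋ h₊ (h₊ + h₋)],

  with h₋ = ln s − ln(s−1), h₊ = ln(s+1) − ln s.  α < 0.5 marks
  anticorrelated beats, α = 1 is 1/f noise, α > 1 is non-stationary,
  Brownian-like behaviour.
- **DPACF** — dynamic partial autocorrelation.  For each lag τ, segments of
  length ℓ(τ) = a·τ (default a = 10) are polynomially detrended (order m,
  default 0) and the lag-τ partial autocorrelation C(t,τ) is the order-τ
  Levinson–Durbin reflection coefficient of the Yule–Walker equations on the
  biased sample autocovariances.  C(t,τ) is flagged significantly non-zero
  at the 5% level when |C| ≥ 1.96/√ℓ(τ), provided ℓ(τ) ≥ 30.

Around the estimators the package provides RR-interval I/O and
technical-artifact (missed-beat) filtering, the conventional moving-window
short-scale exponent α₁ (scales 4–16 beats, 50-beat windows), heart-rate-
binned aggregation of the dynamic fields (absolute and relative HR axes,
gap interpolation, per-HR-bin probability densities, HR-stability quantile
filtering), and synthetic processes of known scaling behaviour — exact
fractional Gaussian noise via circulant embedding, AR(p), 1/f noise, random
walks, a stylised interval-training session — together with a closed-form
oracle for the expected DFA spectrum of any stationary Gaussian process.

Intended users: researchers in exercise physiology, cardiology and
physiological time-series analysis working with beat-to-beat recordings
from ECG or chest-strap heart-rate monitors.

## Worked example

```python
import numpy as np
from dynhrv import compute_ddfa, compute_dpacf, bin_field_by_hr
from dynhrv.synthetic import generate_interval_exercise

series = generate_interval_exercise(seed=1)   # six 160-s intense intervals
ddfa = compute_ddfa(series, scales=np.arange(5, 21), a=5)
dpacf = compute_dpacf(series, lags=np.arange(1, 11), a=10)

hot = ddfa.table[ddfa.table.mean_hr > 160]    # high-intensity segments
cool = ddfa.table[ddfa.table.mean_hr < 100]   # recovery segments
print(f"alpha(s) at high intensity: {hot.alpha.mean():.2f}")
print(f"alpha(s) at recovery:       {cool.alpha.mean():.2f}")
sig = dpacf.table[dpacf.table.valid]
print(f"significant C(t,tau) share: {sig.significant.mean():.2f}")

binned = bin_field_by_hr(ddfa, bin_width=1.0, max_gap=5.0)
print(f"HR bins populated: {(binned.count.sum(axis=0) > 0).sum()}")
```

prints

```
alpha(s) at high intensity: 0.40
alpha(s) at recovery:       0.98
significant C(t,tau) share: 0.03
HR bins populated: 90
```

High-intensity running segments show anticorrelated RR intervals
(α ≈ 0.4 < 0.5): successive beat-interval deviations tend to alternate in
sign.  Recovery segments show persistent, 1/f-like correlations (α ≈ 1.0).
The simulated session carries direct beat-to-beat dependence only at lag 1,
below the ℓ(τ) ≥ 30 validity cutoff (τ ≥ 3 at a = 10), so among *valid*
lags the share of significant C(t,τ) stays at the few-percent false-positive
level — exactly what the significance band is calibrated to produce on
structureless input.

The same pipeline is available from the shell:

```sh
dynhrv simulate --kind interval_exercise --seed 1 -o session.rr
dynhrv run session.rr -o out/ --scales 5:20 --lags 1:10
```

which writes the filtered series, both dynamic fields, their HR-binned
maps, the α₁ curve and a JSON manifest into `out/`.

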