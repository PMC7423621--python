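"""Synthetic signals of known correlation structure, plus an analytic DFA oracle.

Real exercise RR recordings are not distributed with the package, so
validation rests on processes whose scaling behaviour is known exactly:

* fractional Gaussian noise (fGn, Hurst exponent H, DFA exponent α = H),
  sampled *exactly* via circulant embedding of the target covariance;
* stationary AR(p) processes (known partial autocorrelations);
* 1/f (pink) noise via spectral synthesis (α = 1);
* integrated white noise (random-walk increments cumulated, α = 1.5);
* a stylised interval-training session: alternating recovery segments
  (long, positively correlated RR intervals) and high-intensity segments
  (short, anticorrelated intervals), with injected missed-beat artifacts
  available for testing the technical filter.

``theoretical_dfa_spectrum`` computes, for any stationary Gaussian
process given by its autocovariance, the exact expectation E[F²(s)] of
the detrended fluctuation function and the implied scale-dependent
exponent α(s) — the closed-form yardstick against which the dynamic
estimators are validated.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz

from .ddfa import finite_difference_alpha
from .dfa import _detrend_basis
from .rr_io import RRISeries

__all__ = [
    "generate_fgn",
    "fgn_autocovariance",
    "generate_ar",
    "generate_pink",
    "generate_random_walk",
    "theoretical_dfa_spectrum",
    "generate_interval_exercise",
    "series_from_values",
    "inject_missed_beats",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def fgn_autocovariance(lags, H: float, sd: float = 1.0) -> np.ndarray:
    """Exact fGn autocovariance γ(k) = (sd²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * H
    return 0.5 * sd**2 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def generate_fgn(H: float, n: int, sd: float = 1.0, seed=None) -> np.ndarray:
    """Fractional Gaussian noise by exact circulant embedding.

    The circulant embedding (Davies-Harte) of the length-n covariance is
    diagonalised by FFT; its eigenvalues are provably nonnegative for
    fGn with 0 < H < 1, so the synthesised sequence follows the target
    Gaussian law exactly at every lag.
    """
    if not 0 < H < 1:
        raise ValueError("H must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    m = n - 1
    gamma = fgn_autocovariance(np.arange(m + 1), H, sd)
    # first row of the 2m-circulant embedding
    row = np.concatenate([gamma, gamma[m - 1:0:-1]])
    eig = np.fft.fft(row).real
    if eig.min() < -1e-8 * eig.max():
        raise ValueError("circulant embedding produced negative eigenvalues")
    eig = np.clip(eig, 0.0, None)
    size = 2 * m
    z = rng.standard_normal(size) + 1j * rng.standard_normal(size)
    w = np.fft.fft(np.sqrt(eig / size) * z)
    return w[:n].real


def generate_ar(coeffs, n: int, sd: float = 1.0, seed=None) -> np.ndarray:
    """Stationary AR(p) sample with Gaussian innovations.

    ``coeffs`` are φ₁..φ_p in x_t = Σ φ_j x_{t−j} + ε_t.  Burn-in of
    max(10·p, 100) samples is discarded.  Raises for non-stationary
    coefficient sets (characteristic roots inside the unit circle).
    """
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    if coeffs.size and coeffs.any():
        roots = np.roots(np.concatenate([[1.0], -coeffs]))
        if np.any(np.abs(roots) >= 1.0):
            raise ValueError("AR coefficients are not stationary")
    rng = _rng(seed)
    p = coeffs.size
    burn = max(10 * p, 100)
    eps = rng.normal(0.0, sd, size=n + burn)
    if p == 0 or not coeffs.any():
        return eps[burn:]
    from scipy.signal import lfilter

    x = lfilter([1.0], np.concatenate([[1.0], -coeffs]), eps)
    return x[burn:]


def generate_pink(n: int, seed=None, sd: float = 1.0) -> np.ndarray:
    """1/f (pink) noise by spectral synthesis.

    Fourier amplitudes scale as f^{−1/2} (power ∝ 1/f) with random
    phases; the DC component is zero, so the sample is exactly zero-mean.
    The result is rescaled to standard deviation ``sd``.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phase = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phase)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phase[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    return x * (sd / x.std())


def generate_random_walk(n: int, sd: float = 1.0, seed=None) -> np.ndarray:
    """Integrated white noise (cumulative sum of iid Gaussians), DFA α = 1.5."""
    rng = _rng(seed)
    return np.cumsum(rng.normal(0.0, sd, size=n))


def theoretical_dfa_spectrum(acov, scales, order: int = 1):
    """Exact expected DFA fluctuation function for a stationary Gaussian process.

    Parameters
    ----------
    acov : callable or array-like
        Autocovariance γ(k); an array must cover lags 0..max(scales).
    scales : sequence of int
        Window sizes s at which to evaluate; each must satisfy
        s ≥ order + 2 (and s ≥ 2 for the exponent, which needs s−1).
    order : int
        Detrending polynomial order n.

    Returns
    -------
    (F, alpha) : ndarray, ndarray
        F[i] = sqrt(E[F²(s_i)]) and the scale-dependent exponent α(s_i)
        from the same finite-difference scheme used by the dynamic
        estimator, applied to ½·ln E[F²] at {s−1, s, s+1}.

    Notes
    -----
    Within a window of s points the DFA residual is a fixed linear map M
    of the raw data (cumulative sum followed by projection onto the
    orthogonal complement of degree-``order`` polynomials), so
    E[F²(s)] = tr(M Γ Mᵀ)/s with Γ the lag covariance matrix.  The map is
    identical at every window position for a stationary input, hence the
    per-window expectation equals the maximally-overlapping average.
    """
    scales = np.asarray(scales, dtype=int)
    s_needed = np.unique(np.concatenate([scales - 1, scales, scales + 1]))
    s_needed = s_needed[s_needed >= order + 2]
    max_s = int(s_needed.max())
    if callable(acov):
        gamma = np.asarray([acov(k) for k in range(max_s)], dtype=float)
    else:
        gamma = np.asarray(acov, dtype=float)
        if gamma.size < max_s:
            raise ValueError(f"acov must cover lags 0..{max_s - 1}")
    ef2 = {}
    for s in s_needed:
        s = int(s)
        big_gamma = toeplitz(gamma[:s])
        eigmin = np.linalg.eigvalsh(big_gamma).min()
        if eigmin < -1e-8 * max(gamma[0], 1.0):
            raise ValueError("autocovariance is not positive semidefinite")
        L = np.tril(np.ones((s, s)))
        q = _detrend_basis(s, order)
        M = L - q @ (q.T @ L)
        ef2[s] = float(np.einsum("ij,jk,ik->", M, big_gamma, M) / s)
    F = np.array([np.sqrt(ef2[int(s)]) if int(s) in ef2 else np.nan for s in scales])
    alpha = np.full(scales.size, np.nan)
    for i, s in enumerate(scales):
        s = int(s)
        if s - 1 in ef2 and s in ef2 and s + 1 in ef2:
            alpha[i] = finite_difference_alpha(
                0.5 * np.log(ef2[s - 1]), 0.5 * np.log(ef2[s]), 0.5 * np.log(ef2[s + 1]), s
            )
    return F, alpha


def series_from_values(values, base: float | None = None, scale: float = 1.0) -> RRISeries:
    """Wrap an arbitrary zero-mean signal as a positive RR-interval series.

    Shifts (and optionally scales) the signal so all intervals are
    positive: ``rr = base + scale*values`` with ``base`` defaulting to a
    level that keeps the minimum interval at 100 ms.  The dynamic
    estimators are invariant to affine amplitude changes, so this wrapper
    does not alter measured exponents or partial autocorrelations.
    """
    values = np.asarray(values, dtype=float) * scale
    if base is None:
        base = 100.0 - values.min()
    rr = base + values
    if np.any(rr <= 0):
        rr = rr - rr.min() + 100.0
    return RRISeries.from_intervals(rr, source_label="synthetic")


#: AR(1) coefficient, mean RR (ms) and innovation SD (ms) per exercise regime
REGIMES = {
    "rest": {"phi": 0.6, "mean_rr": 700.0, "sd": 20.0},
    "intense": {"phi": -0.4, "mean_rr": 350.0, "sd": 8.0},
}

#: warm-up, then six ~160 s high-intensity intervals with recovery jogs
DEFAULT_INTERVAL_SCHEDULE = (
    [("rest", 180.0)]
    + [r for _ in range(6) for r in (("intense", 160.0), ("rest", 90.0))]
)


def generate_interval_exercise(
    schedule=DEFAULT_INTERVAL_SCHEDULE,
    seed=None,
    regimes=None,
    ramp_beats: int = 10,
    return_labels: bool = False,
):
    """Stylised interval-training RR series with known regime structure.

    ``schedule`` is a list of ``(regime, duration_s)`` pairs with regimes
    drawn from ``REGIMES``: recovery segments have long, positively
    correlated intervals (AR(1), φ > 0); high-intensity segments have
    short, anticorrelated intervals (φ < 0).  Mean RR levels ramp
    linearly over ``ramp_beats`` beats at each regime change so that step
    discontinuities do not dominate short-scale fluctuations.

    With ``return_labels=True`` also returns the per-beat regime labels.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    regimes = {**REGIMES, **(regimes or {})}
    rng = _rng(seed)
    rr_parts, labels = [], []
    prev_mean = None
    for regime, duration in schedule:
        if duration <= 0:
            raise ValueError("durations must be positive")
        spec = regimes[regime]
        n_beats = max(ramp_beats + 1, int(round(duration * 1000.0 / spec["mean_rr"])))
        noise = generate_ar([spec["phi"]], n_beats, sd=spec["sd"], seed=rng)
        level = np.full(n_beats, spec["mean_rr"])
        if prev_mean is not None:
            ramp = np.linspace(prev_mean, spec["mean_rr"], ramp_beats, endpoint=False)
            level[:ramp_beats] = ramp
        rr_parts.append(level + noise)
        labels.extend([regime] * n_beats)
        prev_mean = spec["mean_rr"]
    rr = np.concatenate(rr_parts)
    rr = np.clip(rr, 200.0, None)  # physiological floor; ramps keep this inactive
    series = RRISeries.from_intervals(rr, source_label="synthetic-interval-exercise")
    if return_labels:
        return series, np.asarray(labels)
    return series


def inject_missed_beats(series: RRISeries, fraction: float, seed=None) -> RRISeries:
    """Merge a fraction of adjacent beat pairs, emulating missed-beat artifacts.

    Each selected pair of consecutive intervals is replaced by their sum,
    as a heart-rate monitor dropping an R-peak would record it.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    rng = _rng(seed)
    iv = list(series.intervals)
    n_merge = int(fraction * len(iv) / 2)
    # gate probability chosen so the expected merged-beat share equals `fraction`
    p_gate = fraction / (2.0 - fraction) if fraction else 0.0
    out, i = [], 0
    merged = 0
    while i < len(iv):
        if merged < n_merge and i + 1 < len(iv) and rng.random() < p_gate:
            out.append(iv[i] + iv[i + 1])
            merged += 1
            i += 2
        else:
            out.append(iv[i])
            i += 1
    return RRISeries.from_intervals(out, source_label=series.source_label + "+missed-beats")
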