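"""Dynamic partial autocorrelation functions C(t,τ) of RR-interval series.

The partial autocorrelation at lag τ is the correlation between
observations τ beats apart once the linear dependence on the intervening
beats has been removed — the order-τ reflection coefficient of the
Yule-Walker equations.  Here it is estimated *locally*: for every lag τ
the series is cut into dynamic segments of length ℓ(τ) = a·τ, each
segment is polynomially detrended (order ``m``, applied to the raw
intervals, not an integrated profile), sample autocovariances up to lag τ
are formed with the biased (divide-by-ℓ) estimator — which keeps the
sequence nonnegative definite — and the Levinson-Durbin recursion yields
C(t,τ) = φ_ττ.

Under the null of white noise the large-sample 5% significance band is
|C| < 1.96/√ℓ(τ); the band (and the test) is treated as statistically
meaningful only for segments with ℓ(τ) ≥ 30.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .ddfa import dynamic_segments
from .dfa import _detrend_basis
from .rr_io import RRISeries

__all__ = [
    "DynamicPACFField",
    "pacf_levinson_durbin",
    "compute_dpacf",
    "significance_mask",
    "MIN_VALID_SEGMENT",
]

#: minimum dynamic-segment length for the significance band to be valid
MIN_VALID_SEGMENT = 30


def pacf_levinson_durbin(acov, max_lag: int | None = None) -> np.ndarray:
    """Partial autocorrelations φ_kk from autocovariances via Levinson-Durbin.

    Parameters
    ----------
    acov : array-like, shape (..., p+1)
        Autocovariances γ₀..γ_p; leading axes are independent problems.
    max_lag : int, optional
        Highest order k to return (default p).

    Returns
    -------
    ndarray, shape (..., max_lag)
        Reflection coefficients φ_kk, k = 1..max_lag.  A numerically
        singular step (prediction-error variance ≤ 0) marks the remaining
        lags NaN; for batched input a non-positive γ₀ marks the whole row
        NaN, for a single problem it raises.
    """
    acov = np.asarray(acov, dtype=float)
    p = acov.shape[-1] - 1
    if max_lag is None:
        max_lag = p
    if max_lag < 1 or max_lag > p:
        raise ValueError("max_lag must lie in [1, len(acov) - 1]")
    batched = acov.ndim > 1
    if not batched and not acov[0] > 0:
        raise ValueError("gamma_0 must be positive")
    gamma = np.atleast_2d(acov)
    shape = gamma.shape[:-1]
    gamma = gamma.reshape(-1, p + 1)
    nb = gamma.shape[0]

    pacf = np.full((nb, max_lag), np.nan)
    phi = np.zeros((nb, max_lag + 1))
    err = gamma[:, 0].copy()
    alive = err > 0
    for k in range(1, max_lag + 1):
        num = gamma[:, k].copy()
        if k > 1:
            num -= np.einsum("bj,bj->b", phi[:, 1:k], gamma[:, k - 1:0:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            kappa = np.where(alive, num / err, np.nan)
        pacf[alive, k - 1] = kappa[alive]
        new = phi.copy()
        new[:, k] = kappa
        if k > 1:
            new[:, 1:k] = phi[:, 1:k] - kappa[:, None] * phi[:, k - 1:0:-1]
        phi = np.where(alive[:, None], new, phi)
        err = err * (1.0 - np.where(alive, kappa, 0.0) ** 2)
        alive = alive & (err > 0)
    pacf = pacf.reshape(*shape, max_lag)
    return pacf if batched else pacf[0]


@dataclass
class DynamicPACFField:
    """C(t,τ) over dynamic segments, long-format.

    ``table`` columns: lag, start, length, t_s, mean_hr, hr_std, C,
    valid (ℓ(τ) ≥ 30) and significant (valid and |C| ≥ 1.96/√ℓ).
    """

    table: pd.DataFrame
    a: float
    m: int
    overlap: float

    value_col = "C"
    row_col = "lag"

    @property
    def lags(self) -> np.ndarray:
        return np.unique(self.table["lag"].to_numpy())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, a=np.nan, m=-1, overlap=np.nan) -> "DynamicPACFField":
        return cls(pd.read_csv(path, sep="\t"), a=a, m=m, overlap=overlap)


def _biased_acov(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariances per row, γ_k = (1/ℓ)Σ x_i x_{i+k}."""
    nb, ell = x.shape
    acov = np.empty((nb, max_lag + 1))
    for k in range(max_lag + 1):
        acov[:, k] = np.einsum("bi,bi->b", x[:, : ell - k], x[:, k:]) / ell
    return acov


def compute_dpacf(
    series: RRISeries,
    lags=None,
    a: float = 10.0,
    m: int = 0,
    overlap: float = 0.5,
    min_len: int = MIN_VALID_SEGMENT,
    z: float = 1.96,
) -> DynamicPACFField:
    """Dynamic partial autocorrelations C(t,τ) of an RR-interval series.

    Per lag τ the series is segmented with ℓ(τ) = a·τ; each segment of raw
    intervals is detrended with an order-``m`` polynomial (``m = 0``
    subtracts the segment mean), autocovariances are estimated with the
    biased estimator, and C(t,τ) is the lag-τ reflection coefficient from
    the Levinson-Durbin recursion run to maximum order τ.  Segments with
    zero variance after detrending yield NaN.
    """
    if lags is None:
        lags = np.arange(1, 21)
    lags = np.unique(np.asarray(lags, dtype=int))
    if lags.min() < 1:
        raise ValueError("lags must be >= 1")
    if m < 0:
        raise ValueError("m must be >= 0")
    frames = []
    for tau in lags:
        grid = dynamic_segments(
            len(series), int(tau), a=a, overlap=overlap, times=series.times, hr=series.hr
        )
        if len(grid) == 0 or grid.length < max(m + 2, tau + 1):
            continue
        x = series.intervals[grid.indices].astype(float)
        rms_raw = np.sqrt(np.mean(x**2, axis=1))
        q = _detrend_basis(grid.length, m)
        x = x - (x @ q) @ q.T
        acov = _biased_acov(x, int(tau))
        # variance at rounding level of the raw data is zero variance
        degenerate = acov[:, 0] <= (1e-10 * rms_raw) ** 2
        acov[degenerate, 0] = 0.0
        c = pacf_levinson_durbin(acov, max_lag=int(tau))[:, -1]
        c = np.clip(c, -1.0, 1.0)
        valid = grid.length >= min_len
        significant = valid & (np.abs(c) >= z / np.sqrt(grid.length))
        frames.append(
            pd.DataFrame(
                {
                    "lag": int(tau),
                    "start": grid.starts,
                    "length": grid.length,
                    "t_s": grid.t,
                    "mean_hr": grid.mean_hr,
                    "hr_std": grid.hr_std,
                    "C": c,
                    "valid": valid,
                    "significant": significant,
                }
            )
        )
    if not frames:
        raise ValueError("no lag produced any segment")
    table = pd.concat(frames, ignore_index=True)
    return DynamicPACFField(table=table, a=a, m=m, overlap=overlap)


def significance_mask(
    field: DynamicPACFField, z: float = 1.96, min_len: int = MIN_VALID_SEGMENT
) -> np.ndarray:
    """Boolean mask of segments whose C(t,τ) is non-zero at the 5% level.

    An entry is significant iff |C| ≥ z/√ℓ(τ) *and* ℓ(τ) ≥ ``min_len``;
    entries failing either condition are meant to be masked (white) in
    field renderings.  NaN values are never significant.
    """
    c = field.table["C"].to_numpy()
    ell = field.table["length"].to_numpy()
    band = z / np.sqrt(ell)
    with np.errstate(invalid="ignore"):
        mask = (np.abs(c) >= band) & (ell >= min_len)
    return mask & np.isfinite(c)
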