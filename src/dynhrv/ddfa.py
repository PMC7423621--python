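"""Dynamic detrended fluctuation analysis: the time- and scale-dependent exponent α(t,s).

The series is divided, separately for every scale s, into segments of
length ℓ(s) = a·s beats (optionally overlapping).  Within each segment the
maximally overlapping fluctuation function is evaluated at the three
scales {s−1, s, s+1}, and the local scaling exponent is obtained from a
second-order finite difference of ln F with respect to ln s:

    α(t,s) ≈ [h₋²·F̃(s+1) + (h₊²−h₋²)·F̃(s) − h₊²·F̃(s−1)] / [h₋·h₊·(h₊+h₋)]

with F̃ = ln F, h₋ = ln s − ln(s−1) and h₊ = ln(s+1) − ln s.  The scheme
is exact whenever ln F is affine in ln s, i.e. for a pure power law.
Scale-proportional segment lengths give uniform statistical accuracy per
scale and high temporal resolution at short scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dfa import _batched_fluctuations
from .rr_io import RRISeries

__all__ = [
    "SegmentGrid",
    "DynamicExponentField",
    "segment_length",
    "dynamic_segments",
    "finite_difference_alpha",
    "compute_ddfa",
    "default_scale_grid",
]


def segment_length(scale_or_lag: float, a: float) -> int:
    """Dynamic segment length ℓ = a·s rounded half away from zero to beats."""
    return int(np.floor(a * scale_or_lag + 0.5))


@dataclass
class SegmentGrid:
    """Dynamic segments of equal length for one scale or lag.

    ``t`` is the segment time index (mean beat time within the segment, s);
    ``mean_hr`` and ``hr_std`` summarise the heart rate over segment beats.
    When the grid is built without times/HR, beat indices stand in for
    times and the HR summaries are NaN.
    """

    scale_or_lag: int
    length: int
    starts: np.ndarray
    t: np.ndarray
    mean_hr: np.ndarray
    hr_std: np.ndarray

    def __len__(self) -> int:
        return self.starts.size

    @property
    def indices(self) -> np.ndarray:
        """(n_segments, length) beat-index matrix."""
        return self.starts[:, None] + np.arange(self.length)


def dynamic_segments(
    n_beats: int,
    scale: int,
    a: float = 5.0,
    overlap: float = 0.5,
    times: np.ndarray | None = None,
    hr: np.ndarray | None = None,
) -> SegmentGrid:
    """Divide ``n_beats`` beats into segments of length ℓ(scale) = a·scale.

    Segments advance by ``ℓ·(1−overlap)`` beats (at least one); the final
    segment is anchored to the series end so no trailing beats are
    orphaned.  Returns an empty grid with a warning when the series is
    shorter than one segment.
    """
    if not a > 0:
        raise ValueError("a must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    ell = segment_length(scale, a)
    if n_beats < ell:
        warnings.warn(f"series of {n_beats} beats shorter than segment length {ell}")
        starts = np.empty(0, dtype=int)
    else:
        step = max(1, int(round(ell * (1.0 - overlap))))
        starts = np.arange(0, n_beats - ell + 1, step)
        if starts[-1] != n_beats - ell:
            starts = np.append(starts, n_beats - ell)
    idx = starts[:, None] + np.arange(ell)
    if times is None:
        t = idx.mean(axis=1) if starts.size else np.empty(0)
    else:
        t = np.asarray(times, float)[idx].mean(axis=1) if starts.size else np.empty(0)
    if hr is None or starts.size == 0:
        mean_hr = np.full(starts.size, np.nan)
        hr_std = np.full(starts.size, np.nan)
    else:
        hr_seg = np.asarray(hr, float)[idx]
        mean_hr = hr_seg.mean(axis=1)
        hr_std = hr_seg.std(axis=1, ddof=0)
    return SegmentGrid(
        scale_or_lag=int(scale),
        length=ell,
        starts=starts,
        t=t,
        mean_hr=mean_hr,
        hr_std=hr_std,
    )


def finite_difference_alpha(logF_minus, logF_mid, logF_plus, s):
    """Local scaling exponent from ln F at scales {s−1, s, s+1}.

    Second-order non-uniform finite difference on the ln s axis; exact for
    affine ln F.  Non-finite inputs propagate to NaN (undefined-result
    marker).  Accepts scalars or arrays.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 2):
        raise ValueError("s must be >= 2 so that s-1 >= 1")
    h_minus = np.log(s) - np.log(s - 1.0)
    h_plus = np.log(s + 1.0) - np.log(s)
    fm = np.asarray(logF_minus, dtype=float)
    f0 = np.asarray(logF_mid, dtype=float)
    fp = np.asarray(logF_plus, dtype=float)
    num = h_minus**2 * fp + (h_plus**2 - h_minus**2) * f0 - h_plus**2 * fm
    den = h_minus * h_plus * (h_plus + h_minus)
    with np.errstate(invalid="ignore"):
        alpha = num / den
    return alpha if alpha.ndim else float(alpha)


def default_scale_grid(s_min: int = 5, s_max: int = 128, dense_until: int = 20) -> np.ndarray:
    """Integer scales: every beat up to ``dense_until``, log-spaced beyond."""
    dense = np.arange(s_min, min(dense_until, s_max) + 1)
    if s_max <= dense_until:
        return dense
    coarse = np.unique(
        np.round(np.geomspace(dense_until, s_max, num=16)).astype(int)
    )
    return np.unique(np.concatenate([dense, coarse]))


@dataclass
class DynamicExponentField:
    """α(t,s) over dynamic segments, long-format.

    ``table`` columns: scale, start, length, t_s, mean_hr, hr_std, alpha.
    """

    table: pd.DataFrame
    a: float
    order: int
    overlap: float

    value_col = "alpha"
    row_col = "scale"

    @property
    def scales(self) -> np.ndarray:
        return np.unique(self.table["scale"].to_numpy())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, a=np.nan, order=-1, overlap=np.nan) -> "DynamicExponentField":
        return cls(pd.read_csv(path, sep="\t"), a=a, order=order, overlap=overlap)


def compute_ddfa(
    series: RRISeries,
    scales=None,
    a: float = 5.0,
    order: int = 1,
    overlap: float = 0.5,
) -> DynamicExponentField:
    """Dynamic DFA exponents α(t,s) of an RR-interval series.

    For each scale the series is segmented with ℓ(s) = a·s; per segment,
    fluctuation functions at {s−1, s, s+1} (detrending order ``order``,
    maximally overlapping windows) feed the finite-difference estimate of
    the local exponent.  Scales with no admissible segment are omitted
    with a warning.

    Returns a :class:`DynamicExponentField` whose table carries one row
    per (scale, segment) with the segment time, mean HR and HR standard
    deviation.
    """
    if scales is None:
        scales = default_scale_grid()
    scales = np.unique(np.asarray(scales, dtype=int))
    if scales.min() < order + 3:
        raise ValueError(
            f"min scale {scales.min()} < order + 3 = {order + 3}; "
            "s-1 must support an order-{order} fit"
        )
    frames = []
    for s in scales:
        grid = dynamic_segments(
            len(series), int(s), a=a, overlap=overlap, times=series.times, hr=series.hr
        )
        if len(grid) == 0:
            continue
        x = series.intervals[grid.indices]
        F = _batched_fluctuations(x, (s - 1, s, s + 1), order)
        with np.errstate(divide="ignore"):
            lnF = np.log(F)
        lnF[~(F > 0)] = np.nan
        alpha = finite_difference_alpha(lnF[:, 0], lnF[:, 1], lnF[:, 2], float(s))
        frames.append(
            pd.DataFrame(
                {
                    "scale": s,
                    "start": grid.starts,
                    "length": grid.length,
                    "t_s": grid.t,
                    "mean_hr": grid.mean_hr,
                    "hr_std": grid.hr_std,
                    "alpha": np.atleast_1d(alpha),
                }
            )
        )
    if not frames:
        raise ValueError("no scale produced any segment")
    table = pd.concat(frames, ignore_index=True)
    return DynamicExponentField(table=table, a=a, order=order, overlap=overlap)
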