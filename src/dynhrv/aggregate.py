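"""Heart-rate-binned aggregation of dynamic correlation fields.

Maps α(t,s) or C(t,τ) segment values onto a heart-rate axis: per scale or
lag row, segment values whose mean segment HR falls in a bin are averaged
(0.1-BPM bins on the absolute axis, 0.001 on the relative axis by
convention), short runs of empty bins are linearly interpolated, and
optional per-HR-bin probability densities and HR-stability quantile
filters support robustness analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dfa import moving_alpha1
from .rr_io import RRISeries

__all__ = [
    "HRBinnedMap",
    "DensityMap",
    "bin_field_by_hr",
    "alpha1_hr_curve",
    "probability_density_map",
    "quantile_filter_segments",
]


def _as_table(field, value_col=None, row_col=None):
    """Accept a field object or a long DataFrame; return (table, value, row)."""
    if hasattr(field, "table"):
        return field.table, field.value_col, field.row_col
    df = pd.DataFrame(field)
    if value_col is None:
        value_col = "alpha" if "alpha" in df.columns else "C"
    if row_col is None:
        row_col = "scale" if "scale" in df.columns else "lag"
    return df, value_col, row_col


@dataclass
class HRBinnedMap:
    """Field values averaged into heart-rate bins, one row per scale/lag.

    ``mean_value[i, j]`` is the average field value of row ``rows[i]`` in
    HR bin ``bin_centers[j]``; NaN where the bin is empty and was not
    interpolated.  ``count`` holds segment counts (zero for interpolated
    bins), ``interpolated`` flags bins filled by linear interpolation.
    """

    axis: str
    bin_width: float
    bin_centers: np.ndarray
    rows: np.ndarray
    mean_value: np.ndarray
    count: np.ndarray
    interpolated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean_value, index=self.rows, columns=self.bin_centers)
        df.index.name = "row"
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def _interpolate_row(values: np.ndarray, filled: np.ndarray, max_run: int):
    """Linearly fill empty-bin runs no longer than ``max_run`` between filled bins."""
    out = values.copy()
    interp = np.zeros(values.size, dtype=bool)
    idx = np.flatnonzero(filled)
    for left, right in zip(idx[:-1], idx[1:]):
        run = right - left - 1
        if 0 < run <= max_run:
            frac = np.arange(1, run + 1) / (run + 1)
            out[left + 1 : right] = values[left] + frac * (values[right] - values[left])
            interp[left + 1 : right] = True
    return out, interp


def bin_field_by_hr(
    field,
    axis: str = "absolute",
    bin_width: float | None = None,
    max_gap: float | None = None,
    hr_max: float | None = None,
    value_col: str | None = None,
) -> HRBinnedMap:
    """Average segment values of a dynamic field into heart-rate bins.

    Parameters
    ----------
    field : DynamicExponentField, DynamicPACFField or long DataFrame
        Must carry ``mean_hr`` per segment.
    axis : {"absolute", "relative"}
        Absolute BPM bins (default width 0.1, interpolation gap 0.5 BPM)
        or bins of HR/hr_max (default width 0.001, gap 0.005).
    bin_width, max_gap : float, optional
        Override the axis defaults.  Empty bins are linearly interpolated
        from the flanking non-empty bins iff the gap, measured as
        ``bin_width × run length``, does not exceed ``max_gap``;
        interpolation never extrapolates beyond the outermost data.
    hr_max : float
        Subject maximum HR; required for the relative axis.
    """
    table, value_col, row_col = _as_table(field, value_col)
    if axis == "absolute":
        bin_width = 0.1 if bin_width is None else bin_width
        max_gap = 0.5 if max_gap is None else max_gap
        hr = table["mean_hr"].to_numpy(float)
    elif axis == "relative":
        if hr_max is None:
            raise ValueError("relative axis requires hr_max")
        bin_width = 0.001 if bin_width is None else bin_width
        max_gap = 0.005 if max_gap is None else max_gap
        hr = table["mean_hr"].to_numpy(float) / hr_max
    else:
        raise ValueError(f"unknown axis {axis!r}")

    values = table[value_col].to_numpy(float)
    ok = np.isfinite(hr) & np.isfinite(values)
    if not ok.any():
        raise ValueError("no finite (hr, value) pairs to bin")
    bin_idx = np.floor(hr / bin_width).astype(int)
    lo, hi = bin_idx[ok].min(), bin_idx[ok].max()
    n_bins = hi - lo + 1
    centers = (np.arange(lo, hi + 1) + 0.5) * bin_width
    rows = np.unique(table[row_col].to_numpy())
    max_run = int(np.floor(max_gap / bin_width + 1e-9))

    mean_value = np.full((rows.size, n_bins), np.nan)
    count = np.zeros((rows.size, n_bins), dtype=int)
    interpolated = np.zeros((rows.size, n_bins), dtype=bool)
    row_of = {r: i for i, r in enumerate(rows)}
    for r, sub in table.assign(_hrbin=bin_idx, _ok=ok).groupby(row_col):
        i = row_of[r]
        sub = sub[sub["_ok"]]
        grp = sub.groupby("_hrbin")[value_col]
        sums = grp.sum()
        ns = grp.size()
        cols = sums.index.to_numpy() - lo
        count[i, cols] = ns.to_numpy()
        mean_value[i, cols] = sums.to_numpy() / ns.to_numpy()
        filled = count[i] > 0
        mean_value[i], interpolated[i] = _interpolate_row(mean_value[i], filled, max_run)
    return HRBinnedMap(
        axis=axis,
        bin_width=bin_width,
        bin_centers=centers,
        rows=rows,
        mean_value=mean_value,
        count=count,
        interpolated=interpolated,
    )


def alpha1_hr_curve(
    series: RRISeries,
    window: int = 50,
    bin_width: float | None = None,
    axis: str = "absolute",
    hr_max: float | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Conventional short-scale exponent α₁ summarised per HR bin.

    Moving 50-beat α₁ records are grouped by window mean HR (2-BPM bins on
    the absolute axis, 0.01 on the relative axis by default); each
    populated bin reports mean, standard deviation, standard error of the
    mean and the record count.
    """
    if axis == "absolute":
        bin_width = 2.0 if bin_width is None else bin_width
        scale = 1.0
    elif axis == "relative":
        if hr_max is None:
            raise ValueError("relative axis requires hr_max")
        bin_width = 0.01 if bin_width is None else bin_width
        scale = hr_max
    else:
        raise ValueError(f"unknown axis {axis!r}")
    rec = moving_alpha1(series, window=window, stride=stride)
    rec = rec[np.isfinite(rec["alpha1"])]
    if rec.empty:
        return pd.DataFrame(columns=["hr_bin", "mean", "sd", "sem", "n"])
    hb = np.floor(rec["hr_bpm"].to_numpy() / scale / bin_width).astype(int)
    grp = rec.groupby(hb)["alpha1"]
    out = pd.DataFrame(
        {
            "hr_bin": (grp.mean().index.to_numpy() + 0.5) * bin_width,
            "mean": grp.mean().to_numpy(),
            "sd": grp.std(ddof=1).to_numpy(),
            "n": grp.size().to_numpy(),
        }
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[["hr_bin", "mean", "sd", "sem", "n"]].reset_index(drop=True)


@dataclass
class DensityMap:
    """Per-row 2-D probability densities over (HR bin, value bin).

    ``density[row]`` has shape (n_value_bins, n_hr_bins); every populated
    HR-bin column is normalised to unit sum, so columns compare value
    *distributions* across HR rather than HR prevalence.  ``cap`` is the
    percentile-capped colour-scale ceiling (display metadata only; the
    stored densities are uncapped).
    """

    rows: np.ndarray
    hr_edges: np.ndarray
    value_edges: dict
    density: dict
    cap: float
    cap_pct: float


def probability_density_map(
    field,
    rows_subset=None,
    axis: str = "absolute",
    hr_max: float | None = None,
    n_bins: int = 31,
    cap_pct: float = 99.5,
    value_col: str | None = None,
) -> DensityMap:
    """Column-normalised value histograms per scale/lag row against HR.

    For each selected row the finite segment values are histogrammed into
    ``n_bins`` value bins × ``n_bins`` HR bins and each HR column is
    normalised to unit mass.  Raises if fewer than two distinct HR values
    are present.
    """
    table, value_col, row_col = _as_table(field, value_col)
    hr = table["mean_hr"].to_numpy(float)
    if axis == "relative":
        if hr_max is None:
            raise ValueError("relative axis requires hr_max")
        hr = hr / hr_max
    ok = np.isfinite(hr)
    if np.unique(hr[ok]).size < 2:
        raise ValueError("need at least two distinct HR values")
    hr_edges = np.linspace(hr[ok].min(), hr[ok].max(), n_bins + 1)
    rows = np.unique(table[row_col].to_numpy())
    if rows_subset is not None:
        rows = np.asarray([r for r in rows if r in set(np.atleast_1d(rows_subset))])
    density: dict = {}
    value_edges: dict = {}
    for r in rows:
        sub = table[table[row_col] == r]
        v = sub[value_col].to_numpy(float)
        h = sub["mean_hr"].to_numpy(float) / (hr_max if axis == "relative" else 1.0)
        fin = np.isfinite(v) & np.isfinite(h)
        if not fin.any():
            warnings.warn(f"row {r}: no finite values; skipped")
            continue
        v, h = v[fin], h[fin]
        v_edges = np.linspace(v.min(), v.max(), n_bins + 1)
        if v_edges[0] == v_edges[-1]:  # degenerate: all values identical
            v_edges = np.linspace(v[0] - 0.5, v[0] + 0.5, n_bins + 1)
        hist, _, _ = np.histogram2d(v, h, bins=(v_edges, hr_edges))
        col_mass = hist.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            hist = np.where(col_mass > 0, hist / col_mass, 0.0)
        density[r] = hist
        value_edges[r] = v_edges
    if not density:
        raise ValueError("no row produced a density")
    all_d = np.concatenate([d.ravel() for d in density.values()])
    cap = float(np.percentile(all_d, cap_pct))
    return DensityMap(
        rows=rows,
        hr_edges=hr_edges,
        value_edges=value_edges,
        density=density,
        cap=cap,
        cap_pct=cap_pct,
    )


def quantile_filter_segments(field, q: float, per_row: bool = True):
    """Retain only segments with stable heart rate (low within-segment HR std).

    Keeps segments whose ``hr_std`` is strictly below the ``q``-quantile
    of the hr_std distribution — per scale/lag row by default, globally
    with ``per_row=False``.  ``q = 1`` retains everything.  Used to check
    that anticorrelation structure is not an artefact of HR trends within
    segments.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    table, _, row_col = _as_table(field)
    if q == 1.0:
        keep = np.ones(len(table), dtype=bool)
    elif per_row:
        thr = table.groupby(row_col)["hr_std"].transform(lambda x: np.quantile(x, q))
        keep = table["hr_std"].to_numpy() < thr.to_numpy()
    else:
        keep = table["hr_std"].to_numpy() < np.quantile(table["hr_std"].to_numpy(), q)
    filtered = table[keep].reset_index(drop=True)
    if hasattr(field, "table"):
        return replace(field, table=filtered)
    return filtered
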