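"""Reading, writing, validation and technical-artifact cleaning of RR-interval series.

An RR-interval (RRI) recording is the sequence of times between successive
heart beats, in milliseconds.  Two plain-text dialects are supported:

``single-column-ms``
    one interval per line, milliseconds;
``two-column-time-ms``
    tab-separated ``time_s`` (cumulative beat time, seconds) and ``rr_ms``.

Lines starting with ``#`` are comments in both dialects.  Cumulative beat
times and instantaneous heart rate are always rebuilt from the intervals, so
the invariants ``times[k] = sum(intervals[:k+1]) / 1000`` and
``hr[k] = 60000 / intervals[k]`` hold by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RRISeries",
    "ArtifactReport",
    "read_rr_series",
    "write_rr_series",
    "filter_technical_artifacts",
    "relative_hr",
]

DIALECTS = ("single-column-ms", "two-column-time-ms")


@dataclass
class RRISeries:
    """Beat-indexed RR intervals with derived cumulative time and heart rate.

    Attributes
    ----------
    intervals : ndarray
        Positive beat-to-beat intervals in milliseconds.
    times : ndarray
        Cumulative beat times in seconds, ``times[k] = Σ_{i<=k} intervals[i]/1000``.
    hr : ndarray
        Instantaneous heart rate per beat, ``60000 / intervals`` (BPM).
    source_label : str
        Free-text provenance tag.
    """

    intervals: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]
    hr: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size == 0:
            raise ValueError("no beats")
        if np.any(~np.isfinite(self.intervals)) or np.any(self.intervals <= 0):
            bad = int(np.flatnonzero(~(self.intervals > 0))[0])
            raise ValueError(f"non-positive or non-finite interval at beat {bad}")
        self.times = np.cumsum(self.intervals) / 1000.0
        self.hr = 60000.0 / self.intervals

    def __len__(self) -> int:
        return self.intervals.size

    @classmethod
    def from_intervals(cls, intervals, source_label: str = "") -> "RRISeries":
        return cls(intervals=np.asarray(intervals, dtype=float), source_label=source_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "rr_ms": self.intervals, "hr_bpm": self.hr}
        )


@dataclass
class ArtifactReport:
    """Summary of a technical-artifact filtering pass."""

    n_input: int
    n_removed: int
    n_corrected: int
    removed_indices: np.ndarray
    corrected_indices: np.ndarray

    def __post_init__(self) -> None:
        self.removed_indices = np.asarray(self.removed_indices, dtype=int)
        self.corrected_indices = np.asarray(self.corrected_indices, dtype=int)
        if self.n_removed + self.n_corrected > self.n_input:
            raise ValueError("more artifacts than beats")

    def to_frame(self) -> pd.DataFrame:
        rows = [("removed", i) for i in self.removed_indices] + [
            ("corrected", i) for i in self.corrected_indices
        ]
        return pd.DataFrame(rows, columns=["action", "beat_index"])


def _detect_dialect(path) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            return "two-column-time-ms" if len(line.split()) >= 2 else "single-column-ms"
    return "single-column-ms"


def read_rr_series(path, dialect: str = "auto") -> RRISeries:
    """Read an RR-interval series from a plain-text file.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"auto", "single-column-ms", "two-column-time-ms"}
        ``auto`` inspects the first data row.

    Raises
    ------
    ValueError
        On an empty file ("no beats"), an unparseable row, or a
        non-positive interval (the row number is reported).
    """
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")

    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                value = float(parts[1]) if dialect == "two-column-time-ms" else float(parts[0])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"unparseable row {lineno}: {line!r}") from exc
            if not value > 0:
                raise ValueError(f"non-positive interval {value} at row {lineno}")
            intervals.append(value)
    if not intervals:
        raise ValueError("no beats")
    return RRISeries.from_intervals(intervals, source_label=str(path))


def write_rr_series(path, series: RRISeries, dialect: str = "single-column-ms") -> None:
    """Write a series in one of the supported plain-text dialects."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "single-column-ms":
            for rr in series.intervals:
                fh.write(f"{rr:.10g}\n")
        else:
            fh.write("# time_s\trr_ms\n")
            for t, rr in zip(series.times, series.intervals):
                fh.write(f"{t:.10g}\t{rr:.10g}\n")


def relative_hr(hr, hr_max: float):
    """Heart rate expressed as a fraction of the subject's maximum heart rate."""
    if not hr_max > 0:
        raise ValueError("hr_max must be positive")
    return np.asarray(hr, dtype=float) / hr_max


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def filter_technical_artifacts(
    series: RRISeries,
    ratio_hi: float = 1.75,
    ratio_lo: float = 0.4,
    window: int = 11,
    split_lo: float = 0.75,
    split_hi: float = 1.25,
) -> tuple[RRISeries, ArtifactReport]:
    """Remove or correct technical recording artifacts such as missed beats.

    A beat whose interval is at least ``ratio_hi`` times the local median
    (centered ``window``-beat rolling median) is treated as a candidate
    missed-beat merge: if half the interval falls within
    ``[split_lo, split_hi]`` times the local median it is split into two
    equal halves and counted as *corrected*, otherwise it is *removed*.
    Beats below ``ratio_lo`` times the local median are removed.  No
    physiological (ectopic-beat) classification is attempted.

    Returns the cleaned series together with an :class:`ArtifactReport`.
    Series shorter than ``window`` are passed through with a warning.
    """
    if not (ratio_hi > 1 > ratio_lo > 0):
        raise ValueError("require ratio_hi > 1 > ratio_lo > 0")
    iv = series.intervals
    n = iv.size
    if n < window:
        warnings.warn("series shorter than the median window; passed through unfiltered")
        report = ArtifactReport(n, 0, 0, np.empty(0, int), np.empty(0, int))
        return replace(series), report

    med = _rolling_median(iv, window)
    out: list[float] = []
    removed: list[int] = []
    corrected: list[int] = []
    for i in range(n):
        x, m = iv[i], med[i]
        if x >= ratio_hi * m:
            if split_lo * m <= x / 2.0 <= split_hi * m:
                out.extend([x / 2.0, x / 2.0])
                corrected.append(i)
            else:
                removed.append(i)
        elif x <= ratio_lo * m:
            removed.append(i)
        else:
            out.append(x)
    if not out:
        raise ValueError("no beats survive artifact filtering")
    cleaned = RRISeries.from_intervals(out, source_label=series.source_label)
    report = ArtifactReport(
        n_input=n,
        n_removed=len(removed),
        n_corrected=len(corrected),
        removed_indices=np.array(removed, int),
        corrected_indices=np.array(corrected, int),
    )
    return cleaned, report
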