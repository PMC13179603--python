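"""Population statistics of ratiometric biosensors and cell size.

Two genetically encoded ratiometric sensors are read out per cell: the
QUEEN-2m ATP sensor (uvGFP/GFP; a higher ratio indicates a higher ATP
level) and the GlyRNA FBP sensor (CFP/RFP; a *lower* ratio indicates a
higher glycolytic flux).  For each condition the population distribution is
summarised per timepoint by the median and the 25-75 % interquartile range
of all pooled cells; a single condition-level value is then the arithmetic
mean of the per-timepoint medians within a fixed 10-18 h window (6 h after
the onset of the dynamics, avoiding the cell-number-limited early phase).
Values are compared across strains after normalisation to the
constant-excess control of the same experiment and window.

Gray values are assumed background-corrected upstream.  Fluorescence
metrics use only frames where all four channels are present (the 32 min
fluorescence cadence); cell size uses every 8 min phase-contrast frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSummary",
    "DEFAULT_WINDOW",
    "queen_ratio",
    "glyrna_ratio",
    "timepoint_summary",
    "metric_timepoints",
    "window_mean_of_medians",
    "queen_summary",
    "glyrna_summary",
    "size_summary",
    "normalize_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (10.0, 18.0)

_METRICS = ("queen_ratio", "glyrna_ratio", "area_um2")


@dataclass(frozen=True)
class PopulationSummary:
    """Per-timepoint medians/IQRs and their window mean for one metric.

    ``per_timepoint`` has columns (time_h, median, q25, q75, n_cells);
    ``window_mean_median`` is the arithmetic mean of the medians of the
    timepoints inside the closed window, and ``window_mean_iqr`` the same
    mean applied to the q25 and q75 series.  ``normalized`` is the window
    mean relative to the excess control (set by :func:`normalize_summary`).
    """

    metric: str
    per_timepoint: pd.DataFrame
    window: tuple[float, float]
    window_mean_median: float
    window_mean_iqr: tuple[float, float]
    normalized: float | None = None

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}, got {self.metric!r}")


def queen_ratio(gray_uvgfp, gray_gfp):
    """QUEEN-2m ATP readout: uvGFP / GFP.  Non-positive or missing inputs
    yield NaN (callers drop and count them)."""
    uv = np.asarray(gray_uvgfp, dtype=float)
    g = np.asarray(gray_gfp, dtype=float)
    out = np.where((uv > 0) & (g > 0), uv / np.where(g > 0, g, np.nan), np.nan)
    return float(out) if out.ndim == 0 else out


def glyrna_ratio(gray_cfp, gray_rfp):
    """GlyRNA FBP readout: CFP / RFP (lower ratio = higher glycolytic
    flux).  Non-positive or missing inputs yield NaN."""
    c = np.asarray(gray_cfp, dtype=float)
    r = np.asarray(gray_rfp, dtype=float)
    out = np.where((c > 0) & (r > 0), c / np.where(r > 0, r, np.nan), np.nan)
    return float(out) if out.ndim == 0 else out


def timepoint_summary(values) -> tuple[float, float, float, int]:
    """Median and 25th/75th percentiles (linear interpolation) of one
    timepoint's pooled cell values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("timepoint has no values")
    q25, med, q75 = np.percentile(v, [25.0, 50.0, 75.0])
    return float(med), float(q25), float(q75), int(v.size)


def _metric_values(table: pd.DataFrame, metric: str) -> pd.Series:
    if metric == "queen_ratio":
        vals = queen_ratio(table["gray_uvgfp"], table["gray_gfp"])
    elif metric == "glyrna_ratio":
        vals = glyrna_ratio(table["gray_cfp"], table["gray_rfp"])
    elif metric == "area_um2":
        vals = table["area_um2"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.Series(vals, index=table.index)


def metric_timepoints(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-timepoint (median, q25, q75, n_cells) of a metric over all pooled
    cells.  Fluorescence ratios are computed only at frames carrying all
    channels; records with non-positive channels are skipped and counted."""
    vals = _metric_values(table, metric)
    ok = vals.notna()
    if metric != "area_um2":
        present = table[["gray_uvgfp", "gray_gfp", "gray_cfp", "gray_rfp"]].notna().all(axis=1)
        n_skipped = int((present & ~ok).sum())
        if n_skipped:
            logger.warning("%s: skipped %d records with non-positive gray values",
                           metric, n_skipped)
    df = pd.DataFrame({"time_h": table["time_h"], "value": vals})[ok.to_numpy()]
    if df.empty:
        raise ValueError(f"no usable records for metric {metric!r}")
    rows = []
    for t, group in df.groupby("time_h"):
        med, q25, q75, n = timepoint_summary(group["value"].to_numpy())
        rows.append((t, med, q25, q75, n))
    return pd.DataFrame(rows, columns=["time_h", "median", "q25", "q75", "n_cells"])


def window_mean_of_medians(
    per_timepoint: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    metric: str = "queen_ratio",
) -> PopulationSummary:
    """Mean of per-timepoint medians (and quartiles) across the timepoints
    inside the closed window -- one plotted data point per condition."""
    t0, t1 = window
    inside = per_timepoint[(per_timepoint["time_h"] >= t0 - 1e-9)
                           & (per_timepoint["time_h"] <= t1 + 1e-9)]
    if inside.empty:
        raise ValueError(f"no timepoints inside window [{t0}, {t1}] h")
    return PopulationSummary(
        metric=metric,
        per_timepoint=per_timepoint,
        window=(float(t0), float(t1)),
        window_mean_median=float(inside["median"].mean()),
        window_mean_iqr=(float(inside["q25"].mean()), float(inside["q75"].mean())),
    )


def queen_summary(table: pd.DataFrame, window=DEFAULT_WINDOW) -> PopulationSummary:
    """QUEEN-2m ratio summary at fluorescence cadence."""
    return window_mean_of_medians(metric_timepoints(table, "queen_ratio"), window,
                                  "queen_ratio")


def glyrna_summary(table: pd.DataFrame, window=DEFAULT_WINDOW) -> PopulationSummary:
    """GlyRNA ratio summary at fluorescence cadence."""
    return window_mean_of_medians(metric_timepoints(table, "glyrna_ratio"), window,
                                  "glyrna_ratio")


def size_summary(table: pd.DataFrame, window=DEFAULT_WINDOW) -> PopulationSummary:
    """Cell-size summary at phase-contrast cadence."""
    return window_mean_of_medians(metric_timepoints(table, "area_um2"), window,
                                  "area_um2")


def normalize_summary(
    summary: PopulationSummary, control: PopulationSummary
) -> PopulationSummary:
    """Express a condition's window mean relative to the excess control of
    the same experiment and window; the control normalises to exactly 1."""
    if summary.metric != control.metric:
        raise ValueError(
            f"metric mismatch: {summary.metric!r} vs control {control.metric!r}"
        )
    if not control.window_mean_median > 0:
        raise ValueError("control window mean must be positive")
    return replace(summary, normalized=summary.window_mean_median / control.window_mean_median)
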