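"""Migration summary statistics from per-image detected areas.

The central quantity is the percentage change in the area enclosed by the
leading edge,

    M(t) = 100 * (A(t) - A(0)) / A(0),

together with replicate means and standard deviations of the detected
areas, equivalent circular radii ``sqrt(A / pi)``, and the
threshold-sweep envelope (the minimum and maximum mean areas detected over
the usable Sobel-threshold band, whose difference quantifies how sensitive
the migration estimate is to the threshold choice).

A(0) conventions
----------------
For the manual method, A(0) is the average of the minimum and maximum mean
initial areas over the threshold sweep, and this single value is used for
every manual M(t) in that condition.  Automatic methods use their own
t = 0 mean area.  These conventions reproduce the published worked-example
tables for the automatic pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AreaRecord",
    "ThresholdSweep",
    "replicate_summary",
    "equivalent_radius",
    "migration_rate",
    "initial_area_for_manual",
    "sweep_envelope",
    "summarize_detections",
]


@dataclass(frozen=True)
class AreaRecord:
    """One detected area: which image it came from and how."""

    condition: str
    time: float
    replicate: str
    method: str
    S: float | str
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")
        if self.time < 0:
            raise ValueError("time must be non-negative")


@dataclass
class ThresholdSweep:
    """Mean detected area per (S, time) for one condition.

    ``table`` has columns ``S``, ``time``, ``mean_area`` (and optionally
    ``sd_area``); ``S_min``/``S_max`` are the endpoints of the usable
    threshold band (a sub-range of the sweep grid).
    """

    table: pd.DataFrame
    S_min: float
    S_max: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.S_min >= self.S_max:
            raise ValueError("require S_min < S_max")
        self.table = self.table.sort_values(["time", "S"]).reset_index(drop=True)

    @property
    def S_grid(self) -> np.ndarray:
        return np.unique(self.table["S"].to_numpy())

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.table["time"].to_numpy())

    def band(self) -> pd.DataFrame:
        """Rows restricted to the usable band [S_min, S_max]."""
        t = self.table
        return t[(t["S"] >= self.S_min - 1e-12) & (t["S"] <= self.S_max + 1e-12)]

    def mean_area(self, S: float, time: float) -> float:
        t = self.table
        row = t[np.isclose(t["S"], S) & np.isclose(t["time"], time)]
        if row.empty:
            raise KeyError(f"no sweep entry at S={S}, t={time}")
        return float(row["mean_area"].iloc[0])


def replicate_summary(areas) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of areas.

    A single replicate has an undefined sample SD; it is reported as 0.0
    with a warning.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("replicate_summary needs at least one area")
    mean = float(areas.mean())
    if areas.size == 1:
        warnings.warn(
            "sample SD is undefined for a single replicate; reporting 0.0",
            stacklevel=2,
        )
        return mean, 0.0
    return mean, float(areas.std(ddof=1))


def equivalent_radius(area: float) -> float:
    """Radius (mm) of the circle enclosing the given area: sqrt(A/pi)."""
    if area < 0:
        raise ValueError(f"area must be non-negative, got {area}")
    return float(np.sqrt(area / np.pi))


def migration_rate(A0: float, At: float) -> float:
    """Percentage change in enclosed area, M = 100 * (At - A0) / A0."""
    if A0 <= 0:
        raise ValueError(f"initial area must be positive, got {A0}")
    return 100.0 * (At - A0) / A0


def initial_area_for_manual(sweep: ThresholdSweep) -> float:
    """Manual-method A(0): average of the min and max mean initial areas.

    The minimum and maximum are taken over the usable threshold band at
    t = 0; the single averaged value is then used for every manual M(t) of
    the condition.
    """
    band = sweep.band()
    t0 = band[np.isclose(band["time"], 0.0)]
    if t0.empty:
        raise ValueError("sweep has no t = 0 areas; cannot form A(0)")
    return float((t0["mean_area"].min() + t0["mean_area"].max()) / 2.0)


def sweep_envelope(sweep: ThresholdSweep, time: float) -> tuple[float, float, float]:
    """(min, max, max - min) of the band's mean areas at one time."""
    band = sweep.band()
    at_t = band[np.isclose(band["time"], time)]
    if at_t.empty:
        raise KeyError(f"time {time} h not present in sweep")
    lo = float(at_t["mean_area"].min())
    hi = float(at_t["mean_area"].max())
    return lo, hi, hi - lo


def summarize_detections(
    detections: pd.DataFrame,
    manual_A0: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Replicate means/SDs and M(t) from a per-image detection table.

    Parameters
    ----------
    detections : DataFrame
        Columns ``condition, time, replicate, method, S, area`` (one row
        per image per method/threshold).  ``S`` is numeric and NaN for the
        automatic methods, which choose their own threshold.  NaN areas
        (failed detections) are dropped.
    manual_A0 : dict, optional
        Per-condition A(0) for the manual method (from
        :func:`initial_area_for_manual`).  Without it, manual rows fall
        back to their own t = 0 mean, like the automatic methods.

    Returns
    -------
    DataFrame with columns ``condition, time, method, S, mean_area,
    sd_area, n_replicates, A0_used, M_percent``.
    """
    required = {"condition", "time", "replicate", "method", "S", "area"}
    missing = required - set(detections.columns)
    if missing:
        raise ValueError(f"detections table lacks columns {sorted(missing)}")
    clean = detections.dropna(subset=["area"])

    rows = []
    grouped = clean.groupby(["condition", "method", "S"], sort=True, dropna=False)
    for (cond, method, S), grp in grouped:
        per_time = grp.groupby("time")["area"]
        means = per_time.mean()
        sds = per_time.std(ddof=1).fillna(0.0)
        ns = per_time.count()
        if manual_A0 is not None and method == "manual" and cond in manual_A0:
            A0 = manual_A0[cond]
        elif 0.0 in means.index:
            A0 = float(means.loc[0.0])
        else:
            A0 = np.nan
        for t in means.index:
            rows.append(
                {
                    "condition": cond,
                    "time": float(t),
                    "method": method,
                    "S": S,
                    "mean_area": float(means.loc[t]),
                    "sd_area": float(sds.loc[t]),
                    "n_replicates": int(ns.loc[t]),
                    "A0_used": A0,
                    "M_percent": (
                        migration_rate(A0, float(means.loc[t]))
                        if np.isfinite(A0) and A0 > 0
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["condition", "method", "S", "time"], ignore_index=True
    )
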