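"""Published reference measurements for worked examples.

Mean detected areas (mm^2, three replicates) from a published circular
barrier assay of 3T3 fibroblasts (10,000 and 30,000 seeded cells; 0-72 h),
analysed with four edge-detection pipelines: the manual Sobel method at a
high and a low threshold, an automatic gradient-threshold Sobel method
("auto_matlab") and an interactive-tool automatic method ("auto_imagej").

These numbers are *inputs* for worked examples and regression checks of
the migration arithmetic — the package recomputes the migration rates
M(t) from them — not outputs of this package.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .metrics import migration_rate

__all__ = [
    "reference_areas",
    "reference_migration_rates",
    "manual_initial_area",
    "max_manual_spread",
]

_AREAS_CSV = """\
condition,time,method,mean_area,sd_area
10000,0,manual_s_high,27.4,0.67
10000,24,manual_s_high,31.9,0.91
10000,48,manual_s_high,36.2,1.91
10000,72,manual_s_high,39.7,1.98
10000,0,manual_s_low,30.1,1.61
10000,24,manual_s_low,36.0,0.63
10000,48,manual_s_low,43.4,0.68
10000,72,manual_s_low,47.1,0.62
10000,0,auto_imagej,30.3,0.83
10000,24,auto_imagej,35.0,2.26
10000,48,auto_imagej,41.3,1.11
10000,72,auto_imagej,45.8,0.81
10000,0,auto_matlab,29.0,1.64
10000,24,auto_matlab,34.2,0.78
10000,48,auto_matlab,39.1,2.64
10000,72,auto_matlab,44.6,0.81
30000,0,manual_s_high,31.1,0.21
30000,24,manual_s_high,44.8,2.11
30000,48,manual_s_high,50.0,1.52
30000,72,manual_s_high,52.9,2.25
30000,0,manual_s_low,33.5,0.34
30000,24,manual_s_low,50.3,1.08
30000,48,manual_s_low,55.5,1.78
30000,72,manual_s_low,60.8,2.11
30000,0,auto_imagej,33.1,1.40
30000,24,auto_imagej,49.9,1.40
30000,48,auto_imagej,55.2,1.57
30000,72,auto_imagej,55.9,3.01
30000,0,auto_matlab,30.0,1.56
30000,24,auto_matlab,45.0,2.12
30000,48,auto_matlab,51.4,1.47
30000,72,auto_matlab,54.6,3.10
"""


def reference_areas() -> pd.DataFrame:
    """The reference mean-area table (condition, time, method, mean, SD)."""
    return pd.read_csv(io.StringIO(_AREAS_CSV))


def manual_initial_area(condition: int) -> float:
    """Manual-method A(0): average of the tabulated t = 0 manual extremes."""
    t0 = reference_areas().query(
        "condition == @condition and time == 0 and method.str.startswith('manual')"
    )
    return float((t0["mean_area"].min() + t0["mean_area"].max()) / 2.0)


def reference_migration_rates() -> pd.DataFrame:
    """M(t) recomputed from the reference areas.

    Automatic methods use their own t = 0 mean area as A(0); the manual
    method uses the averaged min/max initial area of its condition.
    Returns columns ``condition, time, method, M_percent``.
    """
    areas = reference_areas()
    rows = []
    for (cond, method), grp in areas.groupby(["condition", "method"], sort=False):
        grp = grp.sort_values("time")
        if method.startswith("manual"):
            A0 = manual_initial_area(cond)
        else:
            A0 = float(grp.loc[grp["time"] == 0, "mean_area"].iloc[0])
        for _, row in grp[grp["time"] > 0].iterrows():
            rows.append(
                {
                    "condition": cond,
                    "time": float(row["time"]),
                    "method": method,
                    "M_percent": migration_rate(A0, float(row["mean_area"])),
                }
            )
    return pd.DataFrame(rows)


def max_manual_spread() -> float:
    """Largest spread (percentage points) between the manual low- and
    high-threshold migration rates across conditions and times."""
    m = reference_migration_rates()
    manual = m[m["method"].str.startswith("manual")]
    spread = (
        manual.pivot_table(
            index=["condition", "time"], columns="method", values="M_percent"
        )
        .eval("manual_s_low - manual_s_high")
        .to_numpy()
    )
    return float(np.max(spread))
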