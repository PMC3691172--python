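"""Physical interpretation of detected areas as cell-density contours.

Edge-detection algorithms return a boundary but no physical definition of
the leading edge.  This module supplies one: a detected area ``A`` is
matched with the density contour ``c`` of the diffusion-model solution
``u(r, t)`` that encloses the same area, i.e. ``c = u(r_c, t)`` with
``r_c = sqrt(A / pi)`` read off the monotone decreasing front of the
profile.  The usable Sobel-threshold band ``[S_min, S_max]`` is then mapped
linearly onto the bracketing contour band ``[c_min, c_max]``::

    c(S) = c_min + (S - S_min) * (c_max - c_min) / (S_max - S_min),

with ``S_min`` (largest detected area) paired with ``c_min`` (lowest
contour) and ``S_max`` with ``c_max``.  Since ``u`` is non-dimensional
(scaled by the carrying capacity ``K``), a contour level is directly a
fraction of the maximum packing density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffusion import DensityProfile
from .metrics import ThresholdSweep, sweep_envelope

__all__ = [
    "CalibrationMap",
    "contour_area",
    "area_to_contour",
    "scale_thresholds",
    "interpret_sweep",
]


@dataclass
class CalibrationMap:
    """Correspondence between Sobel thresholds and density contours.

    ``levels`` maps every sweep threshold ``S`` to its scaled contour
    level ``c(S)``; ``c_min``/``c_max`` bracket the band.  Contour levels
    are fractions of the maximum packing density, so ``100 * c`` is a
    percentage of ``K``.
    """

    S_min: float
    S_max: float
    c_min: float
    c_max: float
    time: float
    condition: str = ""
    levels: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.c_min < self.c_max:
            raise ValueError("require 0 < c_min < c_max")

    @property
    def band_percent(self) -> tuple[float, float]:
        """The contour band as percent of maximum packing density."""
        return 100.0 * self.c_min, 100.0 * self.c_max

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "time": self.time,
            "S_min": self.S_min,
            "S_max": self.S_max,
            "c_min": self.c_min,
            "c_max": self.c_max,
            "band_percent": list(self.band_percent),
            "levels": [{"S": s, "c": c} for s, c in self.levels],
        }


def _front(profile: DensityProfile, time: float) -> tuple[np.ndarray, np.ndarray]:
    """The monotone decreasing front of the profile: (r, u) from the peak out."""
    u = profile.u_at(time)
    peak = int(np.argmax(u))
    return profile.r[peak:], u[peak:]


def contour_area(profile: DensityProfile, time: float, c: float) -> float:
    """Area (mm^2) enclosed by the density contour ``u = c``.

    The crossing radius ``r_c`` is located on the decreasing front of the
    profile by piecewise-linear interpolation between grid points;
    ``area = pi * r_c**2``.  Raises if ``c`` is at or above the profile
    maximum, or at or below the outer-boundary value (no crossing).
    """
    r_front, u_front = _front(profile, time)
    if not 0 < c < u_front[0]:
        raise ValueError(
            f"contour level {c} has no crossing: profile maximum is {u_front[0]:.6g}"
        )
    if c <= u_front[-1]:
        raise ValueError(
            f"contour level {c} has no crossing: profile does not fall below it "
            f"(boundary value {u_front[-1]:.6g})"
        )
    below = np.flatnonzero(u_front < c)
    k = below[0]  # first grid point below the level, k >= 1
    r0, r1 = r_front[k - 1], r_front[k]
    u0, u1 = u_front[k - 1], u_front[k]
    r_c = r0 + (u0 - c) / (u0 - u1) * (r1 - r0)
    return float(np.pi * r_c**2)


def area_to_contour(profile: DensityProfile, time: float, area: float) -> float:
    """Density contour level enclosing the given area: inverse of
    :func:`contour_area`.

    ``r_c = sqrt(area / pi)`` must land on the monotone front region; the
    level is read off by the same piecewise-linear interpolation, so the
    round trip ``area_to_contour(contour_area(c)) == c`` holds to
    interpolation accuracy.
    """
    if area < 0:
        raise ValueError("area must be non-negative")
    r_front, u_front = _front(profile, time)
    r_c = np.sqrt(area / np.pi)
    if not r_front[0] <= r_c <= r_front[-1]:
        raise ValueError(
            f"equivalent radius {r_c:.4g} mm lies outside the front region "
            f"[{r_front[0]:.4g}, {r_front[-1]:.4g}] mm; area not invertible"
        )
    c = float(np.interp(r_c, r_front, u_front))
    if c <= 0:
        raise ValueError(
            f"area {area:.4g} mm^2 falls where the profile has vanished; "
            "no meaningful contour level"
        )
    return c


def scale_thresholds(
    S_grid,
    S_min: float,
    S_max: float,
    c_min: float,
    c_max: float,
) -> np.ndarray:
    """Linear map from thresholds to contour levels, endpoint-exact."""
    if S_min >= S_max:
        raise ValueError("require S_min < S_max")
    if c_min >= c_max:
        raise ValueError("require c_min < c_max")
    S = np.atleast_1d(np.asarray(S_grid, dtype=float))
    if np.any(S < S_min - 1e-12) or np.any(S > S_max + 1e-12):
        raise ValueError(f"thresholds must lie within [{S_min}, {S_max}]")
    levels = c_min + (S - S_min) * (c_max - c_min) / (S_max - S_min)
    levels[np.isclose(S, S_min, rtol=0, atol=1e-12)] = c_min  # endpoint-exact
    levels[np.isclose(S, S_max, rtol=0, atol=1e-12)] = c_max
    return levels


def interpret_sweep(
    sweep: ThresholdSweep,
    profile: DensityProfile,
    time: float,
) -> CalibrationMap:
    """Calibrate a threshold sweep against the model solution at one time.

    ``c_min`` is the contour enclosing the mean area detected with
    ``S_min`` (the largest area maps to the lowest density contour) and
    ``c_max`` the contour for ``S_max``; every threshold in the band is
    assigned its linearly scaled level.
    """
    lo_area, hi_area, _ = sweep_envelope(sweep, time)
    c_min = area_to_contour(profile, time, hi_area)
    c_max = area_to_contour(profile, time, lo_area)
    if c_min >= c_max:
        # degenerate sweep: all areas (hence contours) effectively equal
        c_max = c_min * (1 + 1e-12)
    band = sweep.band()
    S_values = np.unique(band[np.isclose(band["time"], time)]["S"].to_numpy())
    levels = scale_thresholds(S_values, sweep.S_min, sweep.S_max, c_min, c_max)
    return CalibrationMap(
        S_min=sweep.S_min,
        S_max=sweep.S_max,
        c_min=c_min,
        c_max=c_max,
        time=time,
        condition=sweep.condition,
        levels=list(zip(S_values.tolist(), levels.tolist())),
    )
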