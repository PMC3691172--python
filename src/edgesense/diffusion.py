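"""Axisymmetric linear diffusion model of a spreading cell population.

A population of cells is seeded uniformly inside a circular barrier of
radius ``a`` at the centre of a well of radius ``R``.  After the barrier is
lifted the population spreads by random, undirected motility, modelled by
the radially symmetric diffusion equation for the non-dimensional cell
density ``u(r, t)`` (dimensional density scaled by the carrying capacity
``K``)::

    du/dt = D * (1/r) * d/dr (r * du/dr),   0 <= r <= R,

with a symmetry condition ``du/dr = 0`` at ``r = 0``, a zero-flux condition
at the physical well edge ``r = R``, and the step initial condition
``u(r, 0) = C0`` for ``r <= a`` and ``0`` otherwise.  Cell proliferation is
deliberately absent: the assays this model describes are pretreated with
Mitomycin-C so spreading is driven by migration alone.

The solver uses a conservative finite-volume discretisation in ``r`` and
implicit (backward) Euler stepping in time, giving unconditional stability,
a discrete maximum principle and mass conservation to round-off.  The
``r = 0`` coordinate singularity is handled with the standard symmetry
limit of the operator, ``2 * d^2u/dr^2`` at the axis, which is exactly the
finite-volume flux balance for the half-cell around the origin.

Units: lengths in mm and times in hours internally; the diffusivity ``D``
is accepted in um^2/h (the unit cell diffusivities are usually reported in)
and converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import ive

__all__ = [
    "ModelParams",
    "DensityProfile",
    "carrying_capacity",
    "initial_density",
    "initial_condition",
    "solve",
    "total_mass",
    "infinite_domain_profile",
]

#: Average cell diameter (um) used throughout the package for 3T3 fibroblasts.
DEFAULT_CELL_DIAMETER_UM = 25.0

#: Well diameter 15.6 mm => well radius 7.8 mm.
DEFAULT_WELL_RADIUS_MM = 7.8

#: Barrier radius (mm).
DEFAULT_BARRIER_RADIUS_MM = 3.0


def carrying_capacity(cell_diameter_um: float) -> float:
    """Maximum monolayer density (cells/mm^2) under square packing.

    One cell occupies a ``d x d`` square, so ``K = 1 / d^2`` with ``d`` in
    mm.  For the default 25 um cell this gives 1600 cells/mm^2.
    """
    if cell_diameter_um <= 0:
        raise ValueError(f"cell diameter must be positive, got {cell_diameter_um}")
    d_mm = cell_diameter_um / 1000.0
    return 1.0 / d_mm**2


def initial_density(n_cells: float, a: float, K: float) -> float:
    """Non-dimensional initial density ``C0 = n / (K * pi * a^2)``.

    ``n_cells`` cells uniformly distributed inside the barrier of radius
    ``a`` (mm) cannot exceed the monolayer packing ``K * pi * a^2``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if a <= 0 or K <= 0:
        raise ValueError("barrier radius and carrying capacity must be positive")
    capacity = K * np.pi * a**2
    if n_cells > capacity:
        raise ValueError(
            f"{n_cells} cells exceed the monolayer packing capacity "
            f"({capacity:.0f} cells) of a barrier of radius {a} mm"
        )
    return n_cells / capacity


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the axisymmetric diffusion model.

    Parameters
    ----------
    D : float
        Cell diffusivity in um^2/h.  This is a required, assay-specific
        parameter: published estimates for fibroblast populations span
        several hundred to a few thousand um^2/h.
    C0 : float
        Initial non-dimensional density inside the barrier, in (0, 1].
    a, R : float
        Barrier radius and well radius (mm), ``0 < a < R``.
    K : float
        Carrying capacity (cells/mm^2); only used to convert the
        non-dimensional solution back to cell counts.
    dr, dt : float
        Uniform grid spacing (mm) and time step (h).
    """

    D: float
    C0: float
    a: float = DEFAULT_BARRIER_RADIUS_MM
    R: float = DEFAULT_WELL_RADIUS_MM
    K: float = field(default=carrying_capacity(DEFAULT_CELL_DIAMETER_UM))
    dr: float = 0.01
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not 0 < self.C0 <= 1:
            raise ValueError(f"C0 must lie in (0, 1], got {self.C0}")
        if not 0 < self.a < self.R:
            raise ValueError("require 0 < a < R")
        if self.dr <= 0 or self.dt <= 0:
            raise ValueError("dr and dt must be positive")

    @property
    def D_mm2_per_h(self) -> float:
        return self.D * 1e-6


@dataclass
class DensityProfile:
    """Radial density field ``u(r, t)`` on a uniform grid.

    ``u`` has shape ``(len(times), len(r))``; ``u[i]`` is the profile at
    ``times[i]`` hours.
    """

    r: np.ndarray
    u: np.ndarray
    times: np.ndarray
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.u.shape != (self.times.size, self.r.size):
            raise ValueError(
                f"u has shape {self.u.shape}, expected "
                f"({self.times.size}, {self.r.size})"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("density field contains non-finite values")

    def u_at(self, time: float) -> np.ndarray:
        """Profile at one of the saved times (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, time, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"time {time} h not among saved times {self.times}")
        return self.u[idx[0]]


def initial_condition(r: np.ndarray, C0: float, a: float) -> np.ndarray:
    """Step initial condition: ``C0`` inside the barrier, zero outside.

    Grid points exactly at ``r = a`` belong to the (closed) barrier interior
    and take the value ``C0``.
    """
    r = np.asarray(r, dtype=float)
    return np.where(r <= a * (1 + 1e-12), C0, 0.0)


def _build_operator(params: ModelParams, n: int) -> np.ndarray:
    """Banded (ab-form) implicit Euler matrix for ``solve_banded``."""
    dr, dt = params.dr, params.dt
    D = params.D_mm2_per_h
    beta = D * dt / dr**2
    r = np.arange(n + 1) * dr

    lower = np.zeros(n + 1)
    diag = np.ones(n + 1)
    upper = np.zeros(n + 1)

    # interior finite-volume cells: faces at r_{i +/- 1/2}, volume r_i * dr
    i = np.arange(1, n)
    r_minus = r[i] - dr / 2
    r_plus = r[i] + dr / 2
    lower[i] = -beta * r_minus / r[i]
    upper[i] = -beta * r_plus / r[i]
    diag[i] = 1 + beta * (r_minus + r_plus) / r[i]

    # axis: symmetry limit 2 * u_rr -> 4 (u_1 - u_0) / dr^2, equivalently
    # the flux balance for the half-cell of volume dr^2 / 8
    diag[0] = 1 + 4 * beta
    upper[0] = -4 * beta

    # outer wall: zero-flux half cell of volume R*dr/2 - dr^2/8
    vol_n = r[n] * dr / 2 - dr**2 / 8
    gamma = D * dt * (r[n] - dr / 2) / (dr * vol_n)
    diag[n] = 1 + gamma
    lower[n] = -gamma

    ab = np.zeros((3, n + 1))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return ab


def solve(params: ModelParams, save_times) -> DensityProfile:
    """Solve the model and return profiles at the requested times.

    ``save_times`` must be (numerically) integer multiples of ``dt``; the
    solver steps exactly onto each saved time rather than interpolating.
    A grid with fewer than 10 points across the barrier (``a/dr < 10``)
    triggers a warning because the step initial condition is then poorly
    resolved.
    """
    save_times = np.atleast_1d(np.asarray(save_times, dtype=float))
    if save_times.size == 0:
        raise ValueError("save_times must not be empty")
    if np.any(np.diff(save_times) <= 0) or save_times[0] < 0:
        raise ValueError("save_times must be non-negative and strictly increasing")
    steps = save_times / params.dt
    if not np.allclose(steps, np.round(steps), rtol=0, atol=1e-6):
        raise ValueError(
            f"save_times {save_times} are not integer multiples of dt={params.dt}"
        )
    steps = np.round(steps).astype(int)

    if params.a / params.dr < 10:
        warnings.warn(
            f"a/dr = {params.a / params.dr:.1f} < 10: the initial step is "
            "coarsely resolved; consider a finer dr",
            stacklevel=2,
        )

    n = int(round(params.R / params.dr))
    r = np.arange(n + 1) * params.dr
    ab = _build_operator(params, n)

    u = initial_condition(r, params.C0, params.a)
    out = np.empty((save_times.size, n + 1))
    done = 0
    for k, target in enumerate(steps):
        for _ in range(target - done):
            u = solve_banded((1, 1), ab, u, overwrite_b=True)
        done = target
        out[k] = u
    return DensityProfile(r=r, u=out, times=save_times, params=params)


def total_mass(profile: DensityProfile, time: float) -> float:
    """Cell count ``K * 2*pi * integral(u r dr)`` by the trapezoid rule."""
    u = profile.u_at(time)
    K = profile.params.K if profile.params is not None else 1.0
    return K * 2 * np.pi * np.trapezoid(u * profile.r, profile.r)


def infinite_domain_profile(
    r, t: float, D_mm2_per_h: float, C0: float, a: float, order: int = 400
) -> np.ndarray:
    """Closed-form infinite-domain solution for an initially uniform disk.

    Quadrature of the radial heat kernel:

        u(r, t) = C0 * int_0^a rho/(2 D t) * exp(-(r^2+rho^2)/(4 D t))
                       * I0(r rho / (2 D t)) drho,

    evaluated with the exponentially scaled Bessel function ``ive`` for
    numerical stability and Gauss-Legendre quadrature of the given order.
    Valid as a reference for the finite-well solution only while the
    spreading front is far from the outer wall.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if t <= 0:
        return np.where(r <= a, C0, 0.0)
    Dt = D_mm2_per_h * t
    nodes, wts = np.polynomial.legendre.leggauss(order)
    rho = 0.5 * a * (nodes + 1.0)
    w = 0.5 * a * wts
    # exp(-(r-rho)^2/(4Dt)) * ive(0, r rho / (2Dt)) == exp(-(r^2+rho^2)/(4Dt)) I0(...)
    rr = r[:, None]
    arg = rr * rho[None, :] / (2 * Dt)
    integrand = (
        rho[None, :]
        / (2 * Dt)
        * np.exp(-((rr - rho[None, :]) ** 2) / (4 * Dt))
        * ive(0, arg)
    )
    return C0 * integrand @ w
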