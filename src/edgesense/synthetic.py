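"""Synthetic barrier-assay micrographs with known ground truth.

The generator emulates fixed, crystal-violet-stained spreading assays
imaged on a stereo microscope: cells appear as small dark disks on a light,
nearly uniform background.  Cell positions are drawn from a radial density
profile (typically a solution of the diffusion model in
:mod:`edgesense.diffusion`), rendered as stained disks, optically blurred
and corrupted with sensor noise.  Because the generating density is known
exactly, every downstream stage — edge detection, threshold sweeps,
density-contour calibration — can be validated end to end.

Conventions
-----------
* Physical coordinates are mm, with the origin at the barrier centre
  (image centre).  Pixel ``(i, j)`` has centre
  ``((j - size/2 + 0.5) * scale, (i - size/2 + 0.5) * scale)``.
* Stain polarity: cells are dark on a light background by default
  (``invert=True`` flips this for fluorescence-like imagery).
* Overlapping cells compose to the single stain intensity (saturation), so
  darkness does not accumulate without bound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .detection import AssayImage
from .diffusion import DensityProfile

__all__ = [
    "RenderParams",
    "CellPositions",
    "sample_cell_positions",
    "render_assay_image",
    "make_disk_fixture",
]


@dataclass(frozen=True)
class RenderParams:
    """Rendering configuration for synthetic assay images.

    Parameters
    ----------
    pixel_scale : float
        Physical size of one pixel (mm/px).  The default 0.01 mm/px makes a
        25 um cell 2.5 px across, matching low-magnification
        stereo-microscope appearance.
    image_size : int
        Image side length in pixels.  The default 1600 px covers a 16 mm
        field, enough for the 15.6 mm well.
    cell_diameter : float
        Cell diameter in um.
    stain_intensity : float
        Darkness added by the stain, in [0, 1].  A stained pixel takes the
        value ``background_level - stain_intensity`` (clipped to [0, 1]).
    blur_sigma : float
        Gaussian optical blur in pixels.
    noise_sd : float
        Additive Gaussian sensor noise (intensity units).  Stained
        brightfield images are high-contrast and smooth, so the default is
        a small fraction of the intensity range.
    background_level : float
        Background intensity in [0, 1].
    invert : bool
        If True, cells are bright on a dark background.
    seed : int
        Base RNG seed for the noise field (positions carry their own seed).
    """

    pixel_scale: float = 0.01
    image_size: int = 1600
    cell_diameter: float = 25.0
    stain_intensity: float = 0.9
    blur_sigma: float = 1.0
    noise_sd: float = 0.001
    background_level: float = 0.95
    invert: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.image_size < 8:
            raise ValueError("image_size too small to contain a region of interest")
        if self.cell_diameter <= 0:
            raise ValueError("cell_diameter must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.stain_intensity <= 1:
            raise ValueError("stain_intensity must lie in [0, 1]")
        if not 0 <= self.background_level <= 1:
            raise ValueError("background_level must lie in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")

    @property
    def field_mm(self) -> float:
        return self.image_size * self.pixel_scale

    @property
    def cell_radius_px(self) -> float:
        return (self.cell_diameter / 1000.0) / self.pixel_scale / 2.0

    def with_(self, **kwargs) -> "RenderParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CellPositions:
    """Cell centres in mm relative to the barrier centre."""

    coordinates: np.ndarray  # shape (n, 2): columns x, y

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "coordinates", coords)

    @property
    def count(self) -> int:
        return self.coordinates.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.coordinates[:, 0], self.coordinates[:, 1])


def sample_cell_positions(
    profile: DensityProfile,
    n_cells: int,
    seed: int,
    time: float | None = None,
) -> CellPositions:
    """Draw cell positions from a radial density profile.

    Radial coordinates are sampled by inverse-CDF sampling from the density
    ``r * u(r)`` (normalised); angles are uniform on [0, 2*pi).  With a
    fixed seed the draw is fully deterministic.

    Parameters
    ----------
    profile : DensityProfile
        Density field; if it holds several times, ``time`` selects one.
    n_cells : int
        Number of cells to place.
    seed : int
        RNG seed.
    time : float, optional
        Which saved time to sample from; defaults to the only saved time.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if time is None:
        if profile.times.size != 1:
            raise ValueError("profile holds several times; pass `time`")
        time = float(profile.times[0])
    u = profile.u_at(time)
    if np.any(u < 0):
        raise ValueError("density profile must be non-negative")
    if n_cells == 0:
        return CellPositions(np.empty((0, 2)))

    r = profile.r
    w = r * u
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(r))])
    if cdf[-1] <= 0:
        raise ValueError("cannot sample positions from an all-zero density profile")
    cdf /= cdf[-1]

    rng = np.random.default_rng(seed)
    q = rng.random(n_cells)
    # inverse CDF with linear interpolation inside each grid interval
    idx = np.clip(np.searchsorted(cdf, q, side="right"), 1, cdf.size - 1)
    c0, c1 = cdf[idx - 1], cdf[idx]
    frac = np.where(c1 > c0, (q - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
    radii = r[idx - 1] + frac * (r[idx] - r[idx - 1])
    theta = rng.uniform(0.0, 2 * np.pi, n_cells)
    return CellPositions(np.column_stack([radii * np.cos(theta), radii * np.sin(theta)]))


def _pixel_coords(params: RenderParams) -> float:
    """Offset converting mm coordinates to pixel indices."""
    return params.image_size / 2.0 - 0.5


def render_assay_image(
    positions: CellPositions,
    params: RenderParams,
    *,
    time: float = 0.0,
    condition: str = "",
    replicate_id: str = "",
    seed: int | None = None,
) -> AssayImage:
    """Render cell positions as a stained, blurred, noisy micrograph.

    Each cell is drawn as a filled disk of ``cell_diameter`` (converted to
    pixels, rasterised at pixel-centre resolution), darker than the
    background; the image is then Gaussian-blurred and corrupted with
    additive Gaussian noise, clipped to [0, 1].  Deterministic under a
    fixed seed.
    """
    r_px = params.cell_radius_px
    if 2 * r_px < 1.0:
        raise ValueError(
            f"cell diameter {params.cell_diameter} um is below one pixel at "
            f"{params.pixel_scale} mm/px; use a finer pixel_scale"
        )
    half_field = params.field_mm / 2.0
    if positions.count and np.max(np.abs(positions.coordinates)) + r_px * params.pixel_scale > half_field:
        raise ValueError("cell positions do not fit within the rendered field of view")

    size = params.image_size
    canvas = np.full((size, size), params.background_level, dtype=float)
    cell_value = params.background_level + (
        params.stain_intensity if params.invert else -params.stain_intensity
    )
    cell_value = float(np.clip(cell_value, 0.0, 1.0))

    if positions.count:
        off = _pixel_coords(params)
        cx = np.rint(positions.coordinates[:, 0] / params.pixel_scale + off).astype(int)
        cy = np.rint(positions.coordinates[:, 1] / params.pixel_scale + off).astype(int)
        span = int(np.floor(r_px))
        dy, dx = np.mgrid[-span : span + 1, -span : span + 1]
        inside = (dy**2 + dx**2) <= r_px**2
        dy, dx = dy[inside], dx[inside]
        rows = (cy[:, None] + dy[None, :]).ravel()
        cols = (cx[:, None] + dx[None, :]).ravel()
        ok = (rows >= 0) & (rows < size) & (cols >= 0) & (cols < size)
        canvas[rows[ok], cols[ok]] = cell_value

    if params.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, params.blur_sigma)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed if seed is None else seed)
        canvas = canvas + rng.normal(0.0, params.noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return AssayImage(
        pixels=canvas,
        pixel_scale=params.pixel_scale,
        time=time,
        condition=condition,
        replicate_id=replicate_id,
    )


def make_disk_fixture(
    radius: float,
    params: RenderParams,
    *,
    center: tuple[float, float] = (0.0, 0.0),
) -> AssayImage:
    """Sharp, uniformly stained disk with exactly known enclosed area.

    The disk of the given radius (mm) is drawn with no blur and no noise so
    its true area is ``pi * radius**2`` exactly; it is the ground-truth
    fixture for area-accuracy tests of the edge detectors.
    """
    if radius <= 0:
        raise ValueError(f"disk radius must be positive, got {radius}")
    if max(abs(center[0]), abs(center[1])) + radius >= params.field_mm / 2.0:
        raise ValueError("disk does not fit in the field of view")
    size = params.image_size
    off = _pixel_coords(params)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    x_mm = (xx - off) * params.pixel_scale
    y_mm = (yy - off) * params.pixel_scale
    inside = (x_mm - center[0]) ** 2 + (y_mm - center[1]) ** 2 <= radius**2
    cell_value = params.background_level + (
        params.stain_intensity if params.invert else -params.stain_intensity
    )
    pixels = np.full((size, size), params.background_level, dtype=float)
    pixels[inside] = float(np.clip(cell_value, 0.0, 1.0))
    return AssayImage(pixels=pixels, pixel_scale=params.pixel_scale, time=0.0)
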