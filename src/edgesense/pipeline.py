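"""End-to-end study orchestration: generate -> detect -> summarize ->
model -> calibrate.

A :class:`RunConfig` describes a whole synthetic barrier-assay study: the
seeding conditions (cell count and diffusivity per condition), the imaging
times and replicate count, rendering parameters, diffusion-model numerics
and the detection methods with their threshold sweep grid.  The pipeline

1. solves the diffusion model per condition and renders replicate
   micrographs at every time (``generate_study``),
2. runs every detection method / threshold over every image
   (``detect_study``),
3. reduces per-image areas to replicate means/SDs, selects the usable
   threshold band, and computes M(t) (``summarize_study``),
4. calibrates the threshold sweep against the model solution
   (``calibrate_study``), and
5. writes images, CSV tables, calibration and manifest JSON
   (``run_pipeline``), deterministically for a fixed seed.

The usable threshold band reproduces the preliminary step of the manual
procedure: a wide threshold range is applied to all study images and only
thresholds producing a reasonable leading edge are retained.  Concretely,
a threshold is usable when detection succeeds on every image and the
replicate-mean area is non-decreasing in time in every condition (the
leading edge of a spreading population must track outward); thresholds
anchored to interior cell clumps fail this and are excluded.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationMap, interpret_sweep
from .detection import (
    AssayImage,
    DetectionError,
    detect_edge_imagej_style,
    manual_mask_from_magnitude,
    sobel_magnitude,
    to_grayscale,
)
from .diffusion import (
    DensityProfile,
    ModelParams,
    carrying_capacity,
    initial_density,
    solve,
)
from .io import write_image
from .metrics import ThresholdSweep, initial_area_for_manual, summarize_detections
from .synthetic import CellPositions, RenderParams, render_assay_image, sample_cell_positions

__all__ = [
    "ConditionConfig",
    "RunConfig",
    "default_config",
    "generate_study",
    "detect_study",
    "select_usable_band",
    "build_sweeps",
    "summarize_study",
    "calibrate_study",
    "run_pipeline",
]


@dataclass(frozen=True)
class ConditionConfig:
    """One seeding condition: cell count and its cell diffusivity."""

    n_cells: int
    D_um2_per_h: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", str(self.n_cells))


@dataclass
class RunConfig:
    """Full study configuration; see the module docstring."""

    conditions: list[ConditionConfig]
    times_h: list[float] = field(default_factory=lambda: [0.0, 24.0, 48.0, 72.0])
    replicates: int = 3
    seed: int = 1
    output_dir: str = "edgesense_out"
    render: RenderParams = field(default_factory=RenderParams)
    a_mm: float = 3.0
    R_mm: float = 7.8
    dr_mm: float = 0.01
    dt_h: float = 0.01
    cell_diameter_um: float = 25.0
    methods: list[str] = field(default_factory=lambda: ["manual", "auto", "imagej"])
    S_grid: list[float] = field(
        default_factory=lambda: [round(0.01 * k, 2) for k in range(1, 51)]
    )
    selem_radius: int = 7
    median_size: int = 5
    growth_slack: float = 0.02

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("config needs at least one condition")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.S_grid or sorted(self.S_grid) != list(self.S_grid):
            raise ValueError("S_grid must be a non-empty sorted list")
        unknown = set(self.methods) - {"manual", "auto", "imagej"}
        if unknown:
            raise ValueError(f"unknown detection methods {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["conditions"] = [ConditionConfig(**c) for c in d["conditions"]]
        if isinstance(d.get("render"), dict):
            d["render"] = RenderParams(**d["render"])
        grid = d.get("S_grid")
        if isinstance(grid, dict):
            start, stop, step = grid["start"], grid["stop"], grid["step"]
            n = int(round((stop - start) / step)) + 1
            d["S_grid"] = [round(start + k * step, 10) for k in range(n)]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def model_params(self, condition: ConditionConfig) -> ModelParams:
        K = carrying_capacity(self.cell_diameter_um)
        C0 = initial_density(condition.n_cells, self.a_mm, K)
        return ModelParams(
            D=condition.D_um2_per_h,
            C0=C0,
            a=self.a_mm,
            R=self.R_mm,
            K=K,
            dr=self.dr_mm,
            dt=self.dt_h,
        )


def default_config(seed: int = 1, **overrides) -> RunConfig:
    """The standard synthetic study: 10,000- and 30,000-cell assays,
    t = 0/24/48/72 h, three replicates, full threshold sweep."""
    cfg = dict(
        conditions=[
            ConditionConfig(n_cells=10000, D_um2_per_h=1000.0),
            ConditionConfig(n_cells=30000, D_um2_per_h=2000.0),
        ],
        seed=seed,
        render=RenderParams(pixel_scale=0.01, image_size=1100),
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def _derived_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence([base, *key]).generate_state(1)[0] % (2**31))


def generate_study(
    config: RunConfig,
) -> tuple[dict[str, DensityProfile], list[AssayImage]]:
    """Solve the model per condition and render every replicate image.

    Cells sampled outside the rendered field of view (possible only in the
    far exponential tail of the profile) are not drawn, as in a real
    micrograph cropped to the region of interest.
    """
    profiles: dict[str, DensityProfile] = {}
    images: list[AssayImage] = []
    margin = config.render.cell_radius_px * config.render.pixel_scale
    half_field = config.render.field_mm / 2.0 - margin
    for ci, cond in enumerate(config.conditions):
        params = config.model_params(cond)
        profile = solve(params, config.times_h)
        profiles[cond.label] = profile
        for ti, t in enumerate(config.times_h):
            for ri in range(config.replicates):
                pos = sample_cell_positions(
                    profile,
                    cond.n_cells,
                    seed=_derived_seed(config.seed, ci, ti, ri, 0),
                    time=t,
                )
                inside = np.max(np.abs(pos.coordinates), axis=1) < half_field
                images.append(
                    render_assay_image(
                        CellPositions(pos.coordinates[inside]),
                        config.render,
                        time=t,
                        condition=cond.label,
                        replicate_id=f"r{ri + 1}",
                        seed=_derived_seed(config.seed, ci, ti, ri, 1),
                    )
                )
    return profiles, images


def detect_study(config: RunConfig, images: list[AssayImage]) -> pd.DataFrame:
    """Run every configured method/threshold on every image.

    Returns one row per (image, method, S) with columns ``condition, time,
    replicate, method, S, area``; failed detections record ``NaN`` area.
    ``S`` is NaN for the automatic methods (they pick their own threshold;
    the value chosen by the gradient-statistic method is in ``S_used``).
    """
    rows = []
    for img in images:
        base = {
            "condition": img.condition,
            "time": img.time,
            "replicate": img.replicate_id,
        }
        magnitude = sobel_magnitude(to_grayscale(img))  # shared across the sweep
        if "manual" in config.methods:
            for S in config.S_grid:
                try:
                    mask = manual_mask_from_magnitude(
                        magnitude,
                        S,
                        img.pixel_scale,
                        selem_radius=config.selem_radius,
                        median_size=config.median_size,
                    )
                    area = mask.area
                except DetectionError:
                    area = np.nan
                rows.append({**base, "method": "manual", "S": S, "S_used": S, "area": area})
        if "auto" in config.methods:
            try:
                mean_mag = float(magnitude.mean())
                if mean_mag == 0.0:
                    raise DetectionError("constant image")
                S_auto = float(np.clip(4.0 * mean_mag, np.nextafter(0, 1), 1 - 1e-9))
                mask = manual_mask_from_magnitude(
                    magnitude,
                    S_auto,
                    img.pixel_scale,
                    selem_radius=config.selem_radius,
                    median_size=config.median_size,
                )
                area, used = mask.area, S_auto
            except DetectionError:
                area, used = np.nan, np.nan
            rows.append({**base, "method": "auto", "S": np.nan, "S_used": used, "area": area})
        if "imagej" in config.methods:
            try:
                mask = detect_edge_imagej_style(img, selem_radius=config.selem_radius)
                area = mask.area
            except DetectionError:
                area = np.nan
            rows.append({**base, "method": "imagej", "S": np.nan, "S_used": np.nan, "area": area})
    return pd.DataFrame(rows)


def select_usable_band(
    detections: pd.DataFrame,
    S_grid: list[float],
    growth_slack: float = 0.02,
) -> tuple[float, float]:
    """Preliminary threshold-band selection on the study's own images.

    A threshold is usable when (i) manual detection succeeded on every
    image and (ii) in every condition the replicate-mean area is
    non-decreasing in time within a relative slack (replicate noise).
    The band is the maximal contiguous run of usable thresholds starting
    at the lowest usable one.
    """
    manual = detections[detections["method"] == "manual"]
    usable = []
    for S in S_grid:
        at_S = manual[np.isclose(manual["S"], S)]
        if at_S["area"].isna().any():
            usable.append(False)
            continue
        ok = True
        for _, grp in at_S.groupby("condition"):
            means = grp.groupby("time")["area"].mean().sort_index().to_numpy()
            if np.any(means[1:] < means[:-1] * (1.0 - growth_slack)):
                ok = False
                break
        usable.append(ok)
    if not any(usable):
        raise RuntimeError("no usable thresholds: detection failed across the grid")
    first = usable.index(True)
    last = first
    while last + 1 < len(S_grid) and usable[last + 1]:
        last += 1
    if last == first:
        raise RuntimeError("usable threshold band is a single point; widen the grid")
    return float(S_grid[first]), float(S_grid[last])


def build_sweeps(
    detections: pd.DataFrame,
    S_min: float,
    S_max: float,
) -> dict[str, ThresholdSweep]:
    """Per-condition threshold sweeps (mean/SD area per S and time)."""
    manual = detections[detections["method"] == "manual"].dropna(subset=["area"])
    sweeps = {}
    for cond, grp in manual.groupby("condition"):
        table = (
            grp.groupby(["S", "time"])["area"]
            .agg(mean_area="mean", sd_area=lambda a: a.std(ddof=1) if len(a) > 1 else 0.0)
            .reset_index()
        )
        sweeps[cond] = ThresholdSweep(
            table=table, S_min=S_min, S_max=S_max, condition=str(cond)
        )
    return sweeps


def summarize_study(
    config: RunConfig, detections: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, ThresholdSweep], tuple[float, float]]:
    """Band selection, per-condition sweeps and the summary table."""
    S_min, S_max = select_usable_band(detections, config.S_grid, config.growth_slack)
    sweeps = build_sweeps(detections, S_min, S_max)
    manual_A0 = {cond: initial_area_for_manual(sweep) for cond, sweep in sweeps.items()}
    summary = summarize_detections(detections, manual_A0=manual_A0)
    return summary, sweeps, (S_min, S_max)


def calibrate_study(
    sweeps: dict[str, ThresholdSweep],
    profiles: dict[str, DensityProfile],
    times: list[float],
) -> list[CalibrationMap]:
    """Calibration maps for every condition at every positive time."""
    maps = []
    for cond, sweep in sweeps.items():
        for t in times:
            if t <= 0:
                continue
            maps.append(interpret_sweep(sweep, profiles[cond], t))
    return maps


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run all stages, write all artifacts, and return the run manifest."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    t0 = _time.perf_counter()
    profiles, images = generate_study(config)
    image_dir = out / "images"
    image_paths = []
    for img in images:
        name = f"cond{img.condition}_t{int(img.time):03d}_{img.replicate_id}.png"
        write_image(img, image_dir / name, extra={"seed": config.seed})
        image_paths.append(str(image_dir / name))
    for cond, profile in profiles.items():
        df = pd.DataFrame(
            {"r_mm": profile.r, **{f"u_t{int(t)}h": profile.u_at(t) for t in profile.times}}
        )
        df.to_csv(out / f"profile_{cond}.csv", index=False, float_format="%.9g")
    manifest["stages"]["simulate"] = {
        "seconds": round(_time.perf_counter() - t0, 2),
        "images": image_paths,
        "profiles": [str(out / f"profile_{c}.csv") for c in profiles],
    }

    t0 = _time.perf_counter()
    detections = detect_study(config, images)
    det_csv = out / "detections.csv"
    detections.to_csv(det_csv, index=False, float_format="%.6f")
    manifest["stages"]["detect"] = {
        "seconds": round(_time.perf_counter() - t0, 2),
        "detections": str(det_csv),
        "n_rows": int(len(detections)),
        "n_failed": int(detections["area"].isna().sum()),
    }

    t0 = _time.perf_counter()
    summary, sweeps, (S_min, S_max) = summarize_study(config, detections)
    sum_csv = out / "summary.csv"
    summary.to_csv(sum_csv, index=False, float_format="%.6f")
    envelopes = {}
    for cond, sweep in sweeps.items():
        from .metrics import sweep_envelope

        envelopes[cond] = {
            str(t): dict(
                zip(("min_area", "max_area", "difference"), sweep_envelope(sweep, t))
            )
            for t in config.times_h
        }
    env_json = out / "envelopes.json"
    env_json.write_text(
        json.dumps(
            {"S_min": S_min, "S_max": S_max, "envelopes": envelopes},
            indent=2,
            sort_keys=True,
        )
    )
    manifest["stages"]["summarize"] = {
        "seconds": round(_time.perf_counter() - t0, 2),
        "summary": str(sum_csv),
        "envelopes": str(env_json),
        "band": [S_min, S_max],
    }

    t0 = _time.perf_counter()
    maps = calibrate_study(sweeps, profiles, config.times_h)
    cal_json = out / "calibration.json"
    cal_json.write_text(
        json.dumps([m.to_dict() for m in maps], indent=2, sort_keys=True)
    )
    manifest["stages"]["calibrate"] = {
        "seconds": round(_time.perf_counter() - t0, 2),
        "calibration": str(cal_json),
    }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
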