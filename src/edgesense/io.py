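"""Reading and writing assay images with sidecar metadata.

Images are stored as 8-bit grayscale PNG or TIFF; the physical scale and
acquisition metadata travel in a JSON sidecar (``<image>.json``) so a
directory of images is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .detection import AssayImage

__all__ = ["write_image", "read_image", "sidecar_path"]


def sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(Path(image_path).suffix + ".json")


def write_image(image: AssayImage, path: str | Path, extra: dict | None = None) -> Path:
    """Write an 8-bit image plus its JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, data)
    meta = {
        "pixel_scale_mm": image.pixel_scale,
        "time_h": image.time,
        "replicate_id": image.replicate_id,
        "condition": image.condition,
    }
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_image(
    path: str | Path,
    pixel_scale: float | None = None,
) -> AssayImage:
    """Read a PNG/TIFF image, taking metadata from the sidecar if present.

    ``pixel_scale`` overrides (or supplies, when there is no sidecar) the
    physical scale in mm/px.
    """
    path = Path(path)
    data = np.asarray(iio.imread(path), dtype=float)
    if data.ndim == 3 and data.shape[2] == 4:  # drop alpha
        data = data[:, :, :3]
    if data.max() > 1.0:
        data = data / 255.0
    meta = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    scale = pixel_scale if pixel_scale is not None else meta.get("pixel_scale_mm")
    if scale is None:
        raise ValueError(
            f"{path} has no metadata sidecar; pass pixel_scale explicitly"
        )
    return AssayImage(
        pixels=data,
        pixel_scale=float(scale),
        time=float(meta.get("time_h", 0.0)),
        replicate_id=str(meta.get("replicate_id", "")),
        condition=str(meta.get("condition", "")),
    )
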