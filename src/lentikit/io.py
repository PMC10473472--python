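"""Reading and writing of calibrated images and tabular inputs.

Images travel as 16-bit grayscale TIFF (or 8/16-bit PNG) with the
physical calibration recorded in a YAML sidecar next to the image
(`<image>.yaml` with keys ``scale_um_per_px`` and ``channel``); the
sidecar can be overridden by an explicit scale.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .image_morphometry import CalibratedImage


def sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(".yaml")


def write_calibrated_image(image: CalibratedImage, path: str | Path) -> Path:
    """Write a 16-bit grayscale TIFF plus its YAML calibration sidecar."""
    path = Path(path)
    raster = np.clip(np.asarray(image.pixels, dtype=float), 0.0, 1.0)
    raster16 = np.round(raster * 65535).astype(np.uint16)
    tifffile.imwrite(path, raster16)
    side = sidecar_path(path)
    side.write_text(
        yaml.safe_dump(
            {
                "scale_um_per_px": float(image.scale_um_per_px),
                "channel": image.channel,
            },
            sort_keys=True,
        )
    )
    return side


def read_calibrated_image(
    path: str | Path,
    scale_um_per_px: float | None = None,
    channel: str | None = None,
) -> CalibratedImage:
    """Read TIFF/PNG; calibration from the sidecar unless overridden."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raster = tifffile.imread(path)
    else:
        raster = iio.imread(path)
    raster = np.asarray(raster)
    if raster.ndim == 3:  # collapse any color axis to grayscale
        raster = raster.mean(axis=-1)
    if raster.dtype == np.uint16:
        raster = raster.astype(float) / 65535.0
    elif raster.dtype == np.uint8:
        raster = raster.astype(float) / 255.0
    else:
        raster = raster.astype(float)

    side = sidecar_path(path)
    meta = {}
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
    scale = scale_um_per_px if scale_um_per_px is not None else meta.get("scale_um_per_px")
    if scale is None:
        raise ValueError(
            f"no calibration for {path}: provide scale_um_per_px or a sidecar"
        )
    chan = channel if channel is not None else meta.get("channel", "brightfield")
    return CalibratedImage(raster, float(scale), chan)


def read_fruit_table(path: str | Path) -> pd.DataFrame:
    """CSV of fruit measurements (dafb, mass_g, length_mm, diameter1_mm, diameter2_mm)."""
    df = pd.read_csv(path)
    required = {"dafb", "mass_g", "length_mm", "diameter1_mm", "diameter2_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fruit table missing columns: {sorted(missing)}")
    return df


def read_strain_table(path: str | Path) -> pd.DataFrame:
    """CSV of strain samples (areas plus has_lenticels flag)."""
    df = pd.read_csv(path)
    required = {"a_initial_mm2", "a_cm_mm2", "has_lenticels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"strain table missing columns: {sorted(missing)}")
    return df
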