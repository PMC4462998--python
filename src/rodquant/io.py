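"""Hyperstack reading/writing and results export.

Hyperstacks are multi-page TIFFs: 3D (channels, H, W) or 4D
(channels, frames, H, W), channel 1 phase contrast and channels 2..k
fluorescence.  The pixel scale (px/μm) is read from TIFF resolution
metadata (ImageJ-style, unit μm) or supplied as a config override.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from ._errors import ConfigurationError

__all__ = [
    "read_hyperstack",
    "write_hyperstack",
    "write_profile_map_tiff",
    "read_profile_map_tiff",
    "write_results_csv",
]

log = logging.getLogger(__name__)


def _scale_from_tiff(tif: tifffile.TiffFile) -> Optional[float]:
    """px/μm from TIFF resolution tags, or None when absent."""
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if den == 0 or num == 0:
        return None
    res = num / den  # pixels per resolution unit
    unit = None
    if tif.imagej_metadata:
        unit = tif.imagej_metadata.get("unit")
    if unit in ("um", "micron", "µm", "µm"):
        return float(res)
    if "ResolutionUnit" in tags and tags["ResolutionUnit"].value == 3:  # cm
        return float(res) / 1e4
    return float(res) if unit else None


def read_hyperstack(
    path: str | Path, px_per_um: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """Read a multichannel hyperstack; returns (array, px_per_um).

    The array is (channels, H, W) or (channels, frames, H, W).  Raises
    :class:`ConfigurationError` for single-channel files or a missing pixel
    scale without an override.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            meta_scale = _scale_from_tiff(tif)
            axes = None
            if tif.series:
                axes = tif.series[0].axes
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        raise ConfigurationError(
            f"{path} is a single-channel image; hyperstacks need a phase and "
            "at least one fluorescence channel"
        )
    if arr.ndim == 4 and axes and axes.startswith("T") and "C" in axes:
        # ImageJ writes TCYX for frames x channels; reorder to C,T,Y,X
        if axes[:2] == "TC":
            arr = np.moveaxis(arr, 0, 1)
    if arr.shape[0] < 2:
        raise ConfigurationError(
            f"{path} has {arr.shape[0]} channel(s); at least 2 required"
        )
    scale = px_per_um if px_per_um is not None else meta_scale
    if scale is None:
        raise ConfigurationError(
            f"{path} carries no px/μm scale; set px_per_um in the run config"
        )
    return arr.astype(np.float32), float(scale)


def write_hyperstack(path: str | Path, stack: np.ndarray, px_per_um: float) -> Path:
    """Write a (C, H, W) or (C, T, H, W) float32 hyperstack with μm scale."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    axes = "CYX" if stack.ndim == 3 else "CTYX"
    data = stack.astype(np.float32)
    if stack.ndim == 4:
        data = np.moveaxis(data, 1, 0)  # ImageJ expects TCYX
        axes = "TCYX"
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(px_per_um, px_per_um),
        metadata={"unit": "um", "axes": axes},
    )
    return path


def write_profile_map_tiff(path: str | Path, pmap, qualified_only: bool = False) -> Path:
    """Profile map as a 32-bit float multi-channel TIFF.

    Channel 0 holds the diameter columns (μm), subsequent channels the
    fluorescence columns, all vertically centered.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    planes = [pmap.to_image(None, qualified_only)[0]]
    for ch in pmap.channels:
        planes.append(pmap.to_image(ch, qualified_only)[0])
    if planes[0].size == 0:
        log.warning("empty profile map; writing a 1x1 placeholder TIFF")
        stack = np.zeros((len(planes), 1, 1), dtype=np.float32)
    else:
        stack = np.stack(planes).astype(np.float32)
    tifffile.imwrite(path, stack, imagej=True,
                     metadata={"axes": "CYX"})
    return path


def read_profile_map_tiff(path: str | Path) -> np.ndarray:
    """Reload a profile-map TIFF as a (channels, H, n_cells) float array."""
    return tifffile.imread(path).astype(np.float32)


def write_results_csv(path: str | Path, results: pd.DataFrame) -> Path:
    """Results table as UTF-8 comma-separated CSV ('.' decimal, full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if len(results) == 0:
        log.warning("no accepted cells; writing headers-only CSV")
    results.to_csv(path, index=False, float_format="%.17g")
    return path


def write_run_log(path: str | Path, payload: dict) -> Path:
    """Machine-readable provenance record (config, seed, tallies)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
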