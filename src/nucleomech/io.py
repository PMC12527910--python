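"""Reading and writing the package's on-disk formats.

Images travel as multi-page TIFF with ImageJ-style µm calibration
(intensity as 16-bit, masks as integer labels); particle tracks and force
curves as headered CSV with YAML/JSON sidecars for scalar metadata; ground
truth as a JSON sidecar next to the data it describes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import (CalibrationError, ForceCurve, GroundTruth,
                         LabeledVolume, NucleusMaskMovie, ParticleTracks)

PathLike = Union[str, Path]


# ---------------------------------------------------------------- TIFF

def _ij_metadata(pixel_size: float, spacing: float = 1.0,
                 finterval: Optional[float] = None) -> dict:
    meta = {"unit": "um", "spacing": spacing}
    if finterval is not None:
        meta["finterval"] = finterval
    return dict(imagej=True,
                resolution=(1.0 / pixel_size, 1.0 / pixel_size),
                metadata=meta)


def write_movie_tiff(path: PathLike, movie: NucleusMaskMovie,
                     channel: str = "mask") -> None:
    """Write the mask (integer labels) or intensity (uint16) channel."""
    if channel == "mask":
        data = movie.masks.astype(np.uint16)
    elif channel == "intensity":
        if movie.intensity is None:
            raise ValueError("movie has no intensity channel")
        data = np.clip(movie.intensity, 0, 65535).astype(np.uint16)
    else:
        raise ValueError("channel must be 'mask' or 'intensity'")
    tifffile.imwrite(path, data,
                     **_ij_metadata(movie.pixel_size,
                                    finterval=movie.frame_interval))


def read_movie_tiff(path: PathLike, pixel_size: Optional[float] = None,
                    frame_interval: Optional[float] = None,
                    intensity_path: Optional[PathLike] = None,
                    label: Optional[int] = None) -> NucleusMaskMovie:
    """Read a mask movie; calibration from ImageJ tags unless overridden.

    ``label`` selects one label as foreground from a multi-label movie.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        px, dt = _calibration_from_tif(tif)
    pixel_size = pixel_size if pixel_size is not None else px
    frame_interval = frame_interval if frame_interval is not None else dt
    if pixel_size is None or frame_interval is None:
        raise CalibrationError(
            "pixel_size/frame_interval not in TIFF metadata; pass explicitly")
    if label is not None:
        data = (data == label).astype(np.uint8)
    intensity = None
    if intensity_path is not None:
        intensity = tifffile.imread(intensity_path).astype(float)
    return NucleusMaskMovie(masks=data, pixel_size=pixel_size,
                            frame_interval=frame_interval, intensity=intensity)


def _calibration_from_tif(tif: "tifffile.TiffFile"):
    px = dt = None
    try:
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                px = den / num
        meta = tif.imagej_metadata or {}
        dt = meta.get("finterval")
    except Exception:
        pass
    return px, dt


def write_volume_tiff(path: PathLike, vol: LabeledVolume) -> None:
    vz, vy, vx = vol.voxel_size
    tifffile.imwrite(path, vol.voxels.astype(np.uint16),
                     **_ij_metadata(vx, spacing=vz))


def read_volume_tiff(path: PathLike,
                     voxel_size: Optional[tuple] = None) -> LabeledVolume:
    """Read a label stack; ``voxel_size`` (z, y, x) overrides TIFF tags."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if voxel_size is None:
            px, _ = _calibration_from_tif(tif)
            meta = tif.imagej_metadata or {}
            vz = meta.get("spacing")
            if px is None or vz is None:
                raise CalibrationError("voxel size not in TIFF; pass voxel_size")
            voxel_size = (vz, px, px)
    return LabeledVolume(voxels=data.astype(np.int64), voxel_size=voxel_size)


# ---------------------------------------------------------------- tracks

def write_tracks_csv(path: PathLike, tracks: ParticleTracks) -> None:
    tracks.data.to_csv(path, index=False,
                       columns=["track_id", "frame", "x_um", "y_um"])


def read_tracks_csv(path: PathLike, frame_interval: float) -> ParticleTracks:
    df = pd.read_csv(path)
    return ParticleTracks(data=df, frame_interval=frame_interval)


# ---------------------------------------------------------------- AFM

def write_force_curve_csv(path: PathLike, curve: ForceCurve,
                          sidecar: bool = True) -> None:
    pd.DataFrame({"z_um": curve.z_um,
                  "deflection_nm": curve.deflection_nm}).to_csv(path, index=False)
    if sidecar:
        cfg = {"spring_constant": float(curve.spring_constant)}
        if curve.sensitivity is not None:
            cfg["sensitivity"] = float(curve.sensitivity)
        Path(path).with_suffix(".yaml").write_text(yaml.safe_dump(cfg))


def read_force_curve_csv(path: PathLike,
                         spring_constant: Optional[float] = None) -> ForceCurve:
    df = pd.read_csv(path)
    if spring_constant is None:
        sidecar = Path(path).with_suffix(".yaml")
        if not sidecar.exists():
            raise CalibrationError("no spring constant: pass it or add a sidecar")
        cfg = yaml.safe_load(sidecar.read_text())
        spring_constant = float(cfg["spring_constant"])
    return ForceCurve(z_um=df["z_um"].to_numpy(),
                      deflection_nm=df["deflection_nm"].to_numpy(),
                      spring_constant=spring_constant)


# ---------------------------------------------------------------- truth

def write_truth_json(path: PathLike, truth: GroundTruth) -> None:
    Path(path).write_text(truth.to_json())


def read_truth_json(path: PathLike) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
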