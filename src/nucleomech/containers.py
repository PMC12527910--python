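"""Core data containers shared by the synthetic generators and the analysis modules.

All physical quantities are carried in fixed units: lengths in micrometres
(µm), times in seconds, forces in newtons, cantilever deflection in
nanometres, elastic moduli in pascal.  Image arrays follow numpy axis order
(t, y, x) for movies and (z, y, x) for volumes; voxel/pixel sizes are given
in the same axis order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    """Raised when spatial/temporal calibration metadata is missing or invalid."""


@dataclass
class GroundTruth:
    """Record of the parameters (and seed) a synthetic dataset was generated from.

    ``kind`` identifies the modality (``boundary``, ``volume``, ``tracks``,
    ``force``, ``condensate``); ``params`` holds every named scalar that went
    into the generator, so recovery tests can compare estimates against the
    truth without side channels.  Small non-scalar truths (e.g. spot
    centroids) live in ``extras``.
    """

    kind: str
    params: dict
    seed: int
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=_default, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"], seed=d["seed"],
                   extras=d.get("extras", {}))


@dataclass
class SyntheticDataset:
    """A generated payload bundled with the ground truth it was drawn from."""

    payload: object
    truth: GroundTruth


@dataclass
class NucleusMaskMovie:
    """Time series of single-nucleus masks with optional intensity channel.

    ``masks`` is (T, H, W) integer (0 background); ``intensity`` matches the
    shape when present.  ``pixel_size`` is µm/px, ``frame_interval`` seconds.
    """

    masks: np.ndarray
    pixel_size: float
    frame_interval: float
    intensity: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise CalibrationError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise CalibrationError("frame_interval must be positive")
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (T, H, W)")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.masks.shape:
                raise ValueError("intensity channel must match mask shape")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class LabeledVolume:
    """3D integer label image; 0 is background.  ``voxel_size`` is (z, y, x) µm."""

    voxels: np.ndarray
    voxel_size: tuple

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be (Z, H, W)")
        if np.issubdtype(self.voxels.dtype, np.floating):
            raise ValueError("labels must be integer")
        if self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")
        vz, vy, vx = self.voxel_size
        if min(vz, vy, vx) <= 0:
            raise CalibrationError("voxel dimensions must be positive")
        self.voxel_size = (float(vz), float(vy), float(vx))

    @property
    def voxel_volume(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    def labels(self) -> np.ndarray:
        lab = np.unique(self.voxels)
        return lab[lab > 0]


@dataclass
class ParticleTracks:
    """2D particle trajectories in µm, one row per localization.

    ``data`` has columns ``track_id, frame, x_um, y_um``; within a track the
    frames are strictly increasing (gaps allowed).
    """

    data: pd.DataFrame
    frame_interval: float

    REQUIRED = ("track_id", "frame", "x_um", "y_um")

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise CalibrationError("frame_interval must be positive")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"tracks table missing columns: {missing}")
        self.data = self.data.sort_values(["track_id", "frame"]).reset_index(drop=True)
        grp = self.data.groupby("track_id")["frame"]
        if (grp.diff().dropna() <= 0).any():
            raise ValueError("frames must be strictly increasing within a track")

    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()


@dataclass
class ForceCurve:
    """AFM approach segment: piezo height (µm) vs cantilever deflection (nm).

    ``z_um`` increases along the approach (the tip moves toward and then into
    the sample); ``spring_constant`` is in N/m.  ``baseline_noise_sd`` (nm) is
    filled in by baseline correction and used by contact-point detection.
    """

    z_um: np.ndarray
    deflection_nm: np.ndarray
    spring_constant: float
    sensitivity: Optional[float] = None
    baseline_noise_sd: Optional[float] = None

    def __post_init__(self):
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.deflection_nm = np.asarray(self.deflection_nm, dtype=float)
        if self.z_um.shape != self.deflection_nm.shape or self.z_um.ndim != 1:
            raise ValueError("z and deflection must be 1D arrays of equal length")
        if self.z_um.size < 50:
            raise ValueError("force curve needs >= 50 samples")
        dz = np.diff(self.z_um)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone over the approach")
        if np.all(dz < 0):  # store approach-ordered, increasing z
            self.z_um = self.z_um[::-1].copy()
            self.deflection_nm = self.deflection_nm[::-1].copy()
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")

    def force_n(self) -> np.ndarray:
        """Force in newtons (k · deflection)."""
        return self.spring_constant * self.deflection_nm * 1e-9


@dataclass
class CondensateScene:
    """Intensity image + nucleus mask + condensate mask trio for one cell.

    The condensate mask is clipped to the nucleus on construction (the
    aggregation metric divides by nuclear sums); a clip is recorded in
    ``flags`` rather than raised.
    """

    intensity: np.ndarray
    nucleus_mask: np.ndarray
    condensate_mask: np.ndarray
    pixel_size: float
    background_value: Optional[float] = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise CalibrationError("pixel_size must be positive")
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        self.condensate_mask = np.asarray(self.condensate_mask, dtype=bool)
        if not (self.intensity.shape == self.nucleus_mask.shape
                == self.condensate_mask.shape):
            raise ValueError("image and masks must share one shape")
        outside = self.condensate_mask & ~self.nucleus_mask
        if outside.any():
            self.condensate_mask = self.condensate_mask & self.nucleus_mask
            self.flags.append("condensate_mask_clipped_to_nucleus")
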