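"""Synthetic single-nucleus movies with a fluctuating envelope.

The boundary is synthesized in polar coordinates around the nucleus centre:

    r(theta, t) = R + sum_k [ a_k(t) cos(k theta) + b_k(t) sin(k theta) ]

with per-frame mode amplitudes a_k, b_k drawn i.i.d. N(0, sigma_r^2 / n_modes)
for k = 2 .. n_modes+1 (k=1 is excluded as it is degenerate with rigid
translation).
Because each (cos, sin) pair contributes variance sigma_r^2 / n_modes at every
angle, the pointwise radial displacement has temporal standard deviation
exactly ``radial_sigma`` for every theta — the quantity the envelope
fluctuation pipeline must recover.  Rigid drift (translation + rotation) and
exponential photobleaching are applied after shape synthesis so registration
and bleach correction can be exercised against known truth.
"""

from __future__ import annotations

import numpy as np

from ..containers import (CalibrationError, GroundTruth, NucleusMaskMovie,
                          SyntheticDataset)

#: fluorophore level of the nucleoplasm at t=0 (arbitrary camera units)
_I0 = 1000.0


def gen_boundary_movie(
    n_frames: int = 200,
    frame_interval: float = 0.15,
    pixel_size: float = 0.1,
    mean_radius: float = 5.0,
    radial_sigma: float = 0.2,
    n_modes: int = 8,
    drift: tuple = (0.0, 0.0),
    bleach_rate: float = 0.0,
    fov_margin: float = 1.5,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a mask + intensity movie of one fluctuating nucleus.

    Parameters
    ----------
    n_frames, frame_interval, pixel_size
        Movie length, frame spacing (s) and pixel calibration (µm/px).
    mean_radius, radial_sigma
        Mean nuclear radius and the true pointwise radial fluctuation
        amplitude, both in µm.  ``radial_sigma`` is the ground truth for the
        fluctuation pipeline.
    n_modes
        Number of low-order angular modes carrying the fluctuations.
    drift
        ``(translation µm/frame, rotation deg/frame)`` rigid drift applied
        cumulatively; translation is along +x.
    fov_margin
        Clearance (µm) between the fluctuation envelope and the image edge,
        sized so downstream normal-line sampling stays inside the field.
    bleach_rate
        Exponential intensity decay per frame (1/frame).
    seed
        RNG seed; identical (params, seed) give bit-identical movies.
    """
    if frame_interval <= 0 or pixel_size <= 0:
        raise CalibrationError("frame_interval and pixel_size must be positive")
    if mean_radius < 5 * pixel_size:
        raise ValueError("mean_radius must be at least 5 pixels")
    if radial_sigma < 0:
        raise ValueError("radial_sigma must be non-negative")
    if n_frames < 1 or n_modes < 1:
        raise ValueError("n_frames and n_modes must be >= 1")

    rng = np.random.default_rng(seed)
    drift_um, drift_deg = float(drift[0]), float(drift[1])

    # field of view: nucleus + fluctuations + full drift excursion + margin
    reach = mean_radius + 5 * radial_sigma + abs(drift_um) * (n_frames - 1) / 2
    half = int(np.ceil((reach + fov_margin) / pixel_size))
    n_px = 2 * half + 1
    centre0 = np.array([half * pixel_size, half * pixel_size])
    # start displaced so the drifted path stays centred in the field
    centre0 = centre0 - np.array([drift_um * (n_frames - 1) / 2, 0.0])[::-1]

    yy, xx = np.mgrid[0:n_px, 0:n_px].astype(float) * pixel_size

    mode_sd = radial_sigma / np.sqrt(n_modes)
    # modes start at k=2: the k=1 pair is, to first order, a rigid
    # translation of the whole boundary and would be removed (correctly) by
    # drift registration rather than measured as a fluctuation
    k = np.arange(2, n_modes + 2)

    masks = np.zeros((n_frames, n_px, n_px), dtype=np.uint8)
    intensity = np.zeros((n_frames, n_px, n_px), dtype=float)
    for t in range(n_frames):
        a = rng.normal(0.0, mode_sd, size=n_modes)
        b = rng.normal(0.0, mode_sd, size=n_modes)
        cy = centre0[0]
        cx = centre0[1] + drift_um * t
        rot = np.deg2rad(drift_deg * t)
        dy = yy - cy
        dx = xx - cx
        rho = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx) - rot
        r_theta = mean_radius + (np.cos(np.outer(theta.ravel(), k)) @ a
                                 + np.sin(np.outer(theta.ravel(), k)) @ b
                                 ).reshape(theta.shape)
        mask = rho <= r_theta
        masks[t] = mask
        intensity[t] = mask * _I0 * np.exp(-bleach_rate * t)

    movie = NucleusMaskMovie(masks=masks, pixel_size=pixel_size,
                             frame_interval=frame_interval, intensity=intensity)
    truth = GroundTruth(
        kind="boundary",
        params=dict(n_frames=n_frames, frame_interval=frame_interval,
                    pixel_size=pixel_size, mean_radius=mean_radius,
                    radial_sigma=radial_sigma, n_modes=n_modes,
                    drift_um_per_frame=drift_um, drift_deg_per_frame=drift_deg,
                    bleach_rate=bleach_rate),
        seed=seed,
    )
    return SyntheticDataset(payload=movie, truth=truth)
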