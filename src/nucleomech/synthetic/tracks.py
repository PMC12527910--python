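"""Synthetic 2D particle trajectories for MSD microrheology tests.

Three motion models are provided, all with the 2D convention
MSD(τ) = 4·D·τ^β:

``brownian``
    Independent Gaussian increments per axis with variance 2·D·Δt (β = 1).
``fbm``
    Fractional Brownian motion with Hurst exponent H = β/2, generated from
    the exact fractional-Gaussian-noise covariance (Cholesky factor shared
    across tracks), scaled so the ensemble MSD is 4·D·τ^β.
``confined``
    Brownian steps reflected at a circular corral of radius
    ``confinement_radius`` around the track origin.

Gaussian localization noise of standard deviation ``loc_noise`` per
coordinate is added to every stored position; it inflates the measured MSD
by the additive constant 4·loc_noise² at every lag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import GroundTruth, ParticleTracks, SyntheticDataset

_MODELS = ("brownian", "fbm", "confined")


def _fgn_cholesky(n_steps: int, hurst: float) -> np.ndarray:
    """Cholesky factor of the unit-variance fGn covariance (n_steps × n_steps)."""
    k = np.arange(n_steps)
    lag = np.abs(k[:, None] - k[None, :]).astype(float)
    h2 = 2 * hurst
    cov = 0.5 * ((lag + 1) ** h2 - 2 * lag ** h2 + np.abs(lag - 1) ** h2)
    # tiny jitter guards against loss of positive definiteness at H near 1
    return np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))


def gen_tracks(
    n_tracks: int = 100,
    n_frames: int = 300,
    frame_interval: float = 0.1,
    model: str = "brownian",
    D: float = 0.5,
    beta: float = 1.0,
    confinement_radius: float = 0.5,
    loc_noise: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate ``n_tracks`` trajectories of ``n_frames`` positions each.

    ``D`` is in µm²/s^β, ``beta`` is the anomalous-diffusion exponent
    (``brownian`` fixes beta=1), ``loc_noise`` is the per-coordinate
    localization error in µm.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    if n_frames < 3:
        raise ValueError("n_frames < 3: too short to form an MSD")
    if D < 0 or loc_noise < 0:
        raise ValueError("D and loc_noise must be non-negative")
    if model == "brownian":
        beta = 1.0
    elif model == "fbm" and not (0 < beta < 2):
        raise ValueError("fbm requires 0 < beta < 2")

    rng = np.random.default_rng(seed)
    dt = float(frame_interval)
    n_steps = n_frames - 1

    if model == "fbm":
        # per-axis MSD 2·D·τ^β  ->  per-step fGn std sqrt(2 D) dt^{β/2}
        L = _fgn_cholesky(n_steps, hurst=beta / 2.0)
        sd = np.sqrt(2.0 * D) * dt ** (beta / 2.0)
        zx = rng.standard_normal((n_steps, n_tracks))
        zy = rng.standard_normal((n_steps, n_tracks))
        x = np.vstack([np.zeros(n_tracks), np.cumsum(sd * (L @ zx), axis=0)])
        y = np.vstack([np.zeros(n_tracks), np.cumsum(sd * (L @ zy), axis=0)])
    else:
        sd = np.sqrt(2.0 * D * dt)
        steps_x = rng.normal(0.0, sd, size=(n_steps, n_tracks))
        steps_y = rng.normal(0.0, sd, size=(n_steps, n_tracks))
        if model == "brownian":
            x = np.vstack([np.zeros(n_tracks), np.cumsum(steps_x, axis=0)])
            y = np.vstack([np.zeros(n_tracks), np.cumsum(steps_y, axis=0)])
        else:  # confined: reflect radially at the corral boundary
            rc = float(confinement_radius)
            if rc <= 0:
                raise ValueError("confinement_radius must be positive")
            x = np.zeros((n_frames, n_tracks))
            y = np.zeros((n_frames, n_tracks))
            for t in range(1, n_frames):
                px = x[t - 1] + steps_x[t - 1]
                py = y[t - 1] + steps_y[t - 1]
                r = np.hypot(px, py)
                # radial reflection, iterated for steps larger than the corral
                for _ in range(32):
                    out = r > rc
                    if not out.any():
                        break
                    scale = np.abs(2 * rc - r[out]) / r[out]
                    px[out] *= scale
                    py[out] *= scale
                    r = np.hypot(px, py)
                x[t], y[t] = px, py

    if loc_noise > 0:
        x = x + rng.normal(0.0, loc_noise, size=x.shape)
        y = y + rng.normal(0.0, loc_noise, size=y.shape)

    frames = np.tile(np.arange(n_frames), n_tracks)
    ids = np.repeat(np.arange(n_tracks), n_frames)
    df = pd.DataFrame({
        "track_id": ids,
        "frame": frames,
        "x_um": x.T.ravel(),
        "y_um": y.T.ravel(),
    })
    tracks = ParticleTracks(data=df, frame_interval=dt)
    truth = GroundTruth(
        kind="tracks",
        params=dict(n_tracks=n_tracks, n_frames=n_frames, frame_interval=dt,
                    model=model, D=D, beta=beta,
                    confinement_radius=confinement_radius,
                    loc_noise=loc_noise),
        seed=seed,
    )
    return SyntheticDataset(payload=tracks, truth=truth)
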