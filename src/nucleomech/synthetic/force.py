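"""Synthetic AFM approach curves with Hertzian contact.

The piezo extends toward the sample (z increasing, µm).  Before the hidden
contact point ``contact_offset`` the cantilever reads only baseline tilt and
noise; past it, piezo travel is shared between indentation δ and cantilever
bending d (z − z_contact = δ + d), with the force F = k·d following the
closed-form contact law for the chosen tip geometry:

    paraboloid (radius R):      F = 4/3 · E/(1−ν²) · √R · δ^{3/2}
    four-sided pyramid (θ):     F = 0.7453 · E/(1−ν²) · tanθ · δ²
    cone (θ):                   F = 2/π · E/(1−ν²) · tanθ · δ²

The implicit δ(z) is solved to machine precision by Newton iteration, so a
noiseless generated curve embodies the contact law exactly — the basis for
the exact round-trip recovery tests.
"""

from __future__ import annotations

import numpy as np

from ..containers import ForceCurve, GroundTruth, SyntheticDataset

GEOMETRIES = ("paraboloid", "pyramid", "cone")


def hertz_prefactor(E: float, nu: float, geometry: str, tip_param: float) -> float:
    """Prefactor A such that F = A · δ^p (SI units: δ in m, F in N).

    ``tip_param`` is the tip radius in µm for a paraboloid, the face
    half-angle in degrees for pyramid/cone.
    """
    red = E / (1.0 - nu ** 2)
    if geometry == "paraboloid":
        return (4.0 / 3.0) * red * np.sqrt(tip_param * 1e-6)
    if geometry == "pyramid":
        return 0.7453 * red * np.tan(np.deg2rad(tip_param))
    if geometry == "cone":
        return (2.0 / np.pi) * red * np.tan(np.deg2rad(tip_param))
    raise ValueError(f"geometry must be one of {GEOMETRIES}")


def hertz_exponent(geometry: str) -> float:
    """Indentation exponent p of the contact law for a tip geometry."""
    if geometry == "paraboloid":
        return 1.5
    if geometry in ("pyramid", "cone"):
        return 2.0
    raise ValueError(f"geometry must be one of {GEOMETRIES}")


def _solve_indentation(travel_m: np.ndarray, A: float, p: float,
                       k: float) -> np.ndarray:
    """Solve A·δ^p / k + δ = travel for δ (m), vectorized Newton iteration."""
    delta = np.clip(travel_m, 0.0, None)  # upper bound: δ ≤ travel
    for _ in range(60):
        f = A * delta ** p / k + delta - travel_m
        fp = A * p * np.where(delta > 0, delta, 1.0) ** (p - 1.0) / k + 1.0
        step = f / fp
        delta = np.clip(delta - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-18:
            break
    return delta


def gen_force_curves(
    E_true: float = 2000.0,
    nu: float = 0.5,
    geometry: str = "pyramid",
    tip_param: float = 35.0,
    spring_constant: float = 0.01,
    contact_offset: float = 2.0,
    baseline_slope: float = 0.0,
    noise_sd: float = 0.0,
    max_force: float = 3e-9,
    n_curves: int = 1,
    n_samples: int = 1000,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate approach curves with a hidden contact point and known modulus.

    ``E_true`` in Pa, ``contact_offset`` in µm (z of the true contact point),
    ``baseline_slope`` in N/µm of piezo travel (converted to deflection tilt
    through the spring constant), ``noise_sd`` and ``max_force`` in N.  Every
    curve has the same true contact point; noise differs per curve.
    """
    if E_true <= 0:
        raise ValueError("E_true must be positive")
    if max_force <= 0:
        raise ValueError("max_force must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if contact_offset <= 0:
        raise ValueError("contact_offset must be positive")

    rng = np.random.default_rng(seed)
    A = hertz_prefactor(E_true, nu, geometry, tip_param)
    p = hertz_exponent(geometry)
    k = float(spring_constant)

    # z range: baseline, then enough travel to reach max_force
    delta_max = (max_force / A) ** (1.0 / p)            # m
    travel_max = delta_max + max_force / k              # m
    z_end = contact_offset + travel_max * 1e6           # µm
    z = np.linspace(0.0, z_end, int(n_samples))

    travel_m = np.clip(z - contact_offset, 0.0, None) * 1e-6
    delta = _solve_indentation(travel_m, A, p, k)
    force = A * delta ** p                              # N
    defl_nm = force / k * 1e9
    defl_nm = defl_nm + (baseline_slope * z) / k * 1e9  # tilt over whole sweep

    curves = []
    for _ in range(int(n_curves)):
        d = defl_nm.copy()
        if noise_sd > 0:
            d = d + rng.normal(0.0, noise_sd / k * 1e9, size=d.shape)
        curves.append(ForceCurve(z_um=z.copy(), deflection_nm=d,
                                 spring_constant=k))

    truth = GroundTruth(
        kind="force",
        params=dict(E_true=E_true, nu=nu, geometry_code=GEOMETRIES.index(geometry),
                    tip_param=tip_param, spring_constant=k,
                    contact_offset=contact_offset, baseline_slope=baseline_slope,
                    noise_sd=noise_sd, max_force=max_force, n_curves=n_curves,
                    n_samples=int(n_samples),
                    sample_spacing_um=float(z[1] - z[0])),
        seed=seed,
        extras=dict(geometry=geometry),
    )
    return SyntheticDataset(payload=curves, truth=truth)
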