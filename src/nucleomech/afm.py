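"""AFM force-curve processing: baseline, contact point, Hertz-family fits.

The pipeline follows standard force-spectroscopy practice: fit and subtract
a straight baseline from the far-from-surface portion of the approach,
detect the contact point, convert piezo travel to tip–sample indentation by
subtracting cantilever bending, and fit the geometry-appropriate contact
law with Poisson's ratio fixed at 0.5 (incompressible cell):

    paraboloid: F = 4/3·E/(1−ν²)·√R·δ^{3/2}
    pyramid:    F = 0.7453·E/(1−ν²)·tanθ·δ²   (Bilodeau, four-sided tip)
    cone:       F = 2/π·E/(1−ν²)·tanθ·δ²      (Sneddon)

E and a residual contact-point offset are the free parameters; for a given
offset the modulus is linear in the model, so the fit is a 1D bounded
minimization wrapped around a closed-form least-squares solve — deterministic
and convergence-flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ForceCurve
from .synthetic.force import hertz_exponent, hertz_prefactor


@dataclass
class HertzFit:
    E: float                 # Pa
    contact_point_z: float   # µm
    nu: float
    geometry: str
    tip_param: float
    rss: float               # N²
    max_indentation: float   # µm
    valid: bool
    reason: str = ""
    r_squared: float = np.nan


def correct_baseline(curve: ForceCurve,
                     baseline_fraction: float = 0.3) -> ForceCurve:
    """Fit a line to the first ``baseline_fraction`` of the approach and
    subtract it from the whole deflection signal.

    The residual noise SD of the baseline window is stored on the returned
    curve for use by contact-point detection.
    """
    if not (0 < baseline_fraction <= 0.9):
        raise ValueError("baseline_fraction must be in (0, 0.9]")
    n = int(np.floor(curve.z_um.size * baseline_fraction))
    if n < 2:
        raise ValueError("baseline window too short")
    zb = curve.z_um[:n]
    db = curve.deflection_nm[:n]
    # robust iterated fit: a window reaching slightly past contact leaves
    # large positive residuals that would otherwise tilt the baseline
    keep = np.ones(n, dtype=bool)
    slope = offset = 0.0
    for _ in range(10):
        slope, offset = np.polyfit(zb[keep], db[keep], 1)
        resid = db - (slope * zb + offset)
        sd = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
        new_keep = resid <= np.median(resid[keep]) + 3 * max(sd, 1e-12)
        if new_keep.sum() < n // 2 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    resid = db - (slope * zb + offset)
    corrected = curve.deflection_nm - (slope * curve.z_um + offset)
    noise_sd = float(np.std(resid[keep]))
    return ForceCurve(z_um=curve.z_um.copy(), deflection_nm=corrected,
                      spring_constant=curve.spring_constant,
                      sensitivity=curve.sensitivity,
                      baseline_noise_sd=noise_sd)


class NoContactError(RuntimeError):
    pass


def _first_sustained_crossing(defl: np.ndarray, threshold: float,
                              m: int) -> int:
    """First index where deflection exceeds threshold for m consecutive samples."""
    above = defl > threshold
    run = np.convolve(above.astype(int), np.ones(m, dtype=int), mode="valid")
    hits = np.nonzero(run == m)[0]
    if hits.size == 0:
        raise NoContactError("no contact detected")
    return int(hits[0])


def find_contact_point(curve: ForceCurve, method: str = "noise_threshold",
                       k_sigma: float = 3.0, m_consecutive: int = 5,
                       geometry: str = "pyramid",
                       window: int = 30) -> tuple:
    """Locate the contact point on a baseline-corrected approach curve.

    ``noise_threshold``: first sample whose deflection exceeds
    k_sigma·(baseline noise SD) and stays above for ``m_consecutive``
    samples, refined by back-extrapolating the early contact region to zero
    force.  The refinement regresses F^(1/p) (p = contact-law exponent of
    ``geometry``) on tip–sample displacement, whose root is the contact
    point — exact for noiseless Hertzian curves.

    ``ratio_of_variances``: argmax over samples of var(after)/var(before)
    in a sliding window of ``window`` samples; no extrapolation.

    Returns ``(index, z_um)`` of the estimated contact point.
    """
    defl = curve.deflection_nm
    z = curve.z_um
    sd = curve.baseline_noise_sd
    if sd is None:
        sd = float(np.std(defl[: max(2, defl.size // 5)]))

    if method == "ratio_of_variances":
        w = int(window)
        best, best_i = -np.inf, None
        for i in range(w, defl.size - w):
            vb = np.var(defl[i - w:i]) + 1e-30
            va = np.var(defl[i:i + w])
            if va / vb > best:
                best, best_i = va / vb, i
        if best_i is None:
            raise NoContactError("curve too short for variance-ratio method")
        return best_i, float(z[best_i])
    if method != "noise_threshold":
        raise ValueError("method must be 'noise_threshold' or 'ratio_of_variances'")

    thr = k_sigma * sd
    if thr <= 0:  # noiseless curve: any positive deflection is contact
        thr = 1e-9 * max(1.0, float(np.max(np.abs(defl))))
    i0 = _first_sustained_crossing(defl, thr, m_consecutive)

    # back-extrapolation: F^(1/p) is linear in tip-sample displacement
    p = hertz_exponent(geometry)
    force = curve.spring_constant * defl * 1e-9
    zeta = z - defl * 1e-3  # µm, piezo travel minus cantilever bending
    f_lo = max(3.0 * curve.spring_constant * sd * 1e-9, 0.0)
    f_hi = np.nanmax(force) / 3.0
    sel = (np.arange(z.size) >= i0) & (force > f_lo) & (force <= max(f_hi, f_lo * 2))
    if sel.sum() >= 5:
        y = force[sel] ** (1.0 / p)
        a, b = np.polyfit(zeta[sel], y, 1)
        if a > 0:
            z_c = -b / a
            lo, hi = z[i0] - 0.5 * (z[i0] - z[0]), z[i0]
            if lo <= z_c <= hi:
                idx = int(np.searchsorted(z, z_c))
                return min(idx, z.size - 1), float(z_c)
    return i0, float(z[i0])


def to_indentation(curve: ForceCurve, contact_z: float):
    """Convert a baseline-corrected curve to (force N, indentation µm) arrays.

    Indentation is piezo travel past contact minus cantilever bending,
    δ = (z − z_c) − d; only the δ ≥ 0 region is returned.  A curve whose
    bending exceeds piezo travel everywhere is reported invalid.
    """
    if curve.spring_constant <= 0:
        raise ValueError("spring_constant must be positive")
    delta = (curve.z_um - contact_z) - curve.deflection_nm * 1e-3
    force = curve.force_n()
    sel = (curve.z_um >= contact_z) & (delta >= 0)
    if not sel.any():
        raise NoContactError("no positive indentation past contact (invalid curve)")
    return force[sel], delta[sel]


def fit_hertz(force: np.ndarray, indentation: np.ndarray,
              geometry: str = "pyramid", tip_param: float = 35.0,
              nu: float = 0.5, fit_max_force: float = 3e-9,
              max_indentation: Optional[float] = None,
              fit_offset: bool = True, min_points: int = 20) -> HertzFit:
    """Least-squares Hertz fit of a (force, indentation) curve.

    Returns modulus E (Pa); when ``fit_offset`` is on, a residual
    contact-point offset (µm) is co-fitted by bounded 1D minimization with a
    closed-form E at each trial offset.  ``fit_max_force`` caps the fitted
    force range (Hertz validity, default the 3 nN setpoint);
    ``max_indentation`` optionally caps indentation depth.
    """
    force = np.asarray(force, float)
    delta_um = np.asarray(indentation, float)
    sel = (delta_um > 0) & (force <= fit_max_force)
    if max_indentation is not None:
        sel &= delta_um <= max_indentation
    f = force[sel]
    d = delta_um[sel] * 1e-6  # m
    p = hertz_exponent(geometry)
    unit = hertz_prefactor(1.0, nu, geometry, tip_param)  # prefactor per Pa

    def solve(eps_m: float):
        dd = d - eps_m
        ok = dd > 0
        if ok.sum() < min_points:
            return np.nan, np.inf, 0
        c = unit * dd[ok] ** p
        E = float(np.dot(c, f[ok]) / np.dot(c, c))
        rss = float(np.sum((f[ok] - E * c) ** 2))
        return E, rss, int(ok.sum())

    if f.size < min_points:
        return HertzFit(E=np.nan, contact_point_z=np.nan, nu=nu,
                        geometry=geometry, tip_param=tip_param, rss=np.nan,
                        max_indentation=float(delta_um.max(initial=0.0)),
                        valid=False, reason="too_few_points")

    eps = 0.0
    if fit_offset:
        half = 0.2 * float(delta_um[sel].max()) * 1e-6
        res = optimize.minimize_scalar(lambda e: solve(e)[1],
                                       bounds=(-half, half), method="bounded",
                                       options=dict(xatol=1e-13))
        if res.success:
            eps = float(res.x)
    E, rss, n_ok = solve(eps)
    if not np.isfinite(E) or E <= 0:
        return HertzFit(E=np.nan, contact_point_z=np.nan, nu=nu,
                        geometry=geometry, tip_param=tip_param, rss=np.nan,
                        max_indentation=float(delta_um.max(initial=0.0)),
                        valid=False, reason="nonpositive_modulus")
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    return HertzFit(E=E, contact_point_z=eps * 1e6, nu=nu, geometry=geometry,
                    tip_param=tip_param, rss=rss,
                    max_indentation=float((delta_um[sel].max() - eps * 1e6)),
                    valid=True, r_squared=r2)


def process_curve(curve: ForceCurve, geometry: str = "pyramid",
                  tip_param: float = 35.0, nu: float = 0.5,
                  baseline_fraction: float = 0.3, k_sigma: float = 3.0,
                  m_consecutive: int = 5, fit_max_force: float = 3e-9,
                  contact_method: str = "noise_threshold") -> HertzFit:
    """Full single-curve pipeline: baseline → contact → indentation → fit."""
    corr = correct_baseline(curve, baseline_fraction)
    try:
        _, z_c = find_contact_point(corr, method=contact_method,
                                    k_sigma=k_sigma,
                                    m_consecutive=m_consecutive,
                                    geometry=geometry)
        force, delta = to_indentation(corr, z_c)
    except NoContactError as err:
        return HertzFit(E=np.nan, contact_point_z=np.nan, nu=nu,
                        geometry=geometry, tip_param=tip_param, rss=np.nan,
                        max_indentation=0.0, valid=False, reason=str(err))
    fit = fit_hertz(force, delta, geometry=geometry, tip_param=tip_param,
                    nu=nu, fit_max_force=fit_max_force)
    if fit.valid:
        # report absolute contact z: detected + fitted residual offset
        fit.contact_point_z = z_c + fit.contact_point_z
    return fit


def process_force_map(curves: Sequence[ForceCurve],
                      **kwargs) -> pd.DataFrame:
    """Run the pipeline over a force map; one row per curve.

    The per-cell summary statistic is the median modulus of the valid
    technical replicates (use :func:`summarize_map`).  Raises if no curve
    yields a valid fit.
    """
    if len(curves) == 0:
        raise ValueError("no curves provided")
    rows = []
    for i, c in enumerate(curves):
        fit = process_curve(c, **kwargs)
        rows.append(dict(curve_id=i, E_pa=fit.E,
                         contact_z_um=fit.contact_point_z, rss=fit.rss,
                         valid=fit.valid, reason=fit.reason))
    df = pd.DataFrame(rows)
    if not df["valid"].any():
        raise ValueError("zero valid curves in force map")
    return df


def summarize_map(fits: pd.DataFrame) -> dict:
    """Median modulus over valid replicates plus invalid count."""
    ok = fits[fits["valid"]]
    return dict(E_median_pa=float(ok["E_pa"].median()),
                n_valid=int(len(ok)), n_invalid=int(len(fits) - len(ok)))
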