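"""GEM-nanoparticle microrheology: MSD curves and anomalous-diffusion fits.

Per-track time-averaged mean squared displacement in 2D, fitted with the
power law MSD(τ) = 4·D_eff·τ^β by ordinary least squares in log-log space.
By default the fit uses lags 2–10 (skipping lag 1, where static localization
error biases the apparent exponent most strongly); the range is
configurable.  Gapped tracks contribute only displacement pairs whose both
frames exist — no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ParticleTracks


@dataclass
class MSDCurve:
    """Time-averaged MSD per lag.  ``track_id`` is -1 for an ensemble curve."""

    lags: np.ndarray      # s
    msd: np.ndarray       # µm²
    n_pairs: np.ndarray
    track_id: int

    def __post_init__(self):
        if (np.asarray(self.msd) < 0).any():
            raise ValueError("msd must be non-negative")


@dataclass
class RheologyFit:
    track_id: int
    D_eff: float            # µm²/s^β
    beta: float
    fit_lag_range: tuple    # (s, s)
    r_squared: float
    n_lags_used: int
    flags: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.flags


def msd_per_track(tracks: ParticleTracks,
                  max_lag_fraction: float = 0.25) -> List[MSDCurve]:
    """Time-averaged MSD for every analyzable track.

    For lag k the MSD is the mean of |r(t+k) − r(t)|² over all frame pairs
    present in the track; lags run up to ``max_lag_fraction`` of the track's
    frame span.  Tracks shorter than 3 points are skipped; if every track is
    too short an error reports the count.
    """
    dt = tracks.frame_interval
    curves = []
    n_short = 0
    for tid, grp in tracks.data.groupby("track_id"):
        frames = grp["frame"].to_numpy()
        if len(frames) < 3:
            n_short += 1
            continue
        span = frames[-1] - frames[0]
        max_lag = max(1, int(np.floor(span * max_lag_fraction)))
        # frame-indexed arrays with NaN in gaps
        idx = frames - frames[0]
        x = np.full(span + 1, np.nan)
        y = np.full(span + 1, np.nan)
        x[idx] = grp["x_um"].to_numpy()
        y[idx] = grp["y_um"].to_numpy()
        lags = np.arange(1, max_lag + 1)
        msd = np.empty(max_lag)
        n_pairs = np.empty(max_lag, dtype=int)
        for j, k in enumerate(lags):
            d2 = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2
            ok = np.isfinite(d2)
            n_pairs[j] = ok.sum()
            msd[j] = d2[ok].mean() if ok.any() else np.nan
        keep = n_pairs > 0
        curves.append(MSDCurve(lags=lags[keep] * dt, msd=msd[keep],
                               n_pairs=n_pairs[keep], track_id=int(tid)))
    if not curves:
        raise ValueError(f"no analyzable tracks ({n_short} shorter than 3 points)")
    return curves


def ensemble_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    """Pair-count-weighted mean of per-track MSDs at each lag."""
    all_lags = np.unique(np.concatenate([c.lags for c in curves]))
    num = np.zeros(all_lags.size)
    den = np.zeros(all_lags.size, dtype=int)
    for c in curves:
        pos = np.searchsorted(all_lags, c.lags)
        num[pos] += c.msd * c.n_pairs
        den[pos] += c.n_pairs
    keep = den > 0
    return MSDCurve(lags=all_lags[keep], msd=num[keep] / den[keep],
                    n_pairs=den[keep], track_id=-1)


def fit_power_law(msd: MSDCurve, lag_range: Optional[tuple] = (2, 10),
                  r2_floor: float = 0.0,
                  frame_interval: Optional[float] = None) -> RheologyFit:
    """OLS fit of log MSD vs log τ: slope = β, intercept = log(4·D_eff).

    ``lag_range`` selects lag indices (inclusive, in frame units) when the
    curve's frame interval is known or derivable from the lag grid; pass
    ``None`` to use all lags.  Non-positive MSD values are dropped; fewer
    than 4 remaining lags flags the fit instead of raising.
    """
    lags = np.asarray(msd.lags, dtype=float)
    vals = np.asarray(msd.msd, dtype=float)
    if lag_range is not None:
        dt = frame_interval if frame_interval is not None else np.min(lags)
        k = np.rint(lags / dt).astype(int)
        sel = (k >= lag_range[0]) & (k <= lag_range[1])
        lags, vals = lags[sel], vals[sel]
    pos = vals > 0
    flags = []
    if (~pos).any():
        flags.append(f"dropped_{int((~pos).sum())}_nonpositive_lags")
    lags, vals = lags[pos], vals[pos]
    if lags.size < 4:
        return RheologyFit(track_id=msd.track_id, D_eff=np.nan, beta=np.nan,
                           fit_lag_range=(np.nan, np.nan), r_squared=np.nan,
                           n_lags_used=int(lags.size),
                           flags=flags + ["insufficient_lags"])
    lx, ly = np.log(lags), np.log(vals)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    if r2 < r2_floor:
        flags.append("low_r_squared")
    return RheologyFit(track_id=msd.track_id, D_eff=float(np.exp(intercept) / 4.0),
                       beta=float(slope),
                       fit_lag_range=(float(lags.min()), float(lags.max())),
                       r_squared=float(r2), n_lags_used=int(lags.size),
                       flags=flags)


def fit_tracks(tracks: ParticleTracks, lag_range: tuple = (2, 10),
               max_lag_fraction: float = 0.25,
               r2_floor: float = 0.0) -> pd.DataFrame:
    """Per-track (D_eff, β) table: MSD + power-law fit for every track."""
    curves = msd_per_track(tracks, max_lag_fraction=max_lag_fraction)
    fits = [fit_power_law(c, lag_range=lag_range, r2_floor=r2_floor,
                          frame_interval=tracks.frame_interval) for c in curves]
    return pd.DataFrame([dict(track_id=f.track_id, D_eff=f.D_eff, beta=f.beta,
                              r_squared=f.r_squared, n_lags=f.n_lags_used,
                              flags=";".join(f.flags)) for f in fits])


def ensemble_stats(fits: pd.DataFrame,
                   grouping: Optional[Sequence] = None) -> pd.DataFrame:
    """Median and IQR of D_eff and β per condition, flagged fits excluded.

    ``grouping`` assigns a condition label to each row of ``fits`` (a single
    pooled condition by default).  Raises if no unflagged fit remains at all;
    empty groups are omitted.
    """
    df = fits.copy()
    df["condition"] = list(grouping) if grouping is not None else "all"
    rows = []
    for cond, grp in df.groupby("condition"):
        ok = grp[(grp["flags"] == "") & np.isfinite(grp["beta"])]
        n_flagged = len(grp) - len(ok)
        if ok.empty:
            continue
        q = ok[["D_eff", "beta"]].quantile([0.25, 0.5, 0.75])
        rows.append(dict(
            condition=cond, n=len(ok), n_flagged=n_flagged,
            D_eff_median=q.loc[0.5, "D_eff"],
            D_eff_iqr=q.loc[0.75, "D_eff"] - q.loc[0.25, "D_eff"],
            beta_median=q.loc[0.5, "beta"],
            beta_iqr=q.loc[0.75, "beta"] - q.loc[0.25, "beta"],
        ))
    if not rows:
        raise ValueError("no unflagged fits in any group")
    return pd.DataFrame(rows)
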