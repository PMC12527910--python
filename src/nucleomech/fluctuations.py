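"""Nuclear-envelope fluctuation amplitude from single-nucleus mask movies.

The pipeline mirrors the classic edge-fluctuation measurement on lamin
movies: correct photobleaching, register rigid drift, sample the envelope
position along lines perpendicular to the boundary at many anchor points,
and report the temporal standard deviation of the edge position per anchor
and averaged per nucleus.

Anchors are placed at equal arc-length spacing on the frame-0 boundary
(removing the operator subjectivity of manual line placement); the edge
position along each outward normal is the 0.5-level crossing of the
bilinearly sampled, lightly smoothed mask profile, linearly interpolated to
sub-pixel precision.  Standard deviations use the population (1/T)
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .containers import NucleusMaskMovie


@dataclass
class RigidTransforms:
    """Per-frame rigid alignment (translation px, rotation rad) to frame 0."""

    dx: np.ndarray
    dy: np.ndarray
    dtheta: np.ndarray
    qc_flags: list = field(default_factory=list)


@dataclass
class EdgeKymograph:
    """Edge displacement along the outward normal at K anchors over T frames.

    ``positions`` is (K, T) in µm, signed (outward positive), mean-subtracted
    per anchor; missing crossings are NaN, never imputed.  ``arc_pos_um``
    gives each anchor's arc-length position on the reference boundary.
    """

    arc_pos_um: np.ndarray
    anchor_xy_px: np.ndarray
    normals: np.ndarray
    positions: np.ndarray
    pixel_size: float
    frame_interval: float
    excluded_anchors: list = field(default_factory=list)


@dataclass
class FluctuationResult:
    per_anchor_sd: np.ndarray          # µm, NaN for excluded anchors
    nucleus_mean_sd: float             # µm
    n_anchors_used: int
    qc_flags: list = field(default_factory=list)


def bleach_correct(movie: NucleusMaskMovie) -> NucleusMaskMovie:
    """Simple-ratio bleach correction against frame 0.

    Each frame's intensity is rescaled so its mean foreground intensity
    equals that of frame 0; the mask channel is untouched.
    """
    if movie.intensity is None:
        raise ValueError("intensity channel required")
    fg = movie.masks > 0
    means = np.array([
        movie.intensity[t][fg[t]].mean() if fg[t].any() else 0.0
        for t in range(movie.n_frames)
    ])
    bad = np.nonzero(means <= 0)[0]
    if bad.size:
        raise ValueError(f"zero-mean foreground intensity at frame {bad[0]}")
    corrected = movie.intensity * (means[0] / means)[:, None, None]
    return NucleusMaskMovie(masks=movie.masks, pixel_size=movie.pixel_size,
                            frame_interval=movie.frame_interval,
                            intensity=corrected)


def _mask_pose(mask: np.ndarray):
    """Centroid (y, x) and principal-axis orientation of a binary mask.

    Returns (cy, cx, theta, degenerate): theta is the orientation of the
    major axis from second central moments, in radians; ``degenerate`` marks
    circularly symmetric masks whose orientation is undefined.
    """
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)
    aniso = np.hypot(mu20 - mu02, 2 * mu11)
    # below ~5% relative anisotropy the orientation is dominated by shape
    # noise (boundary fluctuations), and "correcting" it scrambles frames;
    # treat as circular: rotation 0 + QC flag
    degenerate = aniso < 0.05 * (mu20 + mu02)
    theta = 0.0 if degenerate else 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    return cy, cx, theta, degenerate


def _wrap_half_pi(a: float) -> float:
    """Wrap an angle difference to (-π/2, π/2] (orientation is mod π)."""
    return (a + np.pi / 2) % np.pi - np.pi / 2


def register_rigid(movie: NucleusMaskMovie):
    """Align every frame to frame 0 by mask centroid + principal-axis rotation.

    Returns (registered movie, :class:`RigidTransforms`).  Frames are
    resampled bilinearly; masks are re-binarized at the 0.5 level.  For
    circularly symmetric masks the rotation is set to 0 and a QC flag is
    recorded (spec of the moment tensor leaves the angle undefined).
    """
    T = movie.n_frames
    poses = [_mask_pose(movie.masks[t] > 0) for t in range(T)]
    cy0, cx0, th0, deg0 = poses[0]

    dxs = np.zeros(T)
    dys = np.zeros(T)
    dths = np.zeros(T)
    flags = []
    out_masks = np.zeros_like(movie.masks, dtype=np.uint8)
    out_int = None if movie.intensity is None else np.zeros_like(movie.intensity)

    for t in range(T):
        cy, cx, th, deg = poses[t]
        dth = 0.0 if (deg or deg0) else _wrap_half_pi(th - th0)
        if deg and t == 0:
            flags.append("degenerate_moments_rotation_zeroed")
        dys[t], dxs[t], dths[t] = cy - cy0, cx - cx0, dth
        if deg and t > 0 and "degenerate_moments_rotation_zeroed" not in flags:
            flags.append("degenerate_moments_rotation_zeroed")

        # output coords are frame-0 centred; map back into frame t
        cth, sth = np.cos(dth), np.sin(dth)
        rot = np.array([[cth, sth], [-sth, cth]])  # rotation by dth in (y, x)
        offset = np.array([cy, cx]) - rot @ np.array([cy0, cx0])
        fmask = ndimage.affine_transform(movie.masks[t].astype(float), rot,
                                         offset=offset, order=1, mode="constant")
        out_masks[t] = fmask >= 0.5
        if out_int is not None:
            out_int[t] = ndimage.affine_transform(movie.intensity[t], rot,
                                                  offset=offset, order=1,
                                                  mode="constant")

    reg = NucleusMaskMovie(masks=out_masks, pixel_size=movie.pixel_size,
                           frame_interval=movie.frame_interval,
                           intensity=out_int)
    return reg, RigidTransforms(dx=dxs, dy=dys, dtheta=dths, qc_flags=flags)


def _reference_contour(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of the mask, (N, 2) array of (y, x)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found in reference frame")
    return max(contours, key=len)


def _edge_crossing(prof: np.ndarray, s: np.ndarray,
                   high: float = 0.6, low: float = 0.4) -> float:
    """Sub-pixel inside→outside 0.5 crossing of a sampled mask profile.

    Hysteresis bands (solidly inside ≥ ``high``, solidly outside ≤ ``low``)
    absorb bilinear-interpolation wiggle around the 0.5 level while genuine
    multiple boundary intersections — a solid exit before the last solid
    inside sample — still come back NaN (flagged, never imputed).
    """
    inside = prof >= high
    outside = prof <= low
    if not inside.any() or not outside.any():
        return np.nan
    i_a = int(np.nonzero(inside)[0][-1])        # last solidly-inside sample
    after = np.nonzero(outside[i_a:])[0]
    if after.size == 0 or outside[:i_a].any():  # re-entry = true double crossing
        return np.nan
    i_b = i_a + int(after[0])
    seg = prof[i_a:i_b + 1]
    below = np.nonzero(seg < 0.5)[0]
    i = i_a + int(below[0]) - 1                 # straddles the 0.5 level
    frac = (prof[i] - 0.5) / (prof[i] - prof[i + 1])
    return s[i] + frac * (s[i + 1] - s[i])


def extract_edge_profiles(
    movie: NucleusMaskMovie,
    n_anchors: int = 16,
    line_half_length: float = 1.0,
    sample_step_px: float = 0.25,
    profile_smooth: int = 3,
) -> EdgeKymograph:
    """Sample signed edge displacement along outward normals at equal-arc anchors.

    For each anchor the binary mask of every frame is sampled bilinearly
    along a line of half-length ``line_half_length`` (µm) perpendicular to
    the frame-0 boundary; the profile is smoothed with a ``profile_smooth``
    -sample moving average and the inside→outside 0.5 crossing is located by
    linear interpolation.  Frames where the profile does not cross 0.5
    exactly once are recorded as NaN; anchors whose line exits the field of
    view are excluded outright.
    """
    if n_anchors < 4:
        raise ValueError("n_anchors must be >= 4")
    mask0 = movie.masks[0] > 0
    contour = _reference_contour(mask0)
    closed = np.vstack([contour, contour[:1]])
    seglen = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]

    targets = np.arange(n_anchors) * total / n_anchors
    ay = np.interp(targets, arc, closed[:, 0])
    ax = np.interp(targets, arc, closed[:, 1])
    anchors = np.column_stack([ay, ax])

    # outward normal from the local tangent, oriented away from the centroid
    cy, cx, _, _ = _mask_pose(mask0)
    eps = max(total / (4 * n_anchors), 1.0)
    ty = np.interp((targets + eps) % total, arc, closed[:, 0]) - \
        np.interp((targets - eps) % total, arc, closed[:, 0])
    tx = np.interp((targets + eps) % total, arc, closed[:, 1]) - \
        np.interp((targets - eps) % total, arc, closed[:, 1])
    ny, nx = -tx, ty
    norm = np.hypot(ny, nx)
    ny, nx = ny / norm, nx / norm
    flip = (ny * (ay - cy) + nx * (ax - cx)) < 0
    ny[flip] *= -1
    nx[flip] *= -1

    half_px = line_half_length / movie.pixel_size
    s = np.arange(-half_px, half_px + sample_step_px / 2, sample_step_px)
    n_s = s.size

    T = movie.n_frames
    K = n_anchors
    positions = np.full((K, T), np.nan)
    excluded = []

    H, W = mask0.shape
    py = anchors[:, 0:1] + s[None, :] * ny[:, None]   # (K, n_s)
    px = anchors[:, 1:2] + s[None, :] * nx[:, None]
    for kk in range(K):
        if (py[kk].min() < 0 or py[kk].max() > H - 1
                or px[kk].min() < 0 or px[kk].max() > W - 1):
            excluded.append(kk)
    coords = np.stack([py, px]).reshape(2, -1)

    for t in range(T):
        profs = ndimage.map_coordinates(movie.masks[t].astype(float), coords,
                                        order=1, mode="nearest").reshape(K, n_s)
        if profile_smooth > 1:
            profs = ndimage.uniform_filter1d(profs, size=profile_smooth, axis=1)
        for kk in range(K):
            if kk in excluded:
                continue
            positions[kk, t] = _edge_crossing(profs[kk], s) * movie.pixel_size

    # signed displacement about the temporal mean, per anchor
    any_valid = np.isfinite(positions).any(axis=1)
    means = np.zeros((K, 1))
    means[any_valid, 0] = np.nanmean(positions[any_valid], axis=1)
    positions -= means

    return EdgeKymograph(
        arc_pos_um=targets * movie.pixel_size,
        anchor_xy_px=anchors[:, ::-1].copy(),
        normals=np.column_stack([nx, ny]),
        positions=positions,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        excluded_anchors=excluded,
    )


def fluctuation_amplitude(kymo: EdgeKymograph,
                          max_missing_fraction: float = 0.2,
                          min_frames: int = 3) -> FluctuationResult:
    """Per-anchor temporal SD of edge position and its per-nucleus mean.

    Anchors with more than ``max_missing_fraction`` missing crossings (or
    fewer than ``min_frames`` valid frames) are excluded with a QC flag.  SD
    is the population (1/T) standard deviation.
    """
    K, T = kymo.positions.shape
    per_anchor = np.full(K, np.nan)
    flags = list()
    used = 0
    for kk in range(K):
        if kk in kymo.excluded_anchors:
            flags.append(f"anchor{kk}:line_exits_fov")
            continue
        vals = kymo.positions[kk]
        valid = np.isfinite(vals)
        missing = 1.0 - valid.sum() / T
        if missing > max_missing_fraction or valid.sum() < min_frames:
            flags.append(f"anchor{kk}:missing_{missing:.0%}")
            continue
        v = vals[valid]
        per_anchor[kk] = np.sqrt(np.mean((v - v.mean()) ** 2))
        used += 1
    if used == 0:
        raise ValueError("all anchors excluded by QC")
    mean_sd = float(np.nanmean(per_anchor))
    return FluctuationResult(per_anchor_sd=per_anchor, nucleus_mean_sd=mean_sd,
                             n_anchors_used=used, qc_flags=flags)


def analyze_movie(movie: NucleusMaskMovie, n_anchors: int = 16,
                  line_half_length: float = 1.0, register: bool = True,
                  bleach: bool = False) -> FluctuationResult:
    """Full fluctuation pipeline: (bleach) → (register) → profiles → amplitude."""
    if bleach:
        movie = bleach_correct(movie)
    if register:
        movie, _ = register_rigid(movie)
    kymo = extract_edge_profiles(movie, n_anchors=n_anchors,
                                 line_half_length=line_half_length)
    return fluctuation_amplitude(kymo)
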