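"""Voxelized ellipsoidal nuclei for volumetry tests.

Nuclei are ellipsoids with semi-axes (a, b, c) along (x, y, z).  Axial
compression — the geometry of a nucleus flattening under a confining
environment — scales the z semi-axis by ``compression_factor``; the
volume-preserving variant rescales x and y by 1/sqrt(factor) so the analytic
volume 4/3·π·a·b·c is unchanged, the volume-losing variant leaves x, y as
they are (height and volume drop together).
"""

from __future__ import annotations

import numpy as np

from ..containers import GroundTruth, LabeledVolume, SyntheticDataset


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Closed-form ellipsoid volume, µm³."""
    return 4.0 / 3.0 * np.pi * a * b * c


def gen_volume_stack(
    semi_axes: tuple = (5.0, 5.0, 5.0),
    voxel_size: tuple = (0.2, 0.2, 0.2),
    n_nuclei: int = 1,
    compression_factor: float = 1.0,
    volume_preserving: bool = False,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a 3D label stack of ellipsoidal nuclei with known volumes.

    ``semi_axes`` is (a, b, c) µm along (x, y, z); ``voxel_size`` is
    (z, y, x) µm matching array axis order.  Nuclei are placed on a regular
    grid with clearance so labels never touch.  ``compression_factor`` in
    (0, 1] models axial flattening (1 = uncompressed).
    """
    a, b, c = (float(v) for v in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    if not (0 < compression_factor <= 1):
        raise ValueError("compression_factor must be in (0, 1]")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")

    cz = c * compression_factor
    if volume_preserving:
        s = 1.0 / np.sqrt(compression_factor)
        ax, by = a * s, b * s
    else:
        ax, by = a, b

    vz, vy, vx = (float(v) for v in voxel_size)
    rng = np.random.default_rng(seed)  # reserved: jitters placement phase
    del rng

    # grid placement with half-a-voxel-safe clearance
    pitch_x = 2 * ax + 4 * vx
    pitch_y = 2 * by + 4 * vy
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    n_rows = int(np.ceil(n_nuclei / n_cols))

    size_x = int(np.ceil((n_cols * pitch_x + 2 * vx) / vx))
    size_y = int(np.ceil((n_rows * pitch_y + 2 * vy) / vy))
    size_z = int(np.ceil((2 * cz + 6 * vz) / vz))

    zc = (np.arange(size_z) + 0.5) * vz
    yc = (np.arange(size_y) + 0.5) * vy
    xc = (np.arange(size_x) + 0.5) * vx

    def snap(v, h):
        # centre each ellipsoid on a voxel centre so the discretization
        # error is phase-coherent across resolutions
        return (np.floor(v / h) + 0.5) * h

    z0 = snap(size_z * vz / 2.0, vz)

    labels = np.zeros((size_z, size_y, size_x), dtype=np.uint16)
    for i in range(n_nuclei):
        row, col = divmod(i, n_cols)
        x0 = snap((col + 0.5) * pitch_x + vx, vx)
        y0 = snap((row + 0.5) * pitch_y + vy, vy)
        ez = ((zc - z0) / cz) ** 2
        ey = ((yc - y0) / by) ** 2
        ex = ((xc - x0) / ax) ** 2
        inside = (ez[:, None, None] + ey[None, :, None] + ex[None, None, :]) <= 1.0
        if (labels[inside] != 0).any():
            raise RuntimeError("ellipsoid placement produced overlapping labels")
        labels[inside] = i + 1

    vol = LabeledVolume(voxels=labels, voxel_size=(vz, vy, vx))
    truth = GroundTruth(
        kind="volume",
        params=dict(semi_axis_a=a, semi_axis_b=b, semi_axis_c=c,
                    compression_factor=compression_factor,
                    volume_preserving=volume_preserving,
                    voxel_z=vz, voxel_y=vy, voxel_x=vx, n_nuclei=n_nuclei,
                    true_volume_um3=ellipsoid_volume(ax, by, cz),
                    true_height_um=2 * cz),
        seed=seed,
    )
    return SyntheticDataset(payload=vol, truth=truth)
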