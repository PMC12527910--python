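import numpy as np
import pytest

from nucleomech import synthetic


@pytest.fixture(scope="session")
def small_boundary_movie():
    """60-frame fluctuating nucleus, σ_r = 0.2 µm, no drift/bleach."""
    return synthetic.gen_boundary_movie(n_frames=60, pixel_size=0.05,
                                        mean_radius=5.0, radial_sigma=0.2,
                                        seed=101)


@pytest.fixture(scope="session")
def sphere_stack():
    """Voxelized sphere r = 5 µm at 0.2 µm isotropic voxels."""
    return synthetic.gen_volume_stack(semi_axes=(5.0, 5.0, 5.0),
                                      voxel_size=(0.2, 0.2, 0.2), seed=7)


@pytest.fixture(scope="session")
def brownian_tracks():
    """200 Brownian tracks, D = 0.5 µm²/s, Δt = 0.1 s, noiseless."""
    return synthetic.gen_tracks(n_tracks=200, n_frames=200, model="brownian",
                                D=0.5, frame_interval=0.1, seed=17)


def random_blob_mask(seed, radial_sigma=0.4, mean_radius=4.0, pixel_size=0.1):
    """Single-frame random smooth blob (for shell-geometry audits)."""
    ds = synthetic.gen_boundary_movie(n_frames=1, pixel_size=pixel_size,
                                      mean_radius=mean_radius,
                                      radial_sigma=radial_sigma, seed=seed)
    return ds.payload.masks[0] > 0
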