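"""Generator-level checks: determinism, calibration coherence, closed forms."""

import numpy as np
import pytest

from nucleomech import synthetic
from nucleomech.containers import CalibrationError
from nucleomech.rheology import ensemble_msd, msd_per_track


GEN_CALLS = [
    ("boundary", lambda s: synthetic.gen_boundary_movie(
        n_frames=8, radial_sigma=0.15, drift=(0.05, 0.5), bleach_rate=0.01,
        seed=s)),
    ("volume", lambda s: synthetic.gen_volume_stack(
        semi_axes=(3, 3, 2), voxel_size=(0.3, 0.3, 0.3), n_nuclei=2, seed=s)),
    ("tracks", lambda s: synthetic.gen_tracks(
        n_tracks=5, n_frames=40, model="fbm", D=0.2, beta=0.7,
        loc_noise=0.02, seed=s)),
    ("force", lambda s: synthetic.gen_force_curves(
        noise_sd=0.05e-9, n_curves=3, seed=s)),
    ("condensate", lambda s: synthetic.gen_condensate_image(
        aggregate_fraction=0.3, seed=s)),
]


def _payload_arrays(kind, ds):
    if kind == "boundary":
        return [ds.payload.masks, ds.payload.intensity]
    if kind == "volume":
        return [ds.payload.voxels]
    if kind == "tracks":
        return [ds.payload.data.to_numpy()]
    if kind == "force":
        return [c.deflection_nm for c in ds.payload]
    return [ds.payload.intensity, ds.payload.condensate_mask]


@pytest.mark.parametrize("kind,call", GEN_CALLS, ids=[k for k, _ in GEN_CALLS])
def test_same_seed_bit_identical(kind, call):
    a, b = call(42), call(42)
    assert a.truth.kind == kind
    for arr_a, arr_b in zip(_payload_arrays(kind, a), _payload_arrays(kind, b)):
        assert np.asarray(arr_a).tobytes() == np.asarray(arr_b).tobytes()


STOCHASTIC = [(k, c) for k, c in GEN_CALLS if k != "volume"]


@pytest.mark.parametrize("kind,call", STOCHASTIC, ids=[k for k, _ in STOCHASTIC])
def test_different_seed_differs(kind, call):
    a, b = call(1), call(2)
    same = all(np.array_equal(np.asarray(x), np.asarray(y))
               for x, y in zip(_payload_arrays(kind, a),
                               _payload_arrays(kind, b)))
    assert not same


def test_truth_records_calibration_coherent(small_boundary_movie):
    ds = small_boundary_movie
    assert ds.payload.pixel_size == ds.truth.params["pixel_size"]
    assert ds.payload.frame_interval == ds.truth.params["frame_interval"]
    assert ds.truth.seed == 101


class TestBoundaryMovie:
    def test_static_sigma_zero_identical_frames(self):
        ds = synthetic.gen_boundary_movie(n_frames=5, radial_sigma=0.0, seed=3)
        m = ds.payload.masks
        assert all(np.array_equal(m[0], m[t]) for t in range(1, 5))

    def test_pointwise_radial_std_matches_truth(self):
        # oracle: evaluate r(theta, t) from the same mode model the masks
        # rasterize, via the empirical per-angle std over many frames
        sigma, n_modes, n_frames = 0.2, 8, 4000
        rng = np.random.default_rng(5)
        k = np.arange(1, n_modes + 1)
        theta = np.linspace(0, 2 * np.pi, 13)[:-1]
        sd_mode = sigma / np.sqrt(n_modes)
        r = np.empty((n_frames, theta.size))
        for t in range(n_frames):
            a = rng.normal(0, sd_mode, n_modes)
            b = rng.normal(0, sd_mode, n_modes)
            r[t] = np.cos(np.outer(theta, k)) @ a + np.sin(np.outer(theta, k)) @ b
        assert np.allclose(r.std(axis=0), sigma, rtol=0.08)

    def test_bleach_decay_applied(self):
        ds = synthetic.gen_boundary_movie(n_frames=10, radial_sigma=0.0,
                                          bleach_rate=0.05, seed=1)
        fg = ds.payload.masks[0] > 0
        m0 = ds.payload.intensity[0][fg].mean()
        m9 = ds.payload.intensity[9][fg].mean()
        assert m9 / m0 == pytest.approx(np.exp(-0.05 * 9), rel=1e-6)

    def test_calibration_errors(self):
        with pytest.raises(CalibrationError):
            synthetic.gen_boundary_movie(pixel_size=0.0)
        with pytest.raises(CalibrationError):
            synthetic.gen_boundary_movie(frame_interval=-1.0)


class TestVolumeStack:
    def test_truth_volume_closed_form(self, sphere_stack):
        assert sphere_stack.truth.params["true_volume_um3"] == \
            pytest.approx(4 / 3 * np.pi * 125, rel=1e-12)

    def test_uncompressed_height_is_2c(self):
        ds = synthetic.gen_volume_stack(semi_axes=(3, 3, 4),
                                        voxel_size=(0.25, 0.25, 0.25),
                                        compression_factor=1.0, seed=2)
        zs = np.nonzero(ds.payload.voxels.any(axis=(1, 2)))[0]
        height = (zs.max() - zs.min() + 1) * 0.25
        assert height == pytest.approx(8.0, abs=0.3)

    def test_volume_preserving_compression(self):
        base = synthetic.gen_volume_stack(seed=4)
        comp = synthetic.gen_volume_stack(compression_factor=0.65,
                                          volume_preserving=True, seed=4)
        v0 = (base.payload.voxels > 0).sum() * base.payload.voxel_volume
        v1 = (comp.payload.voxels > 0).sum() * comp.payload.voxel_volume
        assert v1 == pytest.approx(v0, rel=0.02)

    def test_voxel_volume_converges_monotonically(self):
        errs = []
        for h in (0.4, 0.2, 0.1):
            ds = synthetic.gen_volume_stack(voxel_size=(h, h, h), seed=1)
            v = (ds.payload.voxels > 0).sum() * h ** 3
            errs.append(abs(v - 4 / 3 * np.pi * 125))
        assert errs[0] > errs[1] > errs[2]

    def test_bad_compression_factor(self):
        with pytest.raises(ValueError):
            synthetic.gen_volume_stack(compression_factor=0.0)


class TestTracks:
    def test_stationary_when_D_zero(self):
        ds = synthetic.gen_tracks(n_tracks=3, n_frames=20, D=0.0,
                                  loc_noise=0.0, seed=1)
        df = ds.payload.data
        assert df.groupby("track_id")[["x_um", "y_um"]].std().max().max() == 0.0

    def test_brownian_msd_closed_form(self, brownian_tracks):
        # MSD(Δt) = 4 D Δt = 0.2 µm²
        em = ensemble_msd(msd_per_track(brownian_tracks.payload))
        assert em.msd[0] == pytest.approx(0.2, rel=0.05)

    def test_brownian_loglog_slope_near_one(self, brownian_tracks):
        em = ensemble_msd(msd_per_track(brownian_tracks.payload))
        sl = np.polyfit(np.log(em.lags[:10]), np.log(em.msd[:10]), 1)[0]
        assert sl == pytest.approx(1.0, abs=0.05)

    def test_fbm_generator_msd_slope(self):
        ds = synthetic.gen_tracks(n_tracks=300, n_frames=200, model="fbm",
                                  D=0.3, beta=0.6, seed=23)
        em = ensemble_msd(msd_per_track(ds.payload))
        sl = np.polyfit(np.log(em.lags[:10]), np.log(em.msd[:10]), 1)[0]
        assert sl == pytest.approx(0.6, abs=0.05)

    def test_confined_stays_in_corral(self):
        rc = 0.4
        ds = synthetic.gen_tracks(n_tracks=10, n_frames=200, model="confined",
                                  D=0.5, confinement_radius=rc,
                                  loc_noise=0.0, seed=9)
        df = ds.payload.data
        r = np.hypot(df["x_um"], df["y_um"])
        assert r.max() <= rc + 1e-9

    def test_too_short_movie_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            synthetic.gen_tracks(n_frames=2)

    def test_fbm_beta_bounds(self):
        with pytest.raises(ValueError):
            synthetic.gen_tracks(model="fbm", beta=2.5)


class TestForceCurves:
    def test_E_must_be_positive(self):
        with pytest.raises(ValueError):
            synthetic.gen_force_curves(E_true=0.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_force_curves(noise_sd=-1.0)

    def test_noiseless_curve_satisfies_contact_law(self):
        ds = synthetic.gen_force_curves(E_true=1500.0, geometry="cone",
                                        tip_param=30.0, noise_sd=0.0, seed=2)
        c = ds.payload[0]
        A = synthetic.hertz_prefactor(1500.0, 0.5, "cone", 30.0)
        force = c.force_n()
        delta = np.clip(c.z_um - 2.0, 0, None) * 1e-6 - c.deflection_nm * 1e-9
        post = force > 1e-13
        assert np.allclose(force[post], A * delta[post] ** 2, rtol=1e-9)

    def test_force_capped_at_setpoint(self):
        ds = synthetic.gen_force_curves(noise_sd=0.0, max_force=3e-9, seed=1)
        assert ds.payload[0].force_n().max() <= 3e-9 * (1 + 1e-6)


class TestCondensateImage:
    def test_spot_fraction_exact_by_construction(self):
        ds = synthetic.gen_condensate_image(aggregate_fraction=0.4, seed=12)
        sc = ds.payload
        diffuse = ds.truth.params["background_level"]
        spot_added = (sc.intensity - diffuse * sc.nucleus_mask)[sc.nucleus_mask]
        frac = spot_added.sum() / sc.intensity[sc.nucleus_mask].sum()
        assert frac == pytest.approx(0.4, abs=0.004)

    def test_zero_fraction_is_spotless(self):
        ds = synthetic.gen_condensate_image(aggregate_fraction=0.0, seed=2)
        assert not ds.payload.condensate_mask.any()
        bg = ds.truth.params["background_level"]
        assert np.all(ds.payload.intensity[ds.payload.nucleus_mask] == bg)

    def test_peripheral_bias_centroid_distance(self):
        ds = synthetic.gen_condensate_image(radial_bias="peripheral",
                                            nucleus_radius=5.0, seed=6)
        cents = np.asarray(ds.truth.extras["spot_centres_um"])
        assert np.hypot(cents[:, 0], cents[:, 1]).mean() > 2.5

    def test_impossible_placement_raises(self):
        with pytest.raises(ValueError):
            synthetic.gen_condensate_image(nucleus_radius=1.0, spot_sigma=0.5)
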