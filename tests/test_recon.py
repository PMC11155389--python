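"""Back-projection kernel: delays, weights, FBP integrand, and the volume."""

import numpy as np
import pytest

from pactrecon import (
    DetectorArray,
    SpherePhantom,
    backproject,
    build_fibonacci_hemisphere,
    build_grid,
    delay_index,
    simulate_sphere_signals,
    solid_angle_weight,
    temporal_derivative,
)
from pactrecon.io import zero_boundaries

from conftest import hemi_config, make_config, naive_backproject


class TestDelayIndex:
    def test_hand_arithmetic_rounding(self):
        cfg = make_config(num_times=2048)
        # 10 mm at 1500 m/s sampled at 40 MHz: 266.67 -> 267
        assert delay_index(10e-3, cfg) == 267

    def test_out_of_record_clamps_to_last_zeroed_sample(self):
        cfg = make_config(num_times=100)
        far = (100 + 50) / cfg.fs * cfg.vs  # index T + 50
        assert delay_index(far, cfg) == 99

    def test_tiny_distance_clamps_to_first_sample(self):
        cfg = make_config(num_times=100)
        assert delay_index(1e-12, cfg) == 0

    def test_linear_mode_returns_real_index(self):
        cfg = make_config(num_times=2048, interpolation="linear")
        assert delay_index(10e-3, cfg) == pytest.approx(266.6667, abs=1e-3)


class TestSolidAngleWeight:
    def test_on_axis_geometry(self):
        w = solid_angle_weight([0, 0, 0], [0, 0, 1], [0, 0, 10e-3])
        assert w.cos_theta == pytest.approx(1.0)
        assert w.weight == pytest.approx(1e4)

    def test_oblique_equals_z_over_l_cubed(self):
        w = solid_angle_weight([0, 0, 0], [0, 0, 1], [10e-3, 0, 10e-3])
        lij = np.sqrt(2) * 10e-3
        assert w.lij == pytest.approx(lij)
        assert w.weight == pytest.approx(10e-3 / lij**3)
        assert w.weight == pytest.approx(3535.53, rel=1e-4)

    def test_hemisphere_center(self):
        R = 0.1
        w = solid_angle_weight([0, 0, -R], [0, 0, 1], [0, 0, 0])
        assert w.cos_theta == pytest.approx(1.0)
        assert w.weight == pytest.approx(1 / R**2)

    def test_behind_plane_gets_zero_weight(self):
        w = solid_angle_weight([0, 0, 0], [0, 0, 1], [0, 0, -5e-3])
        assert w.weight == 0.0 and w.cos_theta < 0

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            solid_angle_weight([0, 0, 0], [0, 0, 1], [0, 0, 0])


class TestTemporalDerivative:
    def test_constant_signal_passes_through_interior(self):
        cfg = make_config(num_channels=1, num_steps=1, num_times=32)
        S = np.full((1, 32), 3.0, dtype=np.float32)
        q = temporal_derivative(S, cfg)
        np.testing.assert_allclose(q[0, 1:-1], 3.0, atol=1e-6)

    def test_linear_ramp_cancels_exactly(self):
        cfg = make_config(num_channels=1, num_steps=1, num_times=64)
        # dyadic slope: every sample value 0.25*k is exact in float32
        S = (0.25 * np.arange(64, dtype=np.float32))[None, :]
        q = temporal_derivative(S, cfg)
        assert np.abs(q[0, 1:-1]).max() <= 1e-5

    def test_boundaries_zeroed(self):
        cfg = make_config(num_channels=1, num_steps=2, num_times=16)
        S = np.ones((2, 16), dtype=np.float32)
        q = temporal_derivative(S, cfg)
        assert np.all(q[:, 0] == 0.0) and np.all(q[:, -1] == 0.0)

    def test_matches_fft_derivative_oracle_on_nwave(self):
        """Central-difference integrand agrees with spectral differentiation
        within 2% of the peak away from the support discontinuities (Gibbs
        ringing near the edges is the oracle's, not the integrand's)."""
        cfg = make_config(num_channels=1, num_steps=1, num_times=3000)
        arr = DetectorArray([[0, 0, -0.1]], [[0, 0, 1]])
        S = simulate_sphere_signals(SpherePhantom([0, 0, 0], 1e-3), arr, cfg)
        q = temporal_derivative(S, cfg)[0].astype(np.float64)

        p = S[0].astype(np.float64)
        T = p.size
        freqs = np.fft.fftfreq(T, d=1 / cfg.fs)
        dp = np.real(np.fft.ifft(2j * np.pi * freqs * np.fft.fft(p)))
        q_oracle = p - np.arange(T) / cfg.fs * dp

        support = np.nonzero(p)[0]
        guard = 32
        mask = np.ones(T, dtype=bool)
        for edge in (support.min(), support.max()):
            mask[max(0, edge - guard) : edge + guard + 1] = False
        dev = np.abs(q - q_oracle)[mask].max()
        assert dev < 0.02 * np.abs(q_oracle).max()


def tiny_setup(n_det=8, dims_extent=1.0e-3, seed=0, **cfg_kwargs):
    """Small random scene for oracle comparisons."""
    rng = np.random.default_rng(seed)
    cfg = make_config(num_channels=1, num_steps=n_det, num_times=128,
                      res=0.2e-3, **cfg_kwargs)
    pos = rng.uniform(-1e-3, 1e-3, (n_det, 3))
    pos[:, 2] = -rng.uniform(0.5e-3, 1.5e-3, n_det)
    nrm = rng.normal(size=(n_det, 3))
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm[:, 2] = np.abs(nrm[:, 2])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    arr = DetectorArray(pos, nrm)
    S = rng.normal(size=(n_det, 128)).astype(np.float32)
    S = zero_boundaries(S)
    grid = build_grid([0, 0, 0.8e-3], [dims_extent] * 3, 0.2e-3)
    return S, arr, grid, cfg


@pytest.mark.parametrize("algorithm", ["das", "fbp"])
@pytest.mark.parametrize("interpolation", ["nearest", "linear"])
def test_matches_naive_triple_loop_oracle(algorithm, interpolation):
    S, arr, grid, cfg = tiny_setup(
        n_det=16, algorithm=algorithm, interpolation=interpolation
    )
    vol = backproject(S, arr, grid, cfg).values
    oracle = naive_backproject(S, arr, grid, cfg)
    assert np.abs(vol - oracle).max() <= 1e-5 * np.abs(oracle).max()


def test_matches_oracle_with_solid_angle_normalization():
    S, arr, grid, cfg = tiny_setup(n_det=8, normalize_solid_angle=True)
    vol = backproject(S, arr, grid, cfg).values
    oracle = naive_backproject(S, arr, grid, cfg)
    assert np.abs(vol - oracle).max() <= 1e-5 * np.abs(oracle).max()


def test_single_detector_unit_spike_paints_isochrone():
    """A unit spike at sample k lights exactly the voxels whose delay rounds
    to k, each with its solid-angle weight."""
    cfg = make_config(num_channels=1, num_steps=1, num_times=128)
    arr = DetectorArray([[0, 0, 0]], [[0, 0, 1]])
    k = 40
    S = np.zeros((1, 128), dtype=np.float32)
    S[0, k] = 1.0
    grid = build_grid([0, 0, 1.5e-3], [1e-3] * 3, 0.2e-3)
    vol = backproject(S, arr, grid, cfg).values
    centers = grid.voxel_centers().reshape(-1, 3)
    lij = np.linalg.norm(centers, axis=1)
    idx = np.floor(lij / cfg.vs * cfg.fs + 0.5).astype(int)
    expected = np.where(idx == k, centers[:, 2] / lij**3, 0.0).reshape(grid.dims)
    np.testing.assert_allclose(vol, expected, rtol=1e-5, atol=1e-12)
    assert (expected != 0).any()


def test_all_zero_signals_give_all_zero_volume(sphere_volume_fbp, hemisphere_array, fov_grid):
    cfg = hemi_config()
    S = np.zeros((1024, 3000), dtype=np.float32)
    vol = backproject(S, hemisphere_array, fov_grid, cfg).values
    assert not vol.any()


def test_backprojection_is_linear_in_signals():
    S, arr, grid, cfg = tiny_setup(n_det=8, seed=5)
    rng = np.random.default_rng(6)
    S2 = zero_boundaries(rng.normal(size=S.shape).astype(np.float32))
    v1 = backproject(S, arr, grid, cfg).values.astype(np.float64)
    v2 = backproject(S2, arr, grid, cfg).values.astype(np.float64)
    v12 = backproject(S + S2, arr, grid, cfg).values.astype(np.float64)
    scale = np.abs(v1).max() + np.abs(v2).max()
    assert np.abs(v12 - (v1 + v2)).max() < 1e-5 * scale


def test_detector_permutation_invariance():
    S, arr, grid, cfg = tiny_setup(n_det=12, seed=9)
    rng = np.random.default_rng(10)
    perm = rng.permutation(12)
    arr_p = DetectorArray(arr.positions[perm], arr.normals[perm])
    v = backproject(S, arr, grid, cfg).values.astype(np.float64)
    v_p = backproject(S[perm], arr_p, grid, cfg).values.astype(np.float64)
    assert np.abs(v - v_p).max() < 1e-6 * np.abs(v).max()


class TestSphereRecovery:
    """Hemisphere study: 1 mm sphere at the centre of a 5 mm FOV."""

    def test_center_voxel_attains_the_maximum(self, sphere_volume_fbp):
        """The reconstructed sphere interior is an analytically flat plateau
        (the FBP integrand is p0/2 across the whole N-wave support), so the
        centre voxel must attain the volume maximum up to the plateau's
        discretisation ripple, and the literal argmax must fall inside the
        phantom."""
        v = sphere_volume_fbp.values
        center = tuple((d - 1) // 2 for d in v.shape)
        assert v[center] >= 0.99 * v.max()
        am = np.unravel_index(np.argmax(v), v.shape)
        offset = (np.array(am) - np.array(center)) * 0.2e-3
        assert np.linalg.norm(offset) <= 1e-3  # inside the 1 mm sphere

    def test_fwhm_matches_sphere_diameter(self, sphere_volume_fbp):
        v = sphere_volume_fbp.values
        grid = sphere_volume_fbp.grid
        profile = v[:, 12, 12].astype(np.float64)
        x = grid.axis_centers(0)
        fwhm = _fwhm(x, profile)
        assert fwhm == pytest.approx(2e-3, abs=2 * 0.2e-3)

    def test_translation_moves_argmax_one_voxel(self, hemisphere_array, fov_grid):
        """A sub-resolution sphere shifted by one grid spacing moves the
        argmax voxel by exactly one index."""
        cfg = hemi_config(algorithm="fbp")
        args = []
        for cx in (0.0, 0.2e-3):
            ph = SpherePhantom([cx, 0.0, 0.0], 0.15e-3)
            S = zero_boundaries(
                simulate_sphere_signals(ph, hemisphere_array, cfg)
            )
            v = backproject(S, hemisphere_array, fov_grid, cfg).values
            args.append(np.unravel_index(np.argmax(v), v.shape))
        assert args[1][0] == args[0][0] + 1
        assert args[1][1:] == args[0][1:]

    def test_das_and_fbp_peaks_colocate(self, hemisphere_array, fov_grid):
        """DAS and FBP localise a sub-resolution sphere to neighbouring
        voxels: the raw DAS image of the bipolar N-wave has a null at the
        exact centre, displacing its peak by at most one voxel from the FBP
        peak."""
        ph = SpherePhantom([0.0, 0.0, 0.0], 0.15e-3)
        peaks = {}
        for algorithm in ("das", "fbp"):
            cfg = hemi_config(algorithm=algorithm)
            S = zero_boundaries(
                simulate_sphere_signals(ph, hemisphere_array, cfg)
            )
            v = backproject(S, hemisphere_array, fov_grid, cfg).values
            peaks[algorithm] = np.array(
                np.unravel_index(np.argmax(v), v.shape)
            )
        assert np.abs(peaks["das"] - peaks["fbp"]).max() <= 1


def _fwhm(x, profile):
    half = profile.max() / 2.0
    imax = int(np.argmax(profile))
    li = imax
    while li > 0 and profile[li - 1] >= half:
        li -= 1
    ri = imax
    while ri < profile.size - 1 and profile[ri + 1] >= half:
        ri += 1
    left = x[li] if li == 0 else np.interp(
        half, [profile[li - 1], profile[li]], [x[li - 1], x[li]]
    )
    right = x[ri] if ri == profile.size - 1 else np.interp(
        half, [profile[ri + 1], profile[ri]], [x[ri + 1], x[ri]]
    )
    return right - left


def test_out_of_record_voxel_gets_zero_contribution():
    """A voxel whose time of flight exceeds the record reads only the zeroed
    boundary sample."""
    cfg = make_config(num_channels=1, num_steps=1, num_times=64)
    arr = DetectorArray([[0, 0, 0]], [[0, 0, 1]])
    rng = np.random.default_rng(2)
    S = zero_boundaries(rng.normal(size=(1, 64)).astype(np.float32))
    # T/fs * vs = 2.4 mm record depth; put the voxel at 5 mm
    grid = build_grid([0, 0, 5e-3], [0.2e-3] * 3, 0.2e-3)
    vol = backproject(S, arr, grid, cfg).values
    assert vol[0, 0, 0] == 0.0


def test_shape_mismatch_rejected():
    S, arr, grid, cfg = tiny_setup()
    with pytest.raises(ValueError):
        backproject(S[:-1], arr, grid, cfg)


def test_volume_save_load_round_trip(tmp_path):
    S, arr, grid, cfg = tiny_setup(seed=11)
    vol = backproject(S, arr, grid, cfg)
    path = vol.save(tmp_path / "vol.f32")
    from pactrecon import ReconVolume

    back = ReconVolume.load(path)
    np.testing.assert_array_equal(back.values, vol.values)
    assert back.grid.dims == vol.grid.dims
    np.testing.assert_allclose(back.grid.origin, vol.grid.origin)
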