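"""Forward operator, analytic gradients, fat model, and PDFF branch rule."""

import numpy as np
import pytest

from starfat import (
    AcqParams,
    FatModel,
    ParameterMaps,
    build_trajectory,
    compute_pdff,
    fat_kspace_weights,
    forward_operator,
    make_coils,
    make_phantom,
    nufft_forward,
    simulate_kspace,
)
from starfat.signalmodel import SignalOperator

from .oracles import scalar_signal


class TestFatModel:
    def test_weights_normalized_at_time_zero(self, fat_model):
        assert fat_kspace_weights(fat_model, np.array([0.0]))[0] == pytest.approx(1.0)

    def test_single_peak_reduces_to_phasor(self):
        fm = FatModel(peak_offsets_hz=np.array([-434.0]), relative_amplitudes=np.array([1.0]))
        t = np.array([0.5e-3, 1.23e-3])
        d = fat_kspace_weights(fm, t)
        assert np.allclose(np.abs(d), 1.0)
        assert np.allclose(d, np.exp(2j * np.pi * -434.0 * t))

    def test_six_peak_matches_brute_force_sum(self, fat_model):
        t = 2.46e-3
        oracle = np.sum(
            fat_model.relative_amplitudes
            * np.exp(2j * np.pi * fat_model.peak_offsets_hz * t)
        )
        assert fat_kspace_weights(fat_model, np.array([t]))[0] == pytest.approx(oracle)

    def test_amplitudes_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FatModel(np.array([0.0, -400.0]), np.array([0.5, 0.6]))


class TestForwardOperator:
    def test_reduces_to_nufft_for_water_only(self, fat_model):
        n = 16
        rng = np.random.default_rng(0)
        w = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        traj = build_trajectory(AcqParams(n_read=n, n_proj=8, n_echo=2))
        maps = ParameterMaps(w, np.zeros((n, n), complex), np.zeros((n, n)))
        coils = np.ones((1, n, n), complex)
        pred = forward_operator(maps, np.zeros((n, n)), coils, traj, fat_model)
        direct = nufft_forward(w, traj.coords(0))
        assert np.allclose(pred[0, 0], direct)

    def test_dc_decay_ratio_matches_closed_form(self, fat_model):
        """Uniform water object: DC magnitude ratio between echoes is exp(-R2* dTE)."""
        n = 48
        truth = make_phantom(
            n,
            {
                "liver": {"pdff": 0.0, "r2s": 60.5},
                "subcutaneous_fat": {"pd": 0.0},
                "vessel": {"pd": 0.0},
                "lesion": {"pd": 0.0},
                "b0": {"offset_hz": 0.0, "linear_hz": (0, 0), "quad_hz": 0.0},
                "phase": {"offset": 0.0, "linear": (0, 0)},
            },
        )
        coils = make_coils(n, 1, uniform=True)
        traj = build_trajectory(AcqParams(n_read=n, n_proj=4, n_echo=3))
        data = simulate_kspace(truth, coils, traj, fat_model)
        dc = data.samples[n // 2, 0, 0, 0, :]
        assert abs(dc[1]) / abs(dc[0]) == pytest.approx(np.exp(-60.5 * 1.23e-3), rel=1e-6)

    def test_generator_matches_operator_exactly(self, phantom48, coils48, traj48, fat_model):
        """Zero-noise static simulation equals the forward operator bit-for-bit."""
        data = simulate_kspace(phantom48, coils48, traj48, fat_model)
        op = SignalOperator(traj48, coils48.sensitivities, phantom48.b0_map, fat_model)
        pred = op.forward(phantom48.maps())
        assert np.array_equal(pred, data.slice_data(0))

    def test_pure_fat_single_peak_against_scalar_oracle(self):
        """4x4 single-voxel-by-voxel check of the fat pathway."""
        n = 4
        rng = np.random.default_rng(5)
        fm = FatModel(np.array([-440.0]), np.array([1.0]))
        f = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        r2s = rng.uniform(20, 120, (n, n))
        phi = rng.uniform(-40, 40, (n, n))
        traj = build_trajectory(AcqParams(n_read=n, n_proj=3, n_echo=2))
        maps = ParameterMaps(np.zeros((n, n), complex), f, r2s)
        coils = np.ones((1, n, n), complex)
        pred = forward_operator(maps, phi, coils, traj, fm)
        ii = (np.arange(n) - n // 2) / n
        x, y = np.meshgrid(ii, ii, indexing="ij")
        for e in range(2):
            coords = traj.coords(e)
            times = traj.times(e)
            for s in (0, 5, 11):
                kx, ky = coords[s]
                acc = 0.0
                for i in range(n):
                    for j in range(n):
                        voxel = scalar_signal(
                            0.0, f[i, j], r2s[i, j], phi[i, j],
                            traj.te[e], times[s], fm.peak_offsets_hz,
                            fm.relative_amplitudes,
                        )
                        acc += voxel * np.exp(-2j * np.pi * (kx * x[i, j] + ky * y[i, j]))
                assert pred[0, e, s] == pytest.approx(acc, rel=1e-3)

    def test_linearity_in_water_and_fat(self, fat_model):
        n = 16
        rng = np.random.default_rng(2)
        traj = build_trajectory(AcqParams(n_read=n, n_proj=6, n_echo=3))
        coils = (rng.standard_normal((2, n, n)) + 1j * rng.standard_normal((2, n, n)))
        phi = rng.uniform(-50, 50, (n, n))
        r2s = rng.uniform(0, 100, (n, n))
        op = SignalOperator(traj, coils, phi, fat_model)
        w1, f1 = (rng.standard_normal((2, n, n)) + 1j * rng.standard_normal((2, n, n)))
        w2, f2 = (rng.standard_normal((2, n, n)) + 1j * rng.standard_normal((2, n, n)))
        a, b = 1.7, -0.6 + 0.3j
        lhs = op.forward(ParameterMaps(a * w1 + b * w2, a * f1 + b * f2, r2s))
        rhs = a * op.forward(ParameterMaps(w1, f1, r2s)) + b * op.forward(
            ParameterMaps(w2, f2, r2s)
        )
        assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-8)

    def test_hermitian_symmetry_for_real_maps(self):
        """Real maps with Phi = 0 give Hermitian-symmetric data along a DC spoke."""
        n = 16
        rng = np.random.default_rng(3)
        fm = FatModel(np.array([0.0]), np.array([1.0]))  # on-resonance "fat"
        w = np.abs(rng.standard_normal((n, n))).astype(complex)
        maps = ParameterMaps(w, 0.3 * w, np.zeros((n, n)))
        traj = build_trajectory(
            AcqParams(n_read=n, n_proj=1, n_echo=2, readout_mode="monopolar",
                      blip_rotation_deg=0.0)
        )
        coils = np.ones((1, n, n), complex)
        pred = forward_operator(maps, np.zeros((n, n)), coils, traj, fm)
        spoke = pred[0, 0].reshape(n)
        # sample at +r and -r are conjugates (R2* decay is symmetric in radius
        # only at the echo center, so compare the pure-FT echo-1 spoke)
        for off in (1, 3, 5):
            assert spoke[n // 2 + off] == pytest.approx(np.conj(spoke[n // 2 - off]), rel=1e-6)


class TestGradients:
    @pytest.fixture(scope="class")
    def instance(self, fat_model):
        rng = np.random.default_rng(11)
        n = 8
        traj = build_trajectory(AcqParams(n_read=n, n_proj=12, n_echo=6))
        coils = 0.4 * (rng.standard_normal((2, n, n)) + 1j * rng.standard_normal((2, n, n)))
        phi = rng.uniform(-60, 60, (n, n))
        op = SignalOperator(traj, coils, phi, fat_model)
        maps = ParameterMaps(
            rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)),
            rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)),
            rng.uniform(0, 150, (n, n)),
        )
        target = ParameterMaps(
            rng.standard_normal((n, n)) + 0j, rng.standard_normal((n, n)) + 0j,
            rng.uniform(0, 100, (n, n)),
        )
        data = op.forward(target)
        return op, maps, data

    def test_cost_zero_at_truth(self, phantom48, coils48, traj48, fat_model):
        data = simulate_kspace(phantom48, coils48, traj48, fat_model)
        op = SignalOperator(traj48, coils48.sensitivities, phantom48.b0_map, fat_model)
        cost, gw, gf, gr = op.cost_grad(phantom48.maps(), data.slice_data(0))
        scale = float(np.sum(np.abs(data.samples) ** 2))
        assert cost / scale < 1e-25
        assert np.max(np.abs(gw)) / np.sqrt(scale) < 1e-10
        assert np.max(np.abs(gr)) / np.sqrt(scale) < 1e-10

    @pytest.mark.parametrize("step", [1e-4, 1e-5, 1e-6])
    def test_gradients_match_central_differences(self, instance, step):
        op, maps, data = instance
        cost0, gw, gf, gr = op.cost_grad(maps, data)
        rng = np.random.default_rng(21)
        idx = [(int(a), int(b)) for a, b in rng.integers(0, 8, (4, 2))]

        def fd(perturb):
            m = maps.copy()
            perturb(m, step)
            cp = op.cost_grad(m, data)[0]
            m = maps.copy()
            perturb(m, -step)
            cm = op.cost_grad(m, data)[0]
            return (cp - cm) / (2 * step)

        for i, j in idx:
            num = fd(lambda m, h: m.water.__setitem__((i, j), m.water[i, j] + h))
            assert num == pytest.approx(gw[i, j].real, rel=1e-4, abs=1e-8)
            num = fd(lambda m, h: m.water.__setitem__((i, j), m.water[i, j] + 1j * h))
            assert num == pytest.approx(gw[i, j].imag, rel=1e-4, abs=1e-8)
            num = fd(lambda m, h: m.fat.__setitem__((i, j), m.fat[i, j] + h))
            assert num == pytest.approx(gf[i, j].real, rel=1e-4, abs=1e-8)
            num = fd(lambda m, h: m.r2s.__setitem__((i, j), m.r2s[i, j] + h * 1e2))
            assert num * 1e2 == pytest.approx(gr[i, j] * 1e2 * 1e2, rel=1e-4) or (
                num == pytest.approx(gr[i, j] * 1e2, rel=1e-4)
            )

    def test_cost_homogeneity_in_residual(self, instance):
        op, maps, data = instance
        zero = ParameterMaps(
            np.zeros_like(maps.water), np.zeros_like(maps.fat), np.zeros_like(maps.r2s)
        )
        c1 = op.cost_grad(zero, data)[0]
        c2 = op.cost_grad(zero, 2.0 * data)[0]
        assert c2 == pytest.approx(4.0 * c1, rel=1e-12)


class TestPdff:
    def test_branch_cases(self):
        def scalar_pdff(w, f):
            maps = ParameterMaps(
                np.array([[w]], complex), np.array([[f]], complex), np.zeros((1, 1))
            )
            return compute_pdff(maps)[0, 0]

        assert scalar_pdff(1.0, 0.0) == pytest.approx(0.0, abs=1e-15)
        assert scalar_pdff(0.0, 1.0) == pytest.approx(1.0, abs=1e-15)
        assert scalar_pdff(0.6, 0.4) == pytest.approx(0.4, abs=1e-15)
        assert scalar_pdff(0.4, 0.6) == pytest.approx(0.6, abs=1e-15)
        # magnitude discrimination on a noisy orthogonal fat component
        assert scalar_pdff(1.0, 0.1j) == pytest.approx(1 - 1 / abs(1 + 0.1j), rel=1e-9)

    def test_aligned_phases_stay_in_unit_interval_and_continuous(self):
        rng = np.random.default_rng(4)
        mag = rng.uniform(0, 2, (2, 64))
        phase = np.exp(1j * rng.uniform(-np.pi, np.pi, 64))
        maps = ParameterMaps(
            (mag[0] * phase).reshape(8, 8), (mag[1] * phase).reshape(8, 8), np.zeros((8, 8))
        )
        pdff = compute_pdff(maps)
        assert np.all(pdff >= 0) and np.all(pdff <= 1)
        # branch continuity at |F| = |W| with aligned phases
        maps_eq = ParameterMaps(
            np.full((1, 1), 0.5 + 0.1j), np.full((1, 1), 0.5 + 0.1j), np.zeros((1, 1))
        )
        assert compute_pdff(maps_eq)[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_voxels_masked(self):
        maps = ParameterMaps(
            np.array([[1.0, 0.0]], complex), np.array([[0.5, 0.0]], complex), np.zeros((1, 2))
        )
        pdff, mask = compute_pdff(maps, return_mask=True)
        assert mask[0, 0] and not mask[0, 1]
        assert pdff[0, 1] == 0.0
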