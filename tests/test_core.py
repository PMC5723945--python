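import numpy as np
import pytest

from entroseg import (
    ModelParams,
    bias_correct,
    compute_force_maps,
    dirac,
    evolve_phi,
    heaviside,
    initialize_phi,
    js,
    make_kernel,
    make_phantom,
    region_mask,
    segment,
    total_energy,
    update_bias,
    update_c,
    update_sigma,
)
from entroseg.core import LevelSetState, _sigma_floor

import oracles


def make_state(inst):
    return LevelSetState(
        phi=inst["phi"], c=inst["c"], sigma_sq=inst["sigma_sq"], bias=inst["bias"]
    )


class TestKernel:
    def test_weights_sum_to_one_and_symmetry(self):
        k = make_kernel(3.0, 12)
        assert k.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(k.weights, k.weights[::-1, :])
        assert np.allclose(k.weights, k.weights[:, ::-1])
        assert np.allclose(k.weights, k.weights.T)

    def test_large_sigma_approaches_uniform(self):
        k = make_kernel(1e6, 1)
        assert np.allclose(k.weights, 1.0 / 9.0, atol=1e-9)

    def test_center_value_matches_direct_evaluation(self):
        sigma, radius = 3.0, 12
        k = make_kernel(sigma, radius)
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        w = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
        assert k.weights[radius, radius] == pytest.approx(1.0 / w.sum(), rel=1e-12)

    def test_disk_truncation_zeroes_corners(self):
        k = make_kernel(5.0, 3, shape="disk")
        assert k.weights[0, 0] == 0.0
        assert k.weights.sum() == pytest.approx(1.0)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            make_kernel(0.0, 3)


class TestHeavisideDirac:
    def test_fixed_values(self):
        assert heaviside(0.0, 2.5) == pytest.approx(0.5)
        assert heaviside(1.0, 1.0) == pytest.approx(0.75)
        assert dirac(0.0, 1.0) == pytest.approx(1.0 / np.pi)

    def test_dirac_is_derivative_of_heaviside(self):
        x = np.linspace(-5, 5, 201)
        eps, h = 0.7, 1e-6
        num = (heaviside(x + h, eps) - heaviside(x - h, eps)) / (2 * h)
        assert np.allclose(num, dirac(x, eps), atol=1e-7)

    def test_partition_of_unity(self, rng):
        phi = rng.normal(0, 10, (20, 20))
        for eps in (0.5, 1.0, 3.0):
            m1 = heaviside(phi, eps)
            assert np.allclose(m1 + (1.0 - m1), 1.0)
            assert np.all((m1 > 0) & (m1 < 1))


class TestForceMaps:
    def test_zero_entropy_gives_zero_forces(self, small_params, small_kernel, rng):
        inst = oracles.random_instance(0)
        e1, e2 = compute_force_maps(
            inst["image"], np.zeros_like(inst["image"]), make_state(inst),
            small_kernel, small_params,
        )
        assert np.allclose(e1, 0.0) and np.allclose(e2, 0.0)

    def test_perfect_fit_leaves_only_log_term(self, small_params, small_kernel):
        # constant image equal to b·c_i with b constant: residual term vanishes
        image = np.full((10, 10), 80.0)
        ent = np.ones_like(image)
        st = LevelSetState(phi=np.zeros_like(image), c=(80.0, 40.0),
                           sigma_sq=(100.0, 100.0), bias=np.ones_like(image))
        e1, _ = compute_force_maps(image, ent, st, small_kernel, small_params)
        from scipy.signal import fftconvolve
        ke = fftconvolve(ent, small_kernel.weights, mode="same")
        expected = ke * (np.log(np.sqrt(2 * np.pi)) + 0.5 * np.log(100.0))
        assert np.allclose(e1, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_oracle(self, small_params, small_kernel, seed):
        inst = oracles.random_instance(seed)
        e1, e2 = compute_force_maps(
            inst["image"], inst["entropy"], make_state(inst), small_kernel, small_params
        )
        o1, o2 = oracles.force_maps_loops(
            inst["image"], inst["entropy"], inst["bias"], inst["c"],
            inst["sigma_sq"], small_kernel.weights, small_kernel.radius,
        )
        assert np.allclose(e1, o1, rtol=1e-8)
        assert np.allclose(e2, o2, rtol=1e-8)


class TestClosedFormUpdates:
    def test_constant_image_gives_that_constant(self, small_params, small_kernel, rng):
        image = np.full((8, 8), 42.0)
        phi = rng.normal(0, 2, (8, 8))
        c = update_c(image, np.ones_like(image), phi, small_kernel, small_params)
        assert c[0] == pytest.approx(42.0)
        assert c[1] == pytest.approx(42.0)

    def test_constant_bias_scales_means_inversely(self, small_params, small_kernel, rng):
        image = np.full((8, 8), 42.0)
        phi = rng.normal(0, 2, (8, 8))
        c = update_c(image, np.full((8, 8), 2.0), phi, small_kernel, small_params)
        assert c[0] == pytest.approx(21.0)
        assert c[1] == pytest.approx(21.0)

    def test_piecewise_image_recovers_class_values(self):
        # crisp partition, interior-weighted kernel: means near the true values
        p = ModelParams(kernel_sigma=0.8, radius_r=1)
        k = make_kernel(p.kernel_sigma, 1)
        image = np.full((10, 10), 40.0)
        image[:, :5] = 120.0
        phi = np.where(image == 120.0, 50.0, -50.0)
        c = update_c(image, np.ones_like(image), phi, k, p)
        assert abs(c[0] - 120.0) < 2.0
        assert abs(c[1] - 40.0) < 2.0

    def test_empty_class_keeps_previous_with_warning(self, small_params, small_kernel, rng, caplog):
        image = rng.uniform(0, 255, (8, 8))
        phi = rng.normal(0, 2, (8, 8))
        c = update_c(image, np.zeros_like(image) + 0.0, phi, small_kernel,
                     small_params, entropy=np.zeros_like(image), prev=(7.0, 9.0))
        assert c == (7.0, 9.0)

    def test_bias_identity_when_image_matches_class_mean(self, small_params, small_kernel):
        image = np.full((8, 8), 90.0)
        phi = np.full((8, 8), 50.0)  # membership ~ all class 1
        b = update_bias(image, phi, (90.0, 0.0), (100.0, 100.0), small_kernel, small_params)
        assert np.allclose(b, 1.0, atol=1e-12)

    def test_bias_degenerate_raises(self, small_params, small_kernel, rng):
        image = rng.uniform(0, 255, (8, 8))
        with pytest.raises(ValueError):
            update_bias(image, rng.normal(0, 2, (8, 8)), (0.0, 0.0),
                        (100.0, 100.0), small_kernel, small_params)

    def test_constant_offset_residual_gives_offset_squared(self, small_params, small_kernel):
        image = np.full((10, 10), 60.0 + 12.0)
        phi = np.zeros((10, 10))
        s = update_sigma(image, np.ones_like(image), phi, (60.0, 60.0),
                         small_kernel, small_params)
        assert s[0] == pytest.approx(144.0, rel=1e-10)
        assert s[1] == pytest.approx(144.0, rel=1e-10)

    def test_zero_residual_floors(self, small_params, small_kernel):
        image = np.full((10, 10), 60.0)
        # non-constant so the range-based floor is nonzero
        image[0, 0] = 160.0
        phi = np.full((10, 10), 50.0)
        s = update_sigma(image, np.ones_like(image), phi, (60.0, 60.0),
                         small_kernel, small_params)
        assert s[1] >= _sigma_floor(image)

    @pytest.mark.parametrize("seed", range(3))
    def test_updates_match_bruteforce_oracles(self, small_params, small_kernel, seed):
        inst = oracles.random_instance(seed)
        kw, r = small_kernel.weights, small_kernel.radius
        c = update_c(inst["image"], inst["bias"], inst["phi"], small_kernel,
                     small_params, entropy=inst["entropy"])
        oc = oracles.update_c_loops(inst["image"], inst["entropy"], inst["bias"],
                                    inst["phi"], kw, r)
        assert c == pytest.approx(oc, rel=1e-8)

        b = update_bias(inst["image"], inst["phi"], inst["c"], inst["sigma_sq"],
                        small_kernel, small_params)
        ob = oracles.update_bias_loops(inst["image"], inst["phi"], inst["c"],
                                       inst["sigma_sq"], kw, r)
        assert np.allclose(b, ob, rtol=1e-8)

        s = update_sigma(inst["image"], inst["bias"], inst["phi"], inst["c"],
                         small_kernel, small_params, entropy=inst["entropy"])
        os_ = oracles.update_sigma_loops(inst["image"], inst["entropy"], inst["bias"],
                                         inst["phi"], inst["c"], kw, r,
                                         floor=_sigma_floor(inst["image"]))
        assert s == pytest.approx(os_, rel=1e-8)


class TestEvolvePhi:
    def test_planar_sdf_interior_is_fixed_point(self):
        p = ModelParams(nu=1.0)
        xx = np.arange(16, dtype=float)
        phi = np.tile(xx - 7.5, (16, 1))
        e = np.ones((16, 16))
        out = evolve_phi(phi, e, e, p)  # equal forces cancel with λ1=λ2
        assert np.allclose(out[2:-2, 2:-2], phi[2:-2, 2:-2], atol=1e-12)

    def test_data_force_sign(self):
        p = ModelParams(nu=1e-12, mu=1e-12)
        phi = np.zeros((8, 8))
        e1 = np.full((8, 8), 2.0)
        e2 = np.zeros((8, 8))
        out = evolve_phi(phi, e1, e2, p)
        assert np.all(out < 0)  # λ1e1 > λ2e2 pushes φ down

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_stencil(self, seed):
        p = ModelParams()
        inst = oracles.random_instance(seed)
        out = evolve_phi(inst["phi"], inst["image"] / 100.0, inst["entropy"], p)
        ref = oracles.evolve_loops(inst["phi"], inst["image"] / 100.0, inst["entropy"],
                                   p.dt, p.nu, p.mu, epsilon=p.epsilon)
        assert np.allclose(out, ref, atol=1e-10)

    def test_nan_forces_abort(self):
        p = ModelParams()
        bad = np.full((6, 6), np.nan)
        with pytest.raises(FloatingPointError):
            evolve_phi(np.zeros((6, 6)), bad, bad, p)


class TestTotalEnergy:
    def test_distance_regularizer_vanishes_for_plane(self, small_params, small_kernel):
        xx = np.arange(12, dtype=float)
        phi = np.tile(xx - 100.5, (12, 1))  # SDF plane, uniformly negative
        image = np.full((12, 12), 50.0)
        ent = np.ones_like(image)
        st = LevelSetState(phi=phi, c=(50.0, 50.0), sigma_sq=(25.0, 25.0),
                           bias=np.ones_like(image))
        p_mu = ModelParams(kernel_sigma=1.5, radius_r=3, mu=1.0, nu=1e-12)
        p_nonu = ModelParams(kernel_sigma=1.5, radius_r=3, mu=1e-12, nu=1e-12)
        f_mu = total_energy(image, ent, st, small_kernel, p_mu)
        f_nonu = total_energy(image, ent, st, small_kernel, p_nonu)
        assert f_mu == pytest.approx(f_nonu, abs=1e-9)  # μ-term contributes 0

    def test_length_term_vanishes_far_from_interface(self, small_kernel):
        xx = np.arange(12, dtype=float)
        phi = np.tile(xx, (12, 1)) + 1e6  # uniform sign, |∇φ| = 1
        image = np.full((12, 12), 50.0)
        ent = np.ones_like(image)
        st = LevelSetState(phi=phi, c=(50.0, 50.0), sigma_sq=(25.0, 25.0),
                           bias=np.ones_like(image))
        p = ModelParams(kernel_sigma=1.5, radius_r=3, nu=1e4, mu=1e-12)
        p0 = ModelParams(kernel_sigma=1.5, radius_r=3, nu=1e-12, mu=1e-12)
        diff = total_energy(image, ent, st, small_kernel, p) - total_energy(
            image, ent, st, small_kernel, p0)
        assert abs(diff) < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_oracle(self, small_params, small_kernel, seed):
        inst = oracles.random_instance(seed)
        f = total_energy(inst["image"], inst["entropy"], make_state(inst),
                         small_kernel, small_params)
        ref = oracles.total_energy_loops(
            inst["image"], inst["entropy"], inst["bias"], inst["phi"], inst["c"],
            inst["sigma_sq"], small_kernel.weights, small_kernel.radius,
            small_params.nu, small_params.mu, epsilon=small_params.epsilon,
        )
        assert f == pytest.approx(ref, rel=1e-6)


class TestInitialization:
    def test_binary_values_and_printed_sign_convention(self):
        phi = initialize_phi((32, 32), ("circle", 16, 16, 5), 2.0)
        assert set(np.unique(phi)) == {-2.0, 2.0}
        assert phi[16, 16] == -2.0  # inside is negative by default

    def test_half_plane_sign_pattern(self):
        phi = initialize_phi((10, 10), ("halfplane", 1, 5), 3.0, inside_sign=+1.0)
        assert np.all(phi[:, :5] == 3.0)
        assert np.all(phi[:, 5:] == -3.0)

    def test_negative_count_equals_rasterized_area(self):
        r = 5
        phi = initialize_phi((32, 32), ("circle", 16, 16, r), 2.0)
        count = sum(
            1
            for i in range(32)
            for j in range(32)
            if (i - 16) ** 2 + (j - 16) ** 2 <= r * r
        )
        assert int((phi < 0).sum()) == count

    def test_degenerate_region_raises(self):
        with pytest.raises(ValueError):
            initialize_phi((8, 8), np.zeros((8, 8), dtype=bool), 2.0)
        with pytest.raises(ValueError):
            initialize_phi((8, 8), np.ones((8, 8), dtype=bool), 2.0)
        with pytest.raises(ValueError):
            initialize_phi((8, 8), ("circle", 4, 4, 10), 2.0)

    def test_region_mask_kinds(self):
        m = region_mask((6, 8), ("rectangle", 1, 2, 4, 7))
        assert m.sum() == 3 * 5
        m2 = region_mask((6, 8), ("halfplane", 0, 3))
        assert m2.sum() == 3 * 8
        with pytest.raises(ValueError):
            region_mask((6, 8), ("blob", 1))


class TestBiasCorrect:
    def test_identity_and_scaling(self):
        img = np.full((4, 4), 10.0)
        assert np.allclose(bias_correct(img, np.ones((4, 4))), img)
        assert np.allclose(bias_correct(img, np.full((4, 4), 2.0)), 5.0)

    def test_round_trip_with_true_bias(self, rng):
        true = rng.uniform(10, 200, (8, 8))
        bias = rng.uniform(0.5, 1.5, (8, 8))
        assert np.allclose(bias_correct(true * bias, bias), true, rtol=1e-12)


class TestSegmentDriver:
    def test_zero_iterations_returns_initial_region(self):
        ph = make_phantom("disk", 48, 120, 40, bias_amplitude=0.0, noise_level=0.0)
        p = ModelParams(max_iters=0)
        res = segment(ph.observed, p, init=("circle", 24, 24, 10))
        expected = region_mask((48, 48), ("circle", 24, 24, 10))
        assert np.array_equal(res.mask, expected)
        assert res.iterations_run == 0
        assert len(res.energy_trace) == 1

    def test_clean_disk_recovery(self):
        ph = make_phantom("disk", 48, 120, 40, bias_amplitude=0.0, noise_level=0.0,
                          radius=14)
        res = segment(ph.observed)
        assert js(res.mask, ph.mask) >= 0.95
        assert res.converged

    def test_bias_correction_reduces_within_class_variation(self):
        ph = make_phantom("disk", 64, 120, 40, bias_amplitude=0.3, noise_level=0.0,
                          seed=3)
        res = segment(ph.observed)
        for cls in (ph.mask, ~ph.mask):
            cv_raw = ph.observed[cls].std() / ph.observed[cls].mean()
            cv_corr = res.corrected[cls].std() / res.corrected[cls].mean()
            assert cv_corr < cv_raw

    def test_entropy_weight_ablation(self):
        # zero weight kills the data force: the mask stays at the seed region
        ph = make_phantom("disk", 48, 120, 40, bias_amplitude=0.0, noise_level=0.0)
        init = ("circle", 24, 24, 10)
        p = ModelParams(max_iters=5, tol=1e-30)
        res = segment(ph.observed, p, init=init,
                      entropy_map=np.zeros_like(ph.observed))
        seed_mask = region_mask((48, 48), init)
        assert js(res.mask, seed_mask) > 0.95

    def test_flat_entropy_equals_unweighted_model(self):
        ph = make_phantom("disk", 48, 120, 40, bias_amplitude=0.2, noise_level=0.02,
                          seed=1)
        p = ModelParams(max_iters=30, tol=1e-30)
        res_flat = segment(ph.observed, p, entropy_map=np.ones_like(ph.observed))
        assert np.all(np.isfinite(res_flat.energy_trace))
        assert res_flat.mask.any() and not res_flat.mask.all()

    def test_energy_trace_finite_and_state_sane(self):
        ph = make_phantom("disk", 48, 120, 40, bias_amplitude=0.3, noise_level=0.1,
                          seed=2)
        res = segment(ph.observed)
        assert np.all(np.isfinite(res.energy_trace))
        assert len(res.energy_trace) == res.iterations_run + 1
        assert np.all(res.bias > 0)
        assert all(s > 0 for s in res.state.sigma_sq)
        assert np.all(np.isfinite(res.corrected))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            segment(np.ones((1, 5)))
        with pytest.raises(ValueError):
            segment(np.full((8, 8), np.inf))
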