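"""Shell-by-shell powder-average estimators and their equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from powderavg._sph import real_sh_basis, real_sph_harm, cart_to_sph
from powderavg.sampling import build_scheme, lebedev_rule, repulsion_directions
from powderavg.shell import (
    WeightSet,
    arithmetic_average,
    average_all_shells,
    knutsson_weights,
    lebedev_average,
    sh_powder_average,
    tensor_powder_average,
    weighted_average,
)
from powderavg.simulate import TissueModel, simulate_signal

from conftest import B_GRID


@pytest.fixture(scope="module")
def dirs61():
    return repulsion_directions(61, seed=0).directions


class TestArithmeticAndWeighted:
    def test_basics(self):
        assert arithmetic_average([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert arithmetic_average(np.full(7, 3.14)) == pytest.approx(3.14)
        with pytest.raises(ValueError):
            arithmetic_average([])

    def test_weighted(self):
        assert weighted_average([0.0, 1.0], np.array([1.0, 3.0])) == pytest.approx(0.75)
        # equal weights reduce to the arithmetic mean
        s = np.array([0.1, 0.9, 0.3])
        assert weighted_average(s, np.ones(3)) == pytest.approx(arithmetic_average(s))
        with pytest.raises(ValueError):
            weighted_average([1.0], np.array([0.0]))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_weight_scale_invariance(self, scale):
        s = np.array([0.3, 0.5, 0.1, 0.7])
        w = np.array([1.0, 2.0, 0.5, 1.5])
        assert weighted_average(s, w * scale) == pytest.approx(
            weighted_average(s, w), rel=1e-12)


class TestLebedevAverage:
    def test_constant(self):
        rule = lebedev_rule(43)
        assert lebedev_average(np.full(43, 0.7), rule) == pytest.approx(0.7, abs=1e-14)

    def test_pure_harmonic_has_zero_isotropic_part(self):
        rule = lebedev_rule(43)
        theta, phi = cart_to_sph(rule.directions)
        y20 = real_sph_harm(2, 0, theta, phi)
        assert abs(lebedev_average(y20, rule)) < 1e-10

    def test_dispersed_signal_on_shell(self):
        """kappa=1 signal at b=1.5 on the 43-pair rule: the quadrature
        reproduces the closed-form average 0.5640."""
        rule = lebedev_rule(43)
        from powderavg.sampling import GradientScheme

        sch = GradientScheme(rule.directions, np.full(43, 1.5))
        sig = simulate_signal(sch, TissueModel.single(1.0))
        est = lebedev_average(sig.values, rule, directions=rule.directions)
        assert est == pytest.approx(0.5640, abs=1e-3)

    def test_direction_mismatch_error(self):
        rule = lebedev_rule(19)
        bad = repulsion_directions(19, seed=1).directions
        with pytest.raises(ValueError, match="direction"):
            lebedev_average(np.ones(19), rule, directions=bad)


class TestSHAndTensor:
    def test_isotropic_signal_recovered(self, dirs61):
        for L in (2, 4, 6):
            est, _ = sh_powder_average(dirs61, np.full(61, 0.42), L)
            assert est == pytest.approx(0.42, abs=1e-10)
        est, _ = tensor_powder_average(dirs61, np.full(61, 0.42))
        assert est == pytest.approx(0.42, abs=1e-10)

    def test_quadratic_form_trace(self, dirs61):
        """S(u) = u^T diag(1,2,3) u has orientational mean Tr/3 = 2."""
        M = np.diag([1.0, 2.0, 3.0])
        s = np.einsum("ij,jk,ik->i", dirs61, M, dirs61)
        est_sh, _ = sh_powder_average(dirs61, s, 2)
        est_t, fit = tensor_powder_average(dirs61, s)
        assert est_sh == pytest.approx(2.0, abs=1e-10)
        assert est_t == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(fit.m_vector[:3], [1, 2, 3], atol=1e-9)

    def test_dispersed_signal_printed_value(self, dirs61):
        from powderavg.sampling import GradientScheme

        sch = GradientScheme(dirs61, np.full(61, 6.0))
        sig = simulate_signal(sch, TissueModel.single(1.0))
        est, _ = sh_powder_average(dirs61, sig.values, 6)
        assert est == pytest.approx(0.1682, abs=1e-3)

    def test_rank_deficiency_reports_condition(self):
        clustered = np.tile([0.0, 0.0, 1.0], (30, 1))
        clustered += np.random.default_rng(0).normal(0, 1e-4, clustered.shape)
        clustered /= np.linalg.norm(clustered, axis=1, keepdims=True)
        with pytest.raises(ValueError, match="condition number"):
            sh_powder_average(clustered, np.ones(30), 6)

    def test_insufficient_samples(self):
        d = repulsion_directions(10, seed=0).directions
        with pytest.raises(ValueError, match="at least"):
            sh_powder_average(d, np.ones(10), 6)  # 28 coefficients needed

    def test_tensor_equals_sh2_on_random_signals(self, dirs61):
        rng = np.random.default_rng(42)
        for s in rng.standard_normal((100, 61)):
            t, _ = tensor_powder_average(dirs61, s)
            h, _ = sh_powder_average(dirs61, s, 2)
            assert t == pytest.approx(h, abs=1e-9)


class TestKnutssonWeights:
    def test_octahedron_equal_weights(self):
        d = lebedev_rule(3).directions
        w = knutsson_weights(d, k_max=2)
        np.testing.assert_allclose(w.weights, 1.0 / 3.0, atol=1e-12)

    def test_unit_v_reproduces_sh_estimate(self, dirs61):
        """With V = 1 up to order L the optimal-weight average coincides
        with the SH isotropic component at order L."""
        rng = np.random.default_rng(1)
        for L in (2, 6):
            w = knutsson_weights(dirs61, k_max=L, v_diag=lambda k: 1.0)
            for s in rng.standard_normal((50, 61)):
                est_w = weighted_average(s, w)
                est_sh, _ = sh_powder_average(dirs61, s, L)
                assert est_w == pytest.approx(est_sh, abs=1e-9)

    def test_weighted_sampling_function_is_isotropic(self, dirs61):
        """At the solution of an exactly solvable system, the weighted
        sampling function has vanishing SH coefficients above degree 0
        and sum(w) = 1."""
        w = knutsson_weights(dirs61, k_max=6, v_diag=lambda k: 1.0)
        Y, idx = real_sh_basis(dirs61, 6)
        g = Y.T @ w.weights
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert g[0] == pytest.approx(1 / np.sqrt(4 * np.pi), abs=1e-8)
        assert np.abs(g[1:]).max() < 1e-8

    def test_near_uniform_on_repulsion_set(self, dirs61):
        """On a well-spread 61-point set the optimal weights stay within
        10% of uniform."""
        w = knutsson_weights(dirs61)  # default k_max = 18, V = (1+k^2/36)^-1
        assert w.k_max == 18
        rel_dev = np.abs(w.weights - 1 / 61) * 61
        assert rel_dev.max() < 0.10

    def test_weightset_validation(self):
        with pytest.raises(ValueError):
            WeightSet(np.array([np.nan, 1.0]))
        with pytest.raises(ValueError):
            WeightSet(np.zeros(3))


class TestAverageAllShells:
    @pytest.mark.parametrize("method,kwargs", [
        ("arithmetic", {}),
        ("sh", {"L": 6}),
        ("tensor", {}),
        ("knutsson", {}),
    ])
    def test_noise_free_accuracy_61(self, scheme61, signals61, gt_values,
                                    method, kwargs):
        pa = average_all_shells(scheme61, signals61[np.inf], method, **kwargs)
        np.testing.assert_allclose(pa.b_values, B_GRID)
        np.testing.assert_allclose(pa.s_bar, gt_values, atol=5e-3)

    def test_lebedev_noise_free_43(self, scheme43, signals43, gt_values):
        pa = average_all_shells(scheme43, signals43[1.0], "lebedev")
        np.testing.assert_allclose(pa.s_bar, gt_values, atol=1e-3)

    def test_nonshelled_scheme_rejected(self):
        sch = build_scheme("nonshelled_random", 80, b_max=12.0, seed=0)
        sig = simulate_signal(sch, TissueModel.single(9.0))
        with pytest.raises(ValueError, match="not shelled"):
            average_all_shells(sch, sig, "arithmetic")

    def test_lebedev_requires_lebedev_nodes(self, scheme61, signals61):
        with pytest.raises(ValueError):
            average_all_shells(scheme61, signals61[1.0], "lebedev")

    def test_rotation_equivariance(self, scheme61):
        from scipy.spatial.transform import Rotation

        from powderavg.sampling import GradientScheme
        from powderavg.simulate import DEFAULT_MU

        R = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        sch_rot = GradientScheme(scheme61.directions @ R.T, scheme61.b_values,
                                 scheme61.shell_ids)
        sig = simulate_signal(scheme61, TissueModel.single(9.0))
        sig_rot = simulate_signal(sch_rot, TissueModel.single(9.0, mu=R @ DEFAULT_MU))
        for method in ("arithmetic", "sh", "tensor", "knutsson"):
            a = average_all_shells(scheme61, sig, method)
            b = average_all_shells(sch_rot, sig_rot, method)
            np.testing.assert_allclose(a.s_bar, b.s_bar, atol=1e-8)
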