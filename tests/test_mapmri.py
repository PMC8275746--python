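"""MAP-MRI basis, scale estimation, fit modes and isotropic averages."""

import numpy as np
import pytest

from powderavg.mapmri import (
    MAPBasisSpec,
    MapMriModel,
    b_to_q,
    default_constraint_grid,
    estimate_u0,
    fit_map,
    isotropic_radial_norm,
    laplacian_matrix,
    map_basis_matrix,
    map_powder_average,
    propagator_basis_matrix,
)
from powderavg.sampling import GradientScheme, build_scheme
from powderavg.simulate import TissueModel, add_noise, simulate_signal

from conftest import B_GRID, S_GT_PRINTED


@pytest.fixture(scope="module")
def iso_setup(scheme61=None):
    """Isotropic Gaussian signal with the basis scale matched to MD."""
    sch = build_scheme("shelled_uniform", 61, seed=0)
    D = 0.4267
    u0 = np.sqrt(2 * D * sch.tau)
    sig = np.exp(-sch.b_values * D)
    return sch, D, u0, sig


class TestBasis:
    @pytest.mark.parametrize("n_max,expected", [(0, 1), (2, 7), (6, 50), (8, 95)])
    def test_coefficient_count(self, n_max, expected):
        spec = MAPBasisSpec(n_max, 3.0)
        assert spec.n_coeff == expected
        assert len(spec.index_list) == expected
        # 2j + l = N + 2 with even l >= 0, j >= 1 for every index
        for (j, l, m) in spec.index_list:
            assert j >= 1 and l >= 0 and l % 2 == 0 and abs(m) <= l
            assert (2 * j + l - 2) % 2 == 0 and 2 * j + l - 2 <= n_max

    def test_origin_values(self):
        spec = MAPBasisSpec(8, 4.0)
        sch = GradientScheme(np.array([[0.0, 0.0, 1.0]]), np.array([0.0]))
        A = map_basis_matrix(sch, spec)
        idx = spec.index_list
        assert A[0, idx.index((1, 0, 0))] == pytest.approx(1.0, abs=1e-14)
        for a, (j, l, m) in enumerate(idx):
            if l > 0:
                assert A[0, a] == 0.0

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            MAPBasisSpec(5, 3.0)

    def test_isotropic_subspace_orthogonality(self):
        """Gram matrix of the Xi_j00 radial functions under 4 pi q^2 dq is
        diagonal with the analytic norms Gamma(j+1/2)/((j-1)! 4 pi^2 u0^3)."""
        from powderavg.mapmri import _radial_xi, _SQRT4PI

        u0 = 5.0
        n_j = 5
        x, wx = np.polynomial.legendre.leggauss(400)
        q_max = 2.0 / u0
        q = 0.5 * q_max * (x + 1)
        w = 0.5 * q_max * wx
        s = 2 * np.pi**2 * u0**2 * q**2
        f = np.array([_radial_xi(j, 0, s) / _SQRT4PI for j in range(1, n_j + 1)])
        G = (f * (w * 4 * np.pi * q**2)) @ f.T
        norms = np.array([isotropic_radial_norm(j, u0) for j in range(1, n_j + 1)])
        G_normalized = G / np.sqrt(np.outer(norms, norms))
        np.testing.assert_allclose(G_normalized, np.eye(n_j), atol=1e-6)

    def test_propagator_dual_pair(self):
        """The 3D Fourier transform of the q-space basis equals the
        analytic displacement-space dual, checked by numerical Hankel
        transform on isotropic and anisotropic members."""
        from scipy.special import spherical_jn

        from powderavg._sph import real_sph_harm
        from powderavg.mapmri import _radial_xi

        u0 = 5.0
        spec = MAPBasisSpec(8, u0)
        x, wx = np.polynomial.legendre.leggauss(800)
        q_max = 3.0 / u0
        q = 0.5 * q_max * (x + 1)
        w = 0.5 * q_max * wx
        r = 0.8 * u0
        y = {l: real_sph_harm(l, 0, np.array([0.0]), np.array([0.0]))[0]
             for l in (0, 2, 4)}
        s = 2 * np.pi**2 * u0**2 * q**2
        for (j, l) in [(1, 0), (3, 0), (1, 2), (2, 2), (2, 4)]:
            xi = _radial_xi(j, l, s)
            hankel = 4 * np.pi * (-1) ** (l // 2) * np.sum(
                w * xi * spherical_jn(l, 2 * np.pi * q * r) * q**2)
            numeric = hankel * y[l]
            col = spec.index_list.index((j, l, 0))
            analytic = propagator_basis_matrix(np.array([r]),
                                               np.array([[0.0, 0.0, 1.0]]),
                                               spec)[0, col]
            assert numeric == pytest.approx(analytic, abs=1e-6 * abs(analytic) + 1e-12)


class TestEstimateU0:
    def test_closed_form_isotropic(self, iso_setup):
        sch, D, u0, sig = iso_setup
        assert estimate_u0(sch, sig) == pytest.approx(np.sqrt(2 * D * sch.tau),
                                                      abs=1e-9)
        assert np.sqrt(2 * 0.4267 * 39.567) == pytest.approx(5.811, abs=1e-3)

    def test_sqrt2_scaling(self, iso_setup):
        sch, D, _, _ = iso_setup
        s1 = estimate_u0(sch, np.exp(-sch.b_values * D))
        s2 = estimate_u0(sch, np.exp(-sch.b_values * 2 * D))
        assert s2 / s1 == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_md_recovery_from_dirac_model(self, scheme61, signals61):
        """Noise-free kappa=inf data give MD = (D_par + 2 D_perp)/3."""
        u0 = estimate_u0(scheme61, signals61[np.inf])
        md = u0**2 / (2 * scheme61.tau)
        assert md == pytest.approx((1.0 + 2 * 0.14) / 3.0, abs=1e-6)

    def test_nonpositive_md_error(self, scheme61):
        rising = np.exp(+0.5 * scheme61.b_values)
        with pytest.raises(ValueError, match="diffusivity"):
            estimate_u0(scheme61, rising)


class TestFitModes:
    def test_ls_concentrates_on_c100(self, iso_setup):
        sch, D, u0, sig = iso_setup
        fit = MapMriModel(sig, sch, n_max=8, u0=u0).fit("ls")
        assert fit.coefficients[0] == pytest.approx(1.0, abs=1e-8)
        assert np.abs(fit.coefficients[1:]).max() < 1e-8
        # single-term closed form at arbitrary (off-shell) b
        b = np.array([0.0, 0.37, 2.0, 5.3, 11.8])
        np.testing.assert_allclose(fit.powder_average(b), np.exp(-b * D),
                                   atol=1e-8)

    def test_laplacian_zero_equals_ls(self, scheme61, signals61):
        m = MapMriModel(signals61[1.0], scheme61, n_max=8)
        np.testing.assert_allclose(m.fit("laplacian", lambda_reg=0.0).coefficients,
                                   m.fit("ls").coefficients, atol=1e-10)

    def test_residual_monotone_in_lambda(self, scheme61, signals61):
        m = MapMriModel(signals61[1.0], scheme61, n_max=8)
        res = [m.fit("laplacian", lambda_reg=lam).residual_norm
               for lam in np.logspace(-4, 2, 7)]
        assert np.all(np.diff(res) >= -1e-12)

    def test_constrained_feasibility_on_rician_data(self, scheme43, signals43):
        noisy = add_noise(signals43[9.0], 0.0707, "rician", seed=42)
        model = MapMriModel(noisy, scheme43, n_max=8)
        fit = model.fit("constrained")
        r, d = default_constraint_grid(model.spec)
        K = propagator_basis_matrix(r, d, model.spec)
        assert (K @ fit.coefficients).min() >= -1e-9

    def test_invalid_modes(self, scheme61, signals61):
        m = MapMriModel(signals61[1.0], scheme61, n_max=8)
        with pytest.raises(ValueError):
            m.fit("ridge")
        with pytest.raises(ValueError):
            m.fit("laplacian", lambda_reg=-1.0)

    def test_ls_requires_enough_samples(self, signals43, scheme43):
        sub = GradientScheme(scheme43.directions[:40], scheme43.b_values[:40])
        from powderavg.simulate import SignalArray

        with pytest.raises(ValueError, match="samples"):
            MapMriModel(signals43[1.0].values[:40], sub, n_max=8,
                        u0=5.0).fit("ls")

    def test_rotation_invariance_of_isotropic_coefficients(self, scheme61):
        from scipy.spatial.transform import Rotation

        from powderavg.simulate import DEFAULT_MU

        R = Rotation.from_rotvec([0.4, 0.9, -0.2]).as_matrix()
        sch_rot = GradientScheme(scheme61.directions @ R.T, scheme61.b_values,
                                 scheme61.shell_ids)
        sig = simulate_signal(scheme61, TissueModel.single(9.0))
        sig_rot = simulate_signal(sch_rot, TissueModel.single(9.0, mu=R @ DEFAULT_MU))
        u0 = estimate_u0(scheme61, sig)
        f1 = MapMriModel(sig, scheme61, n_max=8, u0=u0).fit("ls")
        f2 = MapMriModel(sig_rot, sch_rot, n_max=8, u0=u0).fit("ls")
        iso1 = [c for c, (j, l, m) in zip(f1.coefficients, f1.basis.index_list) if l == 0]
        iso2 = [c for c, (j, l, m) in zip(f2.coefficients, f2.basis.index_list) if l == 0]
        np.testing.assert_allclose(iso1, iso2, atol=1e-8)


class TestPowderAverage:
    def test_noise_free_matches_closed_form(self, scheme61, signals61, gt_values):
        fit = MapMriModel(signals61[1.0], scheme61, n_max=8).fit("ls")
        np.testing.assert_allclose(fit.powder_average(B_GRID), gt_values,
                                   atol=1e-2)
        assert fit.powder_average(0.0)[0] == pytest.approx(1.0, abs=1e-2)

    def test_cross_method_consistency_with_sh(self, scheme61, signals61):
        """On shelled noise-free data the MAP isotropic part and the
        per-shell SH (L=6) estimate agree within 2e-2 at every b."""
        from powderavg.shell import average_all_shells

        for kappa in (1.0, np.inf):
            fit = MapMriModel(signals61[kappa], scheme61, n_max=8).fit("ls")
            pa_map = fit.powder_average(B_GRID)
            pa_sh = average_all_shells(scheme61, signals61[kappa], "sh", L=6)
            np.testing.assert_allclose(pa_map, pa_sh.s_bar, atol=2e-2)

    def test_negative_b_rejected(self, scheme61, signals61):
        fit = MapMriModel(signals61[1.0], scheme61, n_max=8).fit("ls")
        with pytest.raises(ValueError):
            fit.powder_average(-1.0)

    def test_functional_wrappers(self, scheme61, signals61):
        fit = fit_map(scheme61, signals61[1.0], mode="ls", n_max=6)
        pa = map_powder_average(fit, B_GRID)
        np.testing.assert_allclose(pa, fit.powder_average(B_GRID))
        assert "MAP-MRI fit" in fit.summary()

    def test_q_mapping(self, scheme61):
        tau = scheme61.tau
        q = b_to_q(1.5, tau)
        assert (2 * np.pi * q) ** 2 * tau == pytest.approx(1.5, rel=1e-12)
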