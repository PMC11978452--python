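import math

import numpy as np
import pytest

from spatburst import (
    Domain1D,
    ModelParams,
    fano_nonspatial,
    fano_spatial,
    integrated_intensity_variance,
    mean_count,
    mean_intensity,
    mean_intensity_robin,
    scale_factor_S,
    scale_factor_Skappa,
    solve_mean_bvp_1d,
    var_count,
)


def _params(d: dict) -> tuple[ModelParams, Domain1D]:
    dom = Domain1D(R=d["R"], boundary="absorbing" if math.isinf(d["kappa"]) else "robin")
    p = ModelParams(
        lam=d["lam"], alpha=d["alpha"], beta=d["beta"], gamma=d["gamma"],
        D=d["D"], z=d["z"], kappa=d["kappa"],
    )
    return p, dom


class TestMeanIntensity:
    def test_vanishes_at_absorbing_boundary(self, base_params, absorbing_domain):
        assert mean_intensity(base_params, absorbing_domain, 1.0) == pytest.approx(0.0, abs=1e-14)
        assert mean_intensity(base_params, absorbing_domain, -1.0) == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_for_central_gene(self, absorbing_domain, base_params):
        p = base_params.with_(z=0.0)
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            mean_intensity(p, absorbing_domain, x), mean_intensity(p, absorbing_domain, -x)
        )

    def test_nonnegative_and_integrates_to_mean_count(self, base_params, absorbing_domain):
        x = np.linspace(-1, 1, 20001)
        u = mean_intensity(base_params, absorbing_domain, x)
        assert np.all(u >= -1e-14)
        assert np.trapezoid(u, x) == pytest.approx(
            mean_count(base_params, absorbing_domain), rel=1e-8
        )

    def test_matches_finite_difference_solve(self, base_params, absorbing_domain):
        p = base_params.with_(z=0.3)
        x, u_fd = solve_mean_bvp_1d(p, absorbing_domain, n=10001)
        u = mean_intensity(p, absorbing_domain, 0.1)
        u_ref = float(np.interp(0.1, x, u_fd))
        assert u == pytest.approx(u_ref, rel=1e-4)  # 4 significant digits

    def test_stable_in_degradation_dominated_regime(self, absorbing_domain, base_params):
        p = base_params.with_(gamma=1e6, z=0.0)  # sqrt(gamma/D)*R = 1000
        u = mean_intensity(p, absorbing_domain, np.linspace(-1, 1, 101))
        assert np.all(np.isfinite(u)) and np.all(u >= 0)


class TestRobinMeanIntensity:
    def test_reflecting_limit_mass_balance(self, base_params, robin_domain):
        p = base_params.with_(kappa=0.0)
        x = np.linspace(-1, 1, 40001)
        total = np.trapezoid(mean_intensity_robin(p, robin_domain, x), x)
        assert total == pytest.approx(p.lam * p.rho / p.gamma, rel=1e-7)

    def test_large_kappa_approaches_absorbing(self, base_params, robin_domain, absorbing_domain):
        p = base_params.with_(kappa=1e6)
        assert mean_intensity_robin(p, robin_domain, 0.0) == pytest.approx(
            mean_intensity(base_params, absorbing_domain, 0.0), rel=1e-4
        )

    @pytest.mark.parametrize("kappa", [0.0, 0.7, 5.0, 50.0])
    def test_flux_jump_at_source(self, base_params, robin_domain, kappa):
        p = base_params.with_(kappa=kappa)
        z, eps = float(p.z), 1e-7
        du_right = (
            mean_intensity_robin(p, robin_domain, z + 2 * eps)
            - mean_intensity_robin(p, robin_domain, z + eps)
        ) / eps
        du_left = (
            mean_intensity_robin(p, robin_domain, z - eps)
            - mean_intensity_robin(p, robin_domain, z - 2 * eps)
        ) / eps
        jump = -p.D * (du_right - du_left)
        assert jump == pytest.approx(p.lam * p.rho, rel=1e-4)

    def test_matches_finite_difference_hypercube(self, param_hypercube):
        for d in param_hypercube:
            p, dom = _params(d)
            x, u_fd = solve_mean_bvp_1d(p, dom, n=20001)
            sel = slice(500, -500, 1000)
            u = mean_intensity_robin(p, dom, x[sel])
            np.testing.assert_allclose(u, u_fd[sel], rtol=2e-4)


class TestScaleFactors:
    def test_S_vanishes_at_boundary_gene(self, base_params, absorbing_domain):
        assert scale_factor_S(base_params.with_(z=0.999999), absorbing_domain) == pytest.approx(
            0.0, abs=1e-4
        )

    def test_S_degradation_dominated_limit(self, base_params, absorbing_domain):
        assert scale_factor_S(base_params.with_(gamma=1e7), absorbing_domain) == pytest.approx(1.0)

    def test_S_printed_value_central_gene(self, base_params, absorbing_domain):
        # direct substitution: S = 1 - sech(1) for gamma = D = R = 1, z = 0
        assert scale_factor_S(base_params.with_(z=0.0), absorbing_domain) == pytest.approx(
            1.0 - 1.0 / math.cosh(1.0)
        )

    def test_S_monotonicities(self, base_params, absorbing_domain):
        S = lambda **kw: scale_factor_S(base_params.with_(**kw), absorbing_domain)
        zs = np.linspace(0, 0.9, 8)
        assert np.all(np.diff([S(z=z) for z in zs]) < 0)
        Ds = np.linspace(0.2, 4, 8)
        assert np.all(np.diff([S(D=D) for D in Ds]) < 0)
        gs = np.linspace(0.2, 4, 8)
        assert np.all(np.diff([S(gamma=g) for g in gs]) > 0)

    def test_Skappa_limits(self, base_params, robin_domain, absorbing_domain):
        # no export at kappa=0: the non-spatial mean is recovered (S_0 = 1);
        # kappa -> inf recovers the absorbing scale factor
        assert scale_factor_Skappa(base_params.with_(kappa=0.0), robin_domain) == pytest.approx(1.0)
        assert scale_factor_Skappa(base_params.with_(kappa=1e9), robin_domain) == pytest.approx(
            scale_factor_S(base_params, absorbing_domain), rel=1e-6
        )

    def test_Skappa_monotone_in_kappa_and_bounded(self, base_params, robin_domain):
        kappas = np.concatenate([[0.0], np.logspace(-2, 3, 20)])
        vals = [scale_factor_Skappa(base_params.with_(kappa=k), robin_domain) for k in kappas]
        assert np.all(np.diff(vals) < 0)
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_Skappa_consistent_with_robin_intensity_quadrature(self, param_hypercube):
        for d in param_hypercube:
            p, dom = _params(d)
            x = np.linspace(-dom.R, dom.R, 30001)
            total = np.trapezoid(mean_intensity_robin(p, dom, x), x)
            S_quad = p.gamma * total / (p.lam * p.rho)
            assert scale_factor_Skappa(p, dom) == pytest.approx(S_quad, rel=1e-6)


class TestMeanCount:
    def test_reflecting_gives_nonspatial_mean(self, base_params):
        dom = Domain1D(R=1.0, boundary="reflecting")
        assert mean_count(base_params.with_(kappa=0.0), dom) == pytest.approx(5.0)

    def test_goes_to_zero_as_gene_approaches_boundary(self, base_params, absorbing_domain):
        assert mean_count(base_params.with_(z=0.99999), absorbing_domain) < 1e-3

    def test_lam_off_not_supported(self, absorbing_domain):
        p = ModelParams(lam=10, lam_off=1, alpha=1, beta=1, gamma=1, D=1, z=0.0)
        with pytest.raises(NotImplementedError):
            mean_count(p, absorbing_domain)


class TestVarianceSeries:
    def test_constitutive_limit_is_poissonian(self, base_params, absorbing_domain):
        res = integrated_intensity_variance(base_params.with_(beta=0.0), absorbing_domain)
        assert res.value == 0.0
        assert var_count(base_params.with_(beta=0.0), absorbing_domain) == pytest.approx(
            mean_count(base_params.with_(beta=0.0), absorbing_domain)
        )

    def test_positive_and_converged(self, base_params, absorbing_domain):
        res = integrated_intensity_variance(base_params, absorbing_domain, tol=1e-10)
        assert res.value > 0
        assert res.est_truncation_error <= 1e-10 * res.value

    def test_stable_under_tighter_truncation(self, base_params, absorbing_domain):
        loose = integrated_intensity_variance(base_params, absorbing_domain, tol=1e-8)
        tight = integrated_intensity_variance(base_params, absorbing_domain, tol=1e-12)
        assert loose.value == pytest.approx(tight.value, rel=1e-6)

    def test_variance_decreases_in_D_gamma_alpha_and_z(self, base_params, absorbing_domain):
        # the alpha sweep starts in the burst-dominated regime alpha >= 2*beta;
        # below that the rising mean (rho grows with alpha) can outweigh the
        # shrinking promoter noise
        ranges = {
            "D": np.linspace(0.4, 2.0, 5),
            "gamma": np.linspace(0.4, 2.0, 5),
            "alpha": np.linspace(2.0, 8.0, 5),
            "z": np.linspace(0.0, 0.9, 5),
        }
        for field, vals in ranges.items():
            v = [
                var_count(base_params.with_(**{field: x}), absorbing_domain) for x in vals
            ]
            assert np.all(np.diff(v) < 0), field

    def test_noise_excess_decreases_in_alpha(self, base_params, absorbing_domain):
        # the super-Poissonian excess psi-weighted series falls with alpha
        # whenever alpha >= beta
        vals = [
            integrated_intensity_variance(base_params.with_(alpha=a), absorbing_domain).value
            for a in np.linspace(1.0, 8.0, 6)
        ]
        assert np.all(np.diff(vals) < 0)


class TestFano:
    def test_no_export_recovers_nonspatial(self, base_params):
        assert fano_spatial(base_params, S=1.0) == pytest.approx(fano_nonspatial(base_params))

    def test_poisson_limits(self, base_params):
        p = base_params.with_(beta=0.0)
        assert fano_spatial(p, S=0.6) == pytest.approx(1.0)
        assert fano_nonspatial(p) == pytest.approx(1.0)
        assert fano_spatial(base_params, S=0.0) == pytest.approx(1.0)

    def test_spatial_never_exceeds_nonspatial(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = ModelParams(
                lam=rng.uniform(0.5, 50),
                alpha=rng.uniform(0.05, 10),
                beta=rng.uniform(0.05, 10),
                gamma=rng.uniform(0.05, 10),
                D=1.0,
            )
            S = rng.uniform(0.0, 1.0)
            assert fano_spatial(p, S=S) <= fano_nonspatial(p) + 1e-12
            assert fano_spatial(p, S=S) >= 1.0
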