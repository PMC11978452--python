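import math

import numpy as np
import pytest
from scipy import stats

from spatburst import (
    Domain1D,
    ModelParams,
    SimConfig,
    apply_boundary_1d,
    mean_count,
    mean_intensity,
    sample_counts,
    simulate_cell,
    simulate_population,
    simulate_telegraph,
)


class TestTelegraph:
    def test_ergodic_on_fraction(self):
        path = simulate_telegraph(2.0, 1.0, 3000.0, rng=0)
        rho = 2.0 / 3.0
        # CLT band for the time-averaged two-state chain
        assert path.on_fraction() == pytest.approx(rho, abs=0.03)

    def test_symmetric_rates_start_half(self):
        rng = np.random.default_rng(1)
        starts = [simulate_telegraph(1.0, 1.0, 0.1, rng).states[0] for _ in range(2000)]
        assert np.mean(starts) == pytest.approx(0.5, abs=0.04)

    def test_on_state_holding_time(self):
        path = simulate_telegraph(1.0, 4.0, 5000.0, rng=2)
        hold = path.holding_times(1)
        assert hold.mean() == pytest.approx(1.0 / 4.0, rel=0.1)

    def test_degenerate_constitutive(self):
        path = simulate_telegraph(1.0, 0.0, 10.0, rng=3)
        assert path.states.tolist() == [1]
        assert path.on_fraction() == 1.0


class TestBoundary1D:
    def test_reflecting_never_exports(self):
        rng = np.random.default_rng(0)
        dom = Domain1D(1.0, "reflecting")
        p = ModelParams(lam=1, alpha=1, beta=1, gamma=1, D=1, kappa=0.0)
        x_old = rng.uniform(-1, 1, 1000)
        x_new = x_old + 0.3 * rng.standard_normal(1000)
        x, exported = apply_boundary_1d(x_old, x_new, dom, p, 1e-3, rng)
        assert not exported.any()
        assert np.all(np.abs(x) <= 1.0)

    def test_infinite_kappa_acts_absorbing(self):
        rng = np.random.default_rng(0)
        dom = Domain1D(1.0, "robin")
        p = ModelParams(lam=1, alpha=1, beta=1, gamma=1, D=1, kappa=math.inf)
        x, exported = apply_boundary_1d(np.array([0.9]), np.array([1.1]), dom, p, 1e-3, rng)
        assert exported.all()

    def test_robin_probability_clamp(self):
        rng = np.random.default_rng(0)
        dom = Domain1D(1.0, "robin")
        p = ModelParams(lam=1, alpha=1, beta=1, gamma=1, D=1, kappa=100.0)
        with pytest.raises(Exception, match="smaller dt"):
            apply_boundary_1d(np.array([0.9]), np.array([1.1]), dom, p, 0.1, rng)


class TestSimulatedMoments:
    def test_constitutive_counts_are_poisson(self):
        # lam == lam_off: deterministic intensity, Fano factor -> 1
        p = ModelParams(lam=10, lam_off=10, alpha=1, beta=1, gamma=1, D=1, z=0.3)
        dom = Domain1D(1.0, "absorbing")
        c = sample_counts(p, dom, 3000, SimConfig(seed=10))
        fano = c.var(ddof=1) / c.mean()
        se = math.sqrt(2.0 / (len(c) - 1))
        assert abs(fano - 1.0) < 4 * se

    def test_mean_matches_prediction_across_z(self):
        dom = Domain1D(1.0, "absorbing")
        for i, z in enumerate([0.0, 0.5, 0.8]):
            p = ModelParams(lam=10, alpha=1, beta=1, gamma=1, D=1, z=z)
            c = sample_counts(p, dom, 2500, SimConfig(seed=20 + i))
            se = c.std(ddof=1) / math.sqrt(len(c))
            assert abs(c.mean() - mean_count(p, dom)) < 3 * se, z

    def test_spatial_histogram_matches_intensity(self):
        # pooled positions vs the normalized mean intensity, chi-square GOF
        p = ModelParams(lam=10, alpha=1, beta=1, gamma=1, D=1, z=0.5)
        dom = Domain1D(1.0, "absorbing")
        pats = simulate_cell(p, dom, SimConfig(seed=30, n_samples=60))
        x = np.concatenate([pat.positions for pat in pats])
        pop = simulate_population(p, lambda rng: (1.0, 0.5), 1200, SimConfig(seed=31))
        x = np.concatenate([x] + [pat.positions for pat in pop])
        assert len(x) > 1000
        edges = np.linspace(-1, 1, 11)
        obs, _ = np.histogram(x, edges)
        grid = np.linspace(-1, 1, 4001)
        u = mean_intensity(p, dom, grid)
        cdf = np.concatenate([[0], np.cumsum((u[1:] + u[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, grid, cdf))
        stat = ((obs - len(x) * probs) ** 2 / (len(x) * probs)).sum()
        # snapshots are weakly correlated, so test at a conservative level
        assert stat < stats.chi2.ppf(0.999, len(probs) - 1)

    def test_halving_dt_within_mc_error(self):
        p = ModelParams(lam=10, alpha=1, beta=1, gamma=1, D=1, z=0.5)
        dom = Domain1D(1.0, "absorbing")
        c1 = sample_counts(p, dom, 2500, SimConfig(dt=1e-3, seed=40))
        c2 = sample_counts(p, dom, 2500, SimConfig(dt=5e-4, seed=41))
        se = math.sqrt(c1.var(ddof=1) / len(c1) + c2.var(ddof=1) / len(c2))
        assert abs(c1.mean() - c2.mean()) < 3 * se

    def test_disjoint_subinterval_counts_uncorrelated_constitutive(self):
        # Poisson representation: with deterministic intensity, counts in
        # disjoint regions are independent
        p = ModelParams(lam=20, lam_off=20, alpha=1, beta=1, gamma=1, D=1, z=0.0)
        dom = Domain1D(1.0, "absorbing")
        pats = simulate_population(p, lambda rng: (1.0, 0.0), 1500, SimConfig(seed=50))
        left = np.array([np.sum(pat.positions < 0) for pat in pats])
        right = np.array([np.sum(pat.positions >= 0) for pat in pats])
        r = np.corrcoef(left, right)[0, 1]
        assert abs(r) < 3.0 / math.sqrt(len(pats))


class TestPopulation:
    def test_empty_population(self):
        p = ModelParams(lam=10, alpha=1, beta=1, gamma=1, D=1, z=0.0)
        assert simulate_population(p, lambda rng: (1.0, 0.0), 0, SimConfig(seed=0)) == []

    def test_deterministic_given_seed(self):
        p = ModelParams(lam=10, alpha=1, beta=2, gamma=1, D=1, kappa=5.0)
        sampler = lambda rng: (rng.uniform(0.8, 1.2), rng.uniform(-0.5, 0.5))
        a = simulate_population(p, sampler, 20, SimConfig(seed=123))
        b = simulate_population(p, sampler, 20, SimConfig(seed=123))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.positions, pb.positions)
            assert pa.domain.R == pb.domain.R and pa.z == pb.z

    def test_pooled_mean_matches_per_cell_prediction(self):
        from spatburst import scale_factor_Skappa

        p = ModelParams(lam=10, alpha=1, beta=1, gamma=1, D=1, kappa=5.0)
        sampler = lambda rng: (rng.uniform(0.8, 1.2), rng.uniform(-0.6, 0.6))
        pats = simulate_population(p, sampler, 2000, SimConfig(seed=60))
        n = np.array([pat.n for pat in pats], dtype=float)
        pred = np.array(
            [
                p.lam * p.rho / p.gamma
                * scale_factor_Skappa(p.with_(z=pat.z), R=pat.domain.R)
                for pat in pats
            ]
        )
        se = n.std(ddof=1) / math.sqrt(len(n))
        assert abs(n.mean() - pred.mean()) < 3 * se
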