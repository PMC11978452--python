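"""Approximate likelihood inference for heterogeneous cell populations.

The exact likelihood of the Cox point process requires integrating over
all realizations of the switching intensity and is intractable.  Following
the factorization that is exact for a deterministic-intensity Poisson
process, the likelihood of one cell (point pattern) is approximated by

    L(theta; x_1..x_n) ~= p_theta(n) * prod_i <u(x_i)> / integral <u>,

where p_theta(n) is the Poisson-beta count law with the per-cell scale
factor S_kappa(R_i, z_i) and the positional density is the normalized
steady-state mean intensity.  Each cell carries its own geometry (R_i,
z_i); kinetic parameters theta = [lam, gamma, alpha, beta, kappa] are
shared and the diffusivity D is assumed known (measurable by tracking).

Maximization is Nelder-Mead over log-parameters (all parameters are
positive rates with scales spanning orders of magnitude).  Identifiability
is diagnosed with profile likelihoods chi(theta_i) = log PL(theta_i) -
log L(theta_hat) compared against the simultaneous 95% confidence
threshold -chi2(0.95, 4)/2 — four degrees of freedom, the number of
nuisance parameters re-optimized in each profile (this is the simultaneous
convention, deliberately wider than the common 1-df pointwise one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .analytic import _mean_intensity_absorbing, _mean_intensity_robin, _S_absorbing, _S_robin
from .core import ModelParams, PointPattern, ValidationError

__all__ = [
    "PARAM_NAMES",
    "PackedData",
    "FitResult",
    "cell_loglik",
    "population_loglik",
    "fit_mle",
    "profile_likelihood",
    "confidence_threshold",
]

PARAM_NAMES = ("lam", "gamma", "alpha", "beta", "kappa")

#: positions closer to an absorbing boundary than this fraction of R are
#: clamped inward (simulated snapshots can land arbitrarily close to it)
BOUNDARY_FLOOR = 1e-9


@dataclass
class PackedData:
    """Population of 1D point patterns flattened into arrays."""

    n: np.ndarray          # (M,) counts per cell
    R: np.ndarray          # (M,) half-widths
    z: np.ndarray          # (M,) gene sites
    x: np.ndarray          # (total points,) positions
    cell_of_x: np.ndarray  # (total points,) owning cell index

    @classmethod
    def from_patterns(cls, patterns: list[PointPattern]) -> "PackedData":
        if len(patterns) == 0:
            raise ValidationError("population likelihood requires at least one cell")
        n = np.array([pat.n for pat in patterns], dtype=int)
        R = np.array([pat.domain.R for pat in patterns], dtype=float)
        z = np.array([float(pat.z) for pat in patterns], dtype=float)
        x = np.concatenate([np.asarray(pat.positions, dtype=float) for pat in patterns])
        cell = np.repeat(np.arange(len(patterns)), n)
        if np.any(np.abs(x) > R[cell]):
            bad = int(cell[np.argmax(np.abs(x) - R[cell])])
            raise ValidationError(f"cell {bad}: position outside its domain")
        # clamp points that sit numerically on an absorbing boundary
        lim = R[cell] * (1.0 - BOUNDARY_FLOOR)
        x = np.clip(x, -lim, lim)
        return cls(n, R, z, x, cell)

    @property
    def M(self) -> int:
        return len(self.n)


def _theta_array(theta) -> np.ndarray:
    if isinstance(theta, dict):
        return np.array([theta[k] for k in PARAM_NAMES], dtype=float)
    if isinstance(theta, ModelParams):
        return np.array([theta.lam, theta.gamma, theta.alpha, theta.beta, theta.kappa])
    return np.asarray(theta, dtype=float)


def _scale_factors(z, R, gamma, D, kappa):
    if math.isinf(kappa):
        return _S_absorbing(z, R, gamma, D)
    return _S_robin(z, R, gamma, D, kappa)


def _count_loglik(S, n, lam, gamma, alpha, beta, max_terms: int = 20000):
    """Vectorized log Poisson-beta pmf at per-cell counts n with per-cell S.

    Uses the all-positive Kummer series; beta = 0 degenerates to the
    Poisson law of the constitutive model (the approximation is then the
    exact Poisson point-process count term).
    """
    S = np.asarray(S, dtype=float)
    n = np.asarray(n, dtype=float)
    if beta == 0.0:
        mu = S * lam / gamma
        return n * np.log(mu) - mu - special.gammaln(n + 1.0)
    a_t = S * alpha / gamma
    b_t = S * beta / gamma
    l_t = S * lam / gamma
    c = a_t + b_t + n
    term = np.ones_like(c)
    tot = np.ones_like(c)
    log_scale = np.zeros_like(c)
    for k in range(max_terms):
        term = term * (b_t + k) * l_t / ((c + k) * (k + 1.0))
        tot += term
        if np.any(tot > 1e250):  # renormalize to dodge overflow
            big = tot > 1e250
            log_scale = np.where(big, log_scale + np.log(tot), log_scale)
            term = np.where(big, term / tot, term)
            tot = np.where(big, 1.0, tot)
        if np.all(term <= 1e-16 * tot):
            break
    else:
        raise ArithmeticError("hypergeometric series failed to converge")
    return (
        log_scale
        +
        n * np.log(l_t)
        - special.gammaln(n + 1.0)
        + special.gammaln(a_t + n)
        - special.gammaln(a_t)
        - special.gammaln(a_t + b_t + n)
        + special.gammaln(a_t + b_t)
        - l_t
        + np.log(tot)
    )


def population_loglik(
    data, theta, D_known: float, include_positions: bool = True
) -> float:
    """Approximate log-likelihood of a heterogeneous population.

    ``data`` is a list of :class:`~spatburst.core.PointPattern` or a
    prebuilt :class:`PackedData`; ``theta`` maps to
    (lam, gamma, alpha, beta, kappa).  ``include_positions=False`` keeps
    only the count terms (used to contrast spatial vs counts-only
    identifiability).
    """
    pk = data if isinstance(data, PackedData) else PackedData.from_patterns(data)
    lam, gamma, alpha, beta, kappa = _theta_array(theta)
    if min(lam, gamma, alpha, kappa) <= 0 or beta < 0:
        raise ValidationError("all rates must be positive (beta may be zero)")
    S = _scale_factors(pk.z, pk.R, gamma, D_known, kappa)
    ll = float(np.sum(_count_loglik(S, pk.n, lam, gamma, alpha, beta)))
    if include_positions and pk.x.size:
        zc, Rc = pk.z[pk.cell_of_x], pk.R[pk.cell_of_x]
        # normalized positional density: the lam*rho prefactor of <u> cancels
        if math.isinf(kappa):
            phi = _mean_intensity_absorbing(pk.x, zc, Rc, 1.0, gamma, D_known)
        else:
            phi = _mean_intensity_robin(pk.x, zc, Rc, 1.0, gamma, D_known, kappa)
        Sc = S[pk.cell_of_x]
        with np.errstate(divide="ignore"):
            ll += float(np.sum(np.log(phi) - np.log(Sc / gamma)))
    return ll


def cell_loglik(pattern: PointPattern, p: ModelParams, D_known: float | None = None) -> float:
    """Approximate log-likelihood of a single cell's point pattern.

    The cell's own geometry (its domain R and gene site z) is used; the
    kinetic parameters and kappa come from ``p``.  ``D_known`` defaults to
    ``p.D``.
    """
    D = p.D if D_known is None else D_known
    return population_loglik(
        [pattern], (p.lam, p.gamma, p.alpha, p.beta, p.kappa), D
    )


# ---------------------------------------------------------------------------
# maximum likelihood and profiles
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """MLE of theta = [lam, gamma, alpha, beta, kappa] plus diagnostics."""

    theta_hat: dict
    loglik: float
    converged: bool
    n_cells: int
    D_known: float
    fixed: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta_hat[k] for k in PARAM_NAMES])


def confidence_threshold(level: float = 0.95, df: int = 4) -> float:
    """Profile log-likelihood drop defining the simultaneous confidence
    region: -chi2(level, df)/2."""
    return -0.5 * float(stats.chi2.ppf(level, df))


def _free_names(fixed: dict) -> list[str]:
    return [k for k in PARAM_NAMES if k not in fixed]


def _neg_loglik_factory(pk: PackedData, D_known: float, fixed: dict, include_positions=True):
    free = _free_names(fixed)

    def neg(log_free: np.ndarray) -> float:
        theta = dict(fixed)
        theta.update({k: math.exp(v) for k, v in zip(free, log_free)})
        try:
            return -population_loglik(pk, theta, D_known, include_positions)
        except (ArithmeticError, FloatingPointError, ValidationError):
            return 1e12
    return neg, free


def fit_mle(
    data,
    theta0,
    D_known: float,
    fixed: dict | None = None,
    xatol: float = 1e-4,
    fatol: float = 1e-6,
    maxiter: int | None = None,
) -> FitResult:
    """Maximize the approximate population likelihood.

    Derivative-free simplex (Nelder-Mead) over log-transformed free
    parameters; ``fixed`` pins a subset by name (e.g. ``{"beta": 0.0}``
    for the constitutive sub-model).  Deterministic given data and
    ``theta0``.  Non-convergence is flagged on the result, with the best
    iterate returned.
    """
    pk = data if isinstance(data, PackedData) else PackedData.from_patterns(data)
    fixed = dict(fixed or {})
    t0 = _theta_array(theta0) if not isinstance(theta0, dict) else None
    theta0d = (
        dict(theta0)
        if isinstance(theta0, dict)
        else {k: v for k, v in zip(PARAM_NAMES, t0)}
    )
    neg, free = _neg_loglik_factory(pk, D_known, fixed)
    x0 = np.log([theta0d[k] for k in free])
    res = optimize.minimize(
        neg,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": xatol,
            "fatol": fatol,
            "maxiter": maxiter or 400 * len(free),
            "maxfev": (maxiter or 400 * len(free)) * 2,
        },
    )
    theta_hat = dict(fixed)
    theta_hat.update({k: math.exp(v) for k, v in zip(free, res.x)})
    return FitResult(
        theta_hat={k: float(theta_hat[k]) for k in PARAM_NAMES if k in theta_hat},
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_cells=pk.M,
        D_known=D_known,
        fixed=fixed,
    )


def profile_likelihood(
    data,
    fit: FitResult,
    param: str,
    grid: np.ndarray | None = None,
    span: float = 4.0,
    n_grid: int = 21,
    level: float = 0.95,
    xatol: float = 2e-3,
    fatol: float = 5e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile log-likelihood curve chi(theta_i) = log PL - log L(theta_hat).

    The parameter of interest is fixed at each grid value (by default 21
    log-spaced points spanning x/÷ ``span`` around its MLE) and the
    remaining parameters are re-optimized, warm-starting outward from the
    MLE in both directions.  The curve and the interval where chi exceeds
    the simultaneous threshold are stored on ``fit`` and returned.
    """
    if param not in PARAM_NAMES or param in fit.fixed:
        raise ValidationError(f"cannot profile parameter {param!r}")
    pk = data if isinstance(data, PackedData) else PackedData.from_patterns(data)
    hat = fit.theta_hat[param]
    if grid is None:
        grid = np.exp(np.linspace(math.log(hat / span), math.log(hat * span), n_grid))
    grid = np.asarray(grid, dtype=float)
    if not (grid.min() <= hat <= grid.max()):
        import warnings

        warnings.warn("profile grid does not bracket the MLE", stacklevel=2)

    others = {k: v for k, v in fit.theta_hat.items() if k != param}
    chi = np.empty_like(grid)
    centre = int(np.argmin(np.abs(np.log(grid) - math.log(hat))))
    for side in (range(centre, len(grid)), range(centre - 1, -1, -1)):
        warm = dict(others)
        for i in side:
            fixed_i = dict(fit.fixed)
            fixed_i[param] = grid[i]
            neg, free = _neg_loglik_factory(pk, fit.D_known, fixed_i)
            x0 = np.log([warm[k] for k in free])
            res = optimize.minimize(
                neg,
                x0,
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": 300 * len(free)},
            )
            chi[i] = -res.fun - fit.loglik
            warm = {k: math.exp(v) for k, v in zip(free, res.x)}
    fit.profiles[param] = {"values": grid, "chi": chi}
    fit.ci[param] = _chi_interval(grid, chi, confidence_threshold(level))
    return grid, chi


def _chi_interval(grid: np.ndarray, chi: np.ndarray, thr: float) -> tuple[float, float]:
    """Interval where the profile curve stays above the threshold,
    linearly interpolated at the crossings; open ends fall back to the
    grid limits."""
    above = chi >= thr
    if not above.any():
        return (math.nan, math.nan)
    idx = np.flatnonzero(above)
    lo, hi = grid[idx[0]], grid[idx[-1]]
    if idx[0] > 0:
        i = idx[0]
        f = (thr - chi[i - 1]) / (chi[i] - chi[i - 1])
        lo = grid[i - 1] * (grid[i] / grid[i - 1]) ** f
    if idx[-1] < len(grid) - 1:
        i = idx[-1]
        f = (thr - chi[i]) / (chi[i + 1] - chi[i])
        hi = grid[i] * (grid[i + 1] / grid[i]) ** f
    return (float(lo), float(hi))
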