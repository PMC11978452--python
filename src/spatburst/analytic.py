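"""Closed-form and series results for the 1D spatial telegraph model.

All formulas describe the steady state of the switching reaction–diffusion
intensity on the symmetric interval Omega = [-R, R]: molecules appear at
the gene site ``z`` at mean rate ``lam * rho`` (``rho = alpha/(alpha+beta)``
the stationary on-fraction), diffuse with diffusivity ``D``, are degraded
at rate ``gamma`` and leave through the boundary according to the export
parameter ``kappa``.

The central dimensionless quantity is the scale factor ``S`` (absorbing
boundary) or ``S_kappa`` (Robin boundary): the probability that a molecule
is degraded inside the domain rather than exported.  The mean molecule
count is ``lam * rho * S / gamma``; ``S = 1`` recovers the non-spatial
telegraph model, while any factor that increases boundary flux (faster
diffusion, smaller domain, gene site near the boundary, faster export)
lowers ``S`` and with it the mean and the Fano factor.

Hyperbolic expressions are evaluated through exponentials with
non-positive arguments only, so they remain finite for arbitrarily large
``sqrt(gamma/D) * R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    Domain1D,
    ModelParams,
    ValidationError,
    require_telegraph_off_zero,
    validate_params,
)

__all__ = [
    "mean_intensity",
    "mean_intensity_robin",
    "scale_factor_S",
    "scale_factor_Skappa",
    "mean_count",
    "integrated_intensity_variance",
    "var_count",
    "fano_spatial",
    "fano_nonspatial",
    "VarianceSeriesResult",
]


# ---------------------------------------------------------------------------
# mean intensity
# ---------------------------------------------------------------------------

def _mean_intensity_absorbing(x, z, R, lam_rho, gamma, D):
    """<u(x)> for absorbing boundaries, elementwise in all arguments.

    Stable form of
        lam*rho/(2*sqrt(gamma*D)) * csch(2Rq) *
            [cosh(q(2R - |x-z|)) - cosh(q(x+z))],   q = sqrt(gamma/D):
    every exponential has a non-positive argument.
    """
    x, z, R = np.broadcast_arrays(*map(np.asarray, (x, z, R)))
    q = np.sqrt(gamma / D)
    a = 2.0 * q * R
    b = q * (2.0 * R - np.abs(x - z))
    c = q * np.abs(x + z)
    num = np.exp(b - a) + np.exp(-b - a) - np.exp(c - a) - np.exp(-c - a)
    den = 1.0 - np.exp(-2.0 * a)
    return lam_rho / (2.0 * np.sqrt(gamma * D)) * num / den


def _mean_intensity_robin(x, z, R, lam_rho, gamma, D, kappa):
    """<u(x)> for Robin boundaries D du/dn = -kappa u, elementwise.

    Piecewise cosh/sinh solution of the two-point boundary-value problem
    with a flux jump lam*rho at z, written with exponentials of
    non-positive argument.  kappa = 0 is pure reflection.
    """
    x, z, R = np.broadcast_arrays(*map(np.asarray, (x, z, R)))
    q = np.sqrt(gamma / D)
    h = kappa / math.sqrt(gamma * D)
    r = (1.0 - h) / (1.0 + h)
    a = 2.0 * q * R
    # span from the boundary on the far side of the source, and from the
    # boundary on the observer's side
    A = np.where(x <= z, q * (R - z), q * (R + z))
    B = np.where(x <= z, q * (x + R), q * (R - x))
    num = (
        np.exp(A + B - a)
        + r * (np.exp(A - B - a) + np.exp(B - A - a))
        + r * r * np.exp(-A - B - a)
    )
    den = 1.0 - r * r * np.exp(-2.0 * a)
    return lam_rho / (2.0 * np.sqrt(gamma * D)) * num / den


def mean_intensity(p: ModelParams, dom: Domain1D, x) -> np.ndarray | float:
    """Steady-state mean intensity <u(x)> with absorbing boundaries.

    Requires ``lam_off = 0``.  Vanishes at x = +-R and is non-negative on
    the interior; positions outside [-R, R] raise.
    """
    p = validate_params(p, dom)
    require_telegraph_off_zero(p, "mean_intensity")
    xa = np.asarray(x, dtype=float)
    if np.any(np.abs(xa) > dom.R * (1 + 1e-12)):
        raise ValidationError("position x outside domain [-R, R]")
    out = _mean_intensity_absorbing(xa, float(p.z), dom.R, p.lam * p.rho, p.gamma, p.D)
    return float(out) if np.isscalar(x) else out


def mean_intensity_robin(p: ModelParams, dom: Domain1D, x) -> np.ndarray | float:
    """Steady-state mean intensity <u(x)> with Robin export boundaries.

    Solves D u'' - gamma u + lam*rho*delta(x-z) = 0 with
    -D u'(+-R) * n = kappa u(+-R) in closed form.  kappa = 0 reduces to
    pure reflection (integral lam*rho/gamma), kappa -> inf to
    :func:`mean_intensity`.
    """
    require_telegraph_off_zero(p, "mean_intensity_robin")
    if p.absorbing:
        return mean_intensity(p, dom, x)
    xa = np.asarray(x, dtype=float)
    if np.any(np.abs(xa) > dom.R * (1 + 1e-12)):
        raise ValidationError("position x outside domain [-R, R]")
    out = _mean_intensity_robin(
        xa, float(p.z), dom.R, p.lam * p.rho, p.gamma, p.D, p.kappa
    )
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# scale factors
# ---------------------------------------------------------------------------

def _S_absorbing(z, R, gamma, D):
    """S = 1 - cosh(z q) sech(R q), elementwise, overflow-safe."""
    z = np.abs(np.asarray(z, dtype=float))
    R = np.asarray(R, dtype=float)
    q = np.sqrt(gamma / D)
    return 1.0 - (np.exp((z - R) * q) + np.exp((-z - R) * q)) / (1.0 + np.exp(-2.0 * R * q))


def _S_robin(z, R, gamma, D, kappa):
    """S_kappa for finite kappa >= 0, elementwise, overflow-safe."""
    z = np.asarray(z, dtype=float)
    R = np.asarray(R, dtype=float)
    q = np.sqrt(gamma / D)
    h = kappa / math.sqrt(gamma * D)
    r = (1.0 - h) / (1.0 + h)
    A = q * (R - z)
    B = q * (R + z)
    a = A + B
    num = (h / (1.0 + h)) * (np.exp(A - a) + np.exp(B - a)) + (
        h * (1.0 - h) / (1.0 + h) ** 2
    ) * (np.exp(-A - a) + np.exp(-B - a))
    den = 1.0 - r * r * np.exp(-2.0 * a)
    return 1.0 - num / den


def scale_factor_S(p: ModelParams, dom: Domain1D) -> float:
    """Scale factor S = 1 - cosh(z sqrt(gamma/D)) sech(R sqrt(gamma/D)).

    S in [0, 1] is the probability that a molecule is degraded before
    reaching the absorbing boundary; the mean count is lam*rho*S/gamma.
    S -> 0 as the gene site approaches the boundary and S -> 1 in the
    degradation-dominated regime gamma/D -> inf.
    """
    return float(_S_absorbing(p.z, dom.R, p.gamma, p.D))


def scale_factor_Skappa(p: ModelParams, dom: Domain1D | None = None, R: float | None = None) -> float:
    """Generalized scale factor S_kappa for a Robin (export rate kappa) boundary.

    Monotone decreasing in kappa, from S_0 = 1 (pure reflection: every
    molecule is degraded in the domain, the non-spatial mean is recovered)
    to S_inf = S, the fully absorbing limit of :func:`scale_factor_S`.
    """
    if R is None:
        R = dom.R
    if p.absorbing:
        return float(_S_absorbing(p.z, R, p.gamma, p.D))
    return float(_S_robin(p.z, R, p.gamma, p.D, p.kappa))


def _scale_factor(p: ModelParams, dom: Domain1D) -> float:
    if dom.boundary == "absorbing" or (dom.boundary == "robin" and p.absorbing):
        return scale_factor_S(p, dom)
    if dom.boundary == "reflecting" or p.kappa == 0:
        return 1.0
    return scale_factor_Skappa(p, dom)


def mean_count(p: ModelParams, dom: Domain1D) -> float:
    """Mean molecule count <n> = lam * rho * S / gamma.

    The appropriate scale factor is chosen from the boundary type:
    S (absorbing), S_kappa (Robin) or 1 (reflecting).
    """
    require_telegraph_off_zero(p, "mean_count")
    p = validate_params(p, dom)
    return p.lam * p.rho / p.gamma * _scale_factor(p, dom)


# ---------------------------------------------------------------------------
# variance of the counts (absorbing boundary, double eigenmode series)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceSeriesResult:
    """Integrated intensity variance evaluated by adaptive shell truncation."""

    value: float
    terms_used: tuple[int, int]
    est_truncation_error: float


def integrated_intensity_variance(
    p: ModelParams, dom: Domain1D, tol: float = 1e-10
) -> VarianceSeriesResult:
    """Var of the integrated intensity, int_Omega int_Omega Cov(u(x), u(y)) dx dy.

    This is the super-Poissonian part of the count variance:
    var(n) = <n> + (this series).  Evaluated as a double sum over the odd
    sine eigenmodes of the absorbing interval; the (k, l) term couples the
    mode decay rates r_m = gamma + pi^2 D (2m-1)^2 / (4 R^2) with the
    promoter relaxation rate omega = alpha + beta:

        psi * (r_k + r_l + 2 omega) / ((r_k + omega)(r_l + omega)(r_k + r_l))
            * 16 sin(pi k (R+z)/(2R)) sin(pi l (R+z)/(2R)) / (pi^2 k l)

    with psi = lam^2 alpha beta / (alpha + beta)^2 the variance of the
    dichotomous production rate.  The truncation order is doubled until the
    relative change falls below ``tol``.
    """
    p = validate_params(p, dom)
    require_telegraph_off_zero(p, "integrated_intensity_variance")
    if dom.boundary != "absorbing":
        raise ValidationError("variance series requires an absorbing boundary")
    omega = p.omega
    psi = p.lam**2 * p.alpha * p.beta / omega**2
    if psi == 0.0:  # constitutive limit: deterministic intensity
        return VarianceSeriesResult(0.0, (0, 0), 0.0)

    R, z = dom.R, float(p.z)
    prev = None
    K, K_cap = 16, 8192
    while True:
        m = np.arange(1, K + 1)
        k = 2 * m - 1
        r = p.gamma + np.pi**2 * p.D * k**2 / (4.0 * R**2)
        w = 4.0 * np.sin(np.pi * k * (R + z) / (2.0 * R)) / (np.pi * k)
        ro = r[:, None] + r[None, :]
        M = (ro + 2.0 * omega) / ((r[:, None] + omega) * (r[None, :] + omega) * ro)
        total = psi * float(np.einsum("i,j,ij->", w, w, M))
        if prev is not None:
            err = abs(total - prev)
            # requested tolerances below the rounding noise of the double
            # sum cannot be resolved in double precision
            if err <= max(tol, 5e-12) * max(abs(total), 1e-300):
                if total < -1e-12 * max(1.0, abs(total)):
                    raise ArithmeticError(
                        f"variance series summed to a negative value {total}"
                    )
                return VarianceSeriesResult(max(total, 0.0), (K, K), err)
        prev = total
        if K >= K_cap:
            raise ArithmeticError(
                f"variance series did not converge at K={K}; partial sum {total}"
            )
        K *= 2


def var_count(p: ModelParams, dom: Domain1D, tol: float = 1e-10) -> float:
    """Count variance var(n) = <n> + integrated intensity variance."""
    return mean_count(p, dom) + integrated_intensity_variance(p, dom, tol).value


# ---------------------------------------------------------------------------
# Fano factors
# ---------------------------------------------------------------------------

def fano_spatial(p: ModelParams, dom: Domain1D | None = None, S: float | None = None) -> float:
    """Fano factor of the spatial model, 1 + lam*beta*S / (omega*(gamma + S*omega)).

    ``S`` may be supplied directly (e.g. from the 2D solver); otherwise it
    is computed from the 1D domain's boundary type.  Always lies between 1
    and :func:`fano_nonspatial`.
    """
    require_telegraph_off_zero(p, "fano_spatial")
    if S is None:
        if dom is None:
            raise ValidationError("either dom or S must be given")
        S = _scale_factor(validate_params(p, dom), dom)
    w = p.omega
    return 1.0 + p.lam * p.beta * S / (w * (p.gamma + S * w))


def fano_nonspatial(p: ModelParams) -> float:
    """Fano factor of the non-spatial telegraph model,
    1 + lam*beta / ((alpha+beta)*(gamma + alpha + beta))."""
    require_telegraph_off_zero(p, "fano_nonspatial")
    w = p.omega
    return 1.0 + p.lam * p.beta / (w * (p.gamma + w))
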