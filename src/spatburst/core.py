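"""Core types for the spatial telegraph model of nuclear transcription.

The model describes mRNA molecules transcribed at a fixed gene site ``z``
inside a nuclear domain, at a rate that switches between an "on" value
``lam`` and an "off" value ``lam_off`` (a two-state / telegraph promoter
with off->on rate ``alpha`` and on->off rate ``beta``).  Molecules diffuse
with diffusivity ``D`` until they are degraded (rate ``gamma``) or exported
at the nuclear boundary (export parameter ``kappa``; ``kappa = 0`` is a
reflecting boundary, ``kappa = inf`` a perfectly absorbing one).

Units are unconstrained but must be mutually consistent; throughout the
documentation lengths are in micrometres and times in seconds, the scales
typical of nuclear mRNA imaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "Domain1D",
    "Domain2D",
    "PointPattern",
    "CountDistribution",
    "ValidationError",
    "validate_params",
    "effective_production",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

#: boundary condition labels for 1D domains
BOUNDARY_KINDS = ("absorbing", "robin", "reflecting")


class ValidationError(ValueError):
    """Raised when a parameter set or domain violates a model precondition."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and transport parameters of the spatial telegraph model.

    Parameters
    ----------
    lam : float
        Transcription rate in the "on" promoter state (molecules / time).
    alpha : float
        Promoter switching rate off -> on (1 / time).
    beta : float
        Promoter switching rate on -> off (1 / time).
    gamma : float
        Degradation rate of individual molecules (1 / time).
    D : float
        Molecular diffusivity (length^2 / time).
    kappa : float
        Boundary export rate parameter (length / time).  ``0`` means a
        purely reflecting boundary, ``math.inf`` a perfectly absorbing one;
        formulas dispatch on ``isinf`` and never evaluate the finite-kappa
        expressions at large kappa.
    z : float or tuple of float
        Gene (transcription) site: a scalar in 1D, an (x, y) pair in 2D.
    lam_off : float, optional
        Transcription rate in the "off" state (default 0, the standard
        telegraph model).
    """

    lam: float
    alpha: float
    beta: float
    gamma: float
    D: float
    kappa: float = math.inf
    z: float | tuple[float, float] = 0.0
    lam_off: float = 0.0

    @property
    def rho(self) -> float:
        """Stationary fraction of time the promoter is on, alpha/(alpha+beta)."""
        return self.alpha / (self.alpha + self.beta)

    @property
    def omega(self) -> float:
        """Total switching rate alpha + beta (inverse promoter correlation time)."""
        return self.alpha + self.beta

    @property
    def lam_p(self) -> float:
        """Lumped mean production rate (alpha*lam + beta*lam_off)/(alpha+beta)."""
        return effective_production(self)

    @property
    def absorbing(self) -> bool:
        """Whether the export parameter encodes a perfectly absorbing boundary."""
        return math.isinf(self.kappa)

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class Domain1D:
    """Symmetric 1D nuclear domain Omega = [-R, R].

    ``boundary`` is one of ``"absorbing"``, ``"robin"`` or ``"reflecting"``;
    ``robin`` uses the export parameter ``kappa`` carried by
    :class:`ModelParams` (``robin`` with kappa=0 is reflecting, with
    kappa=inf absorbing).
    """

    R: float
    boundary: str = "absorbing"

    def __post_init__(self):
        if self.R <= 0:
            raise ValidationError(f"R must be positive, got {self.R}")
        if self.boundary not in BOUNDARY_KINDS:
            raise ValidationError(
                f"boundary must be one of {BOUNDARY_KINDS}, got {self.boundary!r}"
            )

    def contains(self, x) -> np.ndarray:
        return np.abs(np.asarray(x)) <= self.R


@dataclass(frozen=True)
class Domain2D:
    """Planar nuclear domain bounded by a simple closed polygon.

    Parameters
    ----------
    polygon : shapely.geometry.Polygon or (N, 2) array of vertices
        Boundary of the domain.  Purely absorbing.
    diffusivity : callable, optional
        ``diffusivity(x, y) -> D`` giving a spatially varying diffusion
        coefficient (Ito convention); ``None`` means the constant ``D``
        from :class:`ModelParams` is used everywhere.  Must be bounded
        between positive constants on the domain.
    """

    polygon: object
    diffusivity: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        import shapely.geometry as geom

        poly = self.polygon
        if not isinstance(poly, geom.Polygon):
            poly = geom.Polygon(np.asarray(poly, dtype=float))
            object.__setattr__(self, "polygon", poly)
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValidationError("boundary polygon must be simple and closed")

    @property
    def boundary(self) -> str:
        return "absorbing"

    def contains(self, x, y) -> np.ndarray:
        import shapely

        return shapely.contains_xy(self.polygon, np.asarray(x), np.asarray(y))

    def diffusivity_at(self, x, y, default: float) -> np.ndarray:
        if self.diffusivity is None:
            return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, default)
        return np.asarray(self.diffusivity(np.asarray(x), np.asarray(y)), dtype=float)


@dataclass
class PointPattern:
    """Observed transcript positions of a single cell plus its geometry.

    ``positions`` has shape ``(n,)`` in 1D or ``(n, 2)`` in 2D; the empty
    pattern (n = 0) is allowed.  ``z`` is the per-cell gene site.
    """

    positions: np.ndarray
    domain: Domain1D | Domain2D
    z: float | tuple[float, float]

    def __post_init__(self):
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class CountDistribution:
    """Probability mass function over molecule counts n = 0, ..., n_max.

    ``tail_mass`` records the probability mass beyond the truncation bound
    so that ``pmf.sum() + tail_mass == 1`` (to 1e-12).
    """

    pmf: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self):
        self.pmf = np.asarray(self.pmf, dtype=float)
        if np.any(self.pmf < -1e-15):
            raise ValidationError("pmf entries must be non-negative")
        self.pmf = np.clip(self.pmf, 0.0, None)
        total = self.pmf.sum() + self.tail_mass
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"pmf + tail_mass must sum to 1, got {total}")

    @property
    def n_max(self) -> int:
        return len(self.pmf) - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.pmf))

    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot(self.support**2, self.pmf) - m * m)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"n": self.support, "probability": self.pmf})


# ---------------------------------------------------------------------------
# validation and derived quantities
# ---------------------------------------------------------------------------

def validate_params(p: ModelParams, dom: Domain1D | Domain2D) -> ModelParams:
    """Check a parameter set against a domain and return it normalized.

    Raises :class:`ValidationError` naming the offending field.  The
    returned parameters have the boundary-consistent export parameter
    (``kappa = inf`` when the domain is declared absorbing, ``0`` when
    reflecting).
    """
    for name in ("lam", "lam_off", "alpha", "beta", "gamma"):
        v = getattr(p, name)
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"rate {name} must be finite and >= 0, got {v}")
    if p.D <= 0 or not np.isfinite(p.D):
        raise ValidationError(f"D must be positive, got {p.D}")
    if p.alpha + p.beta <= 0:
        raise ValidationError(
            "promoter never switches; rho undefined (alpha + beta must be > 0)"
        )
    if p.kappa < 0:
        raise ValidationError(f"kappa must be >= 0, got {p.kappa}")

    if isinstance(dom, Domain1D):
        z = float(np.asarray(p.z).reshape(()))
        if abs(z) >= dom.R:
            raise ValidationError(
                f"gene site outside domain: |z|={abs(z)} must be < R={dom.R}"
            )
        if dom.boundary == "absorbing":
            p = p.with_(kappa=math.inf)
        elif dom.boundary == "reflecting":
            p = p.with_(kappa=0.0)
    else:
        z = np.asarray(p.z, dtype=float).reshape(2)
        if not dom.contains(z[0], z[1]):
            raise ValidationError(f"gene site outside domain: z={tuple(z)}")
    return p


def effective_production(p: ModelParams) -> float:
    """Stationary mean production rate (alpha*lam + beta*lam_off)/(alpha+beta).

    Reduces to ``lam * rho`` for the standard telegraph model (lam_off = 0)
    and to the constant rate for a constitutive gene (lam == lam_off).
    """
    return (p.alpha * p.lam + p.beta * p.lam_off) / (p.alpha + p.beta)


def require_telegraph_off_zero(p: ModelParams, what: str) -> None:
    """Raise if lam_off > 0 where only the lam_off = 0 results are implemented."""
    if p.lam_off != 0:
        raise NotImplementedError(
            f"{what} is implemented for the standard telegraph model with "
            f"lam_off = 0 only (got lam_off = {p.lam_off})"
        )


# ---------------------------------------------------------------------------
# flat config serialization (keys: lam, lam_off, alpha, beta, gamma, D,
# kappa, z, R)
# ---------------------------------------------------------------------------

_PARAM_KEYS = ("lam", "lam_off", "alpha", "beta", "gamma", "D", "kappa", "z", "R")


def params_to_dict(p: ModelParams, dom: Domain1D | None = None) -> dict:
    """Flatten parameters (and 1D geometry) to a plain key-value mapping."""
    d = {
        "lam": float(p.lam),
        "lam_off": float(p.lam_off),
        "alpha": float(p.alpha),
        "beta": float(p.beta),
        "gamma": float(p.gamma),
        "D": float(p.D),
        "kappa": float(p.kappa),
        "z": p.z if isinstance(p.z, (tuple, list)) else float(p.z),
    }
    if dom is not None:
        d["R"] = float(dom.R)
    return d


def params_from_dict(d: dict) -> tuple[ModelParams, Domain1D | None]:
    """Inverse of :func:`params_to_dict`.

    ``kappa`` may be the string ``"inf"`` (or YAML ``.inf``).  Returns the
    domain as ``None`` when no ``R`` key is present.
    """
    d = dict(d)
    kappa = d.get("kappa", math.inf)
    if isinstance(kappa, str):
        kappa = math.inf if kappa.strip().lower() in ("inf", "infinity", ".inf") else float(kappa)
    z = d.get("z", 0.0)
    z = tuple(z) if isinstance(z, (list, tuple)) else float(z)
    p = ModelParams(
        lam=float(d["lam"]),
        lam_off=float(d.get("lam_off", 0.0)),
        alpha=float(d["alpha"]),
        beta=float(d["beta"]),
        gamma=float(d["gamma"]),
        D=float(d["D"]),
        kappa=float(kappa),
        z=z,
    )
    dom = None
    if "R" in d and d["R"] is not None:
        if math.isinf(p.kappa):
            boundary = "absorbing"
        elif p.kappa == 0:
            boundary = "reflecting"
        else:
            boundary = "robin"
        dom = Domain1D(R=float(d["R"]), boundary=boundary)
    return p, dom


def save_params(path, p: ModelParams, dom: Domain1D | None = None) -> None:
    """Write a parameter set (plus 1D geometry) to a YAML config file."""
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(p, dom), fh, sort_keys=False)


def load_params(path) -> tuple[ModelParams, Domain1D | None]:
    """Read a parameter set written by :func:`save_params`."""
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))
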