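"""Particle-based stochastic simulation of the spatial telegraph model.

The scheme is hybrid: the promoter path is simulated exactly (event-driven
exponential holding times, started from its stationary law), transcription
events are an inhomogeneous Poisson process along that path with particles
born at the gene site ``z``, each particle carries an exponential
degradation lifetime drawn at birth, and diffusion is Euler-Maruyama with
boundary handling per boundary type:

* absorbing -- particles beyond +-R are removed, and survivors are removed
  with the Brownian-bridge first-passage probability
  exp(-(R - x_old)(R - x_new) / (D dt)) to suppress the O(sqrt(dt))
  discretization bias of naive crossing detection;
* Robin (export rate kappa) -- a particle attempting to cross is exported
  with probability kappa * sqrt(pi dt / D) (the partially reflected
  Brownian motion construction), otherwise mirror-reflected;
* reflecting -- always mirror-reflected.

Ensembles of independent cells are propagated together in flat arrays, so
steady-state snapshots for thousands of cells cost a single sweep of the
time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import Domain1D, Domain2D, ModelParams, PointPattern, ValidationError, validate_params

__all__ = [
    "SimConfig",
    "TelegraphPath",
    "simulate_telegraph",
    "apply_boundary_1d",
    "simulate_cell",
    "simulate_population",
    "sample_counts",
    "sample_counts_2d",
]


@dataclass
class SimConfig:
    """Discretization and sampling controls for the particle simulator.

    ``None`` entries are resolved from the model parameters by
    :meth:`resolved`: the time step keeps both the diffusion displacement
    per step well below the domain size and the Robin export probability
    per contact below 1/2; the burn-in covers ten multiples of the slowest
    relaxation time (degradation, domain traversal, promoter switching);
    snapshots are spaced three correlation times apart.
    """

    dt: float | None = None
    t_burnin: float | None = None
    n_samples: int = 1
    sample_spacing: float | None = None
    seed: int | None = None
    max_particles: int = 5_000_000

    def resolved(self, p: ModelParams, R: float) -> "SimConfig":
        dt = self.dt
        if dt is None:
            dt = min(1.0 / (100.0 * p.gamma), R**2 / (1000.0 * p.D))
            if not p.absorbing and p.kappa > 0:
                # keep the export probability per boundary contact,
                # kappa*sqrt(pi*dt/D), at 0.15 so the O(sqrt(dt)) bias of
                # the partial-reflection scheme stays at the percent level
                dt = min(dt, 0.15**2 * p.D / (math.pi * p.kappa**2))
        relax = max(1.0 / p.gamma, R**2 / p.D, 1.0 / p.omega)
        t_burnin = 10.0 * relax if self.t_burnin is None else self.t_burnin
        spacing = self.sample_spacing
        if spacing is None:
            spacing = 3.0 * max(1.0 / p.gamma, 1.0 / p.omega)
        return SimConfig(dt, t_burnin, self.n_samples, spacing, self.seed, self.max_particles)


# ---------------------------------------------------------------------------
# promoter
# ---------------------------------------------------------------------------

@dataclass
class TelegraphPath:
    """Piecewise-constant promoter path on [0, t_end].

    ``times[i]`` is the start of the i-th constant stretch with state
    ``states[i]`` (1 = on, 0 = off); ``times[0] == 0``.
    """

    times: np.ndarray
    states: np.ndarray
    t_end: float

    def intervals(self):
        """Yield (t0, t1, state) for every constant stretch."""
        edges = np.append(self.times, self.t_end)
        for i in range(len(self.times)):
            yield edges[i], edges[i + 1], int(self.states[i])

    def state_at(self, t):
        idx = np.searchsorted(self.times, np.asarray(t), side="right") - 1
        return self.states[idx]

    def on_fraction(self) -> float:
        """Fraction of [0, t_end] spent in the on state."""
        edges = np.append(self.times, self.t_end)
        return float(np.sum(np.diff(edges) * self.states) / self.t_end)

    def holding_times(self, state: int) -> np.ndarray:
        """Completed holding times spent in ``state`` (the final, censored
        stretch is excluded)."""
        durations = np.diff(np.append(self.times, self.t_end))[:-1]
        return durations[self.states[:-1] == state]


def simulate_telegraph(
    alpha: float, beta: float, t_end: float, rng, state0: int | None = None
) -> TelegraphPath:
    """Exact event-driven two-state promoter path.

    Holding times are Exponential(beta) in the on state and
    Exponential(alpha) in the off state; the initial state is drawn from
    the stationary law (on with probability rho = alpha/(alpha+beta))
    unless ``state0`` is given.  ``rng`` may be a seed or a Generator.
    """
    if alpha + beta <= 0 or alpha < 0 or beta < 0:
        raise ValidationError("simulate_telegraph requires alpha + beta > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rho = alpha / (alpha + beta)
    state = int(rng.random() < rho) if state0 is None else int(state0)
    if (state == 1 and beta == 0) or (state == 0 and alpha == 0):
        # degenerate chain: the initial state is permanent
        return TelegraphPath(np.zeros(1), np.array([state]), t_end)
    times, states = [0.0], [state]
    t = 0.0
    while True:
        rate = beta if state else alpha
        if rate == 0.0:  # absorbed in the current state
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        state = 1 - state
        times.append(t)
        states.append(state)
    return TelegraphPath(np.asarray(times), np.asarray(states, dtype=int), t_end)


def _birth_times(path: TelegraphPath, lam: float, lam_off: float, rng) -> np.ndarray:
    """Exact birth times: Poisson counts per constant-rate stretch, uniform
    placement within each stretch."""
    out = []
    for t0, t1, s in path.intervals():
        rate = lam if s else lam_off
        if rate <= 0.0:
            continue
        k = rng.poisson(rate * (t1 - t0))
        if k:
            out.append(t0 + (t1 - t0) * rng.random(k))
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


# ---------------------------------------------------------------------------
# boundary handling
# ---------------------------------------------------------------------------

def _boundary_step_1d(x_old, x_new, R, boundary: str, kappa: float, D: float, dt, rng):
    """Vectorized boundary update; returns (positions, exported_mask).

    ``R`` and ``dt`` may be per-particle arrays.
    """
    x_old = np.asarray(x_old, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    R = np.broadcast_to(np.asarray(R, dtype=float), x_new.shape)
    dt = np.broadcast_to(np.asarray(dt, dtype=float), x_new.shape)

    if boundary == "absorbing":
        exported = np.abs(x_new) >= R
        # Brownian-bridge probability of an unobserved excursion beyond
        # either boundary for paths that ended inside
        inside = ~exported
        if np.any(inside):
            xo, xn = x_old[inside], x_new[inside]
            Ri, dti = R[inside], dt[inside]
            p_hi = np.exp(-np.clip((Ri - xo) * (Ri - xn), 0.0, None) / (D * dti))
            p_lo = np.exp(-np.clip((Ri + xo) * (Ri + xn), 0.0, None) / (D * dti))
            u = rng.random(xo.shape)
            crossed = u < (p_hi + p_lo - p_hi * p_lo)
            idx = np.flatnonzero(inside)[crossed]
            exported[idx] = True
        return x_new, exported

    # partial reflection (kappa = 0 reduces to pure reflection)
    exported = np.zeros(x_new.shape, dtype=bool)
    x = x_new.copy()
    contact = np.abs(x) > R
    if np.any(contact) and kappa > 0.0:
        p_abs = kappa * np.sqrt(math.pi * dt[contact] / D)
        if np.any(p_abs > 1.0):
            raise ValidationError(
                "Robin export probability kappa*sqrt(pi*dt/D) exceeds 1; "
                "use a smaller dt"
            )
        exported[np.flatnonzero(contact)[rng.random(p_abs.shape) < p_abs]] = True
    # mirror-reflect survivors (repeatedly, for rare multi-crossing steps)
    refl = contact & ~exported
    while np.any(refl):
        x[refl] = np.where(x[refl] > 0, 2.0 * R[refl] - x[refl], -2.0 * R[refl] - x[refl])
        refl = (np.abs(x) > R) & ~exported
    return x, exported


def apply_boundary_1d(x_old, x_new, dom: Domain1D, p: ModelParams, dt, rng):
    """Apply the 1D boundary rule to proposed Euler-Maruyama moves.

    Returns ``(positions, exported)``: updated positions and a boolean
    mask of particles removed through the boundary.
    """
    boundary = dom.boundary
    if boundary == "robin" and p.absorbing:
        boundary = "absorbing"
    kappa = 0.0 if boundary == "reflecting" else p.kappa
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _boundary_step_1d(x_old, x_new, dom.R, boundary, kappa, p.D, dt, rng)


# ---------------------------------------------------------------------------
# vectorized ensemble engine (1D)
# ---------------------------------------------------------------------------

def _run_ensemble_1d(
    p: ModelParams,
    R_arr: np.ndarray,
    z_arr: np.ndarray,
    boundary: str,
    snapshot_times: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    max_particles: int,
    keep_positions: bool,
):
    """Propagate one independent cell per (R_i, z_i) and record snapshots.

    Returns ``(counts, positions)`` where ``counts`` has shape
    (n_snapshots, n_cells) and ``positions[s]`` is a list of per-cell
    coordinate arrays (empty when ``keep_positions`` is False).
    """
    E = len(R_arr)
    t_end = float(snapshot_times[-1])
    n_steps = int(round(t_end / dt))
    snap_steps = np.rint(np.asarray(snapshot_times) / dt).astype(int)
    if np.any(np.abs(snap_steps * dt - snapshot_times) > 1e-9 * max(t_end, 1.0)):
        raise ValidationError("snapshot times must be multiples of dt")
    snap_set = {int(s): i for i, s in enumerate(snap_steps)}

    kappa = {"reflecting": 0.0, "absorbing": math.inf}.get(boundary, p.kappa)
    if boundary == "robin" and math.isinf(kappa):
        boundary = "absorbing"

    # pre-draw births and lifetimes per cell; keep only particles that are
    # alive (ignoring export) at one or more snapshot times
    births, owners, deaths = [], [], []
    snap_times = snap_steps * dt
    for j in range(E):
        path = simulate_telegraph(p.alpha, p.beta, t_end, rng)
        tb = _birth_times(path, p.lam, p.lam_off, rng)
        if tb.size == 0:
            continue
        td = tb + rng.exponential(1.0 / p.gamma, size=tb.size)
        nxt = np.searchsorted(snap_times, tb, side="left")
        keep = (nxt < len(snap_times)) & (td > snap_times[np.clip(nxt, 0, len(snap_times) - 1)])
        births.append(tb[keep])
        owners.append(np.full(keep.sum(), j, dtype=np.int64))
        deaths.append(td[keep])
    if births:
        tb = np.concatenate(births)
        order = np.argsort(tb, kind="stable")
        tb = tb[order]
        owner_all = np.concatenate(owners)[order]
        td_all = np.concatenate(deaths)[order]
    else:
        tb = np.empty(0)
        owner_all = np.empty(0, dtype=np.int64)
        td_all = np.empty(0)

    counts = np.zeros((len(snap_steps), E), dtype=np.int64)
    positions: list[list[np.ndarray]] = [[] for _ in snap_steps]
    x = np.empty(0)
    cell = np.empty(0, dtype=np.int64)
    death = np.empty(0)
    ptr = 0
    sq2D = math.sqrt(2.0 * p.D)

    for k in range(n_steps):
        t1 = (k + 1) * dt
        # hatch newborns of this step; they diffuse only their residual time
        ptr_new = np.searchsorted(tb, t1, side="left")
        nb = ptr_new - ptr
        if nb:
            xb = z_arr[owner_all[ptr:ptr_new]].astype(float)
            dt_eff = np.concatenate([np.full(x.size, dt), t1 - tb[ptr:ptr_new]])
            x = np.concatenate([x, xb])
            cell = np.concatenate([cell, owner_all[ptr:ptr_new]])
            death = np.concatenate([death, td_all[ptr:ptr_new]])
            ptr = ptr_new
        else:
            dt_eff = dt
        if x.size:
            x_prop = x + sq2D * np.sqrt(dt_eff) * rng.standard_normal(x.size)
            x_new, exported = _boundary_step_1d(
                x, x_prop, R_arr[cell], boundary, kappa, p.D, dt_eff, rng
            )
            alive = ~exported & (death > t1)
            x, cell, death = x_new[alive], cell[alive], death[alive]
            if x.size > max_particles:
                raise RuntimeError(
                    f"particle count {x.size} exceeded the safety cap; "
                    "review parameters (lam/gamma) or raise max_particles"
                )
        si = snap_set.get(k + 1)
        if si is not None:
            counts[si] = np.bincount(cell, minlength=E)
            if keep_positions:
                order = np.argsort(cell, kind="stable")
                positions[si] = np.split(
                    x[order], np.cumsum(np.bincount(cell, minlength=E))[:-1]
                )
    return counts, positions


def _resolve_boundary(dom: Domain1D, p: ModelParams) -> str:
    b = dom.boundary
    if b == "robin":
        if p.absorbing:
            return "absorbing"
        if p.kappa == 0:
            return "reflecting"
    return b


def simulate_cell(p: ModelParams, dom: Domain1D, cfg: SimConfig) -> list[PointPattern]:
    """Steady-state snapshots of a single 1D cell.

    Runs one trajectory from the empty state, discards the burn-in and
    harvests ``cfg.n_samples`` snapshots spaced ``cfg.sample_spacing``
    apart; each snapshot is returned as a :class:`PointPattern`.
    """
    p = validate_params(p, dom)
    cfg = cfg.resolved(p, dom.R)
    rng = np.random.default_rng(cfg.seed)
    snap = _snap_grid(cfg)
    _, positions = _run_ensemble_1d(
        p,
        np.array([dom.R]),
        np.array([float(p.z)]),
        _resolve_boundary(dom, p),
        snap,
        cfg.dt,
        rng,
        cfg.max_particles,
        keep_positions=True,
    )
    return [PointPattern(pos[0], dom, p.z) for pos in positions]


def _snap_grid(cfg: SimConfig) -> np.ndarray:
    dt = cfg.dt
    b = math.ceil(cfg.t_burnin / dt) * dt
    s = max(1, round(cfg.sample_spacing / dt)) * dt
    return b + s * np.arange(cfg.n_samples)


def simulate_population(
    p: ModelParams,
    domain_sampler: Callable[[np.random.Generator], tuple[float, float]],
    M: int,
    cfg: SimConfig,
) -> list[PointPattern]:
    """One stationary snapshot from each of M heterogeneous cells.

    ``domain_sampler(rng)`` yields a per-cell ``(R_i, z_i)``; kinetics are
    shared.  Cells are statistically independent and the whole output is a
    pure function of ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if M == 0:
        return []
    Rz = np.array([domain_sampler(rng) for _ in range(M)], dtype=float)
    R_arr, z_arr = Rz[:, 0], Rz[:, 1]
    if np.any(np.abs(z_arr) >= R_arr):
        raise ValidationError("domain_sampler produced a gene site outside its domain")
    cfg = cfg.resolved(p, float(R_arr.max()))
    boundary = "absorbing" if p.absorbing else ("reflecting" if p.kappa == 0 else "robin")
    snap = np.array([math.ceil(cfg.t_burnin / cfg.dt) * cfg.dt])
    _, positions = _run_ensemble_1d(
        p, R_arr, z_arr, boundary, snap, cfg.dt, rng, cfg.max_particles, keep_positions=True
    )
    return [
        PointPattern(positions[0][i], Domain1D(R_arr[i], boundary), z_arr[i])
        for i in range(M)
    ]


def sample_counts(
    p: ModelParams,
    dom: Domain1D,
    n_cells: int,
    cfg: SimConfig,
    snapshots_per_cell: int = 1,
) -> np.ndarray:
    """Stationary molecule-count samples from an ensemble of identical cells.

    ``n_cells`` independent trajectories are propagated together; when
    ``snapshots_per_cell > 1``, extra snapshots are harvested per cell at
    ``cfg.sample_spacing`` intervals (three correlation times by default,
    so residual within-cell correlation is ~e^-3).
    """
    p = validate_params(p, dom)
    cfg = cfg.resolved(p, dom.R)
    rng = np.random.default_rng(cfg.seed)
    cfg2 = SimConfig(
        cfg.dt, cfg.t_burnin, snapshots_per_cell, cfg.sample_spacing, cfg.seed, cfg.max_particles
    )
    snap = _snap_grid(cfg2)
    counts, _ = _run_ensemble_1d(
        p,
        np.full(n_cells, dom.R),
        np.full(n_cells, float(p.z)),
        _resolve_boundary(dom, p),
        snap,
        cfg.dt,
        rng,
        cfg.max_particles,
        keep_positions=False,
    )
    return counts.ravel()


# ---------------------------------------------------------------------------
# 2D ensemble (absorbing polygon, Ito space-dependent diffusivity)
# ---------------------------------------------------------------------------

def sample_counts_2d(
    p: ModelParams,
    dom: Domain2D,
    n_cells: int,
    cfg: SimConfig,
    return_final_positions: bool = False,
):
    """Stationary counts for independent realizations in a 2D domain.

    Diffusion uses the Ito convention: the increment standard deviation
    sqrt(2 D(x) dt) is evaluated at the pre-step position.  The polygon
    boundary is purely absorbing; crossing is detected by containment (no
    bridge correction), so the time step should resolve the boundary layer.
    """
    import shapely

    z = np.asarray(p.z, dtype=float).reshape(2)
    if not dom.contains(z[0], z[1]):
        raise ValidationError("gene site outside 2D domain")
    # characteristic radius for step heuristics
    minx, miny, maxx, maxy = dom.polygon.bounds
    R_eff = 0.25 * ((maxx - minx) + (maxy - miny))
    cfg = cfg.resolved(p, R_eff)
    rng = np.random.default_rng(cfg.seed)
    t_end = math.ceil(cfg.t_burnin / cfg.dt) * cfg.dt
    n_steps = int(round(t_end / cfg.dt))

    births, owners, deaths = [], [], []
    for j in range(n_cells):
        path = simulate_telegraph(p.alpha, p.beta, t_end, rng)
        tbj = _birth_times(path, p.lam, p.lam_off, rng)
        tdj = tbj + rng.exponential(1.0 / p.gamma, size=tbj.size)
        keep = tdj > t_end
        births.append(tbj[keep])
        owners.append(np.full(keep.sum(), j, dtype=np.int64))
        deaths.append(tdj[keep])
    tb = np.concatenate(births) if births else np.empty(0)
    owner_all = np.concatenate(owners) if owners else np.empty(0, dtype=np.int64)
    order = np.argsort(tb, kind="stable")
    tb, owner_all = tb[order], owner_all[order]

    xy = np.empty((0, 2))
    cell = np.empty(0, dtype=np.int64)
    ptr = 0
    for k in range(n_steps):
        t1 = (k + 1) * cfg.dt
        ptr_new = np.searchsorted(tb, t1, side="left")
        nb = ptr_new - ptr
        if nb:
            dt_eff = np.concatenate([np.full(len(xy), cfg.dt), t1 - tb[ptr:ptr_new]])
            xy = np.concatenate([xy, np.tile(z, (nb, 1))])
            cell = np.concatenate([cell, owner_all[ptr:ptr_new]])
            ptr = ptr_new
        else:
            dt_eff = np.full(len(xy), cfg.dt)
        if len(xy):
            Dx = dom.diffusivity_at(xy[:, 0], xy[:, 1], p.D)
            step = np.sqrt(2.0 * Dx * dt_eff)[:, None] * rng.standard_normal((len(xy), 2))
            xy_new = xy + step
            inside = shapely.contains_xy(dom.polygon, xy_new[:, 0], xy_new[:, 1])
            xy, cell = xy_new[inside], cell[inside]
            if len(xy) > cfg.max_particles:
                raise RuntimeError("particle count exceeded the safety cap")
    counts = np.bincount(cell, minlength=n_cells)
    if return_final_positions:
        return counts, xy, cell
    return counts
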