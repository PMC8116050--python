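"""IMEX finite-difference integrator for MCAS reaction-diffusion models.

Diffusion is treated implicitly (backward Euler on a flux-form finite
volume Laplacian, solved by a cached sparse LU factorization per
diffusivity and step size) and the nonlinear reaction term explicitly.
The step size adapts by step doubling on the reaction term: each step is
taken once at ``dt`` and again as two half steps, and the step is accepted
when the relative discrepancy is below the tolerance.

Because the Laplacian is assembled in flux form (every inter-cell flux
appears with opposite sign in exactly two rows) and solved directly,
conserved totals drift only at the level of linear-solver round-off,
typically < 1e-12 relative per run.

Grids are 1D or 2D, cell-centered, with periodic or no-flux outer
boundaries.  Internal no-flux walls perpendicular to the x axis insulate
subdomains; insulation is an operator modification (the coupling across
the wall interface is removed), so removing a wall restores the original
operator exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .models import ModelSpec

__all__ = [
    "Grid",
    "FieldState",
    "SolverControls",
    "Trajectory",
    "SolverError",
    "StiffnessError",
    "build_laplacian",
    "integrate",
    "run_to_steady_state",
    "insulate",
    "remove_insulation",
    "conserved_totals",
]


class SolverError(RuntimeError):
    pass


class StiffnessError(SolverError):
    """Step size underflow; carries the time reached."""

    def __init__(self, message: str, time_reached: float):
        super().__init__(message)
        self.time_reached = time_reached


@dataclass(frozen=True)
class Grid:
    """Cell-centered uniform grid, 1D ``(nx,)`` or 2D ``(nx, ny)``.

    ``walls`` holds interface indices ``w`` along the x axis: a wall at
    ``w`` blocks the flux between cell columns ``w-1`` and ``w``
    (``w = 0`` blocks the periodic wrap edge).
    """

    shape: tuple[int, ...]
    lengths: tuple[float, ...]
    bc: str = "periodic"  # "periodic" | "noflux"
    walls: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.shape) not in (1, 2) or len(self.shape) != len(self.lengths):
            raise ValueError("grid must be 1D or 2D with matching lengths")
        if self.bc not in ("periodic", "noflux"):
            raise ValueError(f"unknown boundary condition {self.bc!r}")
        if any(n < 2 for n in self.shape) or any(L <= 0 for L in self.lengths):
            raise ValueError("grid needs >= 2 points per axis and positive lengths")
        nx = self.shape[0]
        for w in self.walls:
            if not (0 <= w < nx):
                raise ValueError(f"wall index {w} outside domain (0..{nx - 1})")
            if w == 0 and self.bc != "periodic":
                raise ValueError("wall at index 0 only meaningful on a periodic grid")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(L / n for L, n in zip(self.lengths, self.shape))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def axis_coordinates(self, axis: int = 0) -> np.ndarray:
        """Cell-center coordinates along one axis."""
        h = self.spacing[axis]
        return (np.arange(self.shape[axis]) + 0.5) * h

    def wall_index_at(self, x: float) -> int:
        """Interface index nearest to position ``x`` (must lie on an interface)."""
        h = self.spacing[0]
        w = int(round(x / h))
        if abs(w * h - x) > 1e-9 * max(self.lengths[0], 1.0):
            raise ValueError(f"wall position {x} does not lie on a grid interface")
        return w % self.shape[0] if self.bc == "periodic" else w


@dataclass
class FieldState:
    """Per-species concentration fields on a grid at one time point."""

    time: float
    fields: np.ndarray  # (n_species, *grid.shape)

    def copy(self) -> "FieldState":
        return FieldState(self.time, self.fields.copy())


@dataclass(frozen=True)
class SolverControls:
    rel_tol: float = 1e-4          # target relative reaction error per step
    min_step: float = 1e-10
    max_step: float = 5.0
    initial_step: float = 1e-3
    steady_tol: float = 1e-8       # max |du/dt| < steady_tol * field scale
    max_time: float = 1e5
    check_interval: int = 20       # accepted steps between steady-state checks
    # solve the reaction sub-step by backward-Euler Newton instead of forward
    # Euler; needed for the mechanistic models, whose membrane binding
    # kinetics make a fully explicit reaction treatment impractically stiff
    implicit_reaction: bool = False

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.steady_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.min_step <= self.max_step):
            raise ValueError("need 0 < min_step <= max_step")


@dataclass
class Trajectory:
    times: list[float]
    states: list[FieldState]
    conservation_drift: float = 0.0   # max relative drift over sampled states
    audit: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operators


def build_laplacian(grid: Grid) -> sp.csr_matrix:
    """Unit-diffusivity flux-form Laplacian honoring BCs and internal walls."""
    n = grid.n_cells
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add_pairs(i: np.ndarray, j: np.ndarray, w: float) -> None:
        # symmetric coupling: L[i,j] += w, L[j,i] += w, L[i,i] -= w, L[j,j] -= w
        rows.extend([i, j, i, j])
        cols.extend([j, i, i, j])
        vals.extend([np.full(i.shape, w), np.full(i.shape, w),
                     np.full(i.shape, -w), np.full(i.shape, -w)])

    if grid.ndim == 1:
        nx = grid.shape[0]
        hx = grid.spacing[0]
        idx = np.arange(nx)
        blocked = set(grid.walls)
        # interface w couples cells (w-1, w); wrap edge is interface 0
        interfaces = [w for w in range(1, nx) if w not in blocked]
        i = np.array([w - 1 for w in interfaces], dtype=int)
        j = np.array(interfaces, dtype=int)
        add_pairs(i, j, 1.0 / hx**2)
        if grid.bc == "periodic" and 0 not in blocked:
            add_pairs(np.array([nx - 1]), np.array([0]), 1.0 / hx**2)
        del idx
    else:
        nx, ny = grid.shape
        hx, hy = grid.spacing
        flat = np.arange(nx * ny).reshape(nx, ny)
        blocked = set(grid.walls)
        # x-direction interfaces
        for w in range(1, nx):
            if w in blocked:
                continue
            add_pairs(flat[w - 1, :], flat[w, :], 1.0 / hx**2)
        if grid.bc == "periodic" and 0 not in blocked:
            add_pairs(flat[nx - 1, :], flat[0, :], 1.0 / hx**2)
        # y-direction interfaces (never walled)
        for w in range(1, ny):
            add_pairs(flat[:, w - 1], flat[:, w], 1.0 / hy**2)
        if grid.bc == "periodic":
            add_pairs(flat[:, ny - 1], flat[:, 0], 1.0 / hy**2)

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    return sp.csr_matrix((v, (r, c)), shape=(n, n))


def insulate(grid: Grid, wall_positions: Sequence[float]) -> Grid:
    """Grid with additional internal no-flux walls at the given x positions."""
    walls = set(grid.walls)
    for x in wall_positions:
        walls.add(grid.wall_index_at(x))
    return replace(grid, walls=tuple(sorted(walls)))


def remove_insulation(grid: Grid) -> Grid:
    """Grid with all internal walls removed (original operator restored)."""
    return replace(grid, walls=())


def conserved_totals(model: ModelSpec, grid: Grid, state: FieldState) -> dict[str, float]:
    """Weighted conserved total per group: cell volume x sum(weight x conc)."""
    vol = grid.cell_volume
    flatfields = state.fields.reshape(model.n_species, -1)
    sums = flatfields.sum(axis=1)
    return {
        gname: float(vol * np.dot(model.group_weights(gname), sums))
        for gname in model.group_names
    }


# ---------------------------------------------------------------------------
# IMEX stepping


class _ImexStepper:
    """Backward-Euler diffusion + explicit (or backward-Euler) reaction.

    Diffusion solves are cached sparse LU factorizations per (diffusivity,
    step).  With ``implicit_reaction`` the reaction sub-step is solved by a
    vectorized per-cell Newton iteration (finite-difference Jacobians,
    batched dense solves); backward Euler preserves the linear conservation
    invariants of the kinetics exactly.
    """

    def __init__(self, model: ModelSpec, grid: Grid, implicit_reaction: bool = False):
        self.model = model
        self.grid = grid
        self.implicit_reaction = implicit_reaction
        # weight matrix (n_groups, n_species) for group-mass error scaling
        self._gw = np.stack([model.group_weights(g) for g in model.group_names])
        self.L = build_laplacian(grid).tocsc()
        self.I = sp.identity(grid.n_cells, format="csc")
        # group species by diffusivity so one factorization serves several fields
        self.d_groups: dict[float, np.ndarray] = {}
        for i, D in enumerate(model.diffusivities):
            self.d_groups.setdefault(float(D), []).append(i)
        self.d_groups = {D: np.array(ix) for D, ix in self.d_groups.items()}
        self._lu_cache: dict[tuple[float, float], object] = {}

    def _lu(self, D: float, dt: float):
        key = (D, dt)
        lu = self._lu_cache.get(key)
        if lu is None:
            lu = splu((self.I - (dt * D) * self.L).tocsc())
            if len(self._lu_cache) > 64:
                self._lu_cache.clear()
            self._lu_cache[key] = lu
        return lu

    def implicit_diffuse(self, c_flat: np.ndarray, dt: float) -> np.ndarray:
        """Solve (I - dt D L) x = c for every species; c_flat is (nspec, n)."""
        out = np.empty_like(c_flat)
        for D, ix in self.d_groups.items():
            if D == 0.0:
                out[ix] = c_flat[ix]
            else:
                out[ix] = self._lu(D, dt).solve(c_flat[ix].T).T
        return out

    def reaction_flat(self, c_flat: np.ndarray) -> np.ndarray:
        shaped = c_flat.reshape(self.model.n_species, *self.grid.shape)
        return self.model.reaction(shaped).reshape(self.model.n_species, -1)

    def _jacobian_cells(self, x: np.ndarray) -> np.ndarray:
        """Per-cell reaction Jacobian, shape (n_cells, ns, ns)."""
        ns = self.model.n_species
        if self.model.jacobian is not None:
            shaped = x.reshape(ns, *self.grid.shape)
            J = self.model.jacobian(shaped).reshape(ns, ns, -1)
            return np.ascontiguousarray(np.moveaxis(J, 2, 0))
        # finite-difference fallback
        n = x.shape[1]
        scale = max(float(np.max(np.abs(x))), 1e-12)
        r = self.reaction_flat(x)
        J = np.empty((n, ns, ns))
        for j in range(ns):
            h = 1e-7 * max(float(np.max(np.abs(x[j]))), 1e-3 * scale, 1e-12)
            xp = x.copy()
            xp[j] += h
            J[:, :, j] = ((self.reaction_flat(xp) - r) / h).T
        return J

    def _react_be(self, c_flat: np.ndarray, dt: float) -> np.ndarray:
        """Backward-Euler reaction sub-step via vectorized modified Newton.

        The Jacobian is evaluated once at the explicit predictor and reused
        across iterations; a stalled iteration returns NaN so the adaptive
        controller rejects and halves the step.
        """
        ns = self.model.n_species
        scale = max(float(np.max(np.abs(c_flat))), 1e-12)
        # start from the current state: an explicit predictor diverges when
        # the fast kinetics make lambda*dt >> 1
        x = c_flat.copy()
        eye = np.eye(ns)
        resid_prev = np.inf
        grew = 0
        refreshed = False
        A = eye[None, :, :] - dt * self._jacobian_cells(x)
        try:
            for _ in range(20):
                F = x - c_flat - dt * self.reaction_flat(x)
                resid = float(np.max(np.abs(F)))
                if resid < 1e-12 * scale:
                    return x
                if resid > resid_prev:
                    grew += 1
                    if grew >= 2:  # diverging: signal a rejection
                        return np.full_like(x, np.nan)
                # modified Newton: reuse the Jacobian unless contraction slows
                if resid > 0.3 * resid_prev and not refreshed:
                    A = eye[None, :, :] - dt * self._jacobian_cells(x)
                    refreshed = True
                resid_prev = resid
                dx = np.linalg.solve(A, F.T[:, :, None])[:, :, 0]
                x = x - dx.T
                if not np.all(np.isfinite(x)):
                    return x
        except np.linalg.LinAlgError:
            return np.full_like(x, np.nan)
        if resid > 1e-8 * scale:  # Newton stalled: signal a rejection
            return np.full_like(x, np.nan)
        return x

    def react_step(self, c_flat: np.ndarray, dt: float,
                   r0: np.ndarray | None = None) -> np.ndarray:
        if self.implicit_reaction:
            return self._react_be(c_flat, dt)
        if r0 is None:
            r0 = self.reaction_flat(c_flat)
        return c_flat + dt * r0

    def attempt(self, c_flat: np.ndarray, dt: float) -> tuple[np.ndarray, float]:
        """One trial step; returns (fine solution, relative reaction error)."""
        r0 = None if self.implicit_reaction else self.reaction_flat(c_flat)
        coarse = self.implicit_diffuse(self.react_step(c_flat, dt, r0), dt)
        half = self.implicit_diffuse(self.react_step(c_flat, 0.5 * dt, r0), 0.5 * dt)
        fine = self.implicit_diffuse(self.react_step(half, 0.5 * dt), 0.5 * dt)
        if not (np.all(np.isfinite(coarse)) and np.all(np.isfinite(fine))):
            return fine, np.inf
        scale = np.maximum(np.max(np.abs(fine), axis=1), 1e-12)
        if self.implicit_reaction:
            # floor each species' error scale at a fraction of its
            # conservation group's weighted mass scale: strongly slaved
            # trace species (e.g. the cytosolic GEF pool, ~1e-3 of the
            # membrane pools) are re-equilibrated by the fast kinetics every
            # step, so measuring their error against their own tiny maximum
            # only throttles the step without improving the solution
            weighted_scale = float(np.max(self._gw * scale[None, :]))
            w_max = np.max(self._gw, axis=0)  # per-species max weight
            scale = np.maximum(scale, 0.05 * weighted_scale / w_max)
        err = float(np.max(np.max(np.abs(fine - coarse), axis=1) / scale))
        return fine, err

    def rate_norm(self, c_flat: np.ndarray) -> float:
        """Max |du/dt| (reaction + diffusion) relative to the field scale."""
        rate = self.reaction_flat(c_flat).copy()
        for D, ix in self.d_groups.items():
            if D != 0.0:
                rate[ix] += D * (self.L @ c_flat[ix].T).T
        scale = max(float(np.max(np.abs(c_flat))), 1e-12)
        return float(np.max(np.abs(rate))) / scale


def _advance(
    stepper: _ImexStepper,
    c_flat: np.ndarray,
    t: float,
    t_target: float,
    dt: float,
    controls: SolverControls,
) -> tuple[np.ndarray, float, float]:
    """Integrate from t to t_target; returns (state, t_target, last dt)."""
    n_accepted = 0
    # hysteresis against accept/reject ping-pong at the explicit stability
    # limit: after a rejection, cap growth below the rejected step for a
    # while, relaxing the cap every 100 accepted steps
    ceiling = controls.max_step
    ceiling_age = 0
    while t < t_target - 1e-12 * max(abs(t_target), 1.0):
        step = min(dt, t_target - t)
        fine, err = stepper.attempt(c_flat, step)
        if not np.isfinite(err) or (err > controls.rel_tol and step > controls.min_step):
            dt = max(step * 0.5, controls.min_step)
            ceiling = max(0.75 * step, controls.min_step)
            ceiling_age = 0
            if dt <= controls.min_step and (not np.isfinite(err) or err > 10 * controls.rel_tol):
                raise StiffnessError(
                    f"step underflow at t={t:.6g} (reaction error {err:.3g})", t)
            continue
        c_flat = fine
        t += step
        if not np.all(np.isfinite(c_flat)):
            raise SolverError(f"non-finite field at t={t:.6g}")
        n_accepted += 1
        if n_accepted % 50 == 0:
            fmax = float(np.max(np.abs(c_flat)))
            if float(c_flat.min()) < -1e-6 * fmax:
                raise SolverError(f"negative concentration blow-up at t={t:.6g}")
        ceiling_age += 1
        if ceiling_age >= 100 and ceiling < controls.max_step:
            ceiling = min(2.0 * ceiling, controls.max_step)
            ceiling_age = 0
        if step >= dt and err < 0.25 * controls.rel_tol:
            dt = min(dt * 2.0, ceiling)
    return c_flat, t_target, dt


def integrate(
    model: ModelSpec,
    grid: Grid,
    state0: FieldState,
    t_end: float,
    controls: SolverControls = SolverControls(),
    sample_times: Sequence[float] | None = None,
    observer: Callable[[FieldState], bool | None] | None = None,
) -> Trajectory:
    """Integrate to ``t_end``, sampling at ``sample_times`` (plus endpoints).

    ``observer`` is called on every sampled state; returning True stops the
    integration early.  The trajectory carries a conservation audit: the
    maximum relative drift of any conserved group total over the run.
    """
    if state0.fields.shape != (model.n_species, *grid.shape):
        raise SolverError("state shape does not match model/grid")
    if t_end <= state0.time:
        raise SolverError("t_end must exceed the initial time")

    if sample_times is None:
        samples = [t_end]
    else:
        samples = sorted(t for t in set(sample_times) if state0.time < t <= t_end)
        if not samples or samples[-1] < t_end:
            samples.append(t_end)

    stepper = _ImexStepper(model, grid, controls.implicit_reaction)
    c = state0.fields.reshape(model.n_species, -1).astype(float).copy()
    t = state0.time
    dt = controls.initial_step

    totals0 = conserved_totals(model, grid, state0)
    traj = Trajectory(times=[t], states=[state0.copy()])
    traj.audit["totals_initial"] = totals0

    max_drift = 0.0
    for ts in samples:
        c, t, dt = _advance(stepper, c, t, ts, dt, controls)
        st = FieldState(t, c.reshape(model.n_species, *grid.shape).copy())
        traj.times.append(t)
        traj.states.append(st)
        tot = conserved_totals(model, grid, st)
        for g, T0 in totals0.items():
            ref = max(abs(T0), 1e-300)
            max_drift = max(max_drift, abs(tot[g] - T0) / ref)
        if observer is not None and observer(st):
            break

    traj.conservation_drift = max_drift
    traj.audit["totals_final"] = conserved_totals(model, grid, traj.states[-1])
    return traj


def run_to_steady_state(
    model: ModelSpec,
    grid: Grid,
    state0: FieldState,
    controls: SolverControls = SolverControls(),
) -> tuple[FieldState, bool, dict]:
    """Integrate until max |du/dt| < steady_tol x field scale (or max_time).

    Returns ``(state, converged, diagnostics)``.  Non-convergence by
    ``max_time`` (e.g. residual oscillation under negative feedback) yields
    ``converged=False`` with the residual rate amplitude in diagnostics.
    """
    if state0.fields.shape != (model.n_species, *grid.shape):
        raise SolverError("state shape does not match model/grid")
    stepper = _ImexStepper(model, grid, controls.implicit_reaction)
    c = state0.fields.reshape(model.n_species, -1).astype(float).copy()
    t = state0.time
    dt = controls.initial_step

    rnorm = stepper.rate_norm(c)
    if rnorm < controls.steady_tol:
        return state0.copy(), True, {"residual": rnorm, "time": t}

    recent: list[float] = []
    while t < controls.max_time:
        target = min(t + controls.check_interval * dt, controls.max_time)
        if target <= t:
            target = min(t + controls.min_step * controls.check_interval, controls.max_time)
        c, t, dt = _advance(stepper, c, t, target, dt, controls)
        rnorm = stepper.rate_norm(c)
        recent.append(rnorm)
        if rnorm < controls.steady_tol:
            return (FieldState(t, c.reshape(model.n_species, *grid.shape)), True,
                    {"residual": rnorm, "time": t})
    tail = np.array(recent[-20:]) if recent else np.array([rnorm])
    diag = {
        "residual": rnorm,
        "time": t,
        "residual_oscillation_amplitude": float(tail.max() - tail.min()),
    }
    return FieldState(t, c.reshape(model.n_species, *grid.shape)), False, diag
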