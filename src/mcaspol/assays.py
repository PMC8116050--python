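"""Simulation protocols: standardized single-peak preparation, two-peak
competition assays, saturation scans, competition-time curves, outcome
phase diagrams, and the basal-substrate-difference predictor.

Protein amounts are expressed in "1x" units.  For the dimensionless
models 1x corresponds to a uniform substrate concentration of 2; for the
mechanistic models it corresponds to uniform cytosolic concentrations of
5.0 uM Cdc42 and 0.017 uM BemGEF (all protein initially in the cytosolic
pools, counted with weight 1/eta).

Two-peak initial conditions are standardized by preparing two insulated
subsystems, each relaxed to a single-peak steady state containing its own
share of the total protein, and then allowing them to communicate by
diffusion at t = 0.  Each subsystem is seeded from the nontrivial
homogeneous steady state with a localized activator bump placed at the
subsystem edge facing away from the shared interface, so the joined
domain carries one peak at each outer end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import ModelSpec, make_indirect_model
from .peaks import (
    CompetitionTrace,
    OutcomeLabel,
    PeakSet,
    PeakTracker,
    basal_level,
    classify_outcome,
    competition_time,
    detect_peaks,
)
from .solver import (
    FieldState,
    Grid,
    SolverControls,
    conserved_totals,
    integrate,
    run_to_steady_state,
)

__all__ = [
    "AssayConfig",
    "PreparedPeak",
    "CompetitionResult",
    "PhaseDiagram",
    "unit_totals",
    "default_grid",
    "default_controls",
    "initial_condition",
    "prepare_single_peak",
    "competition_assay",
    "saturation_scan",
    "limiting_species_scan",
    "competition_time_curve",
    "phase_diagram",
    "basal_difference_predictor",
]

#: uniform concentrations defining the "1x" protein amount
UNIT_CONCENTRATIONS: dict[str, dict[str, float]] = {
    "minimal": {"v": 2.0},
    "indirect": {"v": 2.0},
    "mechanistic": {"Cdc42Dc": 5.0, "BemGEFc": 0.017},
    "mechanistic_nfb": {"Cdc42Dc": 5.0, "BemGEFc": 0.017},
}

ACTIVATOR: dict[str, str] = {
    "minimal": "u",
    "indirect": "u",
    "mechanistic": "Cdc42T",
    "mechanistic_nfb": "Cdc42T",
}


def _is_mechanistic(model: ModelSpec) -> bool:
    return model.name.startswith("mechanistic")


def activator_index(model: ModelSpec) -> int:
    return model.index(ACTIVATOR[model.name])


def cytoplasmic_species(model: ModelSpec) -> list[str]:
    return [s.name for s in model.species if s.compartment == "cytoplasm"]


def unit_totals(model: ModelSpec, amount: float | dict[str, float]) -> dict[str, float]:
    """Weighted conserved totals (per unit area/length) for a protein amount.

    ``amount`` is a multiplier of 1x, or a per-group multiplier map for
    scans that vary one protein only.
    """
    unit = UNIT_CONCENTRATIONS[model.name]
    totals: dict[str, float] = {g: 0.0 for g in model.group_names}
    for sp, conc in unit.items():
        i = model.index(sp)
        for gname in model.group_names:
            w = model.group_weights(gname)
            totals[gname] += w[i] * conc
    if isinstance(amount, dict):
        unknown = set(amount) - set(totals)
        if unknown:
            raise ValueError(f"unknown groups in amount map: {sorted(unknown)}")
        return {g: totals[g] * amount.get(g, 1.0) for g in totals}
    if amount <= 0:
        raise ValueError("amount must be positive")
    return {g: T * amount for g, T in totals.items()}


def default_grid(model: ModelSpec, half: bool = False, resolution: int | None = None) -> Grid:
    """Production grid: 1D L=10, 500 points (dimensionless models);
    2D 8.86 um square, 100x100 points (mechanistic models).  ``half``
    returns one insulated subsystem (half the x extent)."""
    if _is_mechanistic(model):
        n = resolution or 100
        # a 4.43 um square comfortably holds one ~2 um polarity patch per
        # half while keeping peak concentrations (hence stiffness) moderate
        side = 4.43
        if half:
            return Grid((n // 2, n), (side / 2, side), bc="noflux")
        return Grid((n, n), (side, side), bc="noflux")
    n = resolution or 500
    # chosen so a 1x subsystem sits below the saturation point while 2x-4x
    # peaks are saturated, and the indirect model's basal-substrate minimum
    # falls near 1x (mass per subsystem = 2 x amount x L/2)
    L = 5.0
    if half:
        return Grid((n // 2,), (L / 2,), bc="noflux")
    return Grid((n,), (L,), bc="noflux")


def default_controls(model: ModelSpec) -> SolverControls:
    if _is_mechanistic(model):
        return SolverControls(rel_tol=1e-4, initial_step=1e-4, max_step=5.0,
                              steady_tol=1e-6, max_time=2000.0,
                              implicit_reaction=True)
    return SolverControls(rel_tol=1e-4, initial_step=1e-3, max_step=5.0,
                          steady_tol=1e-6, max_time=2000.0)


@dataclass(frozen=True)
class AssayConfig:
    """Configuration shared by the assay protocols."""

    t_max: float = 2000.0
    sample_interval: float | None = None  # auto: 2.0 dimensionless, 10.0 (s) mechanistic
    noise_amplitude: float = 0.01
    seed_factor: float = 5.0
    equality_band: float = 0.01
    retry_cap: int = 3
    stop_on_win: bool = True


# ---------------------------------------------------------------------------
# initial conditions and single-peak preparation


def _renormalize(model: ModelSpec, grid: Grid, fields: np.ndarray,
                 totals: dict[str, float]) -> None:
    """Adjust the dominant cytosolic pool of each group so conserved totals
    match the request exactly (in place)."""
    adjust_species = {
        "minimal": {"total": "v"},
        "indirect": {"total": "v"},
        "mechanistic": {"Cdc42": "Cdc42Dc", "BemGEF": "BemGEFc"},
        "mechanistic_nfb": {"Cdc42": "Cdc42Dc", "BemGEF": "BemGEFc"},
    }[model.name]
    vol = grid.cell_volume
    area = vol * grid.n_cells
    for gname, sp in adjust_species.items():
        w = model.group_weights(gname)
        cur = vol * float(np.dot(w, fields.reshape(model.n_species, -1).sum(axis=1)))
        target = totals[gname] * area
        i = model.index(sp)
        delta = (target - cur) / (area * w[i])
        fields[i] += delta
        if fields[i].min() < 0:
            raise ValueError("renormalization drove a concentration negative")


def initial_condition(
    model: ModelSpec,
    grid: Grid,
    amount: float | dict[str, float],
    seed: int | None = 0,
    noise_amplitude: float = 0.01,
    bump_position: float | tuple[float, float] | None = 0.5,
    seed_factor: float = 5.0,
) -> FieldState:
    """All protein in the cytosolic pools, plus a localized activator seed.

    A Gaussian activator bump at ``bump_position`` (relative coordinates in
    [0, 1] per axis; None disables it) with amplitude ``seed_factor`` times
    the scaled unit substrate concentration ignites the peak both in the
    Turing-unstable regime and in the excitable regime where the patterned
    state must be reached by a finite-amplitude perturbation.  Totals are
    renormalized to the request exactly; seeded multiplicative noise is
    applied to the cytosolic substrates.
    """
    totals = unit_totals(model, amount)
    unit = UNIT_CONCENTRATIONS[model.name]
    fields = np.zeros((model.n_species, *grid.shape))
    for sp, conc in unit.items():
        mult = amount.get(_group_of(model, sp), 1.0) if isinstance(amount, dict) \
            else float(amount)
        fields[model.index(sp)] = conc * mult

    ai = activator_index(model)
    if bump_position is not None and seed_factor > 0:
        if grid.ndim == 1:
            x = grid.axis_coordinates(0)
            x0 = float(np.atleast_1d(bump_position)[0]) * grid.lengths[0]
            sigma = grid.lengths[0] / 20.0
            bump = np.exp(-((x - x0) ** 2) / (2 * sigma**2))
        else:
            bp = bump_position if isinstance(bump_position, tuple) else (bump_position, 0.5)
            x = grid.axis_coordinates(0)[:, None]
            y = grid.axis_coordinates(1)[None, :]
            x0 = bp[0] * grid.lengths[0]
            y0 = bp[1] * grid.lengths[1]
            sigma = min(grid.lengths) / 10.0
            bump = np.exp(-(((x - x0) ** 2) + ((y - y0) ** 2)) / (2 * sigma**2))
        gact = _group_of(model, model.species_names[ai])
        mult = amount.get(gact, 1.0) if isinstance(amount, dict) else float(amount)
        # amplitude on the membrane-concentration scale of the donor pool
        donor_conc = max(
            conc for sp, conc in unit.items() if _group_of(model, sp) == gact
        )
        fields[ai] = bump * (seed_factor * donor_conc * mult)

    if noise_amplitude > 0:
        if not (0 < noise_amplitude <= 0.1):
            raise ValueError("noise amplitude must lie in (0, 0.1]")
        rng = np.random.default_rng(seed)
        for sp in cytoplasmic_species(model):
            i = model.index(sp)
            fields[i] = fields[i] * (1.0 + noise_amplitude
                                     * rng.uniform(-1.0, 1.0, size=grid.shape))
    _renormalize(model, grid, fields, totals)
    return FieldState(0.0, fields)


def _group_of(model: ModelSpec, sp: str) -> str:
    for gname, members in model.conservation_groups:
        if any(s == sp for s, _ in members):
            return gname
    raise KeyError(sp)


@dataclass
class PreparedPeak:
    """A relaxed single-peak (or flagged no-peak) subsystem state."""

    state: FieldState
    peaks: PeakSet
    basal: dict[str, float]      # basal level per cytoplasmic species
    converged: bool
    no_peak: bool
    amount: float | dict[str, float]
    seed: int
    diagnostics: dict = field(default_factory=dict)


def prepare_single_peak(
    model: ModelSpec,
    grid: Grid | None = None,
    amount: float | dict[str, float] = 1.0,
    seed: int = 0,
    peak_position: float | tuple[float, float] = 0.0,
    config: AssayConfig = AssayConfig(),
    controls: SolverControls | None = None,
) -> PreparedPeak:
    """Relax one insulated subsystem to a single-peak steady state.

    Returns a flagged no-peak result when the amount is sub-critical; if
    more than one peak survives relaxation the preparation is retried with
    fresh noise seeds up to ``config.retry_cap`` before raising.
    """
    grid = grid if grid is not None else default_grid(model, half=True)
    if controls is None:
        # basal levels and peak amplitude settle well before the mesa front
        # fully equilibrates; these horizons suffice at the default tolerance
        horizon = 200.0 if _is_mechanistic(model) else 400.0
        controls = replace(default_controls(model), max_time=horizon)
    last_exc: Exception | None = None
    for attempt in range(config.retry_cap):
        use_seed = seed + 1000 * attempt
        state0 = initial_condition(
            model, grid, amount, seed=use_seed,
            noise_amplitude=config.noise_amplitude,
            bump_position=peak_position, seed_factor=config.seed_factor,
        )
        state, converged, diag = run_to_steady_state(model, grid, state0, controls)
        act = state.fields[activator_index(model)]
        # a decayed activator remnant is not a peak: require meaningful mass
        ai = activator_index(model)
        gact = _group_of(model, model.species_names[ai])
        conc_scale = unit_totals(model, amount)[gact] / model.group_weights(gact)[ai]
        if act.max() < 1e-4 * conc_scale:
            ps = detect_peaks(np.zeros_like(act), grid)
        else:
            ps = detect_peaks(act, grid)
        if ps.n_peaks == 0:
            return PreparedPeak(state, ps, {}, converged, True, amount, use_seed, diag)
        if ps.n_peaks == 1:
            basal = {
                sp: basal_level(state.fields[model.index(sp)], ps, 0)
                for sp in cytoplasmic_species(model)
            }
            return PreparedPeak(state, ps, basal, converged, False, amount, use_seed, diag)
        last_exc = RuntimeError(
            f"{ps.n_peaks} peaks after relaxation (amount={amount}, seed={use_seed})")
    raise last_exc  # type: ignore[misc]


# ---------------------------------------------------------------------------
# competition assay


@dataclass
class CompetitionResult:
    trace: CompetitionTrace
    outcome: OutcomeLabel
    prepared: tuple[PreparedPeak, PreparedPeak]
    delta_basal: dict[str, float]   # basal (larger-amount peak) - (smaller)
    conservation_drift: float
    meta: dict = field(default_factory=dict)


def _join_halves(grid_a: Grid, grid_b: Grid, fa: np.ndarray, fb: np.ndarray
                 ) -> tuple[Grid, np.ndarray]:
    nx = grid_a.shape[0] + grid_b.shape[0]
    lengths = (grid_a.lengths[0] + grid_b.lengths[0], *grid_a.lengths[1:])
    shape = (nx, *grid_a.shape[1:])
    full = Grid(shape, lengths, bc="noflux")
    return full, np.concatenate([fa, fb], axis=1)


def _mirror_outward(prep: PreparedPeak, outer: str) -> np.ndarray:
    """Mirror the subsystem along x so its peak sits near the requested
    outer edge ('low' or 'high'); mirroring is a symmetry of the no-flux
    subsystem so the state stays steady."""
    fields = prep.state.fields
    nx = fields.shape[1]
    px = prep.peaks.positions[0][0]
    at_low = px < nx / 2
    if (outer == "low") != at_low:
        fields = fields[:, ::-1].copy()
    return fields


def competition_assay(
    model: ModelSpec,
    amounts: tuple[float, float],
    grid: Grid | None = None,
    seed: int = 0,
    config: AssayConfig = AssayConfig(),
    controls: SolverControls | None = None,
) -> CompetitionResult:
    """Two-peak competition: prepare two insulated single-peak subsystems
    with the given amounts, join them at t = 0, track peak mass fractions
    (on the activator; Cdc42T for mechanistic models), and classify the
    outcome."""
    grid = grid if grid is not None else default_grid(model)
    prep_controls = controls
    controls = controls or default_controls(model)
    nx = grid.shape[0]
    half_shape = (nx // 2, *grid.shape[1:])
    half_lengths = (grid.lengths[0] / 2, *grid.lengths[1:])
    gh = Grid(half_shape, half_lengths, bc="noflux")

    prep_a = prepare_single_peak(model, gh, amounts[0], seed=seed,
                                 peak_position=_edge_pos(grid, "low"),
                                 config=config, controls=prep_controls)
    prep_b = prepare_single_peak(model, gh, amounts[1], seed=seed + 1,
                                 peak_position=_edge_pos(grid, "high"),
                                 config=config, controls=prep_controls)
    for p, name in ((prep_a, "A"), (prep_b, "B")):
        if p.no_peak:
            raise RuntimeError(f"subsystem {name} (amount {p.amount}) formed no peak")

    fa = _mirror_outward(prep_a, "low")
    fb = _mirror_outward(prep_b, "high")
    full, fields0 = _join_halves(gh, gh, fa, fb)
    state0 = FieldState(0.0, fields0)

    ai = activator_index(model)
    init_ps = detect_peaks(fields0[ai], full)
    tracker = PeakTracker(init_ps, fields0[ai])
    times = [0.0]
    fr = [init_ps.fractions.copy()]
    counts = [init_ps.n_peaks]
    raw2 = [_top2(init_ps.fractions)]

    def observer(st: FieldState) -> bool:
        ps = detect_peaks(st.fields[ai], full)
        times.append(st.time)
        fr.append(tracker.assign(ps, st.fields[ai]))
        counts.append(ps.n_peaks)
        raw2.append(_top2(ps.fractions))
        if config.stop_on_win and raw2[-1][0] >= 0.995:
            return True
        # settled two-equal-peak state: the equalization endpoint is reached,
        # no need to integrate out to t_max
        if config.stop_on_win and len(raw2) >= 50 and counts[-1] == 2:
            recent = np.array(raw2[-40:])
            if np.all(np.abs(recent - 0.5) <= 0.005):
                return True
        return False

    sample_dt = config.sample_interval
    if sample_dt is None:
        sample_dt = 10.0 if _is_mechanistic(model) else 2.0
    sample_times = np.arange(sample_dt, config.t_max + 1e-9, sample_dt)
    traj = integrate(model, full, state0, config.t_max, controls,
                     sample_times=sample_times, observer=observer)

    trace = CompetitionTrace(
        times=np.array(times),
        fractions=np.array(fr).T,
        peak_counts=np.array(counts),
        raw_top2=np.array(raw2).T,
        meta={"initial_peak_count": init_ps.n_peaks, "amounts": amounts, "seed": seed},
    )
    outcome = classify_outcome(trace, t_max=config.t_max,
                               equality_band=config.equality_band)

    larger, smaller = (prep_b, prep_a) if _scalar(amounts[1]) >= _scalar(amounts[0]) \
        else (prep_a, prep_b)
    delta = {sp: larger.basal[sp] - smaller.basal[sp] for sp in larger.basal}
    return CompetitionResult(
        trace=trace, outcome=outcome, prepared=(prep_a, prep_b),
        delta_basal=delta, conservation_drift=traj.conservation_drift,
        meta={"amounts": amounts, "seed": seed, "t_max": config.t_max,
              "grid": {"shape": full.shape, "lengths": full.lengths, "bc": full.bc}},
    )


def _top2(fractions: np.ndarray) -> np.ndarray:
    """Two largest identity-free mass fractions (zero-padded)."""
    s = np.sort(np.asarray(fractions))[::-1]
    out = np.zeros(2)
    out[: min(2, len(s))] = s[:2]
    return out


def _scalar(a: float | dict) -> float:
    return float(np.mean(list(a.values()))) if isinstance(a, dict) else float(a)


def _edge_pos(grid: Grid, which: str) -> float | tuple[float, float]:
    # seed at the outer boundary: the boundary-attached half-peak is the
    # stable steady state (interior peaks drift slowly toward a wall)
    p = 0.0 if which == "low" else 1.0
    if grid.ndim == 2:
        return (p, 0.5)
    return p


# ---------------------------------------------------------------------------
# scans


def saturation_scan(
    model: ModelSpec,
    multipliers: tuple[float, ...] = (0.6, 1.0, 2.0, 4.0),
    grid: Grid | None = None,
    seed: int = 0,
    config: AssayConfig = AssayConfig(),
    controls: SolverControls | None = None,
) -> pd.DataFrame:
    """Single-peak steady states over an ascending amount ladder.

    Columns: ``amount``, ``no_peak``, ``peak_activator`` (peak amplitude),
    and ``basal_<species>`` per cytoplasmic species.
    """
    if list(multipliers) != sorted(multipliers):
        raise ValueError("multipliers must be sorted ascending")
    grid = grid if grid is not None else default_grid(model, half=True)
    rows = []
    for m in multipliers:
        prep = prepare_single_peak(model, grid, m, seed=seed, config=config,
                                   controls=controls)
        row: dict[str, float | bool] = {"amount": m, "no_peak": prep.no_peak}
        if prep.no_peak:
            row["peak_activator"] = math.nan
            for sp in cytoplasmic_species(model):
                row[f"basal_{sp}"] = math.nan
        else:
            row["peak_activator"] = float(prep.peaks.amplitudes[0])
            for sp, val in prep.basal.items():
                row[f"basal_{sp}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def limiting_species_scan(
    model: ModelSpec,
    which: str = "both",
    multipliers: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    grid: Grid | None = None,
    seed: int = 0,
    plateau_threshold: float = 0.10,
    config: AssayConfig = AssayConfig(),
    controls: SolverControls | None = None,
) -> tuple[pd.DataFrame, str]:
    """Vary one or both conserved totals of a mechanistic model and identify
    the limiting species: the cytosolic substrate whose basal level
    plateaus (relative increment below threshold over the top step).

    ``which`` is one of ``both``, ``Cdc42``, ``BemGEF``.
    Returns ``(table, limiting_species_or_'undetermined')``.
    """
    if not _is_mechanistic(model):
        raise ValueError("limiting-species scan applies to mechanistic models")
    if which not in ("both", "Cdc42", "BemGEF"):
        raise ValueError(f"unknown scan mode {which!r}")
    grid = grid if grid is not None else default_grid(model, half=True)
    rows = []
    for m in multipliers:
        amount: float | dict[str, float]
        amount = m if which == "both" else {which: m}
        prep = prepare_single_peak(model, grid, amount, seed=seed, config=config,
                                   controls=controls)
        row = {"amount": m, "no_peak": prep.no_peak}
        for sp in ("Cdc42Dc", "BemGEFc"):
            row[f"basal_{sp}"] = prep.basal.get(sp, math.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[~table["no_peak"]]
    limiting = "undetermined"
    if len(ok) >= 2:
        plateaus = {}
        for sp in ("Cdc42Dc", "BemGEFc"):
            col = ok[f"basal_{sp}"].to_numpy()
            rel_inc = (col[-1] - col[-2]) / max(abs(col[-2]), 1e-300)
            plateaus[sp] = rel_inc < plateau_threshold
        flagged = [sp for sp, flat in plateaus.items() if flat]
        if len(flagged) == 1:
            limiting = {"Cdc42Dc": "Cdc42", "BemGEFc": "BemGEF"}[flagged[0]]
    return table, limiting


def competition_time_curve(
    model: ModelSpec,
    total_amounts: tuple[float, ...],
    split: tuple[float, float] = (0.6, 0.4),
    grid: Grid | None = None,
    seed: int = 0,
    config: AssayConfig = AssayConfig(),
    controls: SolverControls | None = None,
) -> pd.DataFrame:
    """Competition time (70:30 -> 99:1) vs total protein amount, the two
    subsystems holding ``split`` shares of the total.  Censored entries
    (thresholds not reached by t_max) carry NaN time plus the reason."""
    rows = []
    for total in total_amounts:
        amounts = (split[0] * total, split[1] * total)
        res = competition_assay(model, amounts, grid=grid, seed=seed,
                                config=config, controls=controls)
        t, reason = competition_time(res.trace)
        rows.append({
            "amount": total,
            "competition_time": math.nan if t is None else t,
            "censored": t is None,
            "reason": reason,
            "outcome": res.outcome.label,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phase diagram and basal-difference predictor


@dataclass
class PhaseDiagram:
    """Outcome labels and basal-substrate differences over a
    (indirect-substrate diffusivity x total amount) sweep."""

    Dvi_values: tuple[float, ...]
    amount_values: tuple[float, ...]
    labels: np.ndarray        # (nD, nA) object array of outcome labels
    delta_v: np.ndarray       # basal v at the 0.6 peak minus the 0.4 peak
    table: pd.DataFrame       # long format: Dvi, amount, label, delta_v, seed

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def phase_diagram(
    Dvi_values: tuple[float, ...],
    amount_values: tuple[float, ...],
    split: tuple[float, float] = (0.6, 0.4),
    base_params: dict[str, float] | None = None,
    grid: Grid | None = None,
    seed: int = 0,
    config: AssayConfig = AssayConfig(),
    controls: SolverControls | None = None,
) -> PhaseDiagram:
    """Sweep the indirect-substrate model over diffusivity and total amount.

    Each cell runs a 0.6:0.4 competition assay and records the dynamical
    outcome together with the difference in basal substrate between the two
    prepared peaks.  Per-cell failures are recorded as label 'error' and
    the sweep continues.
    """
    if len(Dvi_values) < 2 or len(amount_values) < 2:
        raise ValueError("sweep needs at least a 2x2 grid of cells")
    base = dict(base_params or {})
    labels = np.empty((len(Dvi_values), len(amount_values)), dtype=object)
    delta = np.full((len(Dvi_values), len(amount_values)), np.nan)
    rows = []
    for i, Dvi in enumerate(Dvi_values):
        model = make_indirect_model(Dvi=Dvi, **base)
        for j, total in enumerate(amount_values):
            amounts = (split[0] * total, split[1] * total)
            cell_seed = seed + 97 * i + 7919 * j
            try:
                res = competition_assay(model, amounts, grid=grid, seed=cell_seed,
                                        config=config, controls=controls)
                lab = res.outcome.label
                dv = res.delta_basal["v"]
            except Exception as exc:  # record and continue
                lab, dv = "error", math.nan
                rows.append({"Dvi": Dvi, "amount": total, "label": lab,
                             "delta_v": dv, "censored": False,
                             "seed": cell_seed, "error": str(exc)})
                labels[i, j] = lab
                continue
            labels[i, j] = lab
            delta[i, j] = dv
            rows.append({"Dvi": Dvi, "amount": total, "label": lab,
                         "delta_v": dv, "censored": res.outcome.censored,
                         "seed": cell_seed, "error": ""})
    return PhaseDiagram(tuple(Dvi_values), tuple(amount_values), labels, delta,
                        pd.DataFrame(rows))


def predict_from_delta(delta_v: float, band: float = 1e-4) -> str:
    """Outcome predicted by the sign of the basal substrate difference
    (larger-amount peak minus smaller): substrate higher at the smaller
    peak feeds the larger one (competition); higher at the larger peak
    feeds the smaller one (equalization); near-zero differences mean
    negligible net flux (coexistence)."""
    if delta_v > band:
        return "equalization"
    if delta_v < -band:
        return "competition"
    return "coexistence"


def basal_difference_predictor(
    model: ModelSpec,
    amounts: tuple[float, float] = (0.4, 0.6),
    grid: Grid | None = None,
    seed: int = 0,
    band: float = 1e-4,
    config: AssayConfig = AssayConfig(),
    controls: SolverControls | None = None,
) -> tuple[float, str]:
    """Basal substrate difference between two insulated single-peak steady
    states (larger amount minus smaller) and the predicted outcome."""
    grid = grid if grid is not None else default_grid(model)
    nx = grid.shape[0]
    gh = Grid((nx // 2, *grid.shape[1:]), (grid.lengths[0] / 2, *grid.lengths[1:]),
              bc="noflux")
    prep_a = prepare_single_peak(model, gh, amounts[0], seed=seed,
                                 config=config, controls=controls)
    prep_b = prepare_single_peak(model, gh, amounts[1], seed=seed + 1,
                                 config=config, controls=controls)
    if prep_a.no_peak or prep_b.no_peak:
        raise RuntimeError("single-peak preparation failed for the predictor")
    sub = "v" if model.name in ("minimal", "indirect") else "BemGEFc"
    larger, smaller = (prep_b, prep_a) if amounts[1] >= amounts[0] else (prep_a, prep_b)
    dv = larger.basal[sub] - smaller.basal[sub]
    return dv, predict_from_delta(dv, band)
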