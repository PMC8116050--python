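"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: canonical model
parameter tables and assay presets (shipped as YAML inside the package),
noise-perturbed homogeneous fields for symmetry breaking, scripted
competition traces realizing each outcome label (classifier ground truth),
and noisy exponential FRAP traces with the generating parameters recorded
alongside.

All stochastic operations take an explicit seed; there is no hidden
global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .models import ModelSpec, make_model
from .frap_fit import FIT_MODELS
from .peaks import CompetitionTrace
from .solver import FieldState, Grid

__all__ = [
    "FixtureCatalog",
    "load_catalog",
    "model_from_catalog",
    "noisy_initial_condition",
    "synthetic_frap_trace",
    "synthetic_competition_trace",
]


@dataclass(frozen=True)
class FixtureCatalog:
    """Named parameter tables and assay presets."""

    models: dict[str, dict[str, float]]
    presets: dict[str, dict]

    def model_names(self) -> list[str]:
        return sorted(self.models)

    def preset_names(self) -> list[str]:
        return sorted(self.presets)


def load_catalog() -> FixtureCatalog:
    """Load the packaged fixture catalog."""
    text = resources.files("mcaspol").joinpath("fixtures.yaml").read_text()
    data = yaml.safe_load(text)
    return FixtureCatalog(models=data["models"], presets=data["presets"])


def model_from_catalog(name: str, catalog: FixtureCatalog | None = None,
                       **overrides: float) -> ModelSpec:
    """Instantiate a model from its catalog parameter table."""
    catalog = catalog or load_catalog()
    if name not in catalog.models:
        raise KeyError(f"no model {name!r} in the fixture catalog")
    params = dict(catalog.models[name])
    params.update(overrides)
    if name.startswith("mechanistic"):
        return make_model(name, params)
    return make_model(name, params)


def noisy_initial_condition(
    model: ModelSpec,
    grid: Grid,
    total_amount: float | dict[str, float],
    amplitude: float = 0.01,
    seed: int = 0,
) -> FieldState:
    """Homogeneous cytosolic state with seeded multiplicative substrate noise.

    Totals are renormalized to the request exactly (to ~1e-12 relative).
    ``amplitude`` must lie in [0, 0.1]; zero returns the exact homogeneous
    state.
    """
    from .assays import initial_condition

    if not (0 <= amplitude <= 0.1):
        raise ValueError("noise amplitude must lie in [0, 0.1]")
    return initial_condition(model, grid, total_amount, seed=seed,
                             noise_amplitude=amplitude, bump_position=None,
                             seed_factor=0.0)


@dataclass
class FrapTruth:
    """A synthetic FRAP trace plus the parameters that generated it."""

    times: np.ndarray
    values: np.ndarray                # noisy trace
    noiseless: np.ndarray
    model_kind: str
    true_params: dict[str, float]
    noise_sigma: float
    seed: int


def synthetic_frap_trace(
    model_kind: str,
    true_params: dict[str, float],
    noise_sigma: float = 0.0,
    n_points: int = 15,
    t_max: float = 10.0,
    seed: int = 0,
    spacing: str = "uniform",
) -> FrapTruth:
    """Generate a FRAP trace from a designated exponential form.

    ``spacing='uniform'`` places samples evenly on [0, t_max];
    ``'geometric'`` concentrates early samples, mimicking acquisition
    tuned to a ~1 s half-time.
    """
    if n_points < 6:
        raise ValueError("need at least 6 samples")
    if model_kind not in FIT_MODELS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if true_params.get("k", 1.0) <= 0:
        raise ValueError("true rate constant k must be positive")
    fn, names = FIT_MODELS[model_kind]
    missing = set(names) - set(true_params)
    if missing:
        raise ValueError(f"missing parameters for {model_kind}: {sorted(missing)}")
    if spacing == "uniform":
        t = np.linspace(0.0, t_max, n_points)
    elif spacing == "geometric":
        t = t_max * (np.geomspace(1.0, 11.0, n_points) - 1.0) / 10.0
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    clean = fn(t, *(true_params[n] for n in names))
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.normal(0.0, noise_sigma, size=t.shape) if noise_sigma > 0
                     else 0.0)
    return FrapTruth(times=t, values=noisy, noiseless=clean,
                     model_kind=model_kind, true_params=dict(true_params),
                     noise_sigma=noise_sigma, seed=seed)


def synthetic_competition_trace(
    schedule: list[tuple[float, tuple[float, ...]]],
    peak_counts: list[int] | None = None,
    sample_dt: float = 2.0,
    initial_peak_count: int = 2,
) -> CompetitionTrace:
    """Piecewise-linear fraction schedules realizing each outcome label.

    ``schedule`` is a list of ``(time, fractions)`` knots; fractions are
    interpolated linearly between knots and sampled every ``sample_dt``.
    ``peak_counts`` optionally gives the raw detected peak count at each
    knot (default: the number of nonzero fractions).
    """
    if len(schedule) < 2:
        raise ValueError("schedule needs at least two knots")
    knot_t = np.array([s[0] for s in schedule])
    knot_f = np.array([s[1] for s in schedule])
    if np.any(np.diff(knot_t) <= 0):
        raise ValueError("knot times must be strictly increasing")
    times = np.arange(knot_t[0], knot_t[-1] + 1e-9, sample_dt)
    fr = np.stack([np.interp(times, knot_t, knot_f[:, i])
                   for i in range(knot_f.shape[1])])
    if peak_counts is None:
        counts = (fr > 1e-9).sum(axis=0)
    else:
        kc = np.array(peak_counts, dtype=float)
        counts = np.round(np.interp(times, knot_t, kc)).astype(int)
    return CompetitionTrace(
        times=times, fractions=fr, peak_counts=np.asarray(counts),
        meta={"initial_peak_count": initial_peak_count, "synthetic": True},
    )
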