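"""Normalization and exponential fitting of FRAP intensity traces.

Raw traces are normalized against an unbleached reference cell and the
local background:

    I_normalized = (I_raw - I_background) / (I_unbleached - I_background)

Three fit models cover the assay sites: ``decay`` (a e^{-kt} + c) for a
site losing intensity to the bleached zone, ``recovery`` (-a e^{-kt} + c)
for the bleach site itself, and ``two_term`` (a e^{-k t} + b e^{k2 t} + d)
for sites with mixed kinetics (e.g. across a neck); ``k2`` is an
independent rate with unconstrained sign.  The recovery half-time is
T_1/2 = ln(2)/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "normalize_trace",
    "fit_trace",
    "half_time",
    "FIT_MODELS",
]


def normalize_trace(
    raw: np.ndarray,
    background: np.ndarray | float,
    unbleached: np.ndarray | float,
    eps: float = 1e-12,
) -> np.ndarray:
    """Elementwise (raw - background) / (unbleached - background)."""
    raw = np.asarray(raw, dtype=float)
    background = np.broadcast_to(np.asarray(background, dtype=float), raw.shape)
    unbleached = np.broadcast_to(np.asarray(unbleached, dtype=float), raw.shape)
    denom = unbleached - background
    if np.any(np.abs(denom) < eps):
        raise ValueError("unbleached reference equals background (division by ~0)")
    return (raw - background) / denom


def half_time(k: float) -> float:
    """Recovery half-time T_1/2 = ln(2)/k."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return math.log(2.0) / k


def _decay(t, a, k, c):
    return a * np.exp(-k * t) + c


def _recovery(t, a, k, c):
    return -a * np.exp(-k * t) + c


def _two_term(t, a, k, b, k2, d):
    return a * np.exp(-k * t) + b * np.exp(k2 * t) + d


FIT_MODELS = {
    "decay": (_decay, ("a", "k", "c")),
    "recovery": (_recovery, ("a", "k", "c")),
    "two_term": (_two_term, ("a", "k", "b", "k2", "d")),
}


@dataclass
class FitResult:
    kind: str
    params: dict[str, float]
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    residual_norm: float
    r_squared: float
    converged: bool
    half_time: float | None = None
    message: str = ""
    meta: dict = field(default_factory=dict)

    def predict(self, t: np.ndarray) -> np.ndarray:
        fn, names = FIT_MODELS[self.kind]
        return fn(np.asarray(t, dtype=float), *(self.params[n] for n in names))


def _tail_log_rate(t: np.ndarray, y: np.ndarray, asymptote: float) -> float:
    """Deterministic initial guess for k: log-linear regression of
    |y - asymptote| against t over the samples where it is resolvable."""
    dev = np.abs(y - asymptote)
    floor = max(1e-12, 1e-3 * float(dev.max()))
    sel = dev > floor
    if sel.sum() < 3:
        sel = np.ones_like(dev, dtype=bool)
    slope = np.polyfit(t[sel], np.log(np.maximum(dev[sel], floor)), 1)[0]
    k0 = -slope
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 1.0 / max(t[-1] - t[0], 1e-6)
    return float(k0)


def _two_term_guess(t: np.ndarray, y: np.ndarray) -> list[float]:
    """Sequential initial guess for the (weakly identified) two-term model:
    fit the fast decay first, then read the slow component off the residual
    at three points.  Deterministic."""
    c0 = float(np.mean(y[-max(3, len(y) // 5):]))
    amp0 = float(y[0] - c0)
    k0 = _tail_log_rate(t, y, c0)
    try:
        (a1, k1, c1), _ = optimize.curve_fit(
            _decay, t, y, p0=[max(abs(amp0), 1e-6), k0, c0],
            bounds=([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=5000, method="trf")
    except (RuntimeError, ValueError):
        return [amp0 if amp0 != 0 else 1e-3, k0, 1e-3, -0.1 * k0, c0]
    resid = y - a1 * np.exp(-k1 * t)
    # read the slow component where the fast decay has died out
    sel = t >= t[0] + 4.0 / k1
    ts, rs = (t[sel], resid[sel]) if sel.sum() >= 5 else (t, resid)
    T = ts[-1] - ts[0]
    if T <= 0:
        return [float(a1), float(k1), 1e-3, -0.1 * float(k1), float(c1)]
    r0 = float(np.mean(rs[:2]))
    rm = float(np.interp(ts[0] + T / 2, ts, rs))
    r1 = float(np.mean(rs[-2:]))
    ratio = (r1 - rm) / (rm - r0) if abs(rm - r0) > 1e-12 else 1.0
    if ratio > 1e-6 and abs(ratio - 1.0) > 1e-9:
        k2 = 2.0 / T * math.log(ratio)
        q = math.exp(k2 * ts[0])
        denom = math.exp(k2 * (ts[0] + T)) - q
        b = (r1 - r0) / denom if abs(denom) > 1e-12 else 1e-3
        d = r0 - b * q
    else:
        k2, b, d = -0.1 * k1, 1e-3, r0
    return [float(a1), float(k1), float(b), float(k2), float(d)]


def fit_trace(
    times: np.ndarray,
    values: np.ndarray,
    kind: str = "recovery",
    initial_guess: dict[str, float] | None = None,
) -> FitResult:
    """Nonlinear least-squares fit of a FRAP trace.

    Deterministic: initial guesses come from the trace asymptote and a
    log-linear regression on the deviation from it.  A trace whose sign of
    dynamics contradicts the requested model (e.g. a rising trace passed as
    ``decay``) is returned as a flagged failure rather than an exception.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be matching 1D arrays")
    if len(t) < 6:
        raise ValueError("need at least 6 samples to fit")
    if kind not in FIT_MODELS:
        raise ValueError(f"unknown model kind {kind!r}")
    fn, names = FIT_MODELS[kind]

    c0 = float(np.mean(y[-max(3, len(y) // 5):]))  # asymptote from the tail
    amp0 = float(y[0] - c0)
    k0 = _tail_log_rate(t, y, c0)

    wrong_sign = (kind == "decay" and amp0 < 0) or (kind == "recovery" and amp0 > 0)

    if kind == "decay":
        p0 = [max(amp0, 1e-12), k0, c0]
        bounds = ([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
    elif kind == "recovery":
        p0 = [max(-amp0, 1e-12), k0, c0]
        bounds = ([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
    else:  # two_term: decay component + independent (sign-free) second rate
        p0 = _two_term_guess(t, y)
        bounds = ([-np.inf, 1e-12, -np.inf, -np.inf, -np.inf],
                  [np.inf, np.inf, np.inf, np.inf, np.inf])
        wrong_sign = False
    if initial_guess:
        p0 = [initial_guess.get(n, v) for n, v in zip(names, p0)]

    def _failure(msg: str) -> FitResult:
        return FitResult(kind=kind, params=dict(zip(names, p0)),
                         stderr={}, ci95={}, residual_norm=math.inf,
                         r_squared=0.0, converged=False, message=msg)

    if wrong_sign:
        return _failure(f"trace dynamics have the wrong sign for a {kind} model")

    try:
        popt, pcov = optimize.curve_fit(fn, t, y, p0=p0, bounds=bounds,
                                        maxfev=20000, method="trf")
    except (RuntimeError, ValueError) as exc:
        return _failure(f"fit did not converge: {exc}")

    resid = y - fn(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(t) - len(popt), 1)
    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    tq = stats.t.ppf(0.975, dof)
    params = dict(zip(names, map(float, popt)))
    stderr = dict(zip(names, map(float, perr)))
    ci95 = {n: (params[n] - tq * stderr[n], params[n] + tq * stderr[n]) for n in names}

    ht = None
    if params.get("k", 0.0) > 0:
        ht = half_time(params["k"])
    return FitResult(kind=kind, params=params, stderr=stderr, ci95=ci95,
                     residual_norm=math.sqrt(ss_res), r_squared=r2,
                     converged=True, half_time=ht,
                     meta={"dof": dof, "n": len(t)})
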