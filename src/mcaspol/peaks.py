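"""Peak detection, mass partition, basal substrate levels, and outcome
classification for polarity simulations.

A peak is a local maximum of the activator field with sufficient
prominence relative to the field range.  The domain is partitioned into
watershed regions at the inter-peak activator minima (1D) or by basin
assignment (2D); each peak's mass is the integral of the activator over
its region, so mass fractions always sum to one.

The fate of a two-peak initial condition is classified as one of:
``competition`` (one peak absorbs the other), ``coexistence`` (unequal
peaks persist), ``equalization`` (peaks converge to equal mass),
``peaks_split`` (a peak splits in two), or ``homogeneous`` (the pattern
decays).  Competition time is the time taken for the relative activator
share to evolve from 70%:30% to 99%:1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solver import Grid

__all__ = [
    "PeakSet",
    "CompetitionTrace",
    "OutcomeLabel",
    "detect_peaks",
    "basal_level",
    "competition_time",
    "classify_outcome",
    "HOMOGENEITY_EPS",
]

HOMOGENEITY_EPS = 1e-3  # (max-min)/mean below this counts as homogeneous


@dataclass
class PeakSet:
    """Detected activator peaks with their watershed mass partition."""

    grid: Grid
    positions: list[tuple[int, ...]]       # argmax index per peak
    amplitudes: np.ndarray                 # activator value at each peak
    masses: np.ndarray                     # integral of activator per region
    fractions: np.ndarray                  # masses / total
    regions: np.ndarray                    # int label array, -1 where no peaks

    @property
    def n_peaks(self) -> int:
        return len(self.positions)

    def position_coords(self, i: int) -> tuple[float, ...]:
        h = self.grid.spacing
        return tuple((idx + 0.5) * hh for idx, hh in zip(self.positions[i], h))


def _periodic_local_maxima_1d(f: np.ndarray, periodic: bool) -> list[int]:
    """Local maxima, tolerant of flat plateaus (saturated peaks are mesas).

    Cells at least as high as both neighbors (within a small tolerance of
    the field range) are grouped into contiguous runs; each run yields one
    maximum at its highest cell.
    """
    n = len(f)
    frange = float(f.max() - f.min())
    tol = 1e-6 * frange
    if periodic:
        left = np.roll(f, 1)
        right = np.roll(f, -1)
        cand = (f >= left - tol) & (f >= right - tol)
    else:
        left = np.concatenate([[-np.inf], f[:-1]])
        right = np.concatenate([f[1:], [-np.inf]])
        cand = (f >= left - tol) & (f >= right - tol)
    if not np.any(cand):
        return []
    # group contiguous candidate runs (with wraparound when periodic)
    idx = np.nonzero(cand)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, breaks + 1)
    if periodic and len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs.pop()
    out = []
    for run in runs:
        out.append(int(run[np.argmax(f[run])]))
    return sorted(out)


def detect_peaks(
    activator: np.ndarray,
    grid: Grid,
    min_prominence: float = 0.05,
    min_separation: float | None = None,
) -> PeakSet:
    """Detect activator peaks and partition mass between them.

    ``min_prominence`` is relative to the field range.  A field whose
    relative range falls below the homogeneity epsilon yields zero peaks.
    """
    f = np.asarray(activator, dtype=float)
    if f.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    frange = float(f.max() - f.min())
    fmean = float(np.abs(f).mean())
    empty = PeakSet(grid, [], np.array([]), np.array([]), np.array([]),
                    -np.ones(grid.shape, dtype=int))
    if fmean <= 0 or frange < HOMOGENEITY_EPS * fmean:
        return empty

    if grid.ndim == 1:
        return _detect_1d(f, grid, min_prominence, min_separation, frange)
    return _detect_2d(f, grid, min_prominence, min_separation, frange)


def _detect_1d(f, grid, min_prominence, min_separation, frange) -> PeakSet:
    periodic = grid.bc == "periodic" and not grid.walls
    n = len(f)
    maxima = _periodic_local_maxima_1d(f, periodic)
    if not maxima:
        return PeakSet(grid, [], np.array([]), np.array([]), np.array([]),
                       -np.ones(grid.shape, dtype=int))
    maxima = sorted(maxima)

    # region boundaries at minima between adjacent peaks (circular if periodic)
    def interval_min(a: int, b: int) -> int:
        """argmin of f on the open arc from a to b (wrapping if periodic)."""
        if a < b:
            seg = np.arange(a + 1, b)
        else:
            seg = np.concatenate([np.arange(a + 1, n), np.arange(0, b)])
        if len(seg) == 0:
            return b
        return int(seg[np.argmin(f[seg])])

    # prominence filter: peak height above the higher of its two flanking minima
    while True:
        k = len(maxima)
        if k == 0:
            break
        if k == 1:
            prominences = [frange]
        else:
            prominences = []
            for i, p in enumerate(maxima):
                left = maxima[i - 1]
                right = maxima[(i + 1) % k]
                # only saddles toward neighboring peaks count: beyond a
                # no-flux wall there is no higher terrain, so the
                # boundary-side flank contributes no saddle
                mins = []
                if periodic or 0 < i:
                    mins.append(f[interval_min(left, p)])
                if periodic or i < k - 1:
                    mins.append(f[interval_min(p, right)])
                prominences.append(float(f[p]) - max(mins) if mins else frange)
        weakest = int(np.argmin(prominences))
        if prominences[weakest] >= min_prominence * frange or k == 1:
            break
        maxima.pop(weakest)

    # minimum separation: merge peaks closer than the threshold, keep the taller
    if min_separation is not None and len(maxima) > 1:
        h = grid.spacing[0]
        changed = True
        while changed and len(maxima) > 1:
            changed = False
            for i in range(len(maxima)):
                j = (i + 1) % len(maxima)
                a, b = maxima[i], maxima[j]
                d = (b - a) % n if periodic else abs(b - a)
                if d * h < min_separation:
                    maxima.pop(i if f[a] < f[b] else j)
                    changed = True
                    break

    k = len(maxima)
    regions = np.zeros(n, dtype=int)
    vol = grid.cell_volume
    if k == 1:
        masses = np.array([f.sum() * vol])
    else:
        bounds = []  # region of peak i: [bounds[i-1], bounds[i])
        for i in range(k):
            a, b = maxima[i], maxima[(i + 1) % k]
            bounds.append(interval_min(a, b))
        masses = np.zeros(k)
        for i in range(k):
            start = bounds[i - 1]
            stop = bounds[i]
            if periodic:
                if start < stop:
                    idx = np.arange(start, stop)
                else:
                    idx = np.concatenate([np.arange(start, n), np.arange(0, stop)])
            else:
                lo = 0 if i == 0 else bounds[i - 1]
                hi = n if i == k - 1 else bounds[i]
                idx = np.arange(lo, hi)
            regions[idx] = i
            masses[i] = f[idx].sum() * vol
    total = masses.sum()
    fractions = masses / total if total > 0 else masses
    return PeakSet(grid, [(m,) for m in maxima], f[np.array(maxima)].copy(),
                   masses, fractions, regions)


def _detect_2d(f, grid, min_prominence, min_separation, frange) -> PeakSet:
    from scipy import ndimage
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    periodic = grid.bc == "periodic" and not grid.walls
    h = grid.spacing
    min_dist = 1
    if min_separation is not None:
        min_dist = max(1, int(round(min_separation / max(h))))
    thr = float(f.min()) + min_prominence * frange
    if periodic:
        # detect on a wrapped copy and map back to the fundamental domain
        nx, ny = f.shape
        big = np.pad(f, ((nx // 2, nx // 2), (ny // 2, ny // 2)), mode="wrap")
        pts = peak_local_max(big, min_distance=min_dist, threshold_abs=thr,
                             exclude_border=False)
        pts = (pts - np.array([nx // 2, ny // 2])) % np.array([nx, ny])
        pts = np.unique(pts, axis=0)
        # keep only genuine local maxima in the wrapped sense
        keep = []
        for (i, j) in pts:
            nb = big[i + nx // 2 - 1:i + nx // 2 + 2, j + ny // 2 - 1:j + ny // 2 + 2]
            if f[i, j] >= nb.max() - 1e-15:
                keep.append((i, j))
        pts = np.array(keep, dtype=int).reshape(-1, 2)
    else:
        pts = peak_local_max(f, min_distance=min_dist, threshold_abs=thr,
                             exclude_border=False)
    if len(pts) == 0:
        return PeakSet(grid, [], np.array([]), np.array([]), np.array([]),
                       -np.ones(grid.shape, dtype=int))
    markers = np.zeros(f.shape, dtype=int)
    for lab, (i, j) in enumerate(pts, start=1):
        markers[i, j] = lab
    labels = watershed(-f, markers) - 1
    vol = grid.cell_volume
    k = len(pts)
    masses = ndimage.sum_labels(f, labels, index=np.arange(k)) * vol
    total = masses.sum()
    fractions = masses / total if total > 0 else masses
    amplitudes = np.array([f[i, j] for (i, j) in pts])
    return PeakSet(grid, [tuple(p) for p in pts], amplitudes, masses, fractions, labels)


def basal_level(substrate: np.ndarray, peaks: PeakSet, peak_index: int = 0) -> float:
    """Substrate concentration just outside a peak's activator dip.

    Measured at the grid point of the peak's watershed region farthest from
    the peak center, where the substrate profile is flat (for an insulated
    single-peak subdomain this is the subdomain edge).
    """
    grid = peaks.grid
    sub = np.asarray(substrate, dtype=float)
    if sub.shape != grid.shape:
        raise ValueError("substrate shape does not match grid")
    if not (0 <= peak_index < peaks.n_peaks):
        raise IndexError("peak index out of range")
    mask = peaks.regions == peak_index
    if mask.sum() < 3:
        raise ValueError("peak region narrower than 3 grid points")
    periodic = grid.bc == "periodic" and not grid.walls
    pos = peaks.positions[peak_index]
    if grid.ndim == 1:
        idx = np.nonzero(mask)[0]
        d = np.abs(idx - pos[0])
        if periodic:
            d = np.minimum(d, grid.shape[0] - d)
        far = idx[np.argmax(d)]
        return float(sub[far])
    ii, jj = np.nonzero(mask)
    dx = np.abs(ii - pos[0]).astype(float)
    dy = np.abs(jj - pos[1]).astype(float)
    if periodic:
        dx = np.minimum(dx, grid.shape[0] - dx)
        dy = np.minimum(dy, grid.shape[1] - dy)
    hx, hy = grid.spacing
    d2 = (dx * hx) ** 2 + (dy * hy) ** 2
    k = int(np.argmax(d2))
    return float(sub[ii[k], jj[k]])


# ---------------------------------------------------------------------------
# competition traces and outcome classification


@dataclass
class CompetitionTrace:
    """Tracked per-peak activator mass fractions over time.

    ``fractions`` follow the tracked identities (used for competition-time
    crossings); ``raw_top2`` holds the two largest identity-free mass
    fractions per sample, which remain meaningful when transient splits
    degrade the identity bookkeeping.
    """

    times: np.ndarray                # (nt,)
    fractions: np.ndarray            # (n_tracked, nt); columns sum to 1 (or 0)
    peak_counts: np.ndarray          # raw detected peak count per sample
    raw_top2: np.ndarray | None = None  # (2, nt) largest raw fractions
    meta: dict = field(default_factory=dict)

    @property
    def n_tracked(self) -> int:
        return self.fractions.shape[0]

    def final_fractions(self) -> np.ndarray:
        return self.fractions[:, -1]


class PeakTracker:
    """Tracks peak identity across frames by mass-weighted region overlap.

    Overlap between a current watershed region and a previous identity is
    weighted by the previous frame's activator field, so identity follows
    the peak core rather than the (area-dominated) basin — when a loser
    vanishes, the survivor's domain-spanning basin still maps to the
    winning peak's identity.  Ties break by peak-position proximity.  A
    vanished peak keeps its identity with fraction 0; a frame with more
    peaks than tracked identities marks a split (extra mass is credited to
    the overlapping identity, and the raw count records the split).
    """

    def __init__(self, initial: PeakSet, activator: np.ndarray):
        self.n_ids = initial.n_peaks
        self.id_regions = initial.regions.copy()  # identity label per cell
        self.prev_field = np.asarray(activator, dtype=float).copy()
        self.grid = initial.grid

    def assign(self, current: PeakSet, activator: np.ndarray) -> np.ndarray:
        """Fractions per tracked identity for the current frame."""
        frac = np.zeros(self.n_ids)
        if current.n_peaks == 0:
            return frac
        field = np.asarray(activator, dtype=float)
        new_id_regions = np.full(self.id_regions.shape, -1, dtype=int)
        for r in range(current.n_peaks):
            mask = current.regions == r
            overlaps = np.array([
                float(self.prev_field[mask & (self.id_regions == i)].sum())
                for i in range(self.n_ids)
            ])
            if overlaps.max() <= 0:
                ident = int(np.argmin([_dist(current.positions[r], p, self.grid)
                                       for p in _id_argmaxes(self.id_regions, self.n_ids)]))
            else:
                best = np.nonzero(overlaps == overlaps.max())[0]
                ident = int(best[0])
            frac[ident] += current.fractions[r]
            new_id_regions[mask] = ident
        # cells not covered keep their previous identity (handles vanished peaks)
        keep = new_id_regions < 0
        new_id_regions[keep] = self.id_regions[keep]
        self.id_regions = new_id_regions
        self.prev_field = field.copy()
        return frac


def _id_argmaxes(id_regions: np.ndarray, n_ids: int) -> list[tuple[int, ...]]:
    out = []
    for i in range(n_ids):
        idx = np.argwhere(id_regions == i)
        out.append(tuple(idx[len(idx) // 2]) if len(idx) else (0,) * id_regions.ndim)
    return out


def _dist(p: tuple[int, ...], q: tuple[int, ...], grid: Grid) -> float:
    d = 0.0
    for a, b, n, h in zip(p, q, grid.shape, grid.spacing):
        dd = abs(a - b)
        if grid.bc == "periodic" and not grid.walls:
            dd = min(dd, n - dd)
        d += (dd * h) ** 2
    return d ** 0.5


def _crossing_time(times: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First upward crossing of ``level``, linearly interpolated."""
    above = y >= level
    if above[0]:
        return float(times[0])
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    t0, t1 = times[i], times[i + 1]
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def competition_time(trace: CompetitionTrace,
                     start_ratio: float = 0.70,
                     end_ratio: float = 0.99) -> tuple[float | None, str]:
    """Time to evolve from 70%:30% to 99%:1% of the activator share.

    Returns ``(time, reason)``; time is None when either threshold is not
    crossed within the trace (reason explains which).
    """
    if trace.n_tracked > 2:
        raise ValueError("competition time is defined for two tracked peaks; "
                         "handle splits via classify_outcome")
    if trace.n_tracked < 2:
        return None, "fewer than two tracked peaks"
    winner = int(np.argmax(trace.final_fractions()))
    y = trace.fractions[winner]
    t70 = _crossing_time(trace.times, y, start_ratio)
    if t70 is None:
        return None, f"{start_ratio:.0%} share never reached"
    t99 = _crossing_time(trace.times, y, end_ratio)
    if t99 is None:
        return None, f"{end_ratio:.0%} share not reached before t={trace.times[-1]:g}"
    return t99 - t70, "ok"


@dataclass(frozen=True)
class OutcomeLabel:
    label: str  # competition | coexistence | equalization | peaks_split | homogeneous
    censored: bool = False
    metrics: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover
        return self.label + (" (censored)" if self.censored else "")


def _is_settled(times: np.ndarray, fr: np.ndarray, window_frac: float = 0.1,
                tol: float = 0.005) -> bool:
    """Fractions changed by less than ``tol`` over the trailing window."""
    if len(times) < 3:
        return True
    t_end = times[-1]
    w0 = t_end - window_frac * (t_end - times[0])
    sel = times >= w0
    if sel.sum() < 2:
        sel[-2:] = True
    seg = fr[:, sel]
    return float(np.max(seg.max(axis=1) - seg.min(axis=1))) <= tol


def classify_outcome(
    trace: CompetitionTrace,
    t_max: float = 2000.0,
    equality_band: float = 0.01,
    win_threshold: float = 0.99,
) -> OutcomeLabel:
    """Classify a two-peak run: competition / coexistence / equalization /
    peaks_split / homogeneous.

    Equalization requires both fractions within 50% +/- ``equality_band``
    and settled; coexistence requires unequal fractions staying within
    +/- ``equality_band`` of their initial values through ``t_max``.  A run
    still drifting at ``t_max`` without meeting any rule is labeled
    coexistence with ``censored=True``.
    """
    fr = trace.fractions
    counts = trace.peak_counts
    final = trace.final_fractions()
    # identity-free fractions survive transient splits; fall back to the
    # tracked identities for traces that do not carry them
    raw = trace.raw_top2 if trace.raw_top2 is not None else fr[:2]
    n0 = trace.meta.get("initial_peak_count", trace.n_tracked)
    metrics = {
        "final_fractions": final.tolist(),
        "final_raw_fractions": raw[:, -1].tolist(),
        "max_peak_count": int(counts.max()) if len(counts) else 0,
        "t_end": float(trace.times[-1]),
    }

    if len(counts) and counts[-1] == 0:
        return OutcomeLabel("homogeneous", metrics=metrics)
    # every outcome rule describes the end state, so splitting is judged on
    # the final peak count; transient splits during reorganization are
    # recorded in the metrics but do not mask the final outcome
    if len(counts) and counts[-1] > n0:
        return OutcomeLabel("peaks_split", metrics=metrics)

    if counts[-1] == 1 or raw[0, -1] >= win_threshold:
        metrics["time_of_decision"] = _crossing_time(
            trace.times, fr[int(np.argmax(final))], win_threshold)
        return OutcomeLabel("competition", metrics=metrics)
    settled = _is_settled(trace.times, raw)
    if counts[-1] == 2 and np.all(np.abs(raw[:, -1] - 0.5) <= equality_band) \
            and settled:
        return OutcomeLabel("equalization", metrics=metrics)
    start = fr[:, 0]
    # genuine coexistence: fractions stay within the band of their starting
    # values through the whole run; anything still drifting at t_max gets a
    # censored tag (it has no settled dynamical label)
    if np.max(np.abs(fr - start[:, None])) <= equality_band:
        return OutcomeLabel("coexistence", metrics=metrics)
    return OutcomeLabel("coexistence", censored=True, metrics=metrics)
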