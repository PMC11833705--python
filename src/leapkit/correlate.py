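"""Temporal and spatial correlation of classified fluctuation events.

Rare-event timing is summarized by fitting the exponential law

    P_{n>=1}(τ) = 1 − exp(−τ / τ*)

to per-center mean inter-event intervals (or to counts of one event type
preceding another), where τ* is the characteristic scale of the underlying
Poisson process.  Spatial structure comes from cross-class distance
densities, the radial distribution function g(r), neighbor-mean scatter
pairs, and event-aligned χ traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .leap import LEAPSeries
from .trajectory_io import (
    NeighborLists,
    ParticleTrajectory,
    minimum_image_displacement,
)

__all__ = [
    "CdfFit",
    "SpatialCorrelation",
    "interevent_intervals",
    "fit_exponential_cdf",
    "counts_before_event",
    "cross_distance_distribution",
    "rdf",
    "spike_coincidence",
    "neighbor_mean_scatter",
    "align_at_first_event",
]


@dataclass
class CdfFit:
    """Exponential CDF fit 1 − e^(−τ/τ*) to a positive scalar sample."""

    samples: np.ndarray
    tau_star: float
    method: str
    residual: float

    def cdf(self, tau: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.asarray(tau, float) / self.tau_star)

    @property
    def empirical(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted samples and plotting positions k/(n+1)."""
        s = np.sort(self.samples)
        return s, np.arange(1, len(s) + 1) / (len(s) + 1.0)


@dataclass
class SpatialCorrelation:
    """Distance grid plus a density (unit area) or g(r) curve."""

    r: np.ndarray  # bin centers
    density: np.ndarray
    kind: str = "density"  # "density" | "gr"
    edges: np.ndarray | None = None
    stderr: np.ndarray | None = None


def interevent_intervals(
    events: pd.DataFrame,
    per_center_mean: bool = True,
    before_first_of: pd.DataFrame | None = None,
) -> np.ndarray:
    """Intervals between successive event start times.

    With ``per_center_mean`` (the two-stage construction used for the CDFs)
    one mean interval is returned per center having >= 2 events; otherwise
    all intervals are pooled.  With ``before_first_of`` set, only events
    starting strictly before that center's first event of the other type
    are considered (structural fluctuations preceding the diffusive event).
    """
    ev = events
    if before_first_of is not None and len(before_first_of):
        firsts = before_first_of.groupby("center_id")["start_time"].min()
        cut = ev["center_id"].map(firsts)
        ev = ev[cut.isna() | (ev["start_time"] < cut)]
    out = []
    for _, grp in ev.groupby("center_id"):
        starts = np.sort(grp["start_time"].to_numpy())
        if len(starts) < 2:
            continue
        iv = np.diff(starts)
        out.append(iv.mean() if per_center_mean else iv)
    if not out:
        raise ValueError("no center has at least 2 qualifying events")
    return np.asarray(out) if per_center_mean else np.concatenate(out)


def fit_exponential_cdf(samples: np.ndarray, method: str = "mle") -> CdfFit:
    """Fit τ* of P = 1 − e^(−τ/τ*).

    ``mle``: τ* is the sample mean (the exponential MLE).  ``least_squares``:
    τ* minimizes the squared deviation between the model and the empirical
    CDF at plotting positions k/(n+1).
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) == 0 or (x <= 0).any():
        raise ValueError("samples must be positive")
    s = np.sort(x)
    p_emp = np.arange(1, len(s) + 1) / (len(s) + 1.0)

    def sse(tau: float) -> float:
        return float(np.sum((1.0 - np.exp(-s / tau) - p_emp) ** 2))

    if method == "mle":
        tau = float(x.mean())
    elif method == "least_squares":
        res = minimize_scalar(sse, bounds=(1e-12, 100.0 * x.mean()), method="bounded")
        tau = float(res.x)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return CdfFit(samples=x, tau_star=tau, method=method, residual=np.sqrt(sse(tau)))


def counts_before_event(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    windowed: bool = True,
) -> tuple[np.ndarray, CdfFit]:
    """Counts of a-events preceding each b-event on the same center.

    For each b-event, the number of a-events on that center starting
    strictly before it — since the previous b-event when ``windowed`` (the
    default), since the beginning otherwise.  The positive counts are
    fitted with the exponential CDF form in the count variable to give a
    characteristic number n*.
    """
    if len(events_b) == 0:
        raise ValueError("no b-events")
    shared = np.intersect1d(events_a["center_id"].unique(),
                            events_b["center_id"].unique())
    counts = []
    a_by_center = {c: np.sort(g["start_time"].to_numpy())
                   for c, g in events_a.groupby("center_id")}
    for c, grp in events_b.groupby("center_id"):
        if c not in a_by_center:
            continue
        a_starts = a_by_center[c]
        b_starts = np.sort(grp["start_time"].to_numpy())
        prev = -np.inf
        for b in b_starts:
            lo = prev if windowed else -np.inf
            counts.append(int(((a_starts > lo) & (a_starts < b)).sum()))
            prev = b
    counts = np.asarray(counts, dtype=float)
    positive = counts[counts > 0]
    if len(positive) == 0:
        raise ValueError("no b-event is preceded by any a-event")
    return counts, fit_exponential_cdf(positive, method="mle")


def _pair_hist(dists: np.ndarray, bins: int | np.ndarray) -> SpatialCorrelation:
    hist, edges = np.histogram(dists, bins=bins, density=True)
    return SpatialCorrelation(
        r=0.5 * (edges[:-1] + edges[1:]), density=hist, kind="density", edges=edges
    )


def cross_distance_distribution(
    traj: ParticleTrajectory,
    labels: np.ndarray,
    class_a: int,
    class_b: int,
    centers: np.ndarray,
    t0_frame: int = 1,
    a_unit: float | None = None,
    bins: int | np.ndarray | None = None,
) -> SpatialCorrelation:
    """Density of minimum-image distances between class-a and class-b units.

    ``labels`` is the (n_centers, n_steps) quadrant/state label array; per
    step, all a-to-b distances in the step's arrival frame are pooled over
    the trajectory and histogrammed to unit area.  The distance axis is
    rescaled by ``a_unit`` when given (e.g. the first-neighbor spacing).
    """
    labels = np.asarray(labels)
    idx = traj.index_of(centers)
    dists = []
    for s in range(labels.shape[1]):
        f = t0_frame + s
        ia = idx[labels[:, s] == class_a]
        ib = idx[labels[:, s] == class_b]
        if len(ia) == 0 or len(ib) == 0:
            continue
        box_f = traj.box[f] if traj.box is not None else None
        delta = traj.positions[f, ia][:, None, :] - traj.positions[f, ib][None, :, :]
        delta = minimum_image_displacement(delta, box_f, traj.periodic)
        d = np.linalg.norm(delta, axis=-1).ravel()
        dists.append(d[d > 0])
    if not dists:
        raise ValueError("one of the classes is never occupied")
    dists = np.concatenate(dists)
    if a_unit is not None:
        dists = dists / a_unit
    if bins is None:
        bins = max(10, min(100, _freedman_diaconis(dists)))
    return _pair_hist(dists, bins)


def _freedman_diaconis(x: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr == 0:
        return 10
    h = 2 * iqr / len(x) ** (1 / 3)
    return int(np.ceil(np.ptp(x) / h))


def rdf(
    traj: ParticleTrajectory,
    subset: np.ndarray | None = None,
    r_max: float | None = None,
    bins: int = 100,
    frames: np.ndarray | None = None,
) -> SpatialCorrelation:
    """Radial distribution function g(r) of a unit subset.

    Pair distances are binned and normalized by the ideal-gas shell count
    at the subset's number density; requires a periodic box.  The standard
    error per bin follows Poisson counting statistics.
    """
    if traj.box is None or not traj.periodic.all():
        raise ValueError("g(r) normalization requires a fully periodic box")
    ids = traj.ids if subset is None else np.asarray(list(subset), np.int64)
    if len(ids) < 2:
        raise ValueError("need at least 2 subset units")
    idx = traj.index_of(ids)
    frames = np.arange(traj.n_frames) if frames is None else np.asarray(frames)
    half = 0.5 * traj.box.min()
    if r_max is None:
        r_max = 0.95 * half
    if r_max > half:
        raise ValueError("r_max exceeds half the smallest box edge")
    edges = np.linspace(0.0, r_max, bins + 1)
    counts = np.zeros(bins)
    n = len(idx)
    vol_sum = 0.0
    for f in frames:
        box_f = traj.box[f]
        pos = np.mod(traj.positions[f, idx], box_f)
        tree = cKDTree(pos, boxsize=box_f)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs):
            delta = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            delta = minimum_image_displacement(delta, box_f, traj.periodic)
            d = np.linalg.norm(delta, axis=1)
            counts += np.histogram(d, bins=edges)[0]
        vol_sum += np.prod(box_f)
    vol = vol_sum / len(frames)
    rho = n / vol
    if traj.dim == 3:
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    else:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    ideal = 0.5 * n * rho * shell * len(frames)
    g = counts / ideal
    se = np.sqrt(np.maximum(counts, 1.0)) / ideal
    return SpatialCorrelation(
        r=0.5 * (edges[:-1] + edges[1:]), density=g, kind="gr", edges=edges,
        stderr=se,
    )


def spike_coincidence(events: pd.DataFrame, window: float) -> tuple[np.ndarray, float]:
    """Pairwise |Δstart| between events (across centers) and the fraction
    of pairs within ``window``."""
    starts = events["start_time"].to_numpy(dtype=float)
    if len(starts) < 2:
        raise ValueError("need at least 2 events")
    offsets = np.abs(starts[:, None] - starts[None, :])
    offsets = offsets[np.triu_indices(len(starts), k=1)]
    return offsets, float((offsets <= window).mean())


def neighbor_mean_scatter(
    leap: LEAPSeries,
    neighbors: NeighborLists,
    own: str = "lens",
    other: str = "tsoap",
) -> pd.DataFrame:
    """Own-component value vs. mean of the other component over neighbors.

    For every (center, step) with a defined own value and at least one
    valued neighbor among the current neighbor list, one row pairs the
    center's own value with the arithmetic mean of the other component over
    its instantaneous neighbors; centers with no valued neighbor are
    skipped.
    """
    own_vals = getattr(leap, own)
    other_vals = getattr(leap, other)
    pos_of = {int(c): k for k, c in enumerate(leap.centers)}
    rows = []
    for s in range(leap.n_steps):
        lists = neighbors.lists[min(s + 1, neighbors.n_frames - 1)]
        for c, cid in enumerate(neighbors.centers):
            k = pos_of.get(int(cid))
            if k is None or not np.isfinite(own_vals[k, s]):
                continue
            nb = [pos_of[int(j)] for j in lists[c] if int(j) in pos_of]
            vals = other_vals[nb, s] if nb else np.empty(0)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            rows.append((int(cid), s, own_vals[k, s], float(vals.mean())))
    return pd.DataFrame(rows, columns=["center_id", "step", own, f"neighbor_mean_{other}"])


def align_at_first_event(
    chi: np.ndarray,
    events: pd.DataFrame,
    centers: np.ndarray,
    window: int,
    t0_frame: int = 1,
    include: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack χ traces re-indexed to each center's first event start.

    Returns ``(offsets, traces, mean_trace)`` with ``offsets`` spanning
    ``−window .. +window`` steps around t0 (the first event start per
    center); positions outside the series are NaN.  ``include`` optionally
    restricts the centers (e.g. those spending a minimum duration in the
    mixed domain).
    """
    chi = np.asarray(chi)
    centers = np.asarray(centers)
    firsts = events.groupby("center_id")["start_frame"].min()
    if include is not None:
        firsts = firsts[firsts.index.isin(np.asarray(include))]
    firsts = firsts[firsts.index.isin(centers)]
    if len(firsts) == 0:
        raise ValueError("no qualifying centers")
    pos_of = {int(c): k for k, c in enumerate(centers)}
    offsets = np.arange(-window, window + 1)
    traces = np.full((len(firsts), len(offsets)), np.nan)
    for row, (cid, f0) in enumerate(firsts.items()):
        s0 = int(f0) - t0_frame
        for col, off in enumerate(offsets):
            s = s0 + off
            if 0 <= s < chi.shape[1]:
                traces[row, col] = chi[pos_of[int(cid)], s]
    with np.errstate(invalid="ignore"):
        mean_trace = np.nanmean(traces, axis=0)
    return offsets, traces, mean_trace
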