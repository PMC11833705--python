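"""Dynamical-domain identification and discrete event extraction.

Descriptor distributions are summarized by a Gaussian KDE; its peaks seed a
small Gaussian-mixture state model whose states describe background
dynamical domains (e.g. crystal vs. liquid).  Values falling outside the
central 95% interval of *every* state are outliers — the relevant, rare
fluctuations.  Alternatively, explicit (or KDE-tail-derived) thresholds on
the two LEAP components split the phase plane into four quadrants:
quiescent, LENS-dominated, τSOAP-dominated, and mixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .leap import LEAPSeries

__all__ = [
    "KdeProfile",
    "StateModel",
    "kde_profile",
    "fit_states",
    "tail_threshold",
    "leap_quadrants",
    "extract_events",
    "QUADRANT_LABELS",
]

#: Quadrant label codes used throughout; −1 marks a missing step.
QUADRANT_LABELS = ("quiescent", "lens_dominated", "tsoap_dominated", "mixed")
QUIESCENT, LENS_DOMINATED, TSOAP_DOMINATED, MIXED = range(4)
MISSING = -1

OUTLIER = -1  # state-model outlier code


@dataclass
class KdeProfile:
    """Gaussian KDE evaluated on a uniform grid, with located extrema."""

    grid: np.ndarray
    density: np.ndarray
    maxima: np.ndarray  # x-locations, sorted
    minima: np.ndarray  # interior minima x-locations, sorted
    bandwidth: float


def kde_profile(values: np.ndarray, bandwidth: float | None = None,
                grid_size: int = 512) -> KdeProfile:
    """Gaussian KDE (Scott's-rule default bandwidth) plus local extrema.

    The grid spans [min, max] of the finite sample.  Raises on a degenerate
    (constant) sample.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need at least 10 finite values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    kde = gaussian_kde(x, bw_method=bandwidth)
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    from scipy.signal import find_peaks

    # prominence filter suppresses numerical micro-wiggles of the KDE curve
    prom = 0.01 * dens.max()
    maxima = list(grid[find_peaks(dens, prominence=prom)[0]])
    minima = list(grid[find_peaks(-dens, prominence=prom)[0]])
    if dens[0] > dens[1] and dens[0] - dens.min() > prom:
        maxima.insert(0, grid[0])
    if dens[-1] > dens[-2] and dens[-1] - dens.min() > prom:
        maxima.append(grid[-1])
    return KdeProfile(
        grid=grid, density=dens, maxima=np.asarray(maxima),
        minima=np.asarray(minima),
        bandwidth=float(kde.factor * x.std(ddof=1)),
    )


@dataclass
class StateModel:
    """Gaussian summary of the KDE peaks plus a CI-based outlier rule.

    States are sorted by increasing mean; ``predict`` assigns each value the
    maximum-likelihood state, or the OUTLIER code (−1) when the value lies
    outside the central ``ci`` interval of every state.
    """

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    ci_z: float = 1.96
    thresholds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, float)[order]
        self.sigmas = np.asarray(self.sigmas, float)[order]
        self.weights = np.asarray(self.weights, float)[order]
        self.weights = self.weights / self.weights.sum()

    @property
    def n_states(self) -> int:
        return len(self.means)

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Per-value state index, OUTLIER (−1) outside every state's CI."""
        x = np.asarray(values, dtype=float)
        z = (x[..., None] - self.means) / self.sigmas
        loglik = np.log(self.weights) - 0.5 * z**2 - np.log(self.sigmas)
        labels = np.argmax(loglik, axis=-1)
        outlier = (np.abs(z) > self.ci_z).all(axis=-1)
        labels = np.where(outlier, OUTLIER, labels)
        return np.where(np.isfinite(x), labels, MISSING)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "means": self.means.tolist(),
                "sigmas": self.sigmas.tolist(),
                "weights": self.weights.tolist(),
                "ci_z": self.ci_z,
                "thresholds": self.thresholds,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, text: str | Path) -> "StateModel":
        if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text
                                      and Path(text).exists()):
            text = Path(text).read_text()
        d = json.loads(text)
        thr = d.get("thresholds")
        return cls(
            means=np.asarray(d["means"]), sigmas=np.asarray(d["sigmas"]),
            weights=np.asarray(d["weights"]), ci_z=d.get("ci_z", 1.96),
            thresholds=tuple(thr) if thr is not None else None,
        )


def fit_states(values: np.ndarray, k: int | None = None,
               ci_z: float = 1.96, random_state: int = 0) -> StateModel:
    """Fit k Gaussian states to a scalar sample (k defaults to KDE peaks).

    A Gaussian mixture is initialized at the KDE maxima and refined by EM.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct values")
    prof = kde_profile(x)
    n_peaks = max(len(prof.maxima), 1)
    if k is None:
        k = n_peaks
    if k > n_peaks + 1:
        raise ValueError(f"k={k} exceeds KDE maxima count + 1 ({n_peaks + 1})")
    from sklearn.mixture import GaussianMixture

    if len(prof.maxima) >= k:
        heights = np.interp(prof.maxima, prof.grid, prof.density)
        seeds = prof.maxima[np.argsort(heights)[::-1][:k]]
    else:
        seeds = np.quantile(x, np.linspace(0.1, 0.9, k))
    gm = GaussianMixture(
        n_components=k, means_init=np.sort(seeds)[:, None],
        random_state=random_state, n_init=1,
    ).fit(x[:, None])
    return StateModel(
        means=gm.means_.ravel(),
        sigmas=np.sqrt(gm.covariances_.ravel()),
        weights=gm.weights_.ravel(),
        ci_z=ci_z,
    )


def tail_threshold(values: np.ndarray, tail_fraction: float = 0.02,
                   bandwidth: float | None = None) -> float:
    """Threshold isolating the upper tail beyond the dominant KDE peak.

    Returns the value above which the KDE-smoothed distribution holds
    ``tail_fraction`` of its mass, constrained to lie above the dominant
    (highest) peak; separates background vibration from relevant
    fluctuations.
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    prof = kde_profile(x, bandwidth=bandwidth, grid_size=2048)
    heights = np.interp(prof.maxima, prof.grid, prof.density)
    if len(heights) > 1:
        top = np.sort(heights)[::-1]
        if np.isclose(top[0], top[1], rtol=1e-3):
            raise ValueError("multi-modal ambiguity: two dominant peaks of equal height")
    mode = prof.maxima[np.argmax(heights)]
    # tail mass from the KDE on an extended grid (the KDE leaks past max(x))
    kde = gaussian_kde(x, bw_method=bandwidth)
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 4 * bw, x.max() + 4 * bw, 4096)
    dens = kde(grid)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    target = 1.0 - tail_fraction
    k = int(np.searchsorted(cdf, target))
    thr = grid[min(k, len(grid) - 1)]
    return float(max(thr, mode))


def leap_quadrants(leap: LEAPSeries, lens_thr: float, tsoap_thr: float) -> np.ndarray:
    """Per-step quadrant labels from explicit component thresholds.

    Boundaries are inclusive on the quiescent side: a point exactly at the
    thresholds is quiescent.  Returns an ``(n_centers, n_steps)`` int array
    with codes indexing :data:`QUADRANT_LABELS`; missing steps are −1.
    """
    if not (0 < lens_thr < 1 and 0 < tsoap_thr < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    hi_l = leap.lens > lens_thr
    hi_t = leap.tsoap > tsoap_thr
    labels = np.full(leap.lens.shape, QUIESCENT, dtype=int)
    labels[hi_l & ~hi_t] = LENS_DOMINATED
    labels[~hi_l & hi_t] = TSOAP_DOMINATED
    labels[hi_l & hi_t] = MIXED
    labels[leap.missing] = MISSING
    return labels


def extract_events(
    labels: np.ndarray,
    target: int | str,
    centers: np.ndarray,
    dt: float = 1.0,
    t0_frame: int = 1,
    event_type: str | None = None,
) -> pd.DataFrame:
    """Maximal contiguous runs of the target label as an event table.

    Returns a DataFrame with columns ``center_id, event_type, start_frame,
    end_frame, start_time, end_time`` — events of the same type on the same
    center are disjoint and maximal by construction.
    """
    if isinstance(target, str):
        event_type = event_type or target
        target = QUADRANT_LABELS.index(target)
    elif event_type is None:
        event_type = QUADRANT_LABELS[target] if 0 <= target < 4 else str(target)
    labels = np.asarray(labels)
    rows = []
    for c, cid in enumerate(np.asarray(centers)):
        hit = np.flatnonzero(labels[c] == target)
        if len(hit) == 0:
            continue
        breaks = np.flatnonzero(np.diff(hit) > 1)
        starts = np.concatenate([[hit[0]], hit[breaks + 1]])
        ends = np.concatenate([hit[breaks], [hit[-1]]])
        for s, e in zip(starts, ends):
            rows.append((int(cid), event_type, int(s + t0_frame), int(e + t0_frame)))
    df = pd.DataFrame(rows, columns=["center_id", "event_type", "start_frame", "end_frame"])
    df["start_time"] = df["start_frame"] * dt
    df["end_time"] = df["end_frame"] * dt
    return df
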