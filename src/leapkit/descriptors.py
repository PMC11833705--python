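"""Per-center LENS and τSOAP time-series, with smoothing and normalization.

LENS (δ) measures neighbor-identity turnover between consecutive frames:

    δ_i(t+Δt) = #(C_i^t ∪ C_i^{t+Δt} − C_i^t ∩ C_i^{t+Δt}) / #(C_i^t + C_i^{t+Δt})

with C_i^t the set of neighbor ids within rcut.  It is permutationally
variant but structurally invariant: a unit that swaps places with a distant
twin scores δ = 1 even though the geometry is unchanged.

τSOAP (λ) measures the frame-to-frame change of the L2-normalized SOAP
environment vector:

    λ_i(t+Δt) = sqrt(2 − 2 p̂_i^t · p̂_i^{t+Δt})  ∈ [0, √2]

— the Euclidean distance between consecutive unit vectors.  It is
permutationally invariant but structurally variant: identity swaps leave it
at zero, geometric rearrangements raise it.

Both series are optionally smoothed by a centered moving average and
min-max normalized over the whole dataset (all centers jointly) so that the
two components live on a common [0, 1] scale before being combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .soap import SoapCalculator
from .trajectory_io import NeighborLists, ParticleTrajectory, minimum_image_displacement

__all__ = [
    "DescriptorSeries",
    "SoapSeries",
    "lens",
    "soap_spectrum",
    "tau_soap",
    "smooth",
    "normalize",
]

RAW, SMOOTHED, NORMALIZED = "raw", "smoothed", "normalized"


@dataclass
class DescriptorSeries:
    """Per-center scalar time-series for one descriptor.

    ``values`` has shape ``(n_centers, n_steps)`` with ``n_steps =
    n_frames − 1``: the value at step ``s`` describes the transition from
    frame ``t0_frame − 1 + s`` to frame ``t0_frame + s``.  Missing steps
    (e.g. flagged zero SOAP vectors) are NaN.
    """

    kind: str  # "lens" | "tsoap"
    values: np.ndarray
    centers: np.ndarray
    dt: float = 1.0
    t0_frame: int = 1
    state: str = RAW
    meta: dict = field(default_factory=dict)
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.centers = np.asarray(self.centers, dtype=np.int64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.centers):
            raise ValueError("values must have shape (n_centers, n_steps)")

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def step_frames(self) -> np.ndarray:
        """Frame index each step describes (the arrival frame)."""
        return self.t0_frame + np.arange(self.n_steps)

    @property
    def step_times(self) -> np.ndarray:
        return self.step_frames * self.dt

    def denormalize(self) -> "DescriptorSeries":
        """Invert min-max normalization using the recorded bounds."""
        if self.state != NORMALIZED or self.bounds is None:
            raise ValueError("series is not normalized")
        lo, hi = self.bounds
        return replace(self, values=self.values * (hi - lo) + lo, state=SMOOTHED,
                       bounds=None)

    def save(self, prefix: str | Path) -> None:
        """Write a binary array container plus a sidecar metadata text file."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.values)
        meta = {
            "kind": self.kind, "dt": self.dt, "t0_frame": self.t0_frame,
            "state": self.state, "bounds": self.bounds,
            "centers": self.centers.tolist(), **self.meta,
        }
        import json

        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


@dataclass
class SoapSeries:
    """L2-normalized SOAP vectors per center per frame.

    ``vectors`` has shape ``(n_centers, n_frames, n_features)``; centers
    with an empty environment in a frame keep a zero vector and are flagged
    in ``empty`` rather than normalized.
    """

    vectors: np.ndarray
    empty: np.ndarray
    centers: np.ndarray
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[1]


def lens(neighbors: NeighborLists) -> DescriptorSeries:
    """Raw LENS series from per-frame neighbor lists.

    By convention a step between two empty lists scores 0 (no environment,
    no change); a one-sided empty list follows the formula and scores 1.
    """
    if neighbors.n_frames < 2:
        raise ValueError("need at least 2 frames of neighbor lists")
    n_steps = neighbors.n_frames - 1
    out = np.zeros((neighbors.n_centers, n_steps))
    for s in range(n_steps):
        prev, curr = neighbors.lists[s], neighbors.lists[s + 1]
        for c in range(neighbors.n_centers):
            a, b = prev[c], curr[c]
            denom = len(a) + len(b)
            if denom == 0:
                continue
            inter = len(np.intersect1d(a, b, assume_unique=True))
            union = denom - inter
            out[c, s] = (union - inter) / denom
    return DescriptorSeries(
        kind="lens", values=out, centers=neighbors.centers, dt=neighbors.dt,
        meta={"rcut": neighbors.rcut},
    )


def soap_spectrum(
    traj: ParticleTrajectory,
    centers: Sequence[int] | None = None,
    rcut: float = 1.0,
    n_max: int = 8,
    l_max: int = 8,
    sigma: float | None = None,
    candidates: Sequence[int] | None = None,
) -> SoapSeries:
    """L2-normalized SOAP power spectra per center per frame.

    2D trajectories are embedded at z = 0.  Centers with no neighbor inside
    ``rcut`` get a zero vector, flagged in ``empty``.
    """
    centers = traj.ids if centers is None else np.asarray(list(centers), dtype=np.int64)
    candidates = traj.ids if candidates is None else np.asarray(list(candidates), dtype=np.int64)
    calc = SoapCalculator(rcut=rcut, n_max=n_max, l_max=l_max, sigma=sigma)
    c_idx = traj.index_of(centers)
    k_idx = traj.index_of(candidates)
    from scipy.spatial import cKDTree

    from .trajectory_io import _tree_coords

    vectors = np.zeros((len(centers), traj.n_frames, calc.n_features))
    empty = np.zeros((len(centers), traj.n_frames), dtype=bool)
    for f in range(traj.n_frames):
        box_f = traj.box[f] if traj.box is not None else None
        pos, boxsize = _tree_coords(traj.positions[f], box_f, traj.periodic, rcut)
        tree = cKDTree(pos[k_idx], boxsize=boxsize)
        hits = tree.query_ball_point(pos[c_idx], r=rcut)
        rels, counts = [], np.zeros(len(c_idx), dtype=int)
        for c, (ci, hit) in enumerate(zip(c_idx, hits)):
            nb = k_idx[np.asarray(hit, dtype=int)] if len(hit) else np.empty(0, int)
            nb = nb[nb != ci]
            counts[c] = len(nb)
            if len(nb) == 0:
                empty[c, f] = True
                continue
            rel = minimum_image_displacement(
                traj.positions[f, nb] - traj.positions[f, ci], box_f, traj.periodic
            )
            if traj.dim == 2:
                rel = np.column_stack([rel, np.zeros(len(rel))])
            rels.append(rel)
        stacked = np.concatenate(rels) if rels else np.empty((0, 3))
        vecs = calc.batch_power_spectra(stacked, counts)
        norms = np.linalg.norm(vecs, axis=1)
        zero = norms == 0.0
        empty[:, f] |= zero
        vectors[~zero, f] = vecs[~zero] / norms[~zero, None]
    return SoapSeries(
        vectors=vectors, empty=empty, centers=centers, dt=traj.dt,
        meta={"rcut": rcut, "n_max": calc.n_max, "l_max": calc.l_max,
              "sigma": calc.sigma},
    )


def tau_soap(soap: SoapSeries) -> DescriptorSeries:
    """Raw τSOAP series: distance between consecutive SOAP unit vectors.

    Inner products are clamped to [−1, 1] before the square root so rounding
    never produces NaN; steps touching a flagged empty environment are
    missing (NaN) and propagate.
    """
    if soap.n_frames < 2:
        raise ValueError("need at least 2 frames of SOAP vectors")
    dots = np.einsum("cfk,cfk->cf", soap.vectors[:, :-1], soap.vectors[:, 1:])
    dots = np.clip(dots, -1.0, 1.0)
    vals = np.sqrt(2.0 - 2.0 * dots)
    bad = soap.empty[:, :-1] | soap.empty[:, 1:]
    vals[bad] = np.nan
    return DescriptorSeries(
        kind="tsoap", values=vals, centers=soap.centers, dt=soap.dt,
        meta=dict(soap.meta),
    )


def smooth(series: DescriptorSeries, width: int) -> DescriptorSeries:
    """Centered moving average with truncated edge windows.

    Missing values are excluded from each window's average; ``width = 1`` is
    the identity.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > series.n_steps:
        raise ValueError("smoothing width exceeds series length")
    if width == 1:
        return replace(series, state=SMOOTHED,
                       meta={**series.meta, "smooth_width": 1})
    sm = (
        pd.DataFrame(series.values.T)
        .rolling(window=width, center=True, min_periods=1)
        .mean()
        .to_numpy()
        .T
    )
    return replace(series, values=sm, state=SMOOTHED,
                   meta={**series.meta, "smooth_width": width})


def normalize(series: DescriptorSeries) -> DescriptorSeries:
    """Min-max rescale to [0, 1] over the whole dataset (all centers).

    The (min, max) bounds are recorded so the map can be inverted.  A
    constant series maps to all-zeros with a warning.
    """
    finite = np.isfinite(series.values)
    if not finite.any():
        raise ValueError("all values are missing")
    lo = float(np.nanmin(series.values))
    hi = float(np.nanmax(series.values))
    if hi == lo:
        warnings.warn("constant descriptor series normalized to all-zeros")
        vals = np.where(finite, 0.0, np.nan)
    else:
        vals = (series.values - lo) / (hi - lo)
    return replace(series, values=vals, state=NORMALIZED, bounds=(lo, hi))
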