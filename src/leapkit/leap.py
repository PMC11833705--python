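"""The bivariate LEAP series and its derived χ parameter and magnitude.

LEAP_i(t) = (δ_i(t), λ_i(t)) pairs the normalized LENS and τSOAP series of
each center.  Two per-step scalars summarize each pair:

    χ = (δ − λ) / (δ + λ)  ∈ [−1, 1]
    magnitude = sqrt(δ² + λ²)  ∈ [0, √2]

χ > 0 flags a LENS-dominated (diffusive) fluctuation, χ < 0 a
τSOAP-dominated (structural) one, χ ≈ 0 simultaneous change of both kinds.
A quiescent step with δ = λ = 0 is assigned χ = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import NORMALIZED, DescriptorSeries

__all__ = ["LEAPSeries", "combine", "chi", "magnitude", "to_table"]


@dataclass
class LEAPSeries:
    """Paired (δ, λ) series with shared centers, step count, and Δt."""

    lens: np.ndarray  # (n_centers, n_steps)
    tsoap: np.ndarray
    centers: np.ndarray
    dt: float = 1.0
    t0_frame: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.lens.shape[1]

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def missing(self) -> np.ndarray:
        return ~(np.isfinite(self.lens) & np.isfinite(self.tsoap))

    @property
    def step_frames(self) -> np.ndarray:
        return self.t0_frame + np.arange(self.n_steps)

    @property
    def step_times(self) -> np.ndarray:
        return self.step_frames * self.dt


def combine(lens: DescriptorSeries, tsoap: DescriptorSeries) -> LEAPSeries:
    """Pair two normalized descriptor series into a LEAP series.

    A step missing in either component is missing in the pair.
    """
    for s, name in ((lens, "lens"), (tsoap, "tsoap")):
        if s.state != NORMALIZED:
            raise ValueError(f"{name} series must be normalized before combining")
    if not np.array_equal(lens.centers, tsoap.centers):
        raise ValueError("component series must share centers")
    if lens.values.shape != tsoap.values.shape:
        raise ValueError("component series must share step count")
    if lens.dt != tsoap.dt or lens.t0_frame != tsoap.t0_frame:
        raise ValueError("component series must share dt and frame origin")
    d = lens.values.copy()
    l = tsoap.values.copy()
    missing = ~(np.isfinite(d) & np.isfinite(l))
    d[missing] = np.nan
    l[missing] = np.nan
    return LEAPSeries(
        lens=d, tsoap=l, centers=lens.centers.copy(), dt=lens.dt,
        t0_frame=lens.t0_frame,
        meta={"lens": dict(lens.meta), "tsoap": dict(tsoap.meta),
              "lens_bounds": lens.bounds, "tsoap_bounds": tsoap.bounds},
    )


def chi(leap: LEAPSeries) -> np.ndarray:
    """Per-center, per-step χ = (δ − λ)/(δ + λ); χ(0, 0) := 0."""
    total = leap.lens + leap.tsoap
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (leap.lens - leap.tsoap) / total, 0.0)
    out[leap.missing] = np.nan
    return out


def magnitude(leap: LEAPSeries) -> np.ndarray:
    """Per-center, per-step Euclidean norm sqrt(δ² + λ²)."""
    return np.hypot(leap.lens, leap.tsoap)


def to_table(leap: LEAPSeries) -> pd.DataFrame:
    """Tidy export: one row per (center, step) with χ and magnitude."""
    nc, ns = leap.lens.shape
    return pd.DataFrame(
        {
            "center_id": np.repeat(leap.centers, ns),
            "frame": np.tile(leap.step_frames, nc),
            "time": np.tile(leap.step_times, nc),
            "lens": leap.lens.ravel(),
            "tsoap": leap.tsoap.ravel(),
            "chi": chi(leap).ravel(),
            "magnitude": magnitude(leap).ravel(),
        }
    )


def from_table(df: pd.DataFrame, dt: float | None = None) -> LEAPSeries:
    """Rebuild a LEAPSeries from the tidy export of :func:`to_table`."""
    centers = np.sort(df["center_id"].unique())
    frames = np.sort(df["frame"].unique())
    wide_l = df.pivot(index="center_id", columns="frame", values="lens")
    wide_t = df.pivot(index="center_id", columns="frame", values="tsoap")
    wide_l = wide_l.loc[centers, frames]
    wide_t = wide_t.loc[centers, frames]
    if dt is None:
        t = df.drop_duplicates("frame").sort_values("frame")
        dts = np.diff(t["time"].to_numpy()) / np.maximum(np.diff(frames), 1)
        dt = float(dts[0]) if len(dts) else 1.0
    return LEAPSeries(
        lens=wide_l.to_numpy(), tsoap=wide_t.to_numpy(), centers=centers,
        dt=dt, t0_frame=int(frames[0]),
    )
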