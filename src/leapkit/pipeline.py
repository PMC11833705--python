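"""One-call pipeline from a trajectory to a LEAP series."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import descriptors as dsc
from .leap import LEAPSeries, combine
from .trajectory_io import ParticleTrajectory, build_neighbor_lists


def compute_leap(
    traj: ParticleTrajectory,
    rcut: float,
    centers: Sequence[int] | None = None,
    candidates: Sequence[int] | None = None,
    smooth_width: int = 1,
    n_max: int = 6,
    l_max: int = 4,
    sigma: float | None = None,
) -> LEAPSeries:
    """Compute the normalized bivariate LEAP series for a trajectory.

    Runs the full descriptor chain: cutoff neighbor lists → raw LENS,
    SOAP vectors → raw τSOAP, centered moving-average smoothing of both,
    dataset-level min-max normalization, and pairing.  SOAP channel counts
    default to modest values (n_max=6, l_max=4) that resolve lattice-scale
    rearrangements; raise them for subtle structural contrast.
    """
    nl = build_neighbor_lists(traj, rcut, centers=centers, candidates=candidates)
    d_raw = dsc.lens(nl)
    soap = dsc.soap_spectrum(
        traj, centers=nl.centers, candidates=candidates, rcut=rcut,
        n_max=n_max, l_max=l_max, sigma=sigma,
    )
    l_raw = dsc.tau_soap(soap)
    d = dsc.normalize(dsc.smooth(d_raw, smooth_width))
    l = dsc.normalize(dsc.smooth(l_raw, smooth_width))
    return combine(d, l)
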