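"""Synthetic trajectories with scripted, ground-truth-labeled local events.

Each generator emulates, at toy scale, one of the phenomenologies the
analysis is designed to resolve: thermal vibration of a lattice (the
quiescent background), identity swaps between distant twins (pure diffusive
fluctuations), neighbor-shell distortions (pure structural fluctuations), a
sliding adatom, collective slip planes, and a traveling activity wave in
2D.  Background noise is i.i.d. Gaussian jitter rather than integrated
dynamics, which keeps events analytically pure: a swap of units farther
apart than 2·rcut changes every neighbor identity while leaving the
position set untouched (LENS = 1, τSOAP = 0), and a tangential distortion
of a center's shell changes the geometry while provably preserving the
center's neighbor list (LENS = 0, τSOAP > 0).

Every injected event is recorded in a tidy ground-truth table
(event_type, frame, id) that mirrors the directives exactly; all
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory_io import ParticleTrajectory, build_neighbor_lists

__all__ = [
    "LatticeSpec",
    "EventScript",
    "make_vibrating_lattice",
    "inject_swap",
    "inject_rearrangement",
    "inject_slider",
    "inject_slip_plane",
    "make_wave_field",
    "make_poisson_event_series",
]


def _truth(event_type: str, frame: int, ids: Sequence[int]) -> pd.DataFrame:
    return pd.DataFrame(
        {"event_type": event_type, "frame": int(frame), "id": list(map(int, ids))}
    )


@dataclass
class LatticeSpec:
    """Simple-cubic (or square) lattice with thermal jitter.

    ``shape`` counts sites per axis, ``spacing`` the lattice constant, and
    ``vibration`` the standard deviation of the i.i.d. per-frame Gaussian
    jitter (must stay below 0.3·spacing so nearest-neighbor ordering holds).
    """

    shape: tuple[int, ...] = (6, 6, 3)
    spacing: float = 1.0
    vibration: float = 0.05
    periodic: bool = True
    dt: float = 1.0

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.shape))

    @property
    def box(self) -> np.ndarray:
        return np.asarray(self.shape, float) * self.spacing


def make_vibrating_lattice(spec: LatticeSpec, n_frames: int, seed: int) -> ParticleTrajectory:
    """Lattice sites plus i.i.d. Gaussian jitter per frame, seeded."""
    if spec.vibration >= 0.3 * spec.spacing:
        raise ValueError("vibration amplitude must stay below 0.3 * spacing")
    rng = np.random.default_rng(seed)
    axes = [np.arange(n) * spec.spacing for n in spec.shape]
    sites = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, spec.dim)
    jitter = rng.normal(0.0, spec.vibration, size=(n_frames, spec.n_sites, spec.dim))
    if spec.vibration == 0:
        jitter[:] = 0.0
    positions = sites[None, :, :] + jitter
    return ParticleTrajectory(
        positions=positions,
        ids=np.arange(spec.n_sites),
        dt=spec.dt,
        box=spec.box if spec.periodic else None,
        periodic=np.full(spec.dim, spec.periodic),
    )


def _mi_distance(traj: ParticleTrajectory, frame: int, i: int, j: int) -> float:
    delta = traj.positions[frame, i] - traj.positions[frame, j]
    if traj.box is not None:
        for ax in np.nonzero(traj.periodic)[0]:
            L = traj.box[frame, ax]
            delta[ax] -= L * np.round(delta[ax] / L)
    return float(np.linalg.norm(delta))


def inject_swap(
    traj: ParticleTrajectory, frame: int, id_a: int, id_b: int, rcut: float
) -> tuple[ParticleTrajectory, pd.DataFrame]:
    """Exchange the positions of two units from ``frame`` on.

    A pure identity permutation: with the two units farther apart than
    2·rcut (enforced), their neighbor lists become disjoint at the swap
    step while the position set is unchanged — the diffusive fluctuation in
    pure form.
    """
    out = traj.copy()
    ia, ib = out.index_of([id_a, id_b])
    if _mi_distance(out, frame, ia, ib) <= 2.0 * rcut:
        raise ValueError("swap partners must be farther apart than 2*rcut")
    tail = out.positions[frame:].copy()
    out.positions[frame:, ia] = tail[:, ib]
    out.positions[frame:, ib] = tail[:, ia]
    return out, _truth("swap", frame, [id_a, id_b])


def inject_rearrangement(
    traj: ParticleTrajectory,
    frame: int,
    center_id: int,
    displacement_scale: float,
    rcut: float,
    seed: int = 0,
    max_tries: int = 8,
    revert_after: int | None = None,
) -> tuple[ParticleTrajectory, pd.DataFrame]:
    """Displace a center's neighbor shell from ``frame`` on, identities kept.

    With ``revert_after`` set, the shell relaxes back to its original
    geometry that many frames later — a transient rattling event rather
    than a permanent distortion.

    Each neighbor within ``rcut`` of the center (in the frame before the
    event) moves by ``displacement_scale`` along a random direction with a
    guaranteed inward radial component (at least 40% of the displacement),
    i.e. a compression-type collapse of the shell: every neighbor's
    distance to the center strictly shrinks, so none can leave the cutoff,
    while random per-neighbor directions break rigidity and the radial
    motion gives the geometry change the environment descriptor is most
    sensitive to.  The center's neighbor list across the event step is
    verified unchanged post hoc (fresh directions are drawn on violation,
    the scale halved as a last resort) so the event is a pure structural
    fluctuation.
    """
    rng = np.random.default_rng(seed)
    out = traj.copy()
    ic = out.index_of([center_id])[0]
    ref = max(frame - 1, 0)

    def _shell(f: int) -> tuple[np.ndarray, np.ndarray]:
        delta = out.positions[f] - out.positions[f, ic]
        if out.box is not None:
            for ax in np.nonzero(out.periodic)[0]:
                L = out.box[f, ax]
                delta[:, ax] -= L * np.round(delta[:, ax] / L)
        return delta, np.linalg.norm(delta, axis=1)

    delta, dist = _shell(ref)
    _, dist_now = _shell(frame)
    # move only the persistent shell: atoms inside rcut on both sides of the
    # transition, so boundary flickers are never dragged across the cutoff
    nb = np.flatnonzero((dist <= rcut) & (dist_now <= rcut) & (dist > 0))
    if len(nb) == 0:
        raise ValueError("center has no neighbors to rearrange")
    base = build_neighbor_lists(out, rcut, centers=[center_id])
    scale = float(displacement_scale)
    if scale == 0.0:
        return out, _truth("rearrange", frame, [center_id])
    for attempt in range(max_tries):
        if attempt >= max_tries // 2:
            scale *= 0.5  # fresh directions first, shrink only as a last resort
        trial = out.copy()
        stop = (min(frame + revert_after, out.n_frames)
                if revert_after is not None else out.n_frames)
        for j in nb:
            axis = delta[j] / dist[j]
            inward = rng.uniform(0.4, 1.0)
            t = rng.normal(size=out.dim)
            t -= t.dot(axis) * axis
            t_norm = np.linalg.norm(t)
            tangential = np.sqrt(1.0 - inward**2)
            v = -inward * axis
            if t_norm > 1e-12:
                v = v + tangential * t / t_norm
            trial.positions[frame:stop, j] += scale * v
        check = build_neighbor_lists(trial, rcut, centers=[center_id])
        # purity holds at the event step: the center's list must not change
        # across the transition (frame-1 -> frame); later flickers are
        # ordinary background dynamics.
        ok = np.array_equal(check.lists[ref][0], base.lists[ref][0]) and np.array_equal(
            check.lists[frame][0], base.lists[frame][0]
        )
        if ok:
            return trial, _truth("rearrange", frame, [center_id])
    raise ValueError("could not find a list-preserving rearrangement")


def inject_slider(
    traj: ParticleTrajectory,
    unit_id: int,
    start_frame: int,
    n_steps: int,
    step_vector: np.ndarray | None = None,
) -> tuple[ParticleTrajectory, pd.DataFrame]:
    """Translate one unit across the lattice, one site per step.

    Emulates the adatom sliding rigidly on a surface: its neighbor
    identities turn over every step (sustained high LENS) while the
    surrounding structural order barely changes.
    """
    out = traj.copy()
    iu = out.index_of([unit_id])[0]
    if n_steps == 0:
        return out, _truth("slide", start_frame, [])
    if start_frame + n_steps >= out.n_frames:
        raise ValueError("slide path exceeds the trajectory length")
    if step_vector is None:
        step_vector = np.zeros(out.dim)
        step_vector[0] = 1.0
    step_vector = np.asarray(step_vector, dtype=float)
    for f in range(start_frame + 1, out.n_frames):
        k = min(f - start_frame, n_steps)
        out.positions[f, iu] = traj.positions[f, iu] + k * step_vector
    if out.box is not None:
        for ax in range(out.dim):
            L = out.box[0, ax]
            if out.periodic[ax]:
                out.positions[:, iu, ax] = np.mod(out.positions[:, iu, ax], L)
            elif (out.positions[:, iu, ax].min() < 0) or (out.positions[:, iu, ax].max() > L):
                raise ValueError("slide path exits the box on a non-periodic axis")
    frames = np.arange(start_frame + 1, start_frame + n_steps + 1)
    truth = pd.DataFrame({"event_type": "slide", "frame": frames, "id": int(unit_id)})
    return out, truth


def inject_slip_plane(
    traj: ParticleTrajectory,
    frame: int,
    axis: int,
    threshold: float,
    shift_vector: np.ndarray,
) -> tuple[ParticleTrajectory, pd.DataFrame]:
    """Rigidly shift all units with ``coord[axis] > threshold`` from ``frame`` on.

    Emulates dislocation slip: every unit adjacent to the slip interface
    sees its neighbor identities change at the same step, so LENS spikes
    are simultaneous and spatially contiguous on the plane.
    """
    out = traj.copy()
    ref = max(frame - 1, 0)
    mask = out.positions[ref, :, axis] > threshold
    if not mask.any():
        raise ValueError("empty plane selection")
    shift = np.asarray(shift_vector, dtype=float)
    out.positions[frame:, mask] += shift
    if out.box is not None:
        for ax in np.nonzero(out.periodic)[0]:
            L = out.box[0, ax]
            out.positions[frame:, :, ax] = np.mod(out.positions[frame:, :, ax], L)
    return out, _truth("slip", frame, out.ids[mask])


def make_wave_field(
    n_particles: int = 900,
    box2d: tuple[float, float] = (30.0, 30.0),
    wave_speed: float = 1.0,
    band_width: float = 5.0,
    n_frames: int = 60,
    seed: int = 0,
    vibration: float = 0.05,
    distortion: float = 0.2,
) -> tuple[ParticleTrajectory, pd.DataFrame]:
    """2D field crossed left-to-right by a traveling activity band.

    Quiescent particles jitter on a square lattice.  When the band front
    reaches a particle it undergoes a reshuffling kick — entering particles
    in the same front column exchange positions with partners several
    spacings away (identity turnover, LENS spike, χ > 0) — and while inside
    the band it rides a sinusoidal compression field that distorts local
    geometry while mostly preserving identities (τSOAP activity, χ < 0).
    Ground truth records each particle's band-entry frame t0.
    """
    if band_width >= box2d[0]:
        raise ValueError("band wider than the box")
    if wave_speed * n_frames < box2d[0] and wave_speed > 0:
        raise ValueError("wave must cross the box within n_frames")
    rng = np.random.default_rng(seed)
    nx = int(round(np.sqrt(n_particles * box2d[0] / box2d[1])))
    ny = max(int(round(n_particles / max(nx, 1))), 1)
    ax = box2d[0] / nx
    ay = box2d[1] / ny
    sites = np.stack(
        np.meshgrid(np.arange(nx) * ax, np.arange(ny) * ay, indexing="ij"), axis=-1
    ).reshape(-1, 2)
    n = len(sites)
    base = np.tile(sites[None, :, :], (n_frames, 1, 1))

    entry = np.full(n, -1, dtype=int)
    if wave_speed > 0:
        # frame at which the front first reaches each site column
        entry = np.clip(np.ceil(sites[:, 0] / wave_speed).astype(int), 1, None)
        duration = max(int(round(band_width / wave_speed)), 1)
        assigned = sites.copy()  # site currently owned by each particle
        for f in range(1, n_frames):
            entering = np.flatnonzero(entry == f)
            if len(entering) >= 2:
                # reshuffling kick: exchange sites with a partner far in y
                order = entering[np.argsort(assigned[entering, 1])]
                partner = np.roll(order, len(order) // 2)
                assigned[order] = assigned[partner]
            base[f] = assigned
            # sinusoidal compression while inside the band (not persisted)
            front = wave_speed * f
            idx = np.flatnonzero((entry <= f) & (f < entry + duration))
            if len(idx):
                phase = 2.0 * np.pi * (assigned[idx, 0] - front) / band_width
                base[f, idx, 0] += distortion * ax * np.sin(phase)
    jitter = rng.normal(0.0, vibration * min(ax, ay), size=(n_frames, n, 2))
    positions = base + jitter
    traj = ParticleTrajectory(
        positions=positions,
        ids=np.arange(n),
        dt=1.0,
        box=np.asarray(box2d),
        periodic=np.array([False, True]),
    )
    valid = (entry > 0) & (entry < n_frames)
    truth = pd.DataFrame(
        {"event_type": "wave_entry", "frame": entry[valid], "id": np.arange(n)[valid]}
    )
    return traj, truth


def make_poisson_event_series(
    n_centers: int, rate: float, horizon: float, seed: int
) -> pd.DataFrame:
    """Event starts drawn per center from a Poisson process of given rate.

    Returns an event table (center_id, event_type, start_frame, end_frame,
    start_time, end_time) with continuous start times (dt = 1); used for
    τ* parameter-recovery checks.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    mu = rate * horizon
    m = max(int(mu + 6.0 * np.sqrt(mu) + 10), 4)
    gaps = rng.exponential(1.0 / rate, size=(n_centers, m))
    starts = np.cumsum(gaps, axis=1)
    # 6-sigma headroom makes truncation astronomically unlikely; top up if hit
    while (starts[:, -1] <= horizon).any():  # pragma: no cover
        extra = rng.exponential(1.0 / rate, size=(n_centers, m))
        starts = np.concatenate([starts, starts[:, -1:] + np.cumsum(extra, axis=1)],
                                axis=1)
    keep = starts <= horizon
    centers = np.repeat(np.arange(n_centers), keep.sum(axis=1))
    times = starts[keep]
    df = pd.DataFrame(
        {"center_id": centers, "event_type": "poisson",
         "start_frame": times, "end_frame": times}
    )
    df["start_time"] = df["start_frame"]
    df["end_time"] = df["end_frame"]
    return df


def make_mixed_event_lattice(
    n_swaps: int = 10,
    n_rearrangements: int = 10,
    seed: int = 0,
    shape: tuple[int, ...] = (7, 7, 4),
    n_frames: int = 60,
    rcut: float = 1.25,
    vibration: float = 0.05,
    displacement: float = 0.45,
) -> tuple[ParticleTrajectory, pd.DataFrame, float]:
    """Vibrating lattice carrying both swap and rearrangement events.

    The classification confusion benchmark: events at distinct frames on
    distinct units, each recorded in the ground-truth table.  Returns
    ``(trajectory, ground_truth, rcut)``.
    """
    spec = LatticeSpec(shape=shape, spacing=1.0, vibration=vibration)
    rng = np.random.default_rng(seed)
    traj = make_vibrating_lattice(spec, n_frames, seed=seed)
    margin = max(n_frames // 12, 2)
    frames = rng.choice(
        np.arange(margin, n_frames - margin),
        size=n_swaps + n_rearrangements, replace=False,
    )
    used: set[int] = set()
    truths = []
    for f in frames[:n_swaps]:
        while True:
            a, b = rng.choice(traj.ids, 2, replace=False)
            if int(a) in used or int(b) in used:
                continue
            try:
                traj, t = inject_swap(traj, int(f), int(a), int(b), rcut=rcut)
            except ValueError:
                continue
            used |= {int(a), int(b)}
            truths.append(t)
            break
    for f in frames[n_swaps:]:
        while True:
            c = int(rng.choice(traj.ids))
            if c in used:
                continue
            try:
                traj, t = inject_rearrangement(
                    traj, int(f), c, displacement, rcut=rcut,
                    seed=int(rng.integers(2**31)), revert_after=2,
                )
            except ValueError:
                continue
            used.add(c)
            truths.append(t)
            break
    truth = pd.concat(truths, ignore_index=True)
    return traj, truth, rcut


# ---------------------------------------------------------------------------
# scripted composition


@dataclass
class EventScript:
    """Ordered event directives applied to a vibrating lattice.

    The seed fully determines the output; the emitted ground-truth table
    matches the directives exactly.  Directives are dictionaries with an
    ``event`` key (swap | rearrange | slide | slip_plane) plus the
    arguments of the corresponding ``inject_*`` function.
    """

    lattice: LatticeSpec
    n_frames: int
    rcut: float
    directives: list[dict] = field(default_factory=list)
    seed: int = 0

    def run(self) -> tuple[ParticleTrajectory, pd.DataFrame]:
        traj = make_vibrating_lattice(self.lattice, self.n_frames, self.seed)
        truths = []
        for k, d in enumerate(self.directives):
            d = dict(d)
            kind = d.pop("event")
            if kind == "swap":
                traj, t = inject_swap(traj, rcut=self.rcut, **d)
            elif kind == "rearrange":
                d.setdefault("seed", self.seed + 1000 + k)
                traj, t = inject_rearrangement(traj, rcut=self.rcut, **d)
            elif kind == "slide":
                traj, t = inject_slider(traj, **d)
            elif kind == "slip_plane":
                traj, t = inject_slip_plane(traj, **d)
            else:
                raise ValueError(f"unknown event type {kind!r}")
            truths.append(t)
        truth = (
            pd.concat(truths, ignore_index=True)
            if truths
            else pd.DataFrame(columns=["event_type", "frame", "id"])
        )
        return traj, truth

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        doc = {
            "lattice": {
                "shape": list(self.lattice.shape),
                "spacing": self.lattice.spacing,
                "vibration": self.lattice.vibration,
                "periodic": self.lattice.periodic,
                "dt": self.lattice.dt,
            },
            "n_frames": self.n_frames,
            "rcut": self.rcut,
            "seed": self.seed,
            "directives": self.directives,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EventScript":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        lat = doc.get("lattice", {})
        return cls(
            lattice=LatticeSpec(
                shape=tuple(lat.get("shape", (6, 6, 3))),
                spacing=float(lat.get("spacing", 1.0)),
                vibration=float(lat.get("vibration", 0.05)),
                periodic=bool(lat.get("periodic", True)),
                dt=float(lat.get("dt", 1.0)),
            ),
            n_frames=int(doc["n_frames"]),
            rcut=float(doc["rcut"]),
            directives=list(doc.get("directives", [])),
            seed=int(doc.get("seed", 0)),
        )
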