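"""Trajectory containers, format readers, and cutoff neighbor lists.

A :class:`ParticleTrajectory` holds per-frame positions of units with
persistent integer identities — the raw material of every downstream
descriptor.  Boxes are orthorhombic (per-frame edge lengths) with per-axis
periodicity flags; triclinic cells are rejected.  Neighbor lists are built
with a kd-tree per frame, which gives near-linear scaling in the number of
units, and distances on periodic axes use the minimum-image convention.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ParticleTrajectory",
    "NeighborLists",
    "read_trajectory",
    "write_trajectory_csv",
    "select_centers",
    "build_neighbor_lists",
]


@dataclass
class ParticleTrajectory:
    """Per-frame positions of tracked units with persistent identities.

    Parameters
    ----------
    positions : ndarray, shape (n_frames, n_units, dim)
        Cartesian coordinates; units (Å, pixels, μm, ...) are carried
        opaquely.
    ids : ndarray, shape (n_units,)
        Persistent integer identity of each column of ``positions``;
        identical across frames (tracked units).
    dt : float
        Physical time between consecutive sampled frames.
    box : ndarray, shape (n_frames, dim), optional
        Orthorhombic box edge lengths per frame; required when any axis is
        periodic.
    periodic : ndarray of bool, shape (dim,), optional
        Per-axis periodicity flags; defaults to all-free boundaries.
    species : ndarray, optional
        Optional per-unit species label, passed through to SOAP.
    """

    positions: np.ndarray
    ids: np.ndarray
    dt: float = 1.0
    box: np.ndarray | None = None
    periodic: np.ndarray | None = None
    species: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (n_frames, n_units, dim)")
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.positions.shape[2] not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.ids.shape != (self.positions.shape[1],):
            raise ValueError("ids must have one entry per unit")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.periodic is None:
            self.periodic = np.zeros(self.dim, dtype=bool)
        else:
            self.periodic = np.asarray(self.periodic, dtype=bool)
            if self.periodic.shape != (self.dim,):
                raise ValueError("periodic must have one flag per axis")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (self.dim,):
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, self.dim):
                raise ValueError("box must have shape (n_frames, dim) or (dim,)")
            if not (self.box > 0).all():
                raise ValueError("box edges must be positive")
        elif self.periodic.any():
            raise ValueError("periodic axes require a box")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_units(self) -> int:
        return self.positions.shape[1]

    @property
    def dim(self) -> int:
        return self.positions.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame times, ``frame_index * dt`` (0-based frames)."""
        return np.arange(self.n_frames) * self.dt

    def index_of(self, ids: Sequence[int]) -> np.ndarray:
        """Column indices of the given ids (error on unknown ids)."""
        order = np.argsort(self.ids)
        pos = np.searchsorted(self.ids, ids, sorter=order)
        pos = np.clip(pos, 0, len(self.ids) - 1)
        idx = order[pos]
        if not np.array_equal(self.ids[idx], np.asarray(ids)):
            missing = sorted(set(np.asarray(ids).tolist()) - set(self.ids.tolist()))
            raise KeyError(f"unknown unit ids: {missing}")
        return idx

    def copy(self) -> "ParticleTrajectory":
        return replace(
            self,
            positions=self.positions.copy(),
            ids=self.ids.copy(),
            box=None if self.box is None else self.box.copy(),
            periodic=self.periodic.copy(),
            species=None if self.species is None else self.species.copy(),
        )

    # -- serialization -----------------------------------------------------

    def to_npz(self, path: str | Path) -> None:
        """Serialize to a single-file ``.npz`` archive."""
        payload: dict[str, np.ndarray] = {
            "positions": self.positions,
            "ids": self.ids,
            "dt": np.asarray(self.dt),
            "periodic": self.periodic,
        }
        if self.box is not None:
            payload["box"] = self.box
        if self.species is not None:
            payload["species"] = np.asarray(self.species)
        np.savez_compressed(path, **payload)

    @classmethod
    def from_npz(cls, path: str | Path) -> "ParticleTrajectory":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                positions=data["positions"],
                ids=data["ids"],
                dt=float(data["dt"]),
                box=data["box"] if "box" in data else None,
                periodic=data["periodic"],
                species=data["species"] if "species" in data else None,
            )


@dataclass
class NeighborLists:
    """Per-frame, per-center sets of neighbor ids within ``rcut``.

    ``lists[f][c]`` is a sorted integer array of candidate ids at
    minimum-image distance ≤ ``rcut`` from center ``centers[c]`` in frame
    ``f`` (the center itself excluded).
    """

    rcut: float
    centers: np.ndarray
    candidates: np.ndarray
    lists: list[list[np.ndarray]]
    dt: float = 1.0

    @property
    def n_frames(self) -> int:
        return len(self.lists)

    @property
    def n_centers(self) -> int:
        return len(self.centers)


# ---------------------------------------------------------------------------
# readers


def _read_csv_trajectory(path: str | Path, *, dt: float = 1.0,
                         box: np.ndarray | None = None,
                         periodic: np.ndarray | None = None) -> ParticleTrajectory:
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "z" in cols:
        coord_cols = ["x", "y", "z"]
    else:
        coord_cols = ["x", "y"]
    required = ["frame", "id"] + coord_cols
    if any(c not in cols for c in required):
        raise ValueError(f"csv must have columns frame,id,x,y[,z]; got {cols}")
    for c in coord_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"non-numeric coordinates in column {c!r}")
    if df.duplicated(subset=["frame", "id"]).any():
        raise ValueError("duplicate (frame, id) rows in csv")
    frames = np.sort(df["frame"].unique())
    ids = np.sort(df.loc[df["frame"] == frames[0], "id"].unique())
    pivots = []
    for f in frames:
        sub = df[df["frame"] == f].sort_values("id")
        if not np.array_equal(sub["id"].to_numpy(), ids):
            raise ValueError(
                f"broken track: frame {f} does not contain exactly the ids of frame {frames[0]}"
            )
        pivots.append(sub[coord_cols].to_numpy(dtype=float))
    return ParticleTrajectory(
        positions=np.stack(pivots), ids=ids, dt=dt, box=box, periodic=periodic
    )


def _box_from_dimensions(dimensions: np.ndarray | None) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if not (dims[:3] > 0).all():
        return None
    if not np.allclose(dims[3:6], 90.0):
        raise ValueError("only orthorhombic boxes are supported (all angles 90°)")
    return dims[:3].copy()


def _read_mdanalysis(path: str | Path, fmt: str, *, topology: str | Path | None = None,
                     dt: float = 1.0, periodic: np.ndarray | None = None) -> ParticleTrajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "xyz":
            u = mda.Universe(str(path), format="XYZ")
        elif fmt == "gro+xtc":
            if topology is None:
                raise ValueError("gro+xtc requires topology=<.gro path>")
            u = mda.Universe(str(topology), str(path))
        elif fmt == "lammps-dump":
            u = mda.Universe(str(path), format="LAMMPSDUMP")
        else:  # pragma: no cover - guarded by caller
            raise ValueError(fmt)
        try:
            ids = np.asarray(u.atoms.ids, dtype=np.int64)
            if len(np.unique(ids)) != len(ids):
                raise ValueError
        except Exception:
            ids = np.arange(u.atoms.n_atoms, dtype=np.int64)
        frames, boxes = [], []
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
            boxes.append(_box_from_dimensions(ts.dimensions))
        species = None
        try:
            species = np.asarray(u.atoms.names)
        except Exception:
            pass
    positions = np.stack(frames)
    box = None
    if all(b is not None for b in boxes):
        box = np.stack(boxes)
        if periodic is None:
            periodic = np.ones(3, dtype=bool)
    return ParticleTrajectory(
        positions=positions, ids=ids, dt=dt, box=box, periodic=periodic,
        species=species,
    )


def read_trajectory(path: str | Path, format: str, **options) -> ParticleTrajectory:
    """Read a trajectory from a standard format.

    Parameters
    ----------
    path : path
        Coordinate file (for ``gro+xtc`` the XTC; pass ``topology=`` for the
        GRO).
    format : {"xyz", "gro+xtc", "lammps-dump", "csv"}
        File dialect.  CSV columns are ``frame,id,x,y[,z]`` with a header.
    **options
        ``dt``, ``box``, ``periodic``, ``topology`` as applicable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv_trajectory(path, **options)
    if format in ("xyz", "gro+xtc", "lammps-dump"):
        return _read_mdanalysis(path, format, **options)
    raise ValueError(f"unknown trajectory format: {format!r}")


def write_trajectory_csv(traj: ParticleTrajectory, path: str | Path,
                         float_format: str = "%.10g") -> None:
    """Write the trajectory as a tidy ``frame,id,x,y[,z]`` CSV."""
    cols = ["x", "y", "z"][: traj.dim]
    nf, nu = traj.n_frames, traj.n_units
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(nf), nu),
            "id": np.tile(traj.ids, nf),
        }
    )
    flat = traj.positions.reshape(nf * nu, traj.dim)
    for k, c in enumerate(cols):
        df[c] = flat[:, k]
    df.to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# center selection and neighbor lists


def select_centers(
    traj: ParticleTrajectory,
    selection: Sequence[int] | Callable[[np.ndarray], np.ndarray],
    frame: int = 0,
) -> np.ndarray:
    """Resolve a center selection to an ordered id subset.

    ``selection`` is either an explicit id list or a spatial predicate
    applied to the positions of ``frame`` (an ``(n_units, dim) -> bool mask``
    callable), e.g. ``lambda xyz: xyz[:, 2] >= z0`` to keep a top layer.
    """
    if callable(selection):
        mask = np.asarray(selection(traj.positions[frame]), dtype=bool)
        if mask.shape != (traj.n_units,):
            raise ValueError("predicate must return one flag per unit")
        ids = traj.ids[mask]
    else:
        ids = np.asarray(list(selection), dtype=np.int64)
        traj.index_of(ids)  # raises on unknown ids
    if len(ids) == 0:
        raise ValueError("empty center selection")
    return ids


def _tree_coords(pos: np.ndarray, box: np.ndarray | None,
                 periodic: np.ndarray, rcut: float) -> tuple[np.ndarray, np.ndarray]:
    """Map coordinates into [0, L) per axis with a safe period on free axes."""
    dim = pos.shape[1]
    out = pos.copy()
    boxsize = np.empty(dim)
    for ax in range(dim):
        if periodic[ax]:
            L = float(box[ax])
            out[:, ax] = np.mod(out[:, ax], L)
            boxsize[ax] = L
        else:
            lo = out[:, ax].min()
            span = out[:, ax].max() - lo
            out[:, ax] = out[:, ax] - lo + rcut
            boxsize[ax] = span + 4.0 * rcut + 1.0
    return out, boxsize


def build_neighbor_lists(
    traj: ParticleTrajectory,
    rcut: float,
    centers: Sequence[int] | None = None,
    candidates: Sequence[int] | None = None,
) -> NeighborLists:
    """Cutoff neighbor lists per frame with minimum-image distances.

    ``centers`` are the ids descriptors will be computed on; ``candidates``
    the ids eligible as neighbors (default: all units).  Built with a
    kd-tree per frame, so cost scales near-linearly in the unit count.
    """
    if not rcut > 0:
        raise ValueError("rcut must be positive")
    centers = traj.ids if centers is None else np.asarray(list(centers), dtype=np.int64)
    candidates = traj.ids if candidates is None else np.asarray(list(candidates), dtype=np.int64)
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    c_idx = traj.index_of(centers)
    k_idx = traj.index_of(candidates)
    if traj.periodic.any():
        half = 0.5 * traj.box[:, traj.periodic].min()
        if rcut >= half:
            raise ValueError(
                f"rcut={rcut} must be smaller than half the smallest periodic box edge ({half})"
            )
    lists: list[list[np.ndarray]] = []
    for f in range(traj.n_frames):
        box_f = traj.box[f] if traj.box is not None else None
        all_pos, boxsize = _tree_coords(traj.positions[f], box_f, traj.periodic, rcut)
        tree = cKDTree(all_pos[k_idx], boxsize=boxsize)
        hits = tree.query_ball_point(all_pos[c_idx], r=rcut)
        frame_lists = []
        for center_id, hit in zip(centers, hits):
            ids = candidates[np.asarray(hit, dtype=int)] if len(hit) else np.empty(0, np.int64)
            frame_lists.append(np.sort(ids[ids != center_id]))
        lists.append(frame_lists)
    return NeighborLists(rcut=float(rcut), centers=centers, candidates=candidates,
                         lists=lists, dt=traj.dt)


def minimum_image_displacement(
    delta: np.ndarray, box: np.ndarray | None, periodic: np.ndarray
) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    delta = np.asarray(delta, dtype=float).copy()
    if box is not None and periodic.any():
        for ax in np.nonzero(periodic)[0]:
            L = box[ax]
            delta[..., ax] -= L * np.round(delta[..., ax] / L)
    return delta
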