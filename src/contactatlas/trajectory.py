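"""Trajectory streaming with an explicit frame→time mapping.

Frames are streamed single-pass with bounded memory (peak memory is
independent of trajectory length), so microsecond-scale runs can be
analysed without loading coordinates wholesale. Times are always derived
from the mapping ``t = t0 + index * dt``; the saving stride of a
production run is not guessable from coordinates, so ``dt_ns`` is a
required input, never a default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .topology import Topology

__all__ = [
    "Frame",
    "TimeMapping",
    "Replica",
    "ReplicaSet",
    "TrajectoryError",
    "load_frames",
    "select_analysis_window",
    "write_multimodel_pdb",
    "write_xtc",
]

# warn on implausible per-frame atom jumps (unwrapped-PBC sanity check)
_MAX_DISPLACEMENT_A = 20.0


class TrajectoryError(ValueError):
    """Trajectory inconsistent with its topology or truncated."""


@dataclass
class Frame:
    index: int
    time_ns: float
    coords: np.ndarray  # (n_atoms, 3) Å, topology atom order

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryError(f"frame {self.index}: coords must be (n, 3)")
        if self.time_ns < 0:
            raise TrajectoryError(f"frame {self.index}: negative time {self.time_ns}")


@dataclass(frozen=True)
class TimeMapping:
    """Time per saved frame and the time of frame 0, both in ns."""

    dt_ns: float
    t0_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.dt_ns <= 0:
            raise TrajectoryError(f"dt_ns must be > 0, got {self.dt_ns}")

    def time(self, index: int) -> float:
        return self.t0_ns + index * self.dt_ns


@dataclass
class Replica:
    """One replica: a frame source (file path or frame factory) plus mapping."""

    replica_id: str
    source: object  # str | Path | callable yielding Frame iterables
    mapping: TimeMapping

    def iter_frames(self, topology: Topology) -> Iterator[Frame]:
        if callable(self.source):
            yield from self.source()
        else:
            yield from load_frames(self.source, topology, self.mapping)


@dataclass
class ReplicaSet:
    """Ordered replicas sharing one topology and atom ordering."""

    topology: Topology
    replicas: list[Replica] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicas:
            raise TrajectoryError("ReplicaSet needs at least one replica")


def load_frames(
    source: str | Path, topology: Topology, mapping: TimeMapping
) -> Iterator[Frame]:
    """Stream frames from a multi-model PDB, DCD or XTC file.

    Atom count must match the topology; mismatch or a truncated frame is
    rejected at the offending frame index.
    """
    import MDAnalysis as mda

    path = str(source)
    n_top = topology.n_atoms
    u = _open_universe(path, n_top)
    if u is None:  # zero-frame trajectory
        return
    if len(u.atoms) != n_top:
        raise TrajectoryError(
            f"atom count mismatch: trajectory has {len(u.atoms)}, topology has {n_top}"
        )
    prev: Optional[np.ndarray] = None
    for i, ts in enumerate(u.trajectory):
        coords = np.array(ts.positions, dtype=float)
        if coords.shape[0] != n_top:
            raise TrajectoryError(f"truncated frame at index {i}")
        if prev is not None:
            jump = float(np.max(np.linalg.norm(coords - prev, axis=1)))
            if jump > _MAX_DISPLACEMENT_A:
                warnings.warn(
                    f"frame {i}: max per-atom displacement {jump:.1f} Å exceeds "
                    f"{_MAX_DISPLACEMENT_A} Å — trajectory may not be PBC-whole",
                    stacklevel=2,
                )
        prev = coords
        yield Frame(index=i, time_ns=mapping.time(i), coords=coords)


def _open_universe(path: str, n_atoms: int):
    import MDAnalysis as mda

    lower = path.lower()
    if lower.endswith(".pdb"):
        return mda.Universe(path)
    # coordinate-only formats need an atom count
    try:
        u = mda.Universe.empty(n_atoms, trajectory=False)
        u.load_new(path)
        return u
    except (OSError, ValueError, EOFError) as exc:
        if "No frames" in str(exc) or "empty" in str(exc).lower():
            return None
        raise


def select_analysis_window(
    frames: Iterable[Frame], start_ns: float, end_ns: float
) -> Iterator[Frame]:
    """Yield frames with ``start_ns <= time < end_ns`` (half-open window).

    Half-open so that adjacent windows tile a trajectory without double
    counting; the window length used for occupancy normalisation is
    ``end - start``. An empty selection warns rather than fails.
    """
    if not start_ns < end_ns:
        raise TrajectoryError(f"invalid window [{start_ns}, {end_ns})")
    n = 0
    for f in frames:
        if start_ns <= f.time_ns < end_ns:
            n += 1
            yield f
    if n == 0:
        warnings.warn(f"analysis window [{start_ns}, {end_ns}) ns selected no frames", stacklevel=2)


# ---------------------------------------------------------------------------
# fixture writers

def _universe_from_topology(topology: Topology, coords: np.ndarray):
    import MDAnalysis as mda

    n = topology.n_atoms
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=topology.n_residues,
        n_segments=len(topology.chains),
        atom_resindex=topology.atom_residue_index(),
        residue_segindex=[
            next(ci for ci, c in enumerate(topology.chains) if c.chain_id == r.chain_id)
            for r in topology.residues
        ],
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element.capitalize() for a in topology.atoms])
    u.add_TopologyAttr("resnames", [r.name for r in topology.residues])
    u.add_TopologyAttr("resids", [r.seq_number for r in topology.residues])
    u.add_TopologyAttr("segids", [c.chain_id for c in topology.chains])
    u.add_TopologyAttr("chainIDs", [topology.residues[a.residue_index].chain_id for a in topology.atoms])
    u.atoms.positions = coords
    return u


def write_multimodel_pdb(
    path: str | Path, topology: Topology, frames: Iterable[Frame]
) -> None:
    """Write frames as a multi-model PDB (fixture format)."""
    import MDAnalysis as mda

    frames = list(frames)
    if not frames:
        raise TrajectoryError("no frames to write")
    u = _universe_from_topology(topology, frames[0].coords)
    with mda.Writer(str(path), multiframe=True, n_atoms=topology.n_atoms) as w:
        for f in frames:
            u.atoms.positions = f.coords
            w.write(u.atoms)


def write_xtc(path: str | Path, topology: Topology, frames: Iterable[Frame]) -> None:
    """Write frames to XTC (lossy: coordinates stored to 0.001 Å)."""
    import MDAnalysis as mda

    first = None
    frames = iter(frames)
    try:
        first = next(frames)
    except StopIteration:
        raise TrajectoryError("no frames to write") from None
    u = _universe_from_topology(topology, first.coords)
    # precision is in fractional nm digits: 4 -> 1e-4 nm = 1e-3 Å
    with mda.Writer(str(path), n_atoms=topology.n_atoms, precision=4) as w:
        u.atoms.positions = first.coords
        w.write(u.atoms)
        for f in frames:
            u.atoms.positions = f.coords
            w.write(u.atoms)


def write_topology_pdb(path: str | Path, topology: Topology) -> None:
    """Write the reference pose as a single-model PDB."""
    if topology.reference_coords is None:
        raise TrajectoryError("topology has no reference coordinates")
    write_multimodel_pdb(
        path, topology, [Frame(index=0, time_ns=0.0, coords=topology.reference_coords)]
    )
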