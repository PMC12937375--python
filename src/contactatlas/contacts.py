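"""Per-frame geometric detection of non-covalent contacts.

Three interaction types are detected from coordinates alone and
aggregated to residue pairs:

* hydrogen bonds — donor–acceptor distance ≤ ``max_da_dist_A`` and, when
  hydrogens are present, D–H–A angle ≥ ``min_dha_angle_deg``;
* ionic interactions — minimum atom–atom distance between oppositely
  charged *groups* ≤ ``max_group_dist_A`` (a group, e.g. Asp OD1+OD2 or
  the Arg guanidinium nitrogens, counts once however many atom pairs
  qualify);
* van der Waals contacts — heavy-atom pairs with
  ``d ≤ r_i + r_j + radius_slack_A``, excluding atom pairs already
  counted as a hydrogen bond in the same frame so one physical contact
  is never double-booked.

All thresholds are inclusive (≤/≥) for deterministic boundary behaviour.
Covalently adjacent residues and i,i±1 backbone neighbours are excluded
from every type. Detection is accelerated with a k-d tree but is defined
by, and tested against, the all-pairs rules above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .topology import ChemicalRoleTable, Topology
from .trajectory import Frame

__all__ = [
    "HBondParams",
    "IonicParams",
    "VdwParams",
    "DetectionParams",
    "FrameContactSet",
    "ContactDetector",
    "detect_hbonds_frame",
    "detect_ionic_frame",
    "detect_vdw_frame",
    "aggregate_to_residue_pairs",
]

HBOND = "hbond"
IONIC = "ionic"
VDW = "vdw"
INTERACTION_TYPES = (HBOND, IONIC, VDW)


@dataclass(frozen=True)
class HBondParams:
    max_da_dist_A: float = 3.5
    min_dha_angle_deg: float = 120.0

    def __post_init__(self) -> None:
        if self.max_da_dist_A <= 0:
            raise ValueError("max_da_dist_A must be > 0")
        if not 0 <= self.min_dha_angle_deg <= 180:
            raise ValueError("min_dha_angle_deg must be in [0, 180]")


@dataclass(frozen=True)
class IonicParams:
    max_group_dist_A: float = 4.0

    def __post_init__(self) -> None:
        if self.max_group_dist_A <= 0:
            raise ValueError("max_group_dist_A must be > 0")


@dataclass(frozen=True)
class VdwParams:
    radius_slack_A: float = 0.5

    def __post_init__(self) -> None:
        if self.radius_slack_A < 0:
            raise ValueError("radius_slack_A must be >= 0")


@dataclass(frozen=True)
class DetectionParams:
    hbond: HBondParams = HBondParams()
    ionic: IonicParams = IonicParams()
    vdw: VdwParams = VdwParams()

    def as_dict(self) -> dict:
        return {
            "hbond_max_da_dist_A": self.hbond.max_da_dist_A,
            "hbond_min_dha_angle_deg": self.hbond.min_dha_angle_deg,
            "ionic_max_group_dist_A": self.ionic.max_group_dist_A,
            "vdw_radius_slack_A": self.vdw.radius_slack_A,
        }


@dataclass
class FrameContactSet:
    """Residue-pair contacts of one frame, canonicalised ``res_a < res_b``."""

    frame_index: int
    contacts: set[tuple[int, int, str]] = field(default_factory=set)
    #: minimum qualifying atom–atom distance per (res_a, res_b, type)
    min_distances: dict[tuple[int, int, str], float] = field(default_factory=dict)

    def add(self, res_a: int, res_b: int, itype: str, dist: float) -> None:
        if res_a == res_b:
            raise ValueError("self-pair contact")
        key = (min(res_a, res_b), max(res_a, res_b), itype)
        self.contacts.add(key)
        prev = self.min_distances.get(key)
        if prev is None or dist < prev:
            self.min_distances[key] = dist

    def pairs(self, itype: Optional[str] = None) -> set[tuple[int, int, str]]:
        if itype is None:
            return set(self.contacts)
        return {c for c in self.contacts if c[2] == itype}

    def __len__(self) -> int:
        return len(self.contacts)


class ContactDetector:
    """Precomputes exclusion structures once, then detects per frame."""

    def __init__(
        self,
        topology: Topology,
        roles: ChemicalRoleTable,
        params: DetectionParams = DetectionParams(),
    ):
        self.topology = topology
        self.roles = roles
        self.params = params
        self.atom_res = topology.atom_residue_index()
        self.bonded_atom_pairs = set(topology.covalent_links)
        self.excluded_residue_pairs = self._excluded_pairs(topology)

        self.donor_idx = np.asarray(sorted(roles.donors), dtype=np.intp)
        self.donor_hs = [roles.donors[int(i)] for i in self.donor_idx]
        self.acceptor_idx = np.asarray(sorted(roles.acceptors), dtype=np.intp)

        self._pos_atoms, self._pos_gid = _flatten_groups(roles.positive_groups)
        self._neg_atoms, self._neg_gid = _flatten_groups(roles.negative_groups)

        self.heavy_idx = roles.heavy_atoms
        self.heavy_radii = roles.radii
        self._radius_of = dict(zip(self.heavy_idx.tolist(), self.heavy_radii.tolist()))

    @staticmethod
    def _excluded_pairs(topology: Topology) -> set[tuple[int, int]]:
        excluded = set(topology.residue_adjacency())
        # i,i±1 neighbours within a chain, bonded or not (schematic fixtures
        # may omit backbone bonds)
        for chain in topology.chains:
            idxs = chain.residue_indices
            for a, b in zip(idxs, idxs[1:]):
                seq_a = topology.residues[a].seq_number
                seq_b = topology.residues[b].seq_number
                if abs(seq_a - seq_b) <= 1:
                    excluded.add((min(a, b), max(a, b)))
        return excluded

    def _pair_allowed(self, i: int, j: int) -> bool:
        ra, rb = int(self.atom_res[i]), int(self.atom_res[j])
        if ra == rb:
            return False
        if (min(ra, rb), max(ra, rb)) in self.excluded_residue_pairs:
            return False
        if (min(i, j), max(i, j)) in self.bonded_atom_pairs:
            return False
        return True

    # -- hydrogen bonds ----------------------------------------------------
    def detect_hbonds(self, frame: Frame) -> tuple[FrameContactSet, set[tuple[int, int]]]:
        """Return the residue-pair set plus the atom-level (D, A) hits used
        later to exclude the same physical contact from vdW counting."""
        p = self.params.hbond
        out = FrameContactSet(frame.index)
        atom_hits: set[tuple[int, int]] = set()
        if len(self.donor_idx) == 0 or len(self.acceptor_idx) == 0:
            return out, atom_hits
        X = frame.coords
        tree = cKDTree(X[self.acceptor_idx])
        neigh = tree.query_ball_point(X[self.donor_idx], r=p.max_da_dist_A)
        min_cos = np.cos(np.deg2rad(p.min_dha_angle_deg))
        for di, acc_list in enumerate(neigh):
            d_atom = int(self.donor_idx[di])
            hs = self.donor_hs[di]
            for ai in acc_list:
                a_atom = int(self.acceptor_idx[ai])
                if a_atom == d_atom or not self._pair_allowed(d_atom, a_atom):
                    continue
                dist = float(np.linalg.norm(X[d_atom] - X[a_atom]))
                if dist > p.max_da_dist_A:  # guard fp edge of ball query
                    continue
                if hs:
                    if not _angle_ok(X, d_atom, hs, a_atom, min_cos):
                        continue
                atom_hits.add((d_atom, a_atom))
                out.add(int(self.atom_res[d_atom]), int(self.atom_res[a_atom]), HBOND, dist)
        return out, atom_hits

    # -- ionic -------------------------------------------------------------
    def detect_ionic(self, frame: Frame) -> FrameContactSet:
        p = self.params.ionic
        out = FrameContactSet(frame.index)
        if len(self._pos_atoms) == 0 or len(self._neg_atoms) == 0:
            return out
        X = frame.coords
        tree = cKDTree(X[self._neg_atoms])
        neigh = tree.query_ball_point(X[self._pos_atoms], r=p.max_group_dist_A)
        for pi, neg_list in enumerate(neigh):
            i = int(self._pos_atoms[pi])
            for ni in neg_list:
                j = int(self._neg_atoms[ni])
                if not self._pair_allowed(i, j):
                    continue
                dist = float(np.linalg.norm(X[i] - X[j]))
                if dist > p.max_group_dist_A:
                    continue
                out.add(int(self.atom_res[i]), int(self.atom_res[j]), IONIC, dist)
        return out

    # -- van der Waals -----------------------------------------------------
    def detect_vdw(
        self, frame: Frame, hbond_atom_hits: Optional[set[tuple[int, int]]] = None
    ) -> FrameContactSet:
        p = self.params.vdw
        out = FrameContactSet(frame.index)
        if len(self.heavy_idx) == 0:
            return out
        hits = hbond_atom_hits or set()
        hit_pairs = {(min(a, b), max(a, b)) for a, b in hits}
        X = frame.coords[self.heavy_idx]
        rmax = 2.0 * float(np.max(self.heavy_radii)) + p.radius_slack_A
        tree = cKDTree(X)
        for ii, jj in tree.query_pairs(r=rmax, output_type="ndarray"):
            i, j = int(self.heavy_idx[ii]), int(self.heavy_idx[jj])
            if not self._pair_allowed(i, j):
                continue
            if (min(i, j), max(i, j)) in hit_pairs:
                continue
            cutoff = self.heavy_radii[ii] + self.heavy_radii[jj] + p.radius_slack_A
            dist = float(np.linalg.norm(X[ii] - X[jj]))
            if dist <= cutoff:
                out.add(int(self.atom_res[i]), int(self.atom_res[j]), VDW, dist)
        return out

    def detect_all(self, frame: Frame) -> FrameContactSet:
        """All three interaction types of one frame, merged."""
        hb, atom_hits = self.detect_hbonds(frame)
        ion = self.detect_ionic(frame)
        vdw = self.detect_vdw(frame, atom_hits)
        merged = FrameContactSet(frame.index)
        for part in (hb, ion, vdw):
            merged.contacts |= part.contacts
            for k, v in part.min_distances.items():
                prev = merged.min_distances.get(k)
                if prev is None or v < prev:
                    merged.min_distances[k] = v
        return merged


def _angle_ok(
    X: np.ndarray, d_atom: int, hs: tuple[int, ...], a_atom: int, min_cos: float
) -> bool:
    for h in hs:
        v1 = X[d_atom] - X[h]
        v2 = X[a_atom] - X[h]
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        # angle >= min_angle  <=>  cos(angle) <= cos(min_angle)
        if float(np.dot(v1, v2)) / (n1 * n2) <= min_cos + 1e-12:
            return True
    return False


def _flatten_groups(groups: list[tuple[int, ...]]) -> tuple[np.ndarray, np.ndarray]:
    atoms: list[int] = []
    gids: list[int] = []
    for gid, grp in enumerate(groups):
        for a in grp:
            atoms.append(a)
            gids.append(gid)
    return np.asarray(atoms, dtype=np.intp), np.asarray(gids, dtype=np.intp)


# ---------------------------------------------------------------------------
# functional surface

def detect_hbonds_frame(
    frame: Frame, topology: Topology, roles: ChemicalRoleTable, params: HBondParams = HBondParams()
) -> FrameContactSet:
    det = ContactDetector(topology, roles, DetectionParams(hbond=params))
    return det.detect_hbonds(frame)[0]


def detect_ionic_frame(
    frame: Frame, topology: Topology, roles: ChemicalRoleTable, params: IonicParams = IonicParams()
) -> FrameContactSet:
    det = ContactDetector(topology, roles, DetectionParams(ionic=params))
    return det.detect_ionic(frame)


def detect_vdw_frame(
    frame: Frame,
    topology: Topology,
    roles: ChemicalRoleTable,
    params: VdwParams = VdwParams(),
    hbond_atom_hits: Optional[set[tuple[int, int]]] = None,
) -> FrameContactSet:
    det = ContactDetector(topology, roles, DetectionParams(vdw=params))
    return det.detect_vdw(frame, hbond_atom_hits)


def aggregate_to_residue_pairs(
    atom_hits: Iterable[tuple[int, int, str, float]],
    topology: Topology,
    frame_index: int = 0,
) -> FrameContactSet:
    """Collapse atom-level hits ``(atom_i, atom_j, type, dist)`` to canonical
    residue-pair entries, applying the covalent-neighbour exclusions."""
    atom_res = topology.atom_residue_index()
    excluded = ContactDetector._excluded_pairs(topology)
    out = FrameContactSet(frame_index)
    for i, j, itype, dist in atom_hits:
        ra, rb = int(atom_res[i]), int(atom_res[j])
        if ra == rb:
            continue
        if (min(ra, rb), max(ra, rb)) in excluded:
            continue
        out.add(ra, rb, itype, dist)
    return out
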