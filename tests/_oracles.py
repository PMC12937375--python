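"""Independent brute-force oracles for contact detection.

These deliberately re-derive the geometric rules with plain O(n^2)
loops and no spatial acceleration, so they can serve as an independent
reference for the k-d-tree implementation.
"""

from __future__ import annotations

import numpy as np

from contactatlas.topology import Atom, Chain, ChemicalRoleTable, Residue, Topology
from contactatlas.trajectory import Frame


def _excluded(topology: Topology) -> set[tuple[int, int]]:
    excluded = set(topology.residue_adjacency())
    for chain in topology.chains:
        idxs = chain.residue_indices
        for a, b in zip(idxs, idxs[1:]):
            if abs(topology.residues[a].seq_number - topology.residues[b].seq_number) <= 1:
                excluded.add((min(a, b), max(a, b)))
    return excluded


def _allowed(topology: Topology, excluded, i: int, j: int) -> bool:
    ridx = topology.atom_residue_index()
    ra, rb = int(ridx[i]), int(ridx[j])
    if ra == rb:
        return False
    if (min(ra, rb), max(ra, rb)) in excluded:
        return False
    if (min(i, j), max(i, j)) in topology.covalent_links:
        return False
    return True


def brute_hbonds(topology, roles, frame, max_da=3.5, min_angle=120.0):
    """All-pairs hydrogen-bond detection; returns (pair set, atom hits)."""
    X = frame.coords
    excluded = _excluded(topology)
    ridx = topology.atom_residue_index()
    pairs = set()
    atom_hits = set()
    for d, hs in roles.donors.items():
        for a in roles.acceptors:
            if a == d or not _allowed(topology, excluded, d, a):
                continue
            if np.linalg.norm(X[d] - X[a]) > max_da:
                continue
            if hs:
                ok = False
                for h in hs:
                    v1, v2 = X[d] - X[h], X[a] - X[h]
                    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
                    if ang >= min_angle - 1e-9:
                        ok = True
                if not ok:
                    continue
            atom_hits.add((d, a))
            ra, rb = int(ridx[d]), int(ridx[a])
            pairs.add((min(ra, rb), max(ra, rb), "hbond"))
    return pairs, atom_hits


def brute_ionic(topology, roles, frame, max_dist=4.0):
    X = frame.coords
    excluded = _excluded(topology)
    ridx = topology.atom_residue_index()
    pairs = set()
    for pg in roles.positive_groups:
        for ng in roles.negative_groups:
            for i in pg:
                for j in ng:
                    if not _allowed(topology, excluded, i, j):
                        continue
                    if np.linalg.norm(X[i] - X[j]) <= max_dist:
                        ra, rb = int(ridx[i]), int(ridx[j])
                        pairs.add((min(ra, rb), max(ra, rb), "ionic"))
    return pairs


def brute_vdw(topology, roles, frame, slack=0.5, hbond_atom_hits=()):
    X = frame.coords
    excluded = _excluded(topology)
    ridx = topology.atom_residue_index()
    radius = dict(zip(roles.heavy_atoms.tolist(), roles.radii.tolist()))
    hb = {(min(a, b), max(a, b)) for a, b in hbond_atom_hits}
    pairs = set()
    heavy = roles.heavy_atoms.tolist()
    for ii, i in enumerate(heavy):
        for j in heavy[ii + 1:]:
            if not _allowed(topology, excluded, i, j):
                continue
            if (min(i, j), max(i, j)) in hb:
                continue
            if np.linalg.norm(X[i] - X[j]) <= radius[i] + radius[j] + slack:
                ra, rb = int(ridx[i]), int(ridx[j])
                pairs.add((min(ra, rb), max(ra, rb), "vdw"))
    return pairs


# ---------------------------------------------------------------------------
# randomized systems

def random_system(rng: np.random.Generator, n_atoms: int = 40, box: float = 12.0):
    """A random cloud of atoms grouped into residues, with random chemical
    roles — a stress fixture for detector/oracle equivalence."""
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms, p=[0.5, 0.2, 0.25, 0.05])
    coords = rng.uniform(0, box, size=(n_atoms, 3))
    n_res = max(2, n_atoms // 4)
    res_of = np.sort(rng.integers(0, n_res, size=n_atoms))
    residues, atoms = [], []
    chain = Chain(chain_id="X")
    for r in range(n_res):
        res = Residue(chain_id="X", seq_number=r * 3 + 1, name="UNK", klass="protein")
        members = np.flatnonzero(res_of == r)
        for i in members:
            atoms.append(Atom(serial=int(i) + 1, name=f"{elements[i]}{i}",
                              element=str(elements[i]), residue_index=len(residues)))
            res.atom_indices.append(int(i))
        residues.append(res)
        chain.residue_indices.append(r)
    # a few random covalent bonds
    links = set()
    for _ in range(n_atoms // 10):
        i, j = rng.integers(0, n_atoms, size=2)
        if i != j:
            links.add((min(int(i), int(j)), max(int(i), int(j))))
    topo = Topology(chains=[chain], residues=residues, atoms=atoms,
                    covalent_links=links, reference_coords=coords, has_hydrogens=False)

    radii = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
    polar = [i for i in range(n_atoms) if elements[i] in ("N", "O", "S")]
    donors = {int(i): () for i in polar if rng.random() < 0.6}
    acceptors = {int(i) for i in polar if rng.random() < 0.6}
    pos_groups, neg_groups = [], []
    for r in range(n_res):
        members = [int(i) for i in np.flatnonzero(res_of == r)]
        if len(members) >= 2 and rng.random() < 0.3:
            grp = tuple(sorted(rng.choice(members, size=2, replace=False).tolist()))
            (pos_groups if rng.random() < 0.5 else neg_groups).append(grp)
    roles = ChemicalRoleTable(
        donors=donors,
        acceptors=acceptors,
        positive_groups=pos_groups,
        negative_groups=neg_groups,
        heavy_atoms=np.arange(n_atoms, dtype=np.intp),
        radii=np.array([radii[str(e)] for e in elements]),
        implicit_hydrogens=True,
    )
    frame = Frame(index=0, time_ns=0.0, coords=coords)
    return topo, roles, frame
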