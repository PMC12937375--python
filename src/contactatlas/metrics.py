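"""Flexibility and convergence metrics: RMSD, RMSF, radius of gyration.

RMSD uses least-squares optimal superposition (Kabsch); RMSF is computed
after superposing every frame onto the reference using a fit selection
(protein backbone heavy atoms by default), so rigid-body motion of the
whole system does not inflate per-atom fluctuations. The glycan
flexibility reporter is the per-atom RMSF of each monosaccharide's
anomeric C1, indexed along the glycan chain from the innermost GlcNAc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .topology import Topology
from .trajectory import Frame

__all__ = [
    "FlexibilityProfile",
    "ConvergenceSeries",
    "kabsch_superpose",
    "rmsf",
    "radius_of_gyration",
    "backbone_selection",
    "glycan_c1_selection",
    "ATOMIC_MASSES",
]

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "SE": 78.971, "ZN": 65.38,
    "MG": 24.305, "CA": 40.078, "NA": 22.99, "K": 39.098, "FE": 55.845,
}


@dataclass
class FlexibilityProfile:
    label: str
    atom_indices: np.ndarray
    rmsf_A: np.ndarray  # per selected atom

    def __post_init__(self) -> None:
        if np.any(self.rmsf_A < 0):
            raise ValueError("RMSF must be non-negative")
        if len(self.rmsf_A) != len(self.atom_indices):
            raise ValueError("profile length must match selection size")


@dataclass
class ConvergenceSeries:
    rmsd_A: np.ndarray  # per frame, after optimal superposition
    rg_A: np.ndarray  # per frame
    times_ns: np.ndarray


def kabsch_superpose(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mov`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mov @ rotation.T + translation`` best fits ``ref`` in the
    (weighted) least-squares sense; the rotation is proper (det = +1).
    Degenerate point sets (fewer than 3 points, or collinear) are
    rejected — the optimal rotation is not unique there.
    """
    P = np.asarray(ref_coords, dtype=float)
    Q = np.asarray(mov_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cP = (w[:, None] * P).sum(axis=0)
    cQ = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - cP, Q - cQ
    # collinearity check on the reference
    if np.linalg.matrix_rank(P0 * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = (w[:, None] * Q0).T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cP - R @ cQ
    diff = P0 - Q0 @ R.T
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return R, t, rmsd


def rmsf(
    frames: Iterable[Frame],
    selection: Sequence[int],
    fit_selection: Optional[Sequence[int]] = None,
    label: str = "selection",
) -> FlexibilityProfile:
    """Per-atom RMSF of ``selection`` after per-frame superposition.

    Every frame is superposed onto the first frame using
    ``fit_selection`` (defaults to the analysis selection itself);
    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames. Two passes over an
    in-memory list would be wasteful for long trajectories, so the
    aligned selection coordinates are accumulated with running sums.
    """
    sel = np.asarray(selection, dtype=np.intp)
    if sel.size == 0:
        raise ValueError("empty selection")
    fit = np.asarray(fit_selection, dtype=np.intp) if fit_selection is not None else sel

    ref_fit = None
    ref_sel = None
    s1 = np.zeros((sel.size, 3))
    s2 = np.zeros(sel.size)
    n = 0
    for f in frames:
        X = f.coords
        if ref_fit is None:
            ref_fit = X[fit].copy()
            ref_sel = X[sel].copy()
        R, t, _ = kabsch_superpose(ref_fit, X[fit])
        # accumulate deviations from the first aligned frame to avoid
        # cancellation in the one-pass variance
        d = X[sel] @ R.T + t - ref_sel
        s1 += d
        s2 += np.einsum("ij,ij->i", d, d)
        n += 1
    if n < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mean = s1 / n
    msd = s2 / n - np.einsum("ij,ij->i", mean, mean)
    msd = np.maximum(msd, 0.0)
    return FlexibilityProfile(label=label, atom_indices=sel, rmsf_A=np.sqrt(msd))


def radius_of_gyration(
    frame: Frame,
    selection: Sequence[int],
    masses: Optional[np.ndarray] = None,
    topology: Optional[Topology] = None,
) -> float:
    """Mass-weighted radius of gyration about the selection's centre of mass."""
    sel = np.asarray(selection, dtype=np.intp)
    if sel.size < 2:
        raise ValueError("radius of gyration needs at least 2 atoms")
    if masses is None:
        if topology is None:
            m = np.ones(sel.size)
        else:
            m = np.array(
                [ATOMIC_MASSES.get(topology.atoms[int(i)].element, 12.011) for i in sel]
            )
    else:
        m = np.asarray(masses, dtype=float)
    if m.sum() <= 0:
        raise ValueError("total mass must be positive")
    X = frame.coords[sel]
    com = (m[:, None] * X).sum(axis=0) / m.sum()
    d2 = np.einsum("ij,ij->i", X - com, X - com)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def convergence_series(
    frames: Iterable[Frame],
    selection: Sequence[int],
    fit_selection: Optional[Sequence[int]] = None,
    topology: Optional[Topology] = None,
) -> ConvergenceSeries:
    """Per-frame RMSD to the first frame (after superposition on the fit
    selection) and radius of gyration of the analysis selection."""
    sel = np.asarray(selection, dtype=np.intp)
    fit = np.asarray(fit_selection, dtype=np.intp) if fit_selection is not None else sel
    ref_fit = None
    ref_sel = None
    rmsds, rgs, times = [], [], []
    for f in frames:
        X = f.coords
        if ref_fit is None:
            ref_fit = X[fit].copy()
            ref_sel = X[sel].copy()
        R, t, _ = kabsch_superpose(ref_fit, X[fit])
        aligned = X[sel] @ R.T + t
        rmsds.append(float(np.sqrt(np.mean(np.sum((aligned - ref_sel) ** 2, axis=1)))))
        rgs.append(radius_of_gyration(f, sel, topology=topology))
        times.append(f.time_ns)
    return ConvergenceSeries(
        rmsd_A=np.asarray(rmsds), rg_A=np.asarray(rgs), times_ns=np.asarray(times)
    )


# ---------------------------------------------------------------------------
# selections

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def backbone_selection(topology: Topology) -> np.ndarray:
    """Protein backbone heavy atoms (default RMSF fit selection)."""
    idx = [
        i
        for i, a in enumerate(topology.atoms)
        if topology.residues[a.residue_index].klass == "protein"
        and a.name in _BACKBONE_NAMES
        and a.element != "H"
    ]
    return np.asarray(idx, dtype=np.intp)


def glycan_c1_selection(topology: Topology) -> tuple[np.ndarray, list[dict]]:
    """Anomeric C1 atoms of all glycan residues, ordered by (anchor,
    glycan position); returns the selection and per-atom metadata rows."""
    entries = []
    for i, a in enumerate(topology.atoms):
        res = topology.residues[a.residue_index]
        if res.klass == "glycan" and a.name == "C1":
            entries.append((res.glycan_anchor, res.glycan_position, a.serial, i, res))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    sel = np.asarray([e[3] for e in entries], dtype=np.intp)
    meta = [
        {
            "chain": res.chain_id,
            "residue": res.seq_number,
            "name": res.name,
            "anchor": f"{res.glycan_anchor[0]}:{res.glycan_anchor[1]}",
            "glycan_position": res.glycan_position,
        }
        for *_, res in entries
    ]
    return sel, meta
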