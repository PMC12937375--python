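"""Desk-scale synthetic glycoprotein-complex fixtures with programmed
contact kinetics.

The generator builds a schematic multi-chain topology (poly-alanine-like
protein chains with interspersed Lys/Asp/Glu/Ser/Asn at designated
sites, N-glycans chained onto designated asparagines) and multi-replica
coordinate series in which designated residue pairs toggle between
contact and no-contact geometry under exact two-state continuous-time
Markov kinetics (Gillespie sampling of exponential waiting times,
stationary initialisation), plus independent Gaussian positional jitter
on every atom.

Geometry is schematic by design — no force field, no physical MD. The
layout guarantees that designated pairs are the *only* residue pairs
that can ever satisfy a detection criterion (inter-residue separations
are several times any threshold), so the ground-truth manifest gives an
exact expected pair universe and analytic occupancy/dwell-time targets
(occupancy → k_on/(k_on+k_off), mean dwell → 1/k_off) for every
pipeline stage.

Fixtures are heavy-atom only: hydrogen-bond detection runs in its
distance-only (implicit hydrogen) mode, as it does for many deposited
trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from .topology import (
    Topology,
    Atom,
    Chain,
    Residue,
    build_role_tables,
    classify_residues,
)
from .trajectory import Frame, Replica, ReplicaSet, TimeMapping

__all__ = [
    "PairKinetics",
    "ChainPlan",
    "GlycanPlan",
    "SyntheticSpec",
    "expected_occupancy",
    "build_synthetic_topology",
    "simulate_two_state_contacts",
    "sample_two_state",
    "validate_geometry",
    "ground_truth_manifest",
    "replica_states",
    "default_spec",
    "two_variant_specs",
    "rate_grid_spec",
    "occupancy_standard_error",
    "write_fixture",
]

# layout constants (Å); separations are several times any detection
# threshold (max ~4.4 Å) plus the ~3 Å intra-residue atom extent
_RESIDUE_SPACING = 15.0
_CHAIN_SPACING = 60.0
_SUGAR_SPACING = 6.0
_GLYCOSIDIC_BOND = 1.45

# heavy-atom residue templates: name -> {atom name: local offset}
_BACKBONE = {
    "N": (-1.4, 0.6, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.4, 0.6, 0.0),
    "O": (1.4, 1.8, 0.0),
    "CB": (0.0, -1.5, 0.0),
}
_SIDECHAINS = {
    "ALA": {},
    "GLY": {},
    "SER": {"OG": (0.0, -2.6, 0.0)},
    "LYS": {"NZ": (0.0, -3.0, 0.0)},
    "ASP": {"OD1": (0.0, -3.0, 0.0), "OD2": (1.4, -2.8, 0.0)},
    "GLU": {"OE1": (0.0, -3.0, 0.0), "OE2": (1.4, -2.8, 0.0)},
    "ASN": {"ND2": (0.0, -2.6, 0.0), "OD1": (1.3, -2.4, 0.0)},
    "LEU": {"CD1": (0.0, -2.6, 0.0), "CD2": (1.2, -2.6, 0.0)},
    "TRP": {"CG": (0.0, -2.2, 0.0), "CD1": (1.1, -2.7, 0.0), "CD2": (-1.1, -2.7, 0.0)},
}
# sugar template chained along +x with O4 -> next C1 glycosidic geometry
_SUGAR_ATOMS = {
    "C1": (-2.3, 0.0, 0.0),
    "O5": (-1.4, 1.0, 0.0),
    "C2": (-1.2, -1.0, 0.0),
    "O3": (0.0, -1.6, 0.0),
    "C4": (1.2, 0.0, 0.0),
    "O4": (2.3, 0.0, 0.0),
    "O6": (0.0, 1.6, 0.0),
}
_ELEMENT_OF = {
    "N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OG": "O",
    "NZ": "N", "OD1": "O", "OD2": "O", "OE1": "O", "OE2": "O",
    "ND2": "N", "CD1": "C", "CD2": "C", "CG": "C", "C1": "C",
    "O5": "O", "C2": "C", "O3": "O", "C4": "C", "O4": "O", "O6": "O",
    "N2": "N",
}

# default anchor atoms per (residue name, role)
_ANCHOR_ATOMS = {
    "LYS": "NZ", "ASP": "OD1", "GLU": "OE1", "SER": "OG",
    "LEU": "CD1", "TRP": "CG", "ASN": "ND2",
    "NAG": "O3", "BMA": "O3", "MAN": "O3", "GAL": "O3", "FUC": "O3",
}


def expected_occupancy(k_on: float, k_off: float) -> float:
    """Stationary bound probability of the two-state chain."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be > 0")
    return k_on / (k_on + k_off)


def occupancy_standard_error(
    k_on: float, k_off: float, window_ns: float, n_replicas: int = 1
) -> float:
    """Analytic standard error of the time-average occupancy estimator.

    For a stationary two-state chain the indicator autocovariance is
    p(1-p)·exp(-λt) with λ = k_on + k_off, giving an asymptotic variance
    of the window time-average of 2·p(1-p)/(λ·T); averaging over
    independent replicas divides by their number.
    """
    p = expected_occupancy(k_on, k_off)
    lam = k_on + k_off
    var = 2.0 * p * (1.0 - p) / (lam * window_ns) / n_replicas
    return float(np.sqrt(var))


@dataclass(frozen=True)
class PairKinetics:
    """One programmed contact: a static partner, a mobile partner, rates
    and the bound/unbound anchor-atom separations."""

    static: tuple[str, int]  # (chain_id, seq_number)
    mobile: tuple[str, int]
    itype: str  # hbond | ionic | vdw — the designated detection type
    k_on: float  # per ns
    k_off: float  # per ns
    bound_distance_A: float = 2.9
    unbound_distance_A: float = 12.0
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    static_atom: Optional[str] = None
    mobile_atom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be > 0")
        if not self.bound_distance_A < self.unbound_distance_A:
            raise ValueError("bound distance must be below unbound distance")

    @property
    def occupancy(self) -> float:
        return expected_occupancy(self.k_on, self.k_off)


@dataclass(frozen=True)
class ChainPlan:
    chain_id: str
    start_seq: int
    n_residues: int
    special: tuple[tuple[int, str], ...] = ()  # (seq_number, residue name)

    def residue_names(self) -> list[tuple[int, str]]:
        special = dict(self.special)
        return [
            (seq, special.get(seq, "ALA"))
            for seq in range(self.start_seq, self.start_seq + self.n_residues)
        ]


@dataclass(frozen=True)
class GlycanPlan:
    chain_id: str  # chain id of the saccharide residues themselves
    anchor: tuple[str, int]  # (chain_id, seq_number) of the Asn
    sugar_names: tuple[str, ...] = ("NAG", "NAG", "BMA")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic complex: layout + kinetics + noise."""

    label: str = "synthetic"
    chains: tuple[ChainPlan, ...] = ()
    glycans: tuple[GlycanPlan, ...] = ()
    pairs: tuple[PairKinetics, ...] = ()
    jitter_sigma_A: float = 0.1
    n_frames: int = 10000
    dt_ns: float = 0.1
    n_replicas: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma_A < 0:
            raise ValueError("jitter sigma must be >= 0")
        mobiles = [p.mobile for p in self.pairs]
        if len(set(mobiles)) != len(mobiles):
            raise ValueError("a residue may be the mobile partner of at most one pair")
        statics = set(p.static for p in self.pairs)
        if statics & set(mobiles):
            raise ValueError("a residue cannot be both static and mobile")

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.dt_ns


# ---------------------------------------------------------------------------
# topology construction

def build_synthetic_topology(spec: SyntheticSpec) -> Topology:
    """Materialise the schematic topology and its reference pose.

    Protein chain ``c`` lies along x at z = c·60 Å with 15 Å between
    residue centres; each glycan extends along +y from its anchor's ND2
    with 6 Å between sugar centres and a 1.45 Å O4→C1 (ND2→C1 for the
    first sugar) glycosidic geometry, so covalent-link inference and
    breadth-first glycan indexing recover the plan exactly.
    """
    chains: list[Chain] = []
    residues: list[Residue] = []
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 0

    def add_residue(chain: Chain, chain_id: str, seq: int, name: str,
                    center: np.ndarray, template: dict[str, tuple]) -> None:
        nonlocal serial
        res = Residue(chain_id=chain_id, seq_number=seq, name=name)
        ridx = len(residues)
        for atom_name, off in template.items():
            serial += 1
            atoms.append(
                Atom(serial=serial, name=atom_name, element=_ELEMENT_OF[atom_name],
                     residue_index=ridx)
            )
            res.atom_indices.append(len(atoms) - 1)
            coords.append(center + np.asarray(off))
        residues.append(res)
        chain.residue_indices.append(ridx)

    for ci, plan in enumerate(spec.chains):
        chain = Chain(chain_id=plan.chain_id)
        z = ci * _CHAIN_SPACING
        for k, (seq, name) in enumerate(plan.residue_names()):
            if name not in _SIDECHAINS:
                raise ValueError(f"unsupported residue template {name!r}")
            center = np.array([k * _RESIDUE_SPACING, 0.0, z])
            template = {**_BACKBONE, **_SIDECHAINS[name]}
            add_residue(chain, plan.chain_id, seq, name, center, template)
        chains.append(chain)

    key_to_center = {
        (r.chain_id, r.seq_number): coords[r.atom_indices[0]] - np.asarray(_BACKBONE["N"])
        for r in residues
    }
    atom_pos = {
        (residues[a.residue_index].chain_id, residues[a.residue_index].seq_number, a.name): coords[i]
        for i, a in enumerate(atoms)
    }

    for plan in spec.glycans:
        if plan.anchor not in key_to_center:
            raise ValueError(f"glycan anchor {plan.anchor} not in any chain plan")
        nd2 = atom_pos.get((*plan.anchor, "ND2"))
        if nd2 is None:
            raise ValueError(f"glycan anchor {plan.anchor} is not an ASN")
        chain = Chain(chain_id=plan.chain_id)
        d = np.array([0.0, -1.0, 0.0])  # extend along the sidechain direction
        # first sugar: C1 sits _GLYCOSIDIC_BOND beyond ND2 along d
        first_center = nd2 + (abs(_SUGAR_ATOMS["C1"][0]) + _GLYCOSIDIC_BOND) * d
        # rotate the +x-chained template onto d: local x -> d,
        # local y -> world +x, local z -> world +z
        template = {
            nm: tuple(v[0] * d + v[1] * np.array([1.0, 0.0, 0.0])
                      + v[2] * np.array([0.0, 0.0, 1.0]))
            for nm, v in ((nm, np.asarray(v, dtype=float)) for nm, v in _SUGAR_ATOMS.items())
        }
        for k, name in enumerate(plan.sugar_names):
            center = first_center + k * _SUGAR_SPACING * d
            add_residue(chain, plan.chain_id, k + 1, name, center, template)
        chains.append(chain)

    xyz = np.asarray(coords, dtype=float)
    links = _template_links(atoms, residues, xyz)
    topo = Topology(
        chains=chains,
        residues=residues,
        atoms=atoms,
        covalent_links=links,
        reference_coords=xyz,
        has_hydrogens=False,
    )
    classify_residues(topo)
    _check_layout(spec, topo)
    return topo


def _template_links(atoms, residues, xyz) -> set[tuple[int, int]]:
    """Covalent links of the reference pose, inferred by distance exactly as
    build_topology would (so file round-trips agree)."""
    from .topology import _infer_covalent_links

    return _infer_covalent_links(atoms, residues, xyz)


def _check_layout(spec: SyntheticSpec, topo: Topology) -> None:
    for p in spec.pairs:
        for key in (p.static, p.mobile):
            try:
                topo.residue_index_by_key(*key)
            except KeyError:
                raise ValueError(f"kinetics pair references unknown residue {key}") from None
        _anchor_atom_index(topo, p.static, p.static_atom)
        _anchor_atom_index(topo, p.mobile, p.mobile_atom)


def _anchor_atom_index(
    topo: Topology, key: tuple[str, int], atom_name: Optional[str]
) -> int:
    ridx = topo.residue_index_by_key(*key)
    res = topo.residues[ridx]
    name = atom_name or _ANCHOR_ATOMS.get(res.name)
    if name is None:
        raise ValueError(f"no default anchor atom for residue {res.label()}")
    for i in res.atom_indices:
        if topo.atoms[i].name == name:
            return i
    raise ValueError(f"residue {res.label()} has no atom {name!r}")


# ---------------------------------------------------------------------------
# two-state kinetics

def sample_two_state(
    rng: np.random.Generator,
    k_on: float,
    k_off: float,
    n_frames: int,
    dt_ns: float,
) -> np.ndarray:
    """Exact CTMC path discretised at the frame grid.

    Gillespie sampling: exponential waiting times with the exit rate of
    the current state, stationary initial state (bound with probability
    k_on/(k_on+k_off)). Returns the bound indicator at times i·dt.
    """
    t_end = n_frames * dt_ns
    bound = bool(rng.random() < expected_occupancy(k_on, k_off))
    switch_times: list[float] = []
    t = 0.0
    state = bound
    while True:
        rate = k_off if state else k_on
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        switch_times.append(t)
        state = not state
    times = np.arange(n_frames) * dt_ns
    n_switches = np.searchsorted(np.asarray(switch_times), times, side="right")
    states = (n_switches % 2 == 1) ^ bound
    return states.astype(bool)


@dataclass
class _SimPlan:
    topology: Topology
    static_anchor: list[int]
    mobile_anchor: list[int]
    mobile_atoms: list[np.ndarray]
    mobile_offsets: list[np.ndarray]  # atom offsets relative to mobile anchor
    directions: list[np.ndarray]
    static_pos: list[np.ndarray]


def _make_plan(spec: SyntheticSpec, topo: Topology) -> _SimPlan:
    ref = topo.reference_coords
    plan = _SimPlan(topo, [], [], [], [], [], [])
    for p in spec.pairs:
        si = _anchor_atom_index(topo, p.static, p.static_atom)
        mi = _anchor_atom_index(topo, p.mobile, p.mobile_atom)
        m_ridx = topo.residue_index_by_key(*p.mobile)
        m_atoms = np.asarray(topo.residues[m_ridx].atom_indices, dtype=np.intp)
        plan.static_anchor.append(si)
        plan.mobile_anchor.append(mi)
        plan.mobile_atoms.append(m_atoms)
        plan.mobile_offsets.append(ref[m_atoms] - ref[mi])
        d = np.asarray(p.direction, dtype=float)
        plan.directions.append(d / np.linalg.norm(d))
        plan.static_pos.append(ref[si])
    return plan


def _replica_streams(spec: SyntheticSpec, replica: int):
    root = np.random.SeedSequence([spec.seed, replica])
    children = root.spawn(len(spec.pairs) + 1)
    pair_rngs = [np.random.Generator(np.random.PCG64(c)) for c in children[:-1]]
    jitter_rng = np.random.Generator(np.random.PCG64(children[-1]))
    return pair_rngs, jitter_rng


def replica_states(spec: SyntheticSpec, replica: int) -> np.ndarray:
    """Ground-truth bound indicators, shape (n_pairs, n_frames)."""
    pair_rngs, _ = _replica_streams(spec, replica)
    return np.array(
        [
            sample_two_state(rng, p.k_on, p.k_off, spec.n_frames, spec.dt_ns)
            for rng, p in zip(pair_rngs, spec.pairs)
        ],
        dtype=bool,
    ).reshape(len(spec.pairs), spec.n_frames)


def _iter_replica_frames(
    spec: SyntheticSpec, topo: Topology, plan: _SimPlan, replica: int
) -> Iterator[Frame]:
    states = replica_states(spec, replica)
    _, jitter_rng = _replica_streams(spec, replica)
    ref = topo.reference_coords
    n_atoms = ref.shape[0]
    sigma = spec.jitter_sigma_A
    for f in range(spec.n_frames):
        X = ref.copy()
        for k, p in enumerate(spec.pairs):
            d = p.bound_distance_A if states[k, f] else p.unbound_distance_A
            anchor = plan.static_pos[k] + d * plan.directions[k]
            X[plan.mobile_atoms[k]] = anchor + plan.mobile_offsets[k]
        if sigma > 0:
            X += jitter_rng.normal(0.0, sigma, size=(n_atoms, 3))
        yield Frame(index=f, time_ns=f * spec.dt_ns, coords=X)


def simulate_two_state_contacts(
    spec: SyntheticSpec, topology: Optional[Topology] = None
) -> ReplicaSet:
    """Generate the replica set for a spec; frames are produced lazily and
    regenerate identically on every pass (full determinism under the
    master seed)."""
    topo = topology if topology is not None else build_synthetic_topology(spec)
    plan = _make_plan(spec, topo)
    mapping = TimeMapping(dt_ns=spec.dt_ns, t0_ns=0.0)
    replicas = []
    for r in range(spec.n_replicas):
        replicas.append(
            Replica(
                replica_id=f"r{r + 1}",
                source=(lambda rr=r: _iter_replica_frames(spec, topo, plan, rr)),
                mapping=mapping,
            )
        )
    return ReplicaSet(topology=topo, replicas=replicas)


def validate_geometry(
    spec: SyntheticSpec, topo: Topology, margin_A: Optional[float] = None
) -> None:
    """Construction guarantee: with all pairs bound (no jitter) every
    designated pair is detected with its designated type, and no
    non-designated residue pair is detected in either extreme state even
    with every threshold inflated by ``margin_A`` — headroom for jitter,
    defaulting to 6 standard deviations of a jittered pair distance."""
    if margin_A is None:
        margin_A = 6.0 * np.sqrt(2.0) * spec.jitter_sigma_A
    from .contacts import ContactDetector, DetectionParams, HBondParams, IonicParams, VdwParams

    roles = build_role_tables(topo)
    det = ContactDetector(topo, roles, DetectionParams())
    base = DetectionParams()
    inflated = DetectionParams(
        hbond=HBondParams(base.hbond.max_da_dist_A + margin_A, base.hbond.min_dha_angle_deg),
        ionic=IonicParams(base.ionic.max_group_dist_A + margin_A),
        vdw=VdwParams(base.vdw.radius_slack_A + margin_A),
    )
    det_wide = ContactDetector(topo, roles, inflated)
    plan = _make_plan(spec, topo)
    designated = set()
    for p in spec.pairs:
        ia = topo.residue_index_by_key(*p.static)
        ib = topo.residue_index_by_key(*p.mobile)
        designated.add((min(ia, ib), max(ia, ib)))

    for bound in (True, False):
        X = topo.reference_coords.copy()
        for k, p in enumerate(spec.pairs):
            d = p.bound_distance_A if bound else p.unbound_distance_A
            anchor = plan.static_pos[k] + d * plan.directions[k]
            X[plan.mobile_atoms[k]] = anchor + plan.mobile_offsets[k]
        hits = det.detect_all(Frame(index=0, time_ns=0.0, coords=X))
        wide = det_wide.detect_all(Frame(index=0, time_ns=0.0, coords=X))
        seen = {(a, b) for a, b, _ in wide.contacts}
        stray = seen - designated
        if stray:
            labels = [
                f"{topo.residues[a].label()}×{topo.residues[b].label()}" for a, b in stray
            ]
            raise ValueError(
                f"overcrowded spec: non-designated contacts in "
                f"{'bound' if bound else 'unbound'} pose: {labels}"
            )
        if bound:
            types = {(a, b): t for a, b, t in hits.contacts}
            for p in spec.pairs:
                ia = topo.residue_index_by_key(*p.static)
                ib = topo.residue_index_by_key(*p.mobile)
                key = (min(ia, ib), max(ia, ib))
                pair_types = {t for a, b, t in hits.contacts if (a, b) == key}
                if p.itype not in pair_types:
                    raise ValueError(
                        f"designated pair {p.static}×{p.mobile} not detected as "
                        f"{p.itype} in bound pose"
                    )
        else:
            if seen:
                raise ValueError(f"unbound pose still shows contacts: {seen}")


def ground_truth_manifest(spec: SyntheticSpec) -> dict:
    """JSON-able record of the programmed kinetics for test assertions."""
    return {
        "label": spec.label,
        "seed": spec.seed,
        "n_replicas": spec.n_replicas,
        "n_frames": spec.n_frames,
        "dt_ns": spec.dt_ns,
        "jitter_sigma_A": spec.jitter_sigma_A,
        "pairs": [
            {
                "static": list(p.static),
                "mobile": list(p.mobile),
                "type": p.itype,
                "k_on_per_ns": p.k_on,
                "k_off_per_ns": p.k_off,
                "expected_occupancy": p.occupancy,
                "expected_mean_dwell_ns": 1.0 / p.k_off,
                "bound_distance_A": p.bound_distance_A,
                "unbound_distance_A": p.unbound_distance_A,
            }
            for p in spec.pairs
        ],
    }


def write_fixture(spec: SyntheticSpec, outdir: str | Path, fmt: str = "pdb") -> dict:
    """Write topology PDB, per-replica trajectories and the ground-truth
    manifest; returns the path map."""
    from .trajectory import write_multimodel_pdb, write_topology_pdb, write_xtc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topo = build_synthetic_topology(spec)
    plan = _make_plan(spec, topo)
    paths: dict = {"topology": str(outdir / "topology.pdb"), "replicas": []}
    write_topology_pdb(outdir / "topology.pdb", topo)
    for r in range(spec.n_replicas):
        frames = _iter_replica_frames(spec, topo, plan, r)
        if fmt == "xtc":
            p = outdir / f"replica_{r + 1}.xtc"
            write_xtc(p, topo, frames)
        else:
            p = outdir / f"replica_{r + 1}.pdb"
            write_multimodel_pdb(p, topo, frames)
        paths["replicas"].append(str(p))
    manifest = ground_truth_manifest(spec)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = str(outdir / "manifest.json")
    return paths


# ---------------------------------------------------------------------------
# stock fixtures

def default_spec(seed: int = 0, label: str = "variant-A", **overrides) -> SyntheticSpec:
    """The default desk-scale complex: three protein chains (Fc-like A/B
    and a receptor-like C), three N-glycans, and five programmed pairs
    covering every interaction layer the analysis distinguishes:
    protein-protein interchain (ionic, hbond, vdw), protein-glycan
    intrachain and glycan-glycan interchain.

    1000 ns per replica at dt = 0.1 ns, four replicas; the analysis
    window [100, 1000) then holds exactly 9000 frames per replica.
    """
    chains = (
        ChainPlan("A", 234, 12, special=(
            (239, "SER"), (240, "LEU"), (241, "ASP"), (242, "GLU"), (244, "ASN"),
        )),
        ChainPlan("B", 260, 10, special=((265, "ASP"), (268, "ASN"))),
        ChainPlan("C", 115, 8, special=(
            (117, "TRP"), (119, "ASN"), (120, "LYS"), (121, "LYS"),
        )),
    )
    glycans = (
        GlycanPlan("a", anchor=("A", 244), sugar_names=("NAG", "NAG", "BMA", "MAN", "GAL")),
        GlycanPlan("b", anchor=("B", 268), sugar_names=("NAG", "NAG", "BMA")),
        GlycanPlan("c", anchor=("C", 119), sugar_names=("NAG", "NAG", "BMA", "MAN")),
    )
    pairs = (
        # persistent interchain salt bridge (protein-protein)
        PairKinetics(static=("A", 241), mobile=("C", 120), itype="ionic",
                     k_on=0.05, k_off=0.005, bound_distance_A=3.3,
                     direction=(0.0, 0.0, 1.0)),
        # medium-lived interchain hydrogen bond (protein-protein)
        PairKinetics(static=("A", 239), mobile=("C", 121), itype="hbond",
                     k_on=0.02, k_off=0.01, bound_distance_A=2.9,
                     direction=(0.0, 0.0, -1.0)),
        # intrachain protein-glycan hydrogen bond (glycan rides chain B)
        PairKinetics(static=("B", 265), mobile=("b", 1), itype="hbond",
                     k_on=0.01, k_off=0.01, bound_distance_A=2.9,
                     direction=(0.0, 0.0, 1.0)),
        # transient interchain glycan-glycan hydrogen bond (sugar 2, clear
        # of the receptor Asn sidechain)
        PairKinetics(static=("c", 2), mobile=("a", 1), itype="hbond",
                     k_on=0.005, k_off=0.02, bound_distance_A=2.9,
                     direction=(0.55, 0.0, 0.84), static_atom="O6", mobile_atom="O3"),
        # long-lived interchain van der Waals packing (proline-sandwich-like)
        PairKinetics(static=("C", 117), mobile=("A", 240), itype="vdw",
                     k_on=0.02, k_off=0.002, bound_distance_A=3.4,
                     direction=(0.0, 0.0, -1.0)),
    )
    base = dict(
        label=label, chains=chains, glycans=glycans, pairs=pairs,
        jitter_sigma_A=0.1, n_frames=10000, dt_ns=0.1, n_replicas=4, seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


def two_variant_specs(seed: int = 0, **overrides) -> tuple[SyntheticSpec, SyntheticSpec]:
    """Two variants sharing one layout with programmed kinetic differences:

    * the interchain salt bridge is destabilised 20-fold in variant B
      (the programmed differential contact a comparison must flag);
    * the glycan-glycan bridge is effectively abolished in variant B
      (unique to A after the stated occupancy filter).
    """
    a = default_spec(seed=seed, label="variant-A", **overrides)
    pairs_b = list(a.pairs)
    pairs_b[0] = replace(pairs_b[0], k_off=pairs_b[0].k_off * 20.0)
    pairs_b[3] = replace(pairs_b[3], k_on=1e-4, k_off=1.0)
    b = replace(a, label="variant-B", pairs=tuple(pairs_b),
                seed=seed + 1)
    return a, b


def rate_grid_spec(seed: int = 0, rates: Sequence[float] = (0.005, 0.02, 0.05),
                   **overrides) -> SyntheticSpec:
    """Nine ionic pairs on a 3×3 (k_on, k_off) grid for parameter-recovery
    checks; each pair has its own static Asp and mobile Lys so the
    recovered occupancies are independent."""
    n = len(rates) ** 2
    statics = ChainPlan("S", 1, 2 * n, special=tuple((2 * i + 1, "ASP") for i in range(n)))
    mobiles = ChainPlan("M", 1, 2 * n, special=tuple((2 * i + 1, "LYS") for i in range(n)))
    pairs = []
    k = 0
    for k_on in rates:
        for k_off in rates:
            pairs.append(
                PairKinetics(
                    static=("S", 2 * k + 1), mobile=("M", 2 * k + 1), itype="ionic",
                    k_on=k_on, k_off=k_off, bound_distance_A=3.3,
                    direction=(0.0, 0.0, 1.0) if k % 2 == 0 else (0.0, 0.0, -1.0),
                )
            )
            k += 1
    base = dict(
        label="rate-grid", chains=(statics, mobiles), glycans=(), pairs=tuple(pairs),
        jitter_sigma_A=0.1, n_frames=10000, dt_ns=0.1, n_replicas=4, seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)
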