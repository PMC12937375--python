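"""Molecular data model for glycoprotein complexes.

Builds chains/residues/atoms from PDB or mmCIF records, infers covalent
links (peptide, disulfide, glycosidic), classifies residues as protein,
glycan or other, and assigns the chemical roles (H-bond donor/acceptor,
charged group, heavy-atom van der Waals radius) that geometric contact
detection consumes.

Residue numbering from the input (author numbering) is preserved verbatim;
a glycan residue inherits the *carrier* chain of the asparagine it is
covalently attached to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Topology",
    "ChemicalRoleTable",
    "InteractionLayer",
    "TopologyError",
    "STANDARD_AMINO_ACIDS",
    "DEFAULT_GLYCAN_NAMES",
    "VDW_RADII",
    "build_topology",
    "classify_residues",
    "build_role_tables",
    "classify_pair_layer",
]


class TopologyError(ValueError):
    """Malformed or inconsistent structural input."""


#: Three-letter codes of the 20 standard amino acids plus common variants.
STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP HID HIE HIP CYX""".split()
)

#: Saccharide residue names recognised as candidate glycan units (PDB CCD
#: codes and common SNFG/CHARMM equivalents).
DEFAULT_GLYCAN_NAMES = frozenset(
    """NAG BMA MAN GAL FUC FUL GLC NDG BGC SIA NAN A2G NGA XYS
    AGLC BGLC AMAN BMAN AGAL BGAL AFUC BFUC""".split()
)

#: van der Waals radii (Å), element-keyed.
VDW_RADII: Mapping[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "NA": 2.27,
    "K": 2.75, "FE": 1.94, "MN": 1.97,
}

# generic covalent-inference cutoffs (Å); N-glycosidic ND2-C1 uses 2.0
_COVALENT_HEAVY_MAX = 1.9
_COVALENT_H_MAX = 1.25
_GLYCOSIDIC_ND2_C1_MAX = 2.0


@dataclass(frozen=True)
class Atom:
    """One atom; coordinates live in Frame objects, not here."""

    serial: int
    name: str
    element: str
    residue_index: int  # index into Topology.residues

    def __post_init__(self) -> None:
        if not self.element:
            raise TopologyError(f"atom {self.serial} {self.name!r}: empty element")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    klass: str = "other"  # protein | glycan | other
    glycan_anchor: Optional[tuple[str, int]] = None
    glycan_position: Optional[int] = None
    atom_indices: list[int] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_number)

    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_number}"


@dataclass
class Chain:
    chain_id: str
    residue_indices: list[int] = field(default_factory=list)
    label: str = ""


@dataclass
class Topology:
    """Chains, residues, atoms and the covalent bond graph."""

    chains: list[Chain]
    residues: list[Residue]
    atoms: list[Atom]
    covalent_links: set[tuple[int, int]]  # atom-index pairs, i < j
    reference_coords: Optional[np.ndarray] = None  # (n_atoms, 3) Å, first model
    has_hydrogens: bool = False

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("duplicate atom serials in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atom_residue_index(self) -> np.ndarray:
        return np.asarray([a.residue_index for a in self.atoms], dtype=np.intp)

    def residue_by_key(self, chain_id: str, seq_number: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_number == seq_number:
                return r
        raise KeyError(f"no residue {chain_id}:{seq_number}")

    def residue_index_by_key(self, chain_id: str, seq_number: int) -> int:
        for i, r in enumerate(self.residues):
            if r.chain_id == chain_id and r.seq_number == seq_number:
                return i
        raise KeyError(f"no residue {chain_id}:{seq_number}")

    def carrier_chain(self, residue_index: int) -> str:
        """Carrier polypeptide chain: a glycan inherits its anchor's chain."""
        res = self.residues[residue_index]
        if res.klass == "glycan" and res.glycan_anchor is not None:
            return res.glycan_anchor[0]
        return res.chain_id

    def bonded_atoms(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.covalent_links:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def residue_adjacency(self) -> set[tuple[int, int]]:
        """Residue-index pairs (i<j) sharing at least one covalent bond."""
        ridx = self.atom_residue_index()
        pairs: set[tuple[int, int]] = set()
        for i, j in self.covalent_links:
            ra, rb = int(ridx[i]), int(ridx[j])
            if ra != rb:
                pairs.add((min(ra, rb), max(ra, rb)))
        return pairs


@dataclass(frozen=True)
class InteractionLayer:
    """Contact layer of a residue pair: which molecular species meet, and
    whether both partners ride the same carrier polypeptide chain."""

    kind: str  # protein-protein | protein-glycan | glycan-glycan
    span: str  # intrachain | interchain

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}/{self.span}"


@dataclass
class ChemicalRoleTable:
    """Atom-level chemistry used by the geometric detectors.

    ``donors`` maps each donor heavy atom (N/O/S) to the covalently attached
    hydrogens; with ``implicit_hydrogens`` the attached-H tuples are empty
    and H-bond detection degrades to donor–acceptor distance only.
    Charged groups are atom-index *groups* (e.g. Asp OD1+OD2 together).
    """

    donors: dict[int, tuple[int, ...]]
    acceptors: set[int]
    positive_groups: list[tuple[int, ...]]
    negative_groups: list[tuple[int, ...]]
    heavy_atoms: np.ndarray  # atom indices
    radii: np.ndarray  # Å, aligned with heavy_atoms
    implicit_hydrogens: bool = False

    def __post_init__(self) -> None:
        if np.any(self.radii <= 0):
            raise TopologyError("non-positive vdW radius in role table")


# ---------------------------------------------------------------------------
# construction

def _structure_from_path(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def build_topology(source: str | Path | gemmi.Structure) -> Topology:
    """Build a :class:`Topology` from a PDB/mmCIF file or gemmi Structure.

    Covalent links are taken from explicit connection records where present
    (mmCIF ``struct_conn``, PDB ``LINK``/``SSBOND``) and otherwise inferred
    from first-model interatomic distances: heavy–heavy < 1.9 Å, X–H < 1.25 Å,
    and the N-glycosidic ND2–C1 bond at < 2.0 Å.
    """
    st = source if isinstance(source, gemmi.Structure) else _structure_from_path(source)
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise TopologyError("empty structure: no models or no residues")
    model = st[0]

    chains: list[Chain] = []
    residues: list[Residue] = []
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    seen_atom_keys: set[tuple[str, int, str]] = set()
    serial = 0
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            r = Residue(chain_id=ch.name, seq_number=res.seqid.num, name=res.name.strip())
            if any(x.key == r.key for x in residues):
                raise TopologyError(f"duplicate residue key {r.key}")
            ridx = len(residues)
            for at in res:
                key = (ch.name, res.seqid.num, at.name)
                if key in seen_atom_keys:
                    raise TopologyError(
                        f"duplicate atom record chain={ch.name} res={res.seqid.num} name={at.name!r}"
                    )
                seen_atom_keys.add(key)
                serial += 1
                elem = at.element.name.upper() if at.element else ""
                if not elem or elem == "X":
                    elem = _element_from_name(at.name)
                atoms.append(Atom(serial=serial, name=at.name, element=elem, residue_index=ridx))
                r.atom_indices.append(len(atoms) - 1)
                coords.append((at.pos.x, at.pos.y, at.pos.z))
            residues.append(r)
            chain.residue_indices.append(ridx)
        # keep author residue order but require ordering by seq number
        chain.residue_indices.sort(key=lambda i: residues[i].seq_number)
        chains.append(chain)

    xyz = np.asarray(coords, dtype=float)
    links = _infer_covalent_links(atoms, residues, xyz)
    links |= _explicit_connections(st, atoms, residues)
    has_h = any(a.element == "H" for a in atoms)
    topo = Topology(
        chains=chains,
        residues=residues,
        atoms=atoms,
        covalent_links=links,
        reference_coords=xyz,
        has_hydrogens=has_h,
    )
    return topo


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise TopologyError(f"cannot deduce element for atom name {name!r}")
    two = stripped[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE", "MN"):
        return two
    return stripped[0].upper()


def _infer_covalent_links(
    atoms: Sequence[Atom], residues: Sequence[Residue], xyz: np.ndarray
) -> set[tuple[int, int]]:
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=_GLYCOSIDIC_ND2_C1_MAX, output_type="ndarray")
    links: set[tuple[int, int]] = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        a, b = atoms[i], atoms[j]
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if a.element == "H" and b.element == "H":
            continue
        if a.element == "H" or b.element == "H":
            if d <= _COVALENT_H_MAX:
                links.add((min(i, j), max(i, j)))
            continue
        names = {a.name, b.name}
        is_glycosidic = names == {"ND2", "C1"}
        cutoff = _GLYCOSIDIC_ND2_C1_MAX if is_glycosidic else _COVALENT_HEAVY_MAX
        if d <= cutoff:
            links.add((min(i, j), max(i, j)))
    return links


def _explicit_connections(
    st: gemmi.Structure, atoms: Sequence[Atom], residues: Sequence[Residue]
) -> set[tuple[int, int]]:
    index: dict[tuple[str, int, str], int] = {}
    for i, a in enumerate(atoms):
        r = residues[a.residue_index]
        index[(r.chain_id, r.seq_number, a.name)] = i
    links: set[tuple[int, int]] = set()
    for conn in st.connections:
        try:
            p1, p2 = conn.partner1, conn.partner2
            k1 = (p1.chain_name, p1.res_id.seqid.num, p1.atom_name)
            k2 = (p2.chain_name, p2.res_id.seqid.num, p2.atom_name)
        except Exception:  # pragma: no cover - malformed record
            continue
        if k1 in index and k2 in index:
            i, j = index[k1], index[k2]
            if i != j:
                links.add((min(i, j), max(i, j)))
    return links


# ---------------------------------------------------------------------------
# residue classification

def classify_residues(
    topo: Topology, glycan_name_whitelist: Iterable[str] = DEFAULT_GLYCAN_NAMES
) -> Topology:
    """Assign ``klass`` to every residue and index glycan units.

    Protein: name in the standard amino-acid set. Glycan: name in the
    saccharide whitelist *and* reachable from an asparagine through covalent
    links; the position index is the breadth-first distance from the anchor
    (1 = innermost GlcNAc), branch ties broken by atom-serial order so that
    sibling branch residues share a position deterministically. Whitelisted
    saccharides with no covalent path to an Asn become ``other`` with a
    warning, never a silent drop.
    """
    whitelist = frozenset(glycan_name_whitelist)
    if not whitelist:
        raise TopologyError("glycan name whitelist must be non-empty")

    for res in topo.residues:
        if res.name in STANDARD_AMINO_ACIDS:
            res.klass = "protein"
        else:
            res.klass = "other"
        res.glycan_anchor = None
        res.glycan_position = None

    res_adj = _residue_graph(topo)

    # BFS from each Asn through whitelisted saccharides
    for aidx, anchor in enumerate(topo.residues):
        if anchor.name != "ASN":
            continue
        frontier = [aidx]
        depth = 0
        visited = {aidx}
        while frontier:
            depth += 1
            nxt: list[int] = []
            for ridx in frontier:
                for nb in sorted(res_adj.get(ridx, ()), key=lambda k: topo.residues[k].atom_indices[0]):
                    if nb in visited:
                        continue
                    nbres = topo.residues[nb]
                    if nbres.name not in whitelist:
                        continue
                    visited.add(nb)
                    nbres.klass = "glycan"
                    nbres.glycan_anchor = anchor.key
                    nbres.glycan_position = depth
                    nxt.append(nb)
            frontier = nxt

    for res in topo.residues:
        if res.name in whitelist and res.klass != "glycan":
            warnings.warn(
                f"saccharide residue {res.label()} has no covalent path to an Asn; "
                "classified as 'other'",
                stacklevel=2,
            )
    return topo


def _residue_graph(topo: Topology) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for ra, rb in topo.residue_adjacency():
        adj.setdefault(ra, set()).add(rb)
        adj.setdefault(rb, set()).add(ra)
    return adj


# ---------------------------------------------------------------------------
# chemical role tables

# sidechain donor/acceptor templates for standard amino acids (heavy atoms)
_AA_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "HSD": {"ND1"}, "HSE": {"NE2"}, "HSP": {"ND1", "NE2"},
    "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"}, "TRP": {"NE1"},
    "TYR": {"OH"}, "CYS": {"SG"},
}
_AA_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "HSD": {"NE2"},
    "HSE": {"ND1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "MET": {"SD"},
}
_POSITIVE_SIDECHAIN = {
    "LYS": ({"NZ"},),
    "ARG": ({"NE", "NH1", "NH2"},),
    "HSP": ({"ND1", "NE2"},),
}
_HIS_POSITIVE = ({"ND1", "NE2"},)
_NEGATIVE_SIDECHAIN = {
    "ASP": ({"OD1", "OD2"},),
    "GLU": ({"OE1", "OE2"},),
}

# saccharide template: hydroxyl oxygens donate and accept; ring O5 and the
# glycosidic/acetamido oxygens accept only; NAG N2 donates (amide NH).
_SUGAR_HYDROXYLS = {"O1", "O2", "O3", "O4", "O6"}
_SUGAR_ACCEPTOR_ONLY = {"O5", "O7"}
_SUGAR_DONOR_N = {"N2"}


def build_role_tables(
    topo: Topology,
    radii: Mapping[str, float] = VDW_RADII,
    *,
    protonated_his: bool = False,
) -> ChemicalRoleTable:
    """Derive donors, acceptors, charged groups and vdW radii from templates.

    When the topology lacks hydrogens the table is flagged
    ``implicit_hydrogens`` and every template donor is accepted without an
    attached-H requirement. ``protonated_his`` adds His imidazole nitrogens
    to the positive groups (off by default: neutral His forms hydrogen
    bonds, not salt bridges).
    """
    adj = topo.bonded_atoms()
    has_h = topo.has_hydrogens

    donors: dict[int, tuple[int, ...]] = {}
    acceptors: set[int] = set()
    positive: list[tuple[int, ...]] = []
    negative: list[tuple[int, ...]] = []
    heavy: list[int] = []
    heavy_r: list[float] = []

    def attached_h(i: int) -> tuple[int, ...]:
        return tuple(sorted(j for j in adj[i] if topo.atoms[j].element == "H"))

    for ridx, res in enumerate(topo.residues):
        name_to_idx = {topo.atoms[i].name: i for i in res.atom_indices}
        is_protein = res.klass == "protein"
        is_glycan = res.klass == "glycan"

        for i in res.atom_indices:
            at = topo.atoms[i]
            if at.element == "H":
                continue
            r = radii.get(at.element)
            if r is None:
                raise TopologyError(f"no vdW radius for element {at.element!r} (atom {at.serial})")
            heavy.append(i)
            heavy_r.append(float(r))

            if is_protein:
                if at.name == "N":  # backbone amide
                    hs = attached_h(i)
                    if hs or not has_h:
                        donors[i] = hs
                if at.name in ("O", "OXT"):
                    acceptors.add(i)
                tdon = _AA_DONORS.get(res.name, set())
                tacc = _AA_ACCEPTORS.get(res.name, set())
                if at.name in tdon:
                    hs = attached_h(i)
                    if hs or not has_h:
                        donors[i] = hs
                if at.name in tacc:
                    acceptors.add(i)
            elif is_glycan:
                if at.name in _SUGAR_HYDROXYLS:
                    hs = attached_h(i)
                    if hs or not has_h:
                        donors[i] = hs
                    acceptors.add(i)
                elif at.name in _SUGAR_ACCEPTOR_ONLY:
                    acceptors.add(i)
                elif at.name in _SUGAR_DONOR_N:
                    hs = attached_h(i)
                    if hs or not has_h:
                        donors[i] = hs
            else:
                # generic fallback: polar heavy atoms act by element
                if at.element in ("N", "O", "S"):
                    hs = attached_h(i)
                    if hs or not has_h:
                        donors[i] = hs
                    if at.element in ("N", "O"):
                        acceptors.add(i)

        if is_protein:
            for group_names in _POSITIVE_SIDECHAIN.get(res.name, ()):
                grp = tuple(sorted(name_to_idx[n] for n in group_names if n in name_to_idx))
                if grp:
                    positive.append(grp)
            if protonated_his and res.name == "HIS":
                grp = tuple(sorted(name_to_idx[n] for n in _HIS_POSITIVE[0] if n in name_to_idx))
                if grp:
                    positive.append(grp)
            for group_names in _NEGATIVE_SIDECHAIN.get(res.name, ()):
                grp = tuple(sorted(name_to_idx[n] for n in group_names if n in name_to_idx))
                if grp:
                    negative.append(grp)
            # chain termini
            if _is_chain_terminus(topo, ridx, first=True) and "N" in name_to_idx:
                positive.append((name_to_idx["N"],))
            if _is_chain_terminus(topo, ridx, first=False):
                grp = tuple(sorted(name_to_idx[n] for n in ("OXT", "O") if n in name_to_idx))
                if "OXT" in name_to_idx:
                    negative.append(grp)

    return ChemicalRoleTable(
        donors=donors,
        acceptors=acceptors,
        positive_groups=positive,
        negative_groups=negative,
        heavy_atoms=np.asarray(heavy, dtype=np.intp),
        radii=np.asarray(heavy_r, dtype=float),
        implicit_hydrogens=not has_h,
    )


def _is_chain_terminus(topo: Topology, ridx: int, *, first: bool) -> bool:
    res = topo.residues[ridx]
    if res.klass != "protein":
        return False
    chain = next(c for c in topo.chains if c.chain_id == res.chain_id)
    prot = [i for i in chain.residue_indices if topo.residues[i].klass == "protein"]
    if not prot:
        return False
    return ridx == (prot[0] if first else prot[-1])


# ---------------------------------------------------------------------------
# layer classification

def classify_pair_layer(topo: Topology, res_a: int, res_b: int) -> InteractionLayer:
    """Layer of a residue pair (symmetric in its arguments).

    ``intrachain`` compares *carrier* chains: a glycan rides the chain of
    its anchor Asn, so an Asn297 glycan contacting its own CH2 domain is
    intrachain even though the saccharides carry their own chain id.
    """
    ra, rb = topo.residues[res_a], topo.residues[res_b]
    for r in (ra, rb):
        if r.klass not in ("protein", "glycan"):
            raise TopologyError(f"residue {r.label()} has klass={r.klass!r}; classify first")
    kinds = sorted((ra.klass, rb.klass))
    kind = {
        ("protein", "protein"): "protein-protein",
        ("glycan", "protein"): "protein-glycan",
        ("glycan", "glycan"): "glycan-glycan",
    }[tuple(kinds)]
    span = (
        "intrachain"
        if topo.carrier_chain(res_a) == topo.carrier_chain(res_b)
        else "interchain"
    )
    return InteractionLayer(kind=kind, span=span)
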