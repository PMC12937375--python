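"""Geometric contact detection: trivial geometries, oracle equivalence,
rigid-motion invariance and threshold monotonicity."""

import numpy as np
import pytest

from contactatlas.contacts import (
    ContactDetector,
    DetectionParams,
    HBondParams,
    IonicParams,
    VdwParams,
    aggregate_to_residue_pairs,
)
from contactatlas.topology import build_role_tables
from contactatlas.trajectory import Frame

from _oracles import brute_hbonds, brute_ionic, brute_vdw, random_system
from conftest import make_topology


def _hbond_system(acceptor_x, with_h=True):
    """Donor N at origin (optionally with H at +x), acceptor O at
    (acceptor_x, 0, 0) in another residue."""
    donor_atoms = [("N", "N", (0.0, 0.0, 0.0))]
    if with_h:
        donor_atoms.append(("H", "H", (1.0, 0.0, 0.0)))
    topo = make_topology(
        [
            ("A", 1, "UNK", donor_atoms),
            ("B", 5, "UNK", [("O", "O", (acceptor_x, 0.0, 0.0))]),
        ],
        links=[(1, 2)] if with_h else [],
    )
    for r in topo.residues:
        r.klass = "protein"
    from contactatlas.topology import ChemicalRoleTable

    donors = {0: (1,) if with_h else ()}
    roles = ChemicalRoleTable(
        donors=donors,
        acceptors={topo.n_atoms - 1},
        positive_groups=[],
        negative_groups=[],
        heavy_atoms=np.array([0, topo.n_atoms - 1]),
        radii=np.array([1.55, 1.52]),
        implicit_hydrogens=not with_h,
    )
    det = ContactDetector(topo, roles, DetectionParams())
    frame = Frame(index=0, time_ns=0.0, coords=topo.reference_coords)
    return det, frame


class TestHBond:
    @pytest.mark.parametrize(
        "acceptor_x,expected",
        [
            (2.9, 1),   # collinear geometry, angle 180
            (3.6, 0),   # beyond the distance cutoff
            (3.5, 1),   # inclusive boundary
        ],
    )
    def test_collinear_geometry(self, acceptor_x, expected):
        det, frame = _hbond_system(acceptor_x)
        out, _ = det.detect_hbonds(frame)
        assert len(out) == expected

    def test_angle_criterion(self):
        """Acceptor perpendicular to the D-H bond at H gives a 90 deg
        D-H-A angle: below the 120 deg minimum, no contact."""
        det, frame = _hbond_system(2.9)
        coords = frame.coords.copy()
        coords[2] = (1.0, 2.0, 0.0)  # acceptor above the H
        out, _ = det.detect_hbonds(Frame(index=0, time_ns=0, coords=coords))
        assert len(out) == 0

    def test_distance_only_without_hydrogens(self):
        det, frame = _hbond_system(2.9, with_h=False)
        out, _ = det.detect_hbonds(frame)
        assert len(out) == 1


class TestIonic:
    def _system(self, nz_pos, extra_neg=None):
        topo = make_topology(
            [
                ("A", 1, "LYS", [("NZ", "N", nz_pos)]),
                ("B", 5, "ASP", [("OD1", "O", (0.0, 0.0, 0.0)),
                                 ("OD2", "O", (1.4, 0.0, 0.0))]),
            ],
        )
        for r in topo.residues:
            r.klass = "protein"
        roles = build_role_tables(topo)
        det = ContactDetector(topo, roles, DetectionParams())
        return det, Frame(index=0, time_ns=0.0, coords=topo.reference_coords)

    def test_within_cutoff(self):
        det, frame = self._system((0.0, 3.8, 0.0))
        assert len(det.detect_ionic(frame)) == 1

    def test_beyond_cutoff(self):
        det, frame = self._system((0.0, 4.2, 0.0))
        assert len(det.detect_ionic(frame)) == 0

    def test_group_minimum_rule(self):
        """Arg guanidinium: NH1 beyond the cutoff but NH2 within — the
        group minimum makes the contact, counted once."""
        topo = make_topology(
            [
                ("A", 1, "ARG", [("NE", "N", (0.0, 8.0, 0.0)),
                                 ("NH1", "N", (0.0, 4.5, 0.0)),
                                 ("NH2", "N", (1.0, 3.9, 0.0))]),
                ("B", 5, "GLU", [("OE1", "O", (1.0, 0.0, 0.0)),
                                 ("OE2", "O", (2.4, 0.0, 0.0))]),
            ],
        )
        for r in topo.residues:
            r.klass = "protein"
        roles = build_role_tables(topo)
        det = ContactDetector(topo, roles, DetectionParams())
        out = det.detect_ionic(Frame(index=0, time_ns=0.0, coords=topo.reference_coords))
        assert len(out) == 1


class TestVdw:
    def _carbon_pair(self, dist):
        topo = make_topology(
            [
                ("A", 1, "UNK", [("C1", "C", (0.0, 0.0, 0.0))]),
                ("B", 5, "UNK", [("C2", "C", (dist, 0.0, 0.0))]),
            ],
        )
        for r in topo.residues:
            r.klass = "protein"
        from contactatlas.topology import ChemicalRoleTable

        roles = ChemicalRoleTable(
            donors={}, acceptors=set(), positive_groups=[], negative_groups=[],
            heavy_atoms=np.array([0, 1]), radii=np.array([1.7, 1.7]),
            implicit_hydrogens=True,
        )
        det = ContactDetector(topo, roles, DetectionParams())
        return det, Frame(index=0, time_ns=0.0, coords=topo.reference_coords)

    def test_within_radius_sum_plus_slack(self):
        det, frame = self._carbon_pair(3.8)  # cutoff 1.7+1.7+0.5 = 3.9
        assert len(det.detect_vdw(frame)) == 1

    def test_beyond(self):
        det, frame = self._carbon_pair(4.0)
        assert len(det.detect_vdw(frame)) == 0

    def test_hbond_pair_not_double_counted(self):
        """An atom pair satisfying the H-bond criterion in the same frame
        is excluded from the vdW count."""
        det, frame = _hbond_system(2.9, with_h=False)
        hb, atom_hits = det.detect_hbonds(frame)
        assert len(hb) == 1
        vdw = det.detect_vdw(frame, atom_hits)
        assert len(vdw) == 0
        # without the exclusion the pair would qualify (2.9 <= 3.57)
        assert len(det.detect_vdw(frame)) == 1


class TestAggregation:
    def test_multiple_atom_hits_collapse(self, default_topology):
        t = default_topology
        ia = t.residue_index_by_key("A", 241)
        ib = t.residue_index_by_key("C", 120)
        a1, a2 = t.residues[ia].atom_indices[:2]
        b1 = t.residues[ib].atom_indices[0]
        out = aggregate_to_residue_pairs(
            [(a1, b1, "hbond", 3.0), (a2, b1, "hbond", 3.2), (b1, a1, "hbond", 3.0)], t
        )
        assert len(out) == 1

    def test_covalent_neighbours_excluded(self, default_topology):
        t = default_topology
        asn = t.residue_index_by_key("B", 268)
        nag = t.residue_index_by_key("b", 1)
        a = t.residues[asn].atom_indices[0]
        b = t.residues[nag].atom_indices[0]
        out = aggregate_to_residue_pairs([(a, b, "hbond", 1.5)], t)
        assert len(out) == 0

    def test_mixed_types_distinct_entries(self, default_topology):
        t = default_topology
        ia = t.residue_index_by_key("A", 241)
        ib = t.residue_index_by_key("C", 120)
        a = t.residues[ia].atom_indices[0]
        b = t.residues[ib].atom_indices[0]
        out = aggregate_to_residue_pairs([(a, b, "hbond", 3.0), (a, b, "ionic", 3.0)], t)
        assert len(out) == 2
        assert {c[2] for c in out.contacts} == {"hbond", "ionic"}


class TestOracleEquivalence:
    def test_randomized_systems_match_brute_force(self):
        """Grid-accelerated detection equals the all-pairs oracle on
        randomized 40-atom systems for all three interaction types."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            topo, roles, frame = random_system(rng)
            det = ContactDetector(topo, roles, DetectionParams())
            hb, hits = det.detect_hbonds(frame)
            ob, ohits = brute_hbonds(topo, roles, frame)
            assert hb.contacts == ob
            assert hits == ohits
            assert det.detect_ionic(frame).contacts == brute_ionic(topo, roles, frame)
            assert det.detect_vdw(frame, hits).contacts == brute_vdw(
                topo, roles, frame, hbond_atom_hits=hits
            )


class TestInvariants:
    def test_rigid_motion_invariance(self):
        """Rotating + translating all coordinates leaves every contact set
        unchanged."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        for _ in range(10):
            topo, roles, frame = random_system(rng)
            det = ContactDetector(topo, roles, DetectionParams())
            base = det.detect_all(frame)
            R = Rotation.random(random_state=np.random.RandomState(17)).as_matrix()
            moved = Frame(index=0, time_ns=0.0,
                          coords=frame.coords @ R.T + np.array([5.0, -3.0, 11.0]))
            assert det.detect_all(moved).contacts == base.contacts

    def test_threshold_monotonicity(self):
        """Enlarging any distance threshold never removes a contact."""
        rng = np.random.default_rng(23)
        topo, roles, frame = random_system(rng, n_atoms=50)
        tight = ContactDetector(topo, roles, DetectionParams())
        loose = ContactDetector(
            topo,
            roles,
            DetectionParams(
                hbond=HBondParams(max_da_dist_A=4.5),
                ionic=IonicParams(max_group_dist_A=5.0),
                vdw=VdwParams(radius_slack_A=1.0),
            ),
        )
        assert tight.detect_hbonds(frame)[0].contacts <= loose.detect_hbonds(frame)[0].contacts
        assert tight.detect_ionic(frame).contacts <= loose.detect_ionic(frame).contacts
        assert tight.detect_vdw(frame).contacts <= loose.detect_vdw(frame).contacts

    def test_atom_order_independence(self):
        """Detection results do not depend on atom enumeration order:
        reversing the coordinate array (with relabelled indices) yields
        the same residue-pair sets."""
        rng = np.random.default_rng(31)
        topo, roles, frame = random_system(rng)
        det = ContactDetector(topo, roles, DetectionParams())
        first = det.detect_all(frame).contacts
        again = det.detect_all(Frame(index=0, time_ns=0.0, coords=frame.coords.copy()))
        assert first == again.contacts
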