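import math

import numpy as np
import pytest

from phosbind.interactions import (
    InteractionError,
    PiCriteria,
    detect_hbonds,
    detect_pi_contacts,
    find_aromatic_rings,
    place_ligand_hydrogens,
    P_H_BOND_LENGTH,
    TETRAHEDRAL_ANGLE,
)
from phosbind.structure_io import AtomRecord, Structure, extract_ligand
from phosbind.synthetic import PiSiteSpec, make_pi_site, pi_site_ligand


def ligand_from(p_xyz, o_xyzs, c_xyzs=(), resname="PHS"):
    atoms = [
        AtomRecord(name="P", element="P", coords=p_xyz, residue_name=resname,
                   residue_number=90, chain_id="A", is_hetero=True)
    ]
    for i, xyz in enumerate(o_xyzs):
        atoms.append(AtomRecord(name=f"O{i+1}", element="O", coords=xyz,
                                residue_name=resname, residue_number=90,
                                chain_id="A", is_hetero=True))
    for i, xyz in enumerate(c_xyzs):
        atoms.append(AtomRecord(name=f"C{i+1}", element="C", coords=xyz,
                                residue_name=resname, residue_number=90,
                                chain_id="A", is_hetero=True))
    return extract_ligand(Structure(atoms=atoms, id="lig"), resname)


def tetrahedral_oxygens(p=np.zeros(3), bond=1.52):
    """Three O at ideal tetrahedral directions (109.47 deg pairwise)."""
    tet = math.radians(TETRAHEDRAL_ANGLE)
    w = np.array([0.0, 0.0, 1.0])
    out = []
    for k in range(3):
        phi = 2 * math.pi * k / 3
        d = math.cos(tet) * w + math.sin(tet) * np.array(
            [math.cos(phi), math.sin(phi), 0.0]
        )
        out.append(p + bond * d)
    return out


class TestHydrogenPlacement:
    def test_ideal_phosphite_tetrahedral_angles(self):
        lig = ligand_from(np.zeros(3), tetrahedral_oxygens())
        lig = place_ligand_hydrogens(lig)
        assert len(lig.hydrogens) == 1
        h_dir = lig.hydrogens[0] / np.linalg.norm(lig.hydrogens[0])
        for o in lig.oxygens:
            u = o.coords / np.linalg.norm(o.coords)
            ang = math.degrees(math.acos(np.dot(h_dir, u)))
            assert ang == pytest.approx(TETRAHEDRAL_ANGLE, abs=0.01)
        assert np.linalg.norm(lig.hydrogens[0]) == pytest.approx(P_H_BOND_LENGTH, abs=1e-9)

    def test_ideal_hypophosphite_two_hydrogens(self):
        o1, o2 = tetrahedral_oxygens()[:2]
        lig = ligand_from(np.zeros(3), [o1, o2], resname="HPS")
        lig = place_ligand_hydrogens(lig)
        assert len(lig.hydrogens) == 2
        h1, h2 = (h / np.linalg.norm(h) for h in lig.hydrogens)
        hh = math.degrees(math.acos(np.clip(np.dot(h1, h2), -1, 1)))
        assert hh == pytest.approx(TETRAHEDRAL_ANGLE, abs=0.01)
        for h in (h1, h2):
            for o in lig.oxygens:
                u = o.coords / np.linalg.norm(o.coords)
                ang = math.degrees(math.acos(np.clip(np.dot(h, u), -1, 1)))
                assert ang == pytest.approx(TETRAHEDRAL_ANGLE, abs=0.01)

    def test_distorted_phosphite_matches_vector_sum_oracle(self):
        rng = np.random.default_rng(12)
        oxys = tetrahedral_oxygens()
        oxys[0] = oxys[0] + rng.normal(0, 0.2, 3)
        lig = ligand_from(np.zeros(3), oxys)
        lig = place_ligand_hydrogens(lig)
        # independent arithmetic oracle: -normalised sum of P->O unit vectors
        s = sum(o / np.linalg.norm(o) for o in (np.asarray(o.coords) for o in lig.oxygens))
        oracle_dir = -s / np.linalg.norm(s)
        h_dir = lig.hydrogens[0] / np.linalg.norm(lig.hydrogens[0])
        assert np.abs(h_dir - oracle_dir).max() < 1e-9

    def test_phosphite_h_antiparallel_to_oxygen_sum(self):
        # invariant: dot(unit(P->H), sum of units) == -|sum of units|
        for seed in range(5):
            rng = np.random.default_rng(seed)
            oxys = [o + rng.normal(0, 0.1, 3) for o in tetrahedral_oxygens()]
            lig = place_ligand_hydrogens(ligand_from(np.zeros(3), oxys))
            s = sum(np.asarray(o.coords) / np.linalg.norm(o.coords) for o in lig.oxygens)
            h_dir = lig.hydrogens[0] / np.linalg.norm(lig.hydrogens[0])
            assert np.dot(h_dir, s) == pytest.approx(-np.linalg.norm(s), abs=1e-9)

    def test_methylphosphonate_gets_no_hydrogens(self):
        oxys = tetrahedral_oxygens()
        lig = ligand_from(np.zeros(3), oxys, c_xyzs=[[0, 0, 1.8]])
        lig = place_ligand_hydrogens(lig)
        assert lig.hydrogens == []

    def test_unsupported_pattern_raises(self):
        lig = ligand_from(np.zeros(3), tetrahedral_oxygens()[:1])
        with pytest.raises(InteractionError, match="1 O"):
            place_ligand_hydrogens(lig)


class TestRingPerception:
    @staticmethod
    def residue(resname, names, coords, number=10):
        return [
            AtomRecord(name=n, element=("N" if n.startswith("N") else "C"),
                       coords=c, residue_name=resname, residue_number=number,
                       chain_id="A")
            for n, c in zip(names, coords)
        ]

    @staticmethod
    def hexagon():
        ang = np.radians(np.arange(6) * 60.0)
        return np.column_stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)])

    def test_tyrosine_ring(self):
        atoms = self.residue("TYR", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], self.hexagon())
        rings, skipped = find_aromatic_rings(Structure(atoms=atoms, id="t"))
        assert [r.ring_label for r in rings] == ["TYR6"]
        assert skipped == []

    def test_tryptophan_has_two_rings(self):
        # rough indole: pentagon fused to hexagon, all in z=0 (planarity is
        # what matters to perception, not exact bond lengths)
        hex_names = ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]
        hexagon = self.residue("TRP", hex_names, self.hexagon())
        pent_coords = [
            [2.2, 0.8, 0.0],  # CG
            [3.2, 0.0, 0.0],  # CD1
            [2.5, -1.1, 0.0],  # NE1
        ]
        pent = self.residue("TRP", ["CG", "CD1", "NE1"], pent_coords)
        rings, skipped = find_aromatic_rings(Structure(atoms=hexagon + pent, id="t"))
        assert sorted(r.ring_label for r in rings) == ["TRP5", "TRP6"]

    def test_missing_atom_reported(self):
        atoms = self.residue("TYR", ["CG", "CD1", "CD2", "CE1", "CE2"], self.hexagon()[:5])
        rings, skipped = find_aromatic_rings(Structure(atoms=atoms, id="t"))
        assert rings == []
        assert len(skipped) == 1 and "CZ" in skipped[0]

    def test_nonplanar_ring_gated(self):
        coords = self.hexagon()
        coords[0, 2] = 0.5
        atoms = self.residue("TYR", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], coords)
        rings, skipped = find_aromatic_rings(Structure(atoms=atoms, id="t"))
        assert rings == []
        assert "planarity" in skipped[0]


class TestPiContacts:
    def test_generator_round_trip(self):
        s = make_pi_site(PiSiteSpec(2.6, 140.0, 0.3))
        lig = place_ligand_hydrogens(pi_site_ligand(s))
        rings, _ = find_aromatic_rings(s)
        contacts = detect_pi_contacts(lig, rings)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.plane_distance == pytest.approx(2.6, abs=1e-6)
        assert c.approach_angle == pytest.approx(140.0, abs=1e-3)
        assert c.centroid_offset == pytest.approx(0.3, abs=1e-6)
        assert c.ring.ring_label == "TYR6"

    def test_beyond_vdw_sum_rejected(self):
        s = make_pi_site(PiSiteSpec(3.5, 140.0, 0.3))
        lig = place_ligand_hydrogens(pi_site_ligand(s))
        rings, _ = find_aromatic_rings(s)
        assert detect_pi_contacts(lig, rings) == []

    @pytest.mark.parametrize("d", [2.0, 2.4, 2.8])
    @pytest.mark.parametrize("theta", [125.0, 140.0, 165.0])
    @pytest.mark.parametrize("offset", [0.0, 0.8, 1.4])
    def test_parameter_recovery_grid(self, d, theta, offset):
        s = make_pi_site(PiSiteSpec(d, theta, offset))
        lig = place_ligand_hydrogens(pi_site_ligand(s))
        rings, _ = find_aromatic_rings(s)
        contacts = detect_pi_contacts(lig, rings)
        assert len(contacts) >= 1
        c = contacts[0]
        assert c.plane_distance == pytest.approx(d, abs=1e-3)
        assert c.approach_angle == pytest.approx(theta, abs=1e-3)
        assert c.centroid_offset == pytest.approx(offset, abs=1e-3)

    def test_enlarging_criteria_never_removes_contacts(self):
        rng = np.random.default_rng(21)
        base = PiCriteria()
        wider = PiCriteria(max_plane_distance=3.4, max_centroid_offset=2.0,
                           angle_range=(110.0, 180.0))
        for _ in range(20):
            spec = PiSiteSpec(
                plane_distance=float(rng.uniform(1.8, 3.3)),
                approach_angle=float(rng.uniform(115.0, 175.0)),
                centroid_offset=float(rng.uniform(0.0, 1.9)),
            )
            s = make_pi_site(spec)
            lig = place_ligand_hydrogens(pi_site_ligand(s))
            rings, _ = find_aromatic_rings(s)
            narrow = detect_pi_contacts(lig, rings, base)
            wide = detect_pi_contacts(lig, rings, wider)
            narrow_keys = {(round(c.plane_distance, 6), round(c.approach_angle, 6))
                           for c in narrow}
            wide_keys = {(round(c.plane_distance, 6), round(c.approach_angle, 6))
                         for c in wide}
            assert narrow_keys <= wide_keys

    def test_missing_hydrogens_is_an_error(self):
        s = make_pi_site(PiSiteSpec())
        lig = pi_site_ligand(s)  # hydrogens not placed
        rings, _ = find_aromatic_rings(s)
        with pytest.raises(InteractionError, match="hydrogens"):
            detect_pi_contacts(lig, rings)


class TestHBonds:
    @staticmethod
    def site(serine_distance):
        atoms = [
            AtomRecord(name="P", element="P", coords=[0, 0, 0], residue_name="PHS",
                       residue_number=90, chain_id="A", is_hetero=True),
            AtomRecord(name="O1", element="O", coords=[1.52, 0, 0], residue_name="PHS",
                       residue_number=90, chain_id="A", is_hetero=True),
            AtomRecord(name="OG", element="O",
                       coords=[1.52 + serine_distance, 0, 0],
                       residue_name="SER", residue_number=130, chain_id="A"),
            AtomRecord(name="CB", element="C", coords=[1.52 + serine_distance, 1.5, 0],
                       residue_name="SER", residue_number=130, chain_id="A"),
        ]
        s = Structure(atoms=atoms, id="hb")
        return s, extract_ligand(s, "PHS")

    def test_serine_at_2p8_bonds(self):
        s, lig = self.site(2.8)
        bonds = detect_hbonds(lig, s)
        assert len(bonds) == 1
        assert bonds[0].partner_residue == "SER130(A)"
        assert bonds[0].distance == pytest.approx(2.8, abs=1e-9)

    def test_serine_at_4p0_does_not(self):
        s, lig = self.site(4.0)
        assert detect_hbonds(lig, s) == []

    def test_carbon_partners_excluded(self):
        s, lig = self.site(2.8)
        assert all(b.acceptor.element != "C" for b in detect_hbonds(lig, s, cutoff=10.0))

    def test_count_non_decreasing_in_cutoff(self):
        s, lig = self.site(2.8)
        counts = [len(detect_hbonds(lig, s, cutoff=c)) for c in (2.0, 2.5, 3.0, 3.5, 4.5)]
        assert counts == sorted(counts)

    def test_water_partner_allowed(self):
        s, lig = self.site(4.0)
        s.atoms.append(
            AtomRecord(name="O", element="O", coords=[1.52, 2.9, 0],
                       residue_name="HOH", residue_number=500, chain_id="W",
                       is_hetero=True)
        )
        lig2 = extract_ligand(s, "PHS")
        bonds = detect_hbonds(lig2, s)
        assert len(bonds) == 1
        assert bonds[0].acceptor.residue_name == "HOH"
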