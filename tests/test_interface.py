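"""Surface areas, buried-area decomposition, contacts, hydrogen bonds,
epitope segmentation and displacement analysis."""

import numpy as np
import pytest

from allofoot.gridsasa import grid_sasa
from allofoot.interface import (
    HbondCriteria,
    SasaParams,
    analyze_interface,
    buried_surface_area,
    compute_sasa,
    detect_hbonds,
    epitope_segments,
    find_contacts,
    golden_spiral_points,
    pairwise_bsa_decomposition,
    per_residue_displacement,
    shrake_rupley,
)
from allofoot.structure import structure_from_arrays
from allofoot.synthetic import (
    brute_force_contacts,
    brute_force_hbonds,
    hbond_pair_complex,
    oracle_bsa,
)

CARBON_R = 1.70
PROBE = 1.4


class TestShrakeRupley:
    def test_isolated_atom_equals_sphere_area(self):
        areas = shrake_rupley(np.zeros((1, 3)), np.array([CARBON_R]), PROBE, 960)
        assert areas[0] == pytest.approx(4 * np.pi * (CARBON_R + PROBE) ** 2, rel=1e-12)

    def test_far_apart_atoms_unoccluded(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        areas = shrake_rupley(coords, np.array([CARBON_R, CARBON_R]), PROBE, 960)
        iso = 4 * np.pi * (CARBON_R + PROBE) ** 2
        assert np.allclose(areas, iso)

    def test_two_sphere_overlap_matches_spherical_cap_closed_form(self):
        # expanded radii R1 = R2 = 3.1; centre distance d: the accessible area
        # of sphere 1 is 4 pi R^2 minus the cap of height h = R - d/2
        d = 4.0
        R = CARBON_R + PROBE
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = shrake_rupley(coords, np.array([CARBON_R, CARBON_R]), PROBE, 2000)
        h = R - d / 2.0
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * h
        assert areas[0] == pytest.approx(expected, rel=0.02)
        assert areas[1] == pytest.approx(expected, rel=0.02)

    def test_matches_quadrature_oracle_on_random_clusters(self):
        """Mean absolute per-atom deviation < 2% against the independent
        Gauss-Legendre oracle over 50 random toy clusters."""
        rng = np.random.default_rng(20240917)
        devs = []
        for _ in range(50):
            n = int(rng.integers(5, 15))
            coords = rng.uniform(0, 6.0, size=(n, 3))
            radii = rng.choice([1.52, 1.55, 1.70, 1.80], size=n)
            fast = shrake_rupley(coords, radii, PROBE, 960)
            slow = grid_sasa(coords, radii, PROBE, n_lat=24, n_lon=40)
            iso = 4 * np.pi * (radii + PROBE) ** 2
            devs.append(np.mean(np.abs(fast - slow) / iso))
        assert float(np.mean(devs)) < 0.02

    def test_deterministic_lattice(self):
        pts1 = golden_spiral_points(960)
        pts2 = golden_spiral_points(960)
        assert np.array_equal(pts1, pts2)
        assert np.allclose(np.linalg.norm(pts1, axis=1), 1.0)

    def test_unknown_element_raises_with_atom_named(self, fab_toy):
        st, _ = fab_toy
        params = SasaParams(radii_set={"N": 1.55, "O": 1.52})  # no carbon radius
        with pytest.raises(KeyError, match="C"):
            compute_sasa(st, params, ["A"])

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SasaParams(probe_radius=0.0)
        with pytest.raises(ValueError):
            SasaParams(n_sphere_points=50)


class TestBuriedSurfaceArea:
    def test_separated_chains_bury_nothing(self, apart_toy):
        st, _ = apart_toy
        assert buried_surface_area(st, ["A"], ["B"]) == pytest.approx(0.0, abs=1e-9)

    def test_total_footprint_equals_one_sided_delta_sasa(self, fab_toy):
        st, _ = fab_toy
        pair = pairwise_bsa_decomposition(st)
        total = buried_surface_area(st, ["A", "B"], ["H", "L"])
        assert sum(pair.values()) == pytest.approx(total, abs=0.1)

    def test_decomposition_matches_quadrature_oracle(self, fab_toy):
        st, _ = fab_toy
        total = sum(pairwise_bsa_decomposition(st).values())
        oracle = oracle_bsa(st, ["A", "B"], ["H", "L"])
        assert total == pytest.approx(oracle, rel=0.02)

    def test_untouched_pairs_are_exactly_zero(self, fab_toy):
        st, truth = fab_toy
        pair = pairwise_bsa_decomposition(st)
        for zero_pair in truth["zero_pairs"]:
            assert pair[zero_pair] == 0.0

    def test_both_sides_reported_and_half_buried_mean(self, fab_toy):
        # PISA-style cross-check: one-sided losses on either side are both
        # positive and their mean is a sensible half-buried area
        st, _ = fab_toy
        hla_loss = buried_surface_area(st, ["A", "B"], ["H", "L"])
        fab_loss = buried_surface_area(st, ["H", "L"], ["A", "B"])
        assert hla_loss > 0 and fab_loss > 0
        half = 0.5 * (hla_loss + fab_loss)
        assert min(hla_loss, fab_loss) <= half <= max(hla_loss, fab_loss)

    def test_footprint_invariant_under_rigid_motion(self, fab_toy):
        from scipy.spatial.transform import Rotation

        st, _ = fab_toy
        ref = sum(pairwise_bsa_decomposition(st).values())
        moved = st.copy()
        R = Rotation.from_euler("xyz", [31, -47, 102], degrees=True).as_matrix()
        t = np.array([13.0, -7.0, 21.0])
        for residues in moved.chains.values():
            for res in residues:
                for atom in res.atoms:
                    atom.coord = R @ atom.coord + t
        # the fixed sphere lattice makes finite-sample SASA only approximately
        # rotation invariant; 0.5% is the discretization scale at 960 points
        assert sum(pairwise_bsa_decomposition(moved).values()) == pytest.approx(ref, rel=0.005)

    def test_footprint_invariant_under_chain_reordering(self, fab_toy):
        st, _ = fab_toy
        ref = pairwise_bsa_decomposition(st)
        shuffled = st.copy()
        shuffled.chains = {cid: shuffled.chains[cid] for cid in ["L", "B", "H", "A"]}
        assert pairwise_bsa_decomposition(shuffled) == pytest.approx(ref, abs=0.1)

    def test_side_validation(self, fab_toy):
        st, _ = fab_toy
        with pytest.raises(ValueError):
            buried_surface_area(st, [], ["H"])
        with pytest.raises(ValueError):
            buried_surface_area(st, ["A"], ["A"])


class TestContacts:
    @pytest.mark.parametrize("d, expected", [(3.9, 1), (4.1, 0)])
    def test_cutoff_boundary(self, d, expected):
        rows = [
            ("A", 1, "A", [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (1.53, 0.0, 0.0))]),
            ("B", 1, "A", [("CA", "C", (1.53 + d, 0.0, 0.0))]),
        ]
        st = structure_from_arrays("T", rows, {"A": "hla_alpha", "B": "fab_heavy"})
        assert len(find_contacts(st, cutoff=4.0)) == expected

    def test_neighbor_search_equals_brute_force_on_every_fixture(
            self, fab_toy, hb_toy, apart_toy):
        for st, _ in (fab_toy, hb_toy, apart_toy):
            side_a = [c for c, r in st.role_map.items() if r in ("hla_alpha", "b2m")]
            side_b = [c for c, r in st.role_map.items() if r in ("fab_heavy", "fab_light")]
            got = {(c.residue_a.chain_id, c.residue_a.position,
                    c.residue_b.chain_id, c.residue_b.position)
                   for c in find_contacts(st, 4.0, side_a, side_b)}
            assert got == brute_force_contacts(st, side_a, side_b, 4.0)

    def test_contacts_monotone_in_cutoff(self, fab_toy):
        st, _ = fab_toy
        small = {(c.residue_a, c.residue_b) for c in find_contacts(st, 3.5)}
        large = {(c.residue_a, c.residue_b) for c in find_contacts(st, 4.5)}
        assert small <= large

    def test_contact_kinds_annotated(self, fab_toy):
        st, _ = fab_toy
        by_pair = {(c.residue_a.chain_id, c.residue_a.position,
                    c.residue_b.chain_id, c.residue_b.position): c.kind
                   for c in find_contacts(st)}
        assert by_pair[("A", 90, "L", 31)] == "hbond"
        assert by_pair[("A", 90, "L", 30)] == "nonbonded"

    def test_invalid_cutoff(self, fab_toy):
        st, _ = fab_toy
        with pytest.raises(ValueError):
            find_contacts(st, cutoff=0.0)


class TestHbonds:
    def test_ideal_pair_detected(self, hb_toy):
        st, truth = hb_toy
        got = {(h.residue_a.chain_id, h.residue_a.position, h.atom_a,
                h.residue_b.chain_id, h.residue_b.position, h.atom_b)
               for h in detect_hbonds(st)}
        assert got == truth["hbonds"] == {truth["planted_hbond"]}

    def test_pair_beyond_distance_criterion_rejected(self):
        st, _ = hbond_pair_complex(distance=3.8)
        assert detect_hbonds(st, HbondCriteria(3.5, 90.0)) == []

    def test_hbonds_monotone_in_distance_criterion(self, fab_toy):
        st, _ = fab_toy
        tight = {(h.atom_a, h.atom_b, h.residue_a, h.residue_b)
                 for h in detect_hbonds(st, HbondCriteria(3.0, 90.0))}
        loose = {(h.atom_a, h.atom_b, h.residue_a, h.residue_b)
                 for h in detect_hbonds(st, HbondCriteria(3.6, 90.0))}
        assert tight <= loose

    def test_full_inventory_matches_brute_force(self, fab_toy):
        st, truth = fab_toy
        got = {(h.residue_a.chain_id, h.residue_a.position, h.atom_a,
                h.residue_b.chain_id, h.residue_b.position, h.atom_b)
               for h in detect_hbonds(st)}
        assert got == truth["hbonds"]

    def test_deduplicated_per_atom_pair(self, fab_toy):
        st, _ = fab_toy
        keys = [(h.residue_a, h.atom_a, h.residue_b, h.atom_b) for h in detect_hbonds(st)]
        assert len(keys) == len(set(keys))

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HbondCriteria(max_donor_acceptor_distance=5.0)
        with pytest.raises(ValueError):
            HbondCriteria(min_donor_angle=-10.0)


class TestEpitopeSegments:
    @pytest.mark.parametrize("positions, gap, expected", [
        ({14, 16, 17, 18, 19, 39, 90}, 3, [[14, 16, 17, 18, 19], [39], [90]]),
        ({10}, 3, [[10]]),
        (set(), 3, []),
        ({1, 2, 3, 10, 11}, 3, [[1, 2, 3], [10, 11]]),
        ({1, 4, 7}, 3, [[1, 4, 7]]),
        ({1, 5}, 3, [[1], [5]]),
    ])
    def test_segmentation(self, positions, gap, expected):
        assert epitope_segments(positions, gap) == expected

    def test_report_segments_partition_epitope(self, fab_toy):
        st, truth = fab_toy
        rep = analyze_interface(st)
        assert rep.segments == truth["segments"]
        flattened = {p for seg in rep.segments for p in seg}
        assert flattened == {p for c, p in rep.epitope_residues if c == "A"}
        # every epitope residue appears in at least one contact
        contact_res = {(c.residue_a.chain_id, c.residue_a.position) for c in rep.contacts}
        assert rep.epitope_residues <= contact_res


class TestDisplacement:
    def _rod(self, cid="A"):
        rows = []
        for i in range(12):  # zig-zag keeps the CA trace non-collinear
            ca = (i * 3.8, 1.5 * (i % 2), 0.9 * (i % 3))
            rows.append((cid, i + 1, "G", [("CA", "C", ca),
                                           ("N", "N", (ca[0] - 1.0, ca[1] + 0.5, ca[2]))]))
        return structure_from_arrays("ROD", rows, {cid: "hla_alpha"})

    def test_identical_structures_show_zero_displacement(self):
        a, b = self._rod(), self._rod()
        disp = per_residue_displacement(a, b, range(1, 13))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in disp.values())

    def test_translated_residue_detected_when_excluded_from_fit(self):
        bound = self._rod()
        unbound = self._rod()
        for atom in bound.chains["A"][4].atoms:  # residue 5 moved 2 A in the bound form
            atom.coord = atom.coord + np.array([0.0, 0.0, 2.0])
        fit = [p for p in range(1, 13) if p != 5]
        disp = per_residue_displacement(bound, unbound, fit)
        assert disp[5] == pytest.approx(2.0, abs=1e-6)
        assert disp[1] == pytest.approx(0.0, abs=1e-6)

    def test_requires_three_shared_positions(self):
        a, b = self._rod(), self._rod()
        with pytest.raises(ValueError):
            per_residue_displacement(a, b, [1, 2])
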