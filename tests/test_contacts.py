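import numpy as np
import pytest

from pincermd import (DomainMap, Trajectory, catalog_to_table, detect_contacts,
                      hbond_count_series, unique_contact_catalog)

from conftest import make_topology


def _frame(atoms):
    """Build (coords, topology) from (resid, resname, atomname, xyz) tuples."""
    coords = np.array([a[3] for a in atoms], dtype=float)
    top = make_topology(
        len(atoms),
        resids=[a[0] for a in atoms],
        resnames=[a[1] for a in atoms],
        names=[a[2] for a in atoms],
        elements=[a[2][0] for a in atoms],
    )
    return coords, top


def _ring(resid, resname, center, normal, radius=1.4):
    """Six ring atoms of a Phe-like ring in the plane orthogonal to normal."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, normal)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    atoms = []
    for i, name in enumerate(names):
        angle = 2 * np.pi * i / 6
        pos = np.asarray(center) + radius * (np.cos(angle) * u +
                                             np.sin(angle) * v)
        atoms.append((resid, resname, name, tuple(pos)))
    return atoms


class TestSaltBridge:
    def test_within_threshold_detected(self):
        coords, top = _frame([
            (5, "LYS", "NZ", (0.0, 0, 0)),
            (100, "GLU", "OE1", (3.2, 0, 0)),
        ])
        events = detect_contacts(coords, top, types=["sb"])
        assert len(events) == 1
        e = events[0]
        assert (e.type, e.res_i, e.res_j) == ("sb", 5, 100)
        assert e.distance == pytest.approx(3.2)

    def test_beyond_threshold_ignored(self):
        coords, top = _frame([
            (5, "LYS", "NZ", (0.0, 0, 0)),
            (100, "GLU", "OE1", (4.5, 0, 0)),
        ])
        assert detect_contacts(coords, top, types=["sb"]) == []

    def test_boundary_inclusive(self):
        coords, top = _frame([
            (5, "LYS", "NZ", (0.0, 0, 0)),
            (100, "ASP", "OD2", (4.0, 0, 0)),
        ])
        assert len(detect_contacts(coords, top, types=["sb"])) == 1


class TestStacking:
    def test_parallel_rings_are_pi_stacking(self):
        atoms = _ring(1, "PHE", (0, 0, 0), (0, 0, 1)) + \
            _ring(50, "PHE", (0, 0, 4.0), (0, 0, 1))
        coords, top = _frame(atoms)
        events = detect_contacts(coords, top, types=["ps", "ts"])
        assert [e.type for e in events] == ["ps"]
        assert events[0].distance == pytest.approx(4.0)
        assert events[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_tilted_rings_are_t_stacking(self):
        tilt = np.radians(75)
        normal2 = (np.sin(tilt), 0.0, np.cos(tilt))
        atoms = _ring(1, "PHE", (0, 0, 0), (0, 0, 1)) + \
            _ring(50, "PHE", (0, 0, 4.0), normal2)
        coords, top = _frame(atoms)
        events = detect_contacts(coords, top, types=["ps", "ts"])
        assert [e.type for e in events] == ["ts"]
        assert events[0].angle == pytest.approx(75.0, abs=1e-6)

    def test_distant_rings_ignored(self):
        atoms = _ring(1, "PHE", (0, 0, 0), (0, 0, 1)) + \
            _ring(50, "PHE", (0, 0, 9.0), (0, 0, 1))
        coords, top = _frame(atoms)
        assert detect_contacts(coords, top, types=["ps", "ts"]) == []

    def test_incomplete_ring_skipped_with_warning(self):
        atoms = _ring(1, "PHE", (0, 0, 0), (0, 0, 1))[:-1]  # drop CZ
        atoms += _ring(50, "PHE", (0, 0, 4.0), (0, 0, 1))
        coords, top = _frame(atoms)
        with pytest.warns(UserWarning, match="ring"):
            events = detect_contacts(coords, top, types=["ps"])
        assert events == []


class TestPiCation:
    def test_cation_over_ring_detected(self):
        atoms = _ring(10, "TYR", (0, 0, 0), (0, 0, 1))
        atoms.append((80, "LYS", "NZ", (0.0, 0.0, 4.0)))
        coords, top = _frame(atoms)
        events = detect_contacts(coords, top, types=["pc"])
        assert len(events) == 1
        assert events[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_cation_in_ring_plane_rejected(self):
        atoms = _ring(10, "TYR", (0, 0, 0), (0, 0, 1))
        atoms.append((80, "LYS", "NZ", (5.0, 0.0, 0.0)))  # 90 deg off normal
        coords, top = _frame(atoms)
        assert detect_contacts(coords, top, types=["pc"]) == []


class TestHydrogenBonds:
    def test_ideal_donor_hydrogen_acceptor_counted(self):
        # N-H...O, 10 degrees off linear at the hydrogen
        h_pos = (1.0, 0.0, 0.0)
        angle = np.radians(180 - 10)
        a_pos = (1.0 + 1.9 * np.cos(np.radians(10)),
                 1.9 * np.sin(np.radians(10)), 0.0)
        coords, top = _frame([
            (1, "GLY", "N", (0.0, 0, 0)),
            (1, "GLY", "H", h_pos),
            (30, "GLY", "O", a_pos),
        ])
        events = detect_contacts(coords, top, types=["hbbb"])
        assert len(events) == 1
        assert events[0].type == "hbbb"

    def test_bent_geometry_rejected(self):
        coords, top = _frame([
            (1, "GLY", "N", (0.0, 0, 0)),
            (1, "GLY", "H", (1.0, 0, 0)),
            (30, "GLY", "O", (1.0, 2.5, 0.0)),  # ~90 deg at H
        ])
        assert detect_contacts(coords, top, types=["hbbb"]) == []

    def test_subtype_assignment(self):
        coords, top = _frame([
            (2, "SER", "OG", (0.0, 0, 0)),     # side-chain donor
            (40, "GLY", "O", (2.9, 0, 0)),     # backbone acceptor
        ])
        events = detect_contacts(coords, top,
                                 types=["hbbb", "hbsb", "hbss"])
        assert [e.type for e in events] == ["hbsb"]

    def test_sidechain_to_sidechain(self):
        coords, top = _frame([
            (2, "LYS", "NZ", (0.0, 0, 0)),
            (40, "ASN", "OD1", (3.0, 0, 0)),
        ])
        events = detect_contacts(coords, top, types=["hbss"])
        assert [e.type for e in events] == ["hbss"]

    def test_apolar_topology_has_zero_count(self):
        coords = np.zeros((3, 3))
        coords[1, 0], coords[2, 0] = 3.0, 6.0
        top = make_topology(3, resids=[1, 2, 3],
                            resnames=["ALA", "ALA", "ALA"],
                            names=["CB", "CB", "CB"],
                            elements=["C", "C", "C"])
        traj = Trajectory(topology=top, coords=coords[None], stride_ps=10.0)
        assert hbond_count_series(traj).values[0] == 0

    def test_persistent_bond_constant_series(self):
        coords, top = _frame([
            (1, "GLY", "N", (0.0, 0, 0)),
            (30, "GLY", "O", (2.9, 0, 0)),
        ])
        stack = np.repeat(coords[None], 10, axis=0)
        traj = Trajectory(topology=top, coords=stack, stride_ps=10.0)
        np.testing.assert_array_equal(hbond_count_series(traj).values,
                                      np.ones(10))


class TestCatalog:
    def _sb_frame(self, flip=False):
        a = (5, "LYS", "NZ", (0.0, 0, 0))
        b = (100, "GLU", "OE1", (3.2, 0, 0))
        atoms = [b, a] if flip else [a, b]
        return _frame(atoms)

    def test_single_medoid_catalog(self):
        coords, top = self._sb_frame()
        catalog = unique_contact_catalog([coords], top, types=["sb"])
        assert ("sb", 5, 100) in catalog
        assert catalog[("sb", 5, 100)]["n_medoids_observed"] == 1

    def test_union_idempotent(self):
        coords, top = self._sb_frame()
        one = unique_contact_catalog([coords], top, types=["sb"])
        two = unique_contact_catalog([coords, coords.copy()], top, types=["sb"])
        assert set(one) == set(two)
        assert two[("sb", 5, 100)]["n_medoids_observed"] == 2

    def test_atom_order_invariance(self):
        coords_a, top_a = self._sb_frame(flip=False)
        coords_b, top_b = self._sb_frame(flip=True)
        cat_a = unique_contact_catalog([coords_a], top_a, types=["sb"])
        cat_b = unique_contact_catalog([coords_b], top_b, types=["sb"])
        assert set(cat_a) == set(cat_b) == {("sb", 5, 100)}

    def test_domain_labels_in_table(self):
        coords, top = self._sb_frame()
        dmap = DomainMap(protein="toy",
                         entries=(("MID", 1, 50), ("PIWI", 60, 120)))
        catalog = unique_contact_catalog([coords], top, dmap, types=["sb"])
        table = catalog_to_table(catalog)
        row = table.iloc[0]
        assert (row.domain_i, row.domain_j, row.span) == \
            ("MID", "PIWI", "interdomain")

    def test_empty_medoid_list_rejected(self):
        coords, top = self._sb_frame()
        with pytest.raises(ValueError):
            unique_contact_catalog([], top)

    def test_events_satisfy_own_thresholds(self):
        atoms = _ring(1, "PHE", (0, 0, 0), (0, 0, 1)) + \
            _ring(50, "TYR", (1.0, 0, 4.0), (0.2, 0, 1.0))
        atoms += [(5, "LYS", "NZ", (0.5, 0.5, 3.0)),
                  (100, "GLU", "OE1", (0.5, 3.5, 3.0))]
        coords, top = _frame(atoms)
        for e in detect_contacts(coords, top):
            if e.type == "sb":
                assert e.distance <= 4.0
            elif e.type.startswith("hb"):
                assert e.distance <= 3.5
            elif e.type == "pc":
                assert e.distance <= 6.0 and e.angle <= 60.0
            elif e.type == "ps":
                assert e.distance <= 7.0 and e.angle <= 30.0
            elif e.type == "ts":
                assert e.distance <= 7.0 and 60.0 <= e.angle <= 90.0
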