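"""CPDb pseudodihedral, open/closed classification, SASA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flipscape import (Conformation, MoveSpec, build_duplex, classify_state,
                       cpdb, cpdb_sasa_table, group_rotation, minimize,
                       pseudo_dihedral, sasa)
from flipscape.database import PathDatabase


@pytest.mark.parametrize("pts, expected", [
    (((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)), 0.0),      # planar cis
    (((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)), 180.0),    # planar trans
    (((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)), -90.0),
])
def test_signed_dihedral_examples(pts, expected):
    assert pseudo_dihedral(*pts) == pytest.approx(expected, abs=1e-10)


def test_dihedral_degenerate_geometry_rejected():
    with pytest.raises(ValueError):
        pseudo_dihedral((0, 0, 0), (0, 0, 0), (1, 1, 0), (2, 1, 0))
    with pytest.raises(ValueError):  # collinear first three points
        pseudo_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None)
def test_dihedral_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3)) * 3.0
    try:
        ang = pseudo_dihedral(*pts)
    except ValueError:
        return
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.normal(size=3)
    moved = pts @ q.T + shift
    assert pseudo_dihedral(*moved) == pytest.approx(ang, abs=1e-9)
    # reflection flips the sign exactly
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    ang_m = pseudo_dihedral(*mirrored)
    if abs(abs(ang) - 180.0) > 1e-9:
        assert ang_m == pytest.approx(-ang, abs=1e-9)


@pytest.mark.parametrize("angle, state", [
    (0.0, "closed"), (30.0, "closed"), (-30.0, "closed"),
    (30.0001, "open_minor"), (95.0, "open_minor"),
    (-30.0001, "open_major"), (-170.0, "open_major"),
])
def test_open_closed_boundary_is_strict(angle, state):
    assert classify_state(angle) == state


class TestCpdbOnDuplex:
    def test_closed_duplex_central_bases_closed(self, duplex12):
        conf, pot, closed = duplex12
        cc = Conformation(closed.coords.reshape(-1, 3), conf.topology)
        for resid in range(3, 9):
            ang = cpdb(cc, (0, resid))
            assert abs(ang) < 30.0

    def test_flipped_base_large_angle(self, duplex12):
        conf, pot, closed = duplex12
        topo = conf.topology
        cc = Conformation(closed.coords.reshape(-1, 3), topo)
        flipped = minimize(group_rotation(
            cc, MoveSpec("glycosidic_axis", 0, 5, 180.0),
            angle_deg=150.0).flat, pot)
        fc = Conformation(flipped.coords.reshape(-1, 3), topo)
        assert abs(cpdb(fc, (0, 5))) > 90.0

    def test_mirror_flips_sign_exactly(self, duplex12):
        conf, *_ = duplex12
        ang = cpdb(conf, (0, 5))
        mirrored = Conformation(conf.coords * np.array([1.0, 1.0, -1.0]),
                                conf.topology)
        assert cpdb(mirrored, (0, 5)) == pytest.approx(-ang, abs=1e-9)

    def test_rigid_motion_invariance(self, duplex12):
        conf, *_ = duplex12
        ang = cpdb(conf, (0, 6))
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Conformation(conf.coords @ q.T + 7.0, conf.topology)
        assert cpdb(moved, (0, 6)) == pytest.approx(ang, abs=1e-9)

    def test_terminal_residue_rejected(self, duplex12):
        conf, *_ = duplex12
        with pytest.raises(ValueError):
            cpdb(conf, (0, 0))


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        r, probe = 2.0, 1.4
        area = sasa(np.zeros((1, 3)), [r], probe=probe, n_points=960)[0]
        assert area == pytest.approx(4 * np.pi * (r + probe) ** 2, rel=0.01)

    def test_distant_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = sasa(coords, [1.5, 2.5])
        singles = [sasa(np.zeros((1, 3)), [r])[0] for r in (1.5, 2.5)]
        assert areas[0] == pytest.approx(singles[0], rel=1e-6)
        assert areas[1] == pytest.approx(singles[1], rel=1e-6)

    def test_fully_buried_atom_zero(self):
        # central atom caged by 26 overlapping neighbors
        grid = np.array([[i, j, k] for i in (-1.5, 0, 1.5)
                         for j in (-1.5, 0, 1.5) for k in (-1.5, 0, 1.5)
                         if (i, j, k) != (0, 0, 0)])
        coords = np.vstack([[0.0, 0.0, 0.0], grid])
        radii = np.full(len(coords), 1.6)
        areas = sasa(coords, radii, probe=1.4)
        assert areas[0] == 0.0

    def test_convergence_in_point_count(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(8, 3)) * 2.0
        radii = np.full(8, 1.7)
        a1 = sasa(coords, radii, n_points=960)
        a2 = sasa(coords, radii, n_points=1920)
        scale = max(a2.max(), 1.0)
        assert np.max(np.abs(a1 - a2)) / scale < 0.005

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), [-1.0])


def test_cpdb_sasa_table_empty_db(duplex12):
    conf, *_ = duplex12
    db = PathDatabase(beads_3d=True, topology=conf.topology)
    assert cpdb_sasa_table(db, (0, 5)) == []


def test_cpdb_sasa_table_records(duplex12):
    conf, pot, closed = duplex12
    db = PathDatabase(beads_3d=True, topology=conf.topology)
    db.add_minimum(closed)
    records = cpdb_sasa_table(db, (0, 5), n_points=240)
    assert len(records) == 1
    rec = records[0]
    assert rec.state == "closed"
    assert rec.sasa["B"] >= 0.0


# --- all-atom dialect ------------------------------------------------------

def synthetic_allatom_pdb_atoms():
    """A synthetic three-residue two-chain fragment with proper atom
    names, built programmatically (a geometric stand-in, not a real
    structure)."""
    from flipscape.io import PdbAtom
    rng = np.random.default_rng(31)
    atoms = []
    serial = 0
    ring_names = {"DG": ("N9", "C8", "N7", "C5", "C4"),
                  "DA": ("N9", "C8", "N7", "C5", "C4"),
                  "DC": ("N1", "C2", "N3", "C4", "C5", "C6"),
                  "DT": ("N1", "C2", "N3", "C4", "C5", "C6")}
    chains = {"A": ["DG", "DA", "DG"], "B": ["DC", "DT", "DC"]}
    for ci, (chain, resnames) in enumerate(chains.items()):
        for ri, resname in enumerate(resnames):
            theta = np.deg2rad(ri * 36.0 + (60.0 if ci == 0 else -60.0))
            z = ri * 3.4
            base_center = np.array([2 * np.cos(theta), 2 * np.sin(theta), z])
            sugar = np.array([6 * np.cos(theta), 6 * np.sin(theta), z])
            phos = np.array([8.8 * np.cos(theta - 0.3),
                             8.8 * np.sin(theta - 0.3), z - 1.7])
            for name, pos in [("P", phos), ("OP1", phos + [0.5, 0, 0.2]),
                              ("OP2", phos + [-0.5, 0, 0.2]),
                              ("O5'", phos + [0, 0.5, 0.6]),
                              ("O3'", sugar + [0.3, -0.4, -0.8]),
                              ("C1'", sugar)]:
                serial += 1
                atoms.append(PdbAtom(serial, name, resname, chain, ri + 1,
                                     np.array(pos, dtype=float),
                                     name[0]))
            for k, name in enumerate(ring_names[resname]):
                serial += 1
                offset = rng.normal(scale=0.05, size=3)
                ring_pos = base_center + 0.8 * np.array(
                    [np.cos(2 * np.pi * k / 6), np.sin(2 * np.pi * k / 6),
                     0.0]) + offset
                atoms.append(PdbAtom(serial, name, resname, chain, ri + 1,
                                     ring_pos, name[0]))
    return atoms


def test_cpdb_allatom_dialect():
    atoms = synthetic_allatom_pdb_atoms()
    ang = cpdb(atoms, ("A", 2), dialect="allatom")
    assert -180.0 < ang <= 180.0
    mirrored = [a for a in atoms]
    import copy
    mirrored = copy.deepcopy(atoms)
    for a in mirrored:
        a.xyz = a.xyz * np.array([1.0, 1.0, -1.0])
    assert cpdb(mirrored, ("A", 2), dialect="allatom") == pytest.approx(
        -ang, abs=1e-9)


def test_cpdb_allatom_terminal_rejected():
    atoms = synthetic_allatom_pdb_atoms()
    with pytest.raises(ValueError):
        cpdb(atoms, ("A", 1), dialect="allatom")
    with pytest.raises(ValueError):
        cpdb(atoms, ("A", 9), dialect="allatom")
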