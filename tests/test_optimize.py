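"""Minimization, classification, group-rotation moves and basin-hopping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flipscape import (Conformation, MinimizationError, MoveSpec, basin_hop,
                       build_duplex, classify, group_rotation, minimize)
from flipscape.optimize import (metropolis_accept, random_displacement_move,
                                structural_distance)


def test_minimize_double_well(dw):
    sp = minimize([0.5], dw)
    assert sp.coords[0] == pytest.approx(1.0, abs=1e-6)
    assert sp.energy == pytest.approx(0.0, abs=1e-10)
    assert sp.index == 0


def test_minimize_muller_brown_global(mb):
    sp = minimize([0.0, 1.5], mb)
    assert np.allclose(sp.coords, [-0.558224, 1.441726], atol=1e-4)
    assert sp.energy == pytest.approx(-146.699517, abs=1e-4)


def test_minimize_never_returns_higher_energy(mb):
    rng = np.random.default_rng(2)
    for _ in range(10):
        x0 = rng.uniform([-1.2, -0.2], [1.0, 1.8])
        e0 = mb.energy(x0)
        sp = minimize(x0, mb)
        assert sp.energy <= e0 + 1e-10


def test_minimize_input_validation(dw):
    with pytest.raises(ValueError):
        minimize([np.nan], dw)
    with pytest.raises(ValueError):
        minimize([0.5], dw, gtol=-1.0)


def test_classify_zero_mode_removal():
    # six near-zero rigid modes removed by count, one genuine negative
    ev = np.array([-0.5] + [1e-9] * 6 + [0.3, 0.7])
    index, retained, ambiguous = classify(ev, n_zero_modes=6)
    assert index == 1
    assert len(retained) == 3
    assert not ambiguous
    # a soft mode inside the threshold is flagged, not dropped
    ev2 = np.array([5e-7] + [1e-12] * 6 + [0.3])
    _, _, amb2 = classify(ev2, n_zero_modes=6)
    assert amb2


def test_classify_point_particles():
    index, retained, _ = classify(np.array([-1.0, 2.0]), n_zero_modes=0)
    assert index == 1 and len(retained) == 2


class TestGroupRotation:
    @pytest.fixture(scope="class")
    def conf(self):
        return build_duplex("GAGAGAGA")

    def test_identity_at_zero_angle(self, conf):
        out = group_rotation(conf, MoveSpec("glycosidic_axis", 0, 3, 90.0),
                             angle_deg=0.0)
        assert np.array_equal(out.coords, conf.coords)

    def test_rotation_inverse(self, conf):
        move = MoveSpec("glycosidic_axis", 0, 3, 180.0)
        fwd = group_rotation(conf, move, angle_deg=180.0)
        back = group_rotation(fwd, move, angle_deg=-180.0)
        assert np.max(np.abs(back.coords - conf.coords)) < 1e-10

    def test_seeded_reproducibility(self, conf):
        move = MoveSpec("backbone_axis", 0, 3, 120.0, seed=42)
        a = group_rotation(conf, move)
        b = group_rotation(conf, move)
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, conf.coords)

    def test_only_target_beads_move(self, conf):
        topo = conf.topology
        out = group_rotation(conf, MoveSpec("glycosidic_axis", 0, 3, 180.0),
                             angle_deg=135.0)
        moved = topo.bead(0, 3, "B")
        for b in range(topo.n_beads):
            if b == moved:
                assert not np.array_equal(out.coords[b], conf.coords[b])
            else:
                assert np.array_equal(out.coords[b], conf.coords[b])

    def test_backbone_pivot_moves_whole_nucleotide(self, conf):
        topo = conf.topology
        out = group_rotation(conf, MoveSpec("backbone_axis", 0, 3, 180.0),
                             angle_deg=120.0)
        changed = {b for b in range(topo.n_beads)
                   if not np.allclose(out.coords[b], conf.coords[b],
                                      atol=1e-12)}
        expected = {topo.bead(0, 3, r) for r in "SB"}  # P lies on the axis
        assert changed <= expected | {topo.bead(0, 3, "P")}
        assert expected <= changed

    def test_pairwise_distances_preserved_within_rotated_set(self, conf):
        topo = conf.topology
        out = group_rotation(conf, MoveSpec("backbone_axis", 0, 4, 180.0),
                             angle_deg=77.0)
        beads = [topo.bead(0, 4, r) for r in "PSB"]
        for i in beads:
            for j in beads:
                d0 = np.linalg.norm(conf.coords[i] - conf.coords[j])
                d1 = np.linalg.norm(out.coords[i] - out.coords[j])
                assert abs(d0 - d1) < 1e-9

    def test_terminal_residue_refused(self, conf):
        with pytest.raises(ValueError, match="edge effects"):
            group_rotation(conf, MoveSpec("glycosidic_axis", 0, 0, 90.0))

    @given(st.floats(min_value=-180.0, max_value=180.0),
           st.floats(min_value=-180.0, max_value=180.0))
    @settings(max_examples=25, deadline=None)
    def test_rotations_compose(self, a1, a2):
        conf = build_duplex("GAGAGAGA")
        move = MoveSpec("glycosidic_axis", 0, 3, 180.0)
        seq = group_rotation(group_rotation(conf, move, angle_deg=a1),
                             move, angle_deg=a2)
        joint = group_rotation(conf, move, angle_deg=a1 + a2)
        assert np.max(np.abs(seq.coords - joint.coords)) < 1e-9

    def test_invalid_move_spec(self):
        with pytest.raises(ValueError):
            MoveSpec("bogus", 0, 3, 90.0)
        with pytest.raises(ValueError):
            MoveSpec("glycosidic_axis", 0, 3, 0.0)


def test_metropolis_limits():
    rng = np.random.default_rng(0)
    assert all(metropolis_accept(10.0, 1e12, rng) for _ in range(50))
    assert not any(metropolis_accept(1.0, 1e-12, rng) for _ in range(50))
    assert all(metropolis_accept(-1.0, 1e-12, rng) for _ in range(50))


def test_basin_hop_double_well_finds_both_minima(dw):
    minima = basin_hop([-1.0], dw, random_displacement_move(1.5),
                       temperature=2.0, n_steps=50, seed=7)
    xs = sorted(round(float(m.coords[0]), 6) for m in minima)
    assert xs == [-1.0, 1.0]


def test_basin_hop_muller_brown_finds_all_three(mb):
    minima = basin_hop([-1.0, 1.5], mb, random_displacement_move(1.0),
                       temperature=30.0, n_steps=200, seed=1)
    assert len(minima) == 3
    assert minima[0].energy == pytest.approx(-146.699517, abs=1e-4)


def test_basin_hop_reproducible(mb):
    kw = dict(temperature=30.0, n_steps=40, seed=9)
    a = basin_hop([0.0, 1.0], mb, random_displacement_move(1.0), **kw)
    b = basin_hop([0.0, 1.0], mb, random_displacement_move(1.0), **kw)
    assert len(a) == len(b)
    for ma, mbb in zip(a, b):
        assert np.array_equal(ma.coords, mbb.coords)


def test_basin_hop_validation(dw):
    with pytest.raises(ValueError):
        basin_hop([0.5], dw, random_displacement_move(1.0), temperature=1.0,
                  n_steps=0)
    with pytest.raises(ValueError):
        basin_hop([0.5], dw, random_displacement_move(1.0), temperature=-1.0,
                  n_steps=5)


def test_structural_distance_superposition():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(10, 3))
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    b = a @ q.T + np.array([3.0, -1.0, 2.0])
    assert structural_distance(a.ravel(), b.ravel(), beads_3d=True) < 1e-10
    assert structural_distance(a.ravel(), b.ravel(), beads_3d=False) > 1.0
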