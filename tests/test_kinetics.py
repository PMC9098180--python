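"""Harmonic thermodynamics, TST rates, graph transformation, and the
published-rate bookkeeping identities."""

import math

import numpy as np
import pytest

from flipscape import (RateNetwork, equilibrium_constant, gt_eliminate,
                       gt_reduce, harmonic_free_energy, lifetimes_from_rates,
                       mfpt, order_of_magnitude_ratio, tst_rate,
                       two_state_kinetics)
from flipscape.kinetics import equilibrium_occupations, gt_mfpt
from flipscape.reference import (kinetic_bookkeeping, load_reference_rates,
                                 thymine_decade_ratios)


def random_ergodic_network(rng, n):
    """Connected network with random rates in both directions."""
    rates = {}
    for i in range(1, n):
        j = int(rng.integers(0, i))
        rates[(i, j)] = float(rng.uniform(0.1, 10.0))
        rates[(j, i)] = float(rng.uniform(0.1, 10.0))
    for _ in range(n):
        i, j = (int(v) for v in rng.integers(0, n, 2))
        if i != j:
            rates[(i, j)] = float(rng.uniform(0.1, 10.0))
            rates[(j, i)] = float(rng.uniform(0.1, 10.0))
    return RateNetwork.from_rates(rates)


class TestHarmonicFreeEnergy:
    def test_single_mode_at_temperature(self):
        # one mode with nu = T makes the vibrational term vanish
        t = 0.7
        f = harmonic_free_energy(2.0, math.log(t), 1, t)
        assert f == pytest.approx(2.0, abs=1e-14)

    def test_doubling_frequencies_raises_f(self):
        t, kappa = 0.5, 4
        lpf = 4 * math.log(0.3)
        f1 = harmonic_free_energy(0.0, lpf, kappa, t)
        f2 = harmonic_free_energy(0.0, lpf + kappa * math.log(2.0), kappa, t)
        assert f2 - f1 == pytest.approx(t * kappa * math.log(2.0), rel=1e-12)

    def test_symmetry_number_lowers_f(self):
        f1 = harmonic_free_energy(0.0, 0.0, 1, 1.0, symmetry_number=1)
        f2 = harmonic_free_energy(0.0, 0.0, 1, 1.0, symmetry_number=2)
        assert f1 - f2 == pytest.approx(math.log(2.0), rel=1e-12)

    def test_identical_minima_equal_occupation(self):
        f = {0: 1.3, 1: 1.3}
        p = equilibrium_occupations(f, 0.4)
        assert p[0] == pytest.approx(0.5, abs=1e-14)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)


class TestTstRate:
    def test_zero_barrier_rate_is_prefactor(self):
        # 1-D: one minimum mode nu=1, no ts modes retained
        k = tst_rate(0.0, 0.0, 0.0, math.log(1.0), temperature=1.0)
        assert k == pytest.approx(1.0, rel=1e-12)

    def test_barrier_equal_temperature(self):
        nu = 0.8
        k = tst_rate(1.0, 0.0, 0.0, math.log(nu), temperature=1.0)
        assert k == pytest.approx(nu * math.exp(-1.0), rel=1e-12)

    def test_double_well_rate_vs_hand_computation(self, dw):
        """Symbolic second derivatives: V''(+-1)=8, V''(0)=-4, barrier 1."""
        from flipscape import connect_ts, hybrid_ef, minimize
        t = 0.1
        m = minimize([0.9], dw)
        ts = hybrid_ef(np.array([0.05]), dw)
        k = tst_rate(ts.energy, ts.point.log_product_frequencies,
                     m.energy, m.log_product_frequencies, t)
        nu_min = math.sqrt(8.0) / (2.0 * math.pi)
        k_hand = nu_min * math.exp(-1.0 / t)
        assert k == pytest.approx(k_hand, rel=1e-8)

    def test_ts_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            tst_rate(-1.0, 0.0, 0.0, 0.0, 1.0)


class TestGraphTransformation:
    def test_three_state_chain_mfpt(self):
        net = RateNetwork.from_rates({("A", "I"): 2.0, ("I", "A"): 1.0,
                                      ("I", "B"): 1.0, ("B", "I"): 2.0})
        assert mfpt(net, "A", {"B"}) == pytest.approx(2.0, rel=1e-12)
        assert gt_mfpt(net, "A", {"B"}) == pytest.approx(2.0, rel=1e-12)

    def test_mfpt_trivial_cases(self):
        net = RateNetwork.from_rates({("A", "B"): 5.0, ("B", "A"): 5.0})
        assert mfpt(net, "A", {"A"}) == 0.0
        assert mfpt(net, "A", {"B"}) == pytest.approx(0.2, rel=1e-12)

    def test_eliminating_single_neighbor_node(self):
        # dead-end node x reachable only from u: elimination folds x's
        # waiting time into u and adds no new edges
        net = RateNetwork.from_rates({("u", "x"): 1.0, ("x", "u"): 2.0,
                                      ("u", "v"): 1.0, ("v", "u"): 1.0})
        before_edges = set(net.branching["v"])
        reduced = gt_eliminate(net, "x")
        assert "x" not in reduced.branching
        assert set(reduced.branching["v"]) == before_edges
        # tau_u grows by P_xu * tau_x / (1 - P_xx)
        assert reduced.tau["u"] == pytest.approx(
            net.tau["u"] + 0.5 * net.tau["x"] / (1 - 0.0), rel=1e-12)

    def test_columns_still_sum_to_one(self):
        rng = np.random.default_rng(5)
        net = random_ergodic_network(rng, 12)
        red = gt_reduce(net, {0, 1})
        for u, nb in red.branching.items():
            assert sum(nb.values()) == pytest.approx(1.0, abs=1e-12)

    def test_gt_matches_dense_solve_20_nodes(self):
        rng = np.random.default_rng(8)
        net = random_ergodic_network(rng, 20)
        t_dense = mfpt(net, 0, {19})
        t_gt = gt_mfpt(net, 0, {19})
        assert abs(t_gt - t_dense) / t_dense < 1e-8

    def test_order_independence(self):
        rng = np.random.default_rng(21)
        net = random_ergodic_network(rng, 15)
        keep = {0, 14}
        inter = [n for n in net.nodes() if n not in keep]
        r1 = gt_reduce(net, keep)
        r2 = net.copy()
        for node in reversed(inter):
            gt_eliminate(r2, node, in_place=True)
        for u in r1.branching:
            assert r1.tau[u] == pytest.approx(r2.tau[u], rel=1e-10)
            for v in set(r1.branching[u]) | set(r2.branching[u]):
                assert r1.branching[u].get(v, 0.0) == pytest.approx(
                    r2.branching[u].get(v, 0.0), abs=1e-10)

    def test_eliminating_endpoint_guarded(self):
        net = RateNetwork.from_rates({("A", "B"): 1.0, ("B", "A"): 1.0})
        with pytest.raises(KeyError):
            gt_eliminate(net, "Z")


class TestTwoStateKinetics:
    def test_symmetric_double_well(self, dw_database):
        ids = sorted(dw_database.minima)
        ks = two_state_kinetics(dw_database, [ids[0]], [ids[1]], 0.25)
        assert ks.k_open == pytest.approx(ks.k_close, rel=1e-9)
        assert ks.equilibrium_constant == pytest.approx(1.0, rel=1e-9)
        assert ks.barrier_open > 0 and ks.barrier_close > 0

    def test_detailed_balance_of_tst_network(self, mb_database):
        t = 10.0
        net = RateNetwork.from_database(mb_database, t)
        for u in net.branching:
            for v in net.branching[u]:
                if u == v:
                    continue
                lhs = net.rate(u, v) * net.p_eq[u]
                rhs = net.rate(v, u) * net.p_eq[v]
                assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_keq_matches_partition_function_ratio(self, mb_database):
        t = 10.0
        ids = sorted(mb_database.minima,
                     key=lambda m: mb_database.minima[m].energy)
        ks = two_state_kinetics(mb_database, [ids[0]], [ids[1], ids[2]], t)
        zr = math.exp(-(ks.f_reactant) / t)
        zp = math.exp(-(ks.f_product) / t)
        assert ks.equilibrium_constant == pytest.approx(zp / zr, rel=1e-8)

    def test_lifetimes_are_exact_reciprocals(self, dw_database):
        ids = sorted(dw_database.minima)
        ks = two_state_kinetics(dw_database, [ids[0]], [ids[1]], 0.3)
        assert ks.lifetime_closed * ks.k_open == 1.0
        assert ks.lifetime_open * ks.k_close == 1.0

    def test_overlapping_groups_rejected(self, dw_database):
        ids = sorted(dw_database.minima)
        with pytest.raises(ValueError):
            two_state_kinetics(dw_database, [ids[0]], [ids[0]], 1.0)


class TestReferenceBookkeeping:
    def test_guanine_major_equilibrium_constant(self):
        df = kinetic_bookkeeping()
        row = df[(df.base == "G") & (df.groove == "major")
                 & (df.cpdb_deg == -47.99)].iloc[0]
        assert row.k_eq == pytest.approx(3.27e-7, rel=5e-3)

    def test_adenine_major_closed_lifetime(self):
        df = kinetic_bookkeeping()
        row = df[(df.base == "A") & (df.groove == "major")].iloc[0]
        assert row.lifetime_closed_s == pytest.approx(9.17e7, rel=5e-3)

    def test_equilibrium_constant_identity(self):
        assert equilibrium_constant(2.0, 8.0) == 0.25
        lc, lo = lifetimes_from_rates(4.0, 0.5)
        assert lc == 0.25 and lo == 2.0

    def test_thymine_rate_decades(self):
        ratios = thymine_decade_ratios()
        assert ratios["major_small_vs_major_large"] == 6
        assert ratios["minor_small_vs_major_large"] == 3

    def test_table_loads_with_expected_shape(self):
        df = load_reference_rates()
        assert len(df) == 14
        assert set(df.base) == {"A", "C", "G", "T"}
        assert set(df.groove) == {"major", "minor"}


def test_order_of_magnitude_ratio():
    assert order_of_magnitude_ratio(1e6, 1.0) == 6
    assert order_of_magnitude_ratio(1.0, 3.2e3) == 4  # log10 = 3.505
    assert order_of_magnitude_ratio(5.0, 5.0) == 0
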