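"""Harmonic thermodynamics, harmonic-TST rates, graph-transformation
reduction, and two-state opening/closing kinetics.

Conventions: internal units with k_B = h = 1 and unit masses.  A minimum
with potential energy V, symmetry number n and harmonic frequencies nu_l
(over its kappa retained positive modes) has classical free energy

    F = V + T * sum_l ln(nu_l / T) - T ln n.

The minimum-to-minimum rate constant through an adjacent transition state
is the classical harmonic TST expression

    k = (prod_l nu_l^min / prod_l nu_l^ts) * exp(-(V_ts - V_min) / T),

with kappa modes in the numerator and kappa - 1 in the denominator.
Phenomenological two-state rates are obtained by eliminating every
intermediate node of the branching-probability/waiting-time network with
the graph-transformation update rules, then weighting the escape rates of
the surviving reactant members by their equilibrium occupations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "harmonic_free_energy", "equilibrium_occupations", "tst_rate",
    "RateNetwork", "gt_eliminate", "gt_reduce", "mfpt",
    "two_state_kinetics", "KineticsSummary",
    "lifetimes_from_rates", "equilibrium_constant", "order_of_magnitude_ratio",
]


def harmonic_free_energy(energy: float, log_prod_freq: float, n_modes: int,
                         temperature: float, symmetry_number: int = 1) -> float:
    """Classical harmonic free energy of one stationary point.

    ``log_prod_freq`` is sum(ln nu_l) over the retained positive modes
    (kappa for a minimum, kappa - 1 for a transition state), ``n_modes``
    their count.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    t = temperature
    return (energy + t * (log_prod_freq - n_modes * math.log(t))
            - t * math.log(symmetry_number))


def free_energy_of(rec, temperature: float, n_modes: int | None = None) -> float:
    """Harmonic free energy of a database record (MinimumRecord/TSRecord)."""
    if n_modes is None:
        raise ValueError("n_modes required")
    return harmonic_free_energy(rec.energy, rec.log_prod_freq, n_modes,
                                temperature,
                                getattr(rec, "symmetry_number", 1))


def equilibrium_occupations(free_energies: dict, temperature: float) -> dict:
    """p_eq over a set of states from their free energies (sums to 1)."""
    fmin = min(free_energies.values())
    w = {k: math.exp(-(f - fmin) / temperature)
         for k, f in free_energies.items()}
    z = sum(w.values())
    return {k: v / z for k, v in w.items()}


def tst_rate(ts_energy: float, ts_log_prod_freq: float,
             min_energy: float, min_log_prod_freq: float,
             temperature: float) -> float:
    """Harmonic TST rate constant out of a minimum through one adjacent
    transition state (k_B = h = 1, frequencies in per-time units)."""
    if ts_energy < min_energy - 1e-9:
        raise ValueError("transition state lies below the minimum")
    prefactor = math.exp(min_log_prod_freq - ts_log_prod_freq)
    return prefactor * math.exp(-(ts_energy - min_energy) / temperature)


# ---------------------------------------------------------------------------
# rate networks and graph transformation

class RateNetwork:
    """Branching probabilities and waiting times over a set of nodes.

    ``branching[u][v]`` is the probability that the next jump from u goes
    to v; ``tau[u]`` the mean waiting time in u.  Built either directly
    from pairwise rate constants or from a stationary-point database.
    """

    def __init__(self):
        self.branching: dict = {}
        self.tau: dict = {}
        self.p_eq: dict = {}

    @classmethod
    def from_rates(cls, rates: dict, p_eq: dict | None = None) -> "RateNetwork":
        """``rates[(u, v)]`` = rate constant u -> v."""
        net = cls()
        total: dict = {}
        for (u, v), k in rates.items():
            if k < 0:
                raise ValueError("negative rate constant")
            total[u] = total.get(u, 0.0) + k
            net.branching.setdefault(u, {})
            net.branching.setdefault(v, {})
        for (u, v), k in rates.items():
            if total[u] > 0:
                net.branching[u][v] = net.branching[u].get(v, 0.0) + k / total[u]
        for u in net.branching:
            if total.get(u, 0.0) <= 0:
                raise ValueError(f"node {u} has no outgoing rate")
            net.tau[u] = 1.0 / total[u]
        if p_eq:
            net.p_eq = dict(p_eq)
        return net

    @classmethod
    def from_database(cls, db, temperature: float,
                      n_modes_min: int | None = None) -> "RateNetwork":
        """TST network over all minima of a path database.

        ``n_modes_min`` is the number of vibrational modes of a minimum
        (inferred from the first record's coordinates if omitted: 3N - 6
        for 3-D bead systems, the coordinate count for model surfaces).
        """
        first = next(iter(db.minima.values()))
        if n_modes_min is None:
            n = first.coords.size
            n_modes_min = n - 6 if db.beads_3d else n
        rates: dict = {}
        for rec in db.ts.values():
            if rec.min1 == rec.min2:
                continue
            for u, v in ((rec.min1, rec.min2), (rec.min2, rec.min1)):
                k = tst_rate(rec.energy, rec.log_prod_freq,
                             db.minima[u].energy, db.minima[u].log_prod_freq,
                             temperature)
                rates[(u, v)] = rates.get((u, v), 0.0) + k
        f = {m: free_energy_of(db.minima[m], temperature, n_modes_min)
             for m in db.minima
             if any(m in pair for pair in rates)}
        connected = {u for (u, v) in rates} | {v for (u, v) in rates}
        f = {m: f[m] for m in f if m in connected}
        net = cls.from_rates(rates,
                             p_eq=equilibrium_occupations(f, temperature))
        return net

    def nodes(self):
        return list(self.branching)

    def copy(self) -> "RateNetwork":
        net = RateNetwork()
        net.branching = {u: dict(nb) for u, nb in self.branching.items()}
        net.tau = dict(self.tau)
        net.p_eq = dict(self.p_eq)
        return net

    def column_sums(self) -> dict:
        return {u: sum(nb.values()) for u, nb in self.branching.items()}

    def rate(self, u, v) -> float:
        """Effective rate constant u -> v implied by branching/waiting."""
        return self.branching.get(u, {}).get(v, 0.0) / self.tau[u]


def gt_eliminate(net: RateNetwork, node, in_place: bool = False) -> RateNetwork:
    """Remove one intermediate node with the exact graph-transformation
    update: for all remaining u, v,

        P'_vu = P_vu + P_vx P_xu / (1 - P_xx),
        tau'_u = tau_u + P_xu tau_x / (1 - P_xx).

    (written with P_vu = probability of jumping u -> v).
    """
    if not in_place:
        net = net.copy()
    x = node
    if x not in net.branching:
        raise KeyError(f"node {x!r} not in network")
    pxx = net.branching[x].get(x, 0.0)
    denom = 1.0 - pxx
    if denom < 1e-14:
        raise FloatingPointError(
            f"1 - P_xx underflow ({denom:g}) eliminating node {x!r}")
    out_x = {v: p for v, p in net.branching[x].items() if v != x}
    for u in list(net.branching):
        if u == x:
            continue
        pxu = net.branching[u].pop(x, 0.0)
        if pxu == 0.0:
            continue
        net.tau[u] += pxu * net.tau[x] / denom
        for v, pvx in out_x.items():
            net.branching[u][v] = net.branching[u].get(v, 0.0) + pxu * pvx / denom
    del net.branching[x]
    del net.tau[x]
    net.p_eq.pop(x, None)
    return net


def gt_reduce(net: RateNetwork, keep, in_place: bool = False) -> RateNetwork:
    """Eliminate every node outside ``keep`` (any order; the result is
    order-independent)."""
    keep = set(keep)
    if not in_place:
        net = net.copy()
    for node in [n for n in net.nodes() if n not in keep]:
        gt_eliminate(net, node, in_place=True)
    return net


def mfpt(net: RateNetwork, source, target_set) -> float:
    """Mean first-passage time from ``source`` into ``target_set`` by an
    exact dense linear solve of t_u = tau_u + sum_v P_vu t_v."""
    targets = set(target_set)
    if source in targets:
        return 0.0
    others = [n for n in net.nodes() if n not in targets]
    if source not in others:
        raise KeyError("source not in network")
    idx = {n: i for i, n in enumerate(others)}
    m = len(others)
    a = np.eye(m)
    b = np.array([net.tau[n] for n in others])
    for u in others:
        for v, p in net.branching[u].items():
            if v in idx:
                a[idx[u], idx[v]] -= p
    t = np.linalg.solve(a, b)
    return float(t[idx[source]])


def gt_mfpt(net: RateNetwork, source, target_set) -> float:
    """Mean first-passage time via graph transformation: eliminate all
    nodes except the source and the targets, then tau'_s / (1 - P'_ss)."""
    targets = set(target_set)
    if source in targets:
        return 0.0
    reduced = gt_reduce(net, targets | {source})
    pss = reduced.branching[source].get(source, 0.0)
    return reduced.tau[source] / (1.0 - pss)


# ---------------------------------------------------------------------------
# two-state kinetics

@dataclass
class KineticsSummary:
    """Opening/closing rates between a reactant (closed) group A and a
    product (open) group B, with the derived bookkeeping quantities."""

    k_open: float
    k_close: float
    temperature: float
    barrier_open: float
    barrier_close: float
    f_reactant: float
    f_product: float
    f_ts: float

    @property
    def lifetime_closed(self) -> float:
        return 1.0 / self.k_open

    @property
    def lifetime_open(self) -> float:
        return 1.0 / self.k_close

    @property
    def equilibrium_constant(self) -> float:
        return self.k_open / self.k_close


def _group_free_energy(fs: dict, members, temperature: float) -> float:
    vals = [fs[m] for m in members]
    fmin = min(vals)
    z = sum(math.exp(-(f - fmin) / temperature) for f in vals)
    return fmin - temperature * math.log(z)


def _minimax_ts_free_energy(db, a_ids, b_ids, temperature: float,
                            n_modes_min: int) -> float:
    """Free energy of the highest-F transition state on the lowest-F path
    between the two groups (union-find over TS sorted by free energy)."""
    import networkx as nx
    f_ts = {t: free_energy_of(db.ts[t], temperature, n_modes_min - 1)
            for t in db.ts if db.ts[t].min1 != db.ts[t].min2}
    g = nx.Graph()
    g.add_nodes_from(db.minima)
    parent = {m: m for m in db.minima}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    a_set, b_set = set(a_ids), set(b_ids)
    for t in sorted(f_ts, key=lambda t: f_ts[t]):
        rec = db.ts[t]
        ra, rb = find(rec.min1), find(rec.min2)
        if ra != rb:
            parent[ra] = rb
        roots_a = {find(m) for m in a_set}
        roots_b = {find(m) for m in b_set}
        if roots_a & roots_b:
            return f_ts[t]
    raise ValueError("reactant and product groups are not connected")


def two_state_kinetics(db, a_ids, b_ids, temperature: float,
                       a_ensemble=None, b_ensemble=None) -> KineticsSummary:
    """Graph-transformation rates between a closed group A and an open
    group B of a stationary-point database.

    All intermediate minima are eliminated exactly; the phenomenological
    rate is the equilibrium-occupation-weighted escape rate from the
    reduced reactant group (steady-state formulation).

    ``a_ensemble`` / ``b_ensemble`` (supersets of the flux-carrying
    groups) set the occupation normalization and the group free
    energies.  With a partially sampled database whose reactant members
    equilibrate among themselves much faster than the reaction (local
    equilibrium), occupations belong to the whole ensemble even when
    only some members carry sampled reactive pathways; ensemble members
    outside the network contribute occupation but no flux, which biases
    the rate downward (unsampled pathways are counted as zero), never
    upward.
    """
    a_ids, b_ids = list(a_ids), list(b_ids)
    if not a_ids or not b_ids:
        raise ValueError("empty endpoint group")
    if set(a_ids) & set(b_ids):
        raise ValueError("reactant and product groups overlap")
    a_ensemble = list(a_ensemble) if a_ensemble is not None else a_ids
    b_ensemble = list(b_ensemble) if b_ensemble is not None else b_ids
    if not set(a_ids) <= set(a_ensemble) or not set(b_ids) <= set(b_ensemble):
        raise ValueError("ensembles must contain their flux groups")
    if set(a_ensemble) & set(b_ensemble):
        raise ValueError("reactant and product ensembles overlap")
    first = next(iter(db.minima.values()))
    n_modes_min = (first.coords.size - 6 if db.beads_3d
                   else first.coords.size)
    net = RateNetwork.from_database(db, temperature, n_modes_min=n_modes_min)
    for m in a_ids + b_ids:
        if m not in net.branching:
            raise ValueError(f"endpoint minimum {m} is not connected")
    # drop side components that contain no endpoint (their last member
    # would end up with a pure self-loop during elimination)
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(net.branching)
    for u, nb in net.branching.items():
        for v in nb:
            if u != v:
                g.add_edge(u, v)
    keep_nodes = set()
    for component in nx.connected_components(g):
        if component & (set(a_ids) | set(b_ids)):
            keep_nodes |= component
    missing = (set(a_ids) | set(b_ids)) - keep_nodes
    if missing:
        raise ValueError(f"endpoint minima {sorted(missing)} are not "
                         "connected to the reaction network")
    for node in [n for n in net.nodes() if n not in keep_nodes]:
        del net.branching[node]
        net.tau.pop(node, None)
        net.p_eq.pop(node, None)
    for u in net.branching:
        net.branching[u] = {v: p for v, p in net.branching[u].items()
                            if v in keep_nodes}
    reduced = gt_reduce(net, set(a_ids) | set(b_ids))

    fs = {m: free_energy_of(db.minima[m], temperature, n_modes_min)
          for m in db.minima}
    f_ref = min(fs.values())

    def group_rate(sources, sinks, ensemble):
        z = sum(math.exp(-(fs[m] - f_ref) / temperature) for m in ensemble)
        k = 0.0
        for s in sources:
            esc = sum(reduced.branching[s].get(t, 0.0) for t in sinks)
            w = math.exp(-(fs[s] - f_ref) / temperature) / z
            k += w * esc / reduced.tau[s]
        return k

    k_open = group_rate(a_ids, b_ids, a_ensemble)
    k_close = group_rate(b_ids, a_ids, b_ensemble)

    f_a = _group_free_energy(fs, a_ensemble, temperature)
    f_b = _group_free_energy(fs, b_ensemble, temperature)
    f_ts = _minimax_ts_free_energy(db, a_ids, b_ids, temperature, n_modes_min)
    return KineticsSummary(
        k_open=k_open, k_close=k_close, temperature=temperature,
        barrier_open=f_ts - f_a, barrier_close=f_ts - f_b,
        f_reactant=f_a, f_product=f_b, f_ts=f_ts)


# ---------------------------------------------------------------------------
# bookkeeping identities for published rate tables

def lifetimes_from_rates(k_open: float, k_close: float) -> tuple[float, float]:
    """(closed-state lifetime, open-state lifetime) = (1/k_open, 1/k_close)."""
    return 1.0 / k_open, 1.0 / k_close


def equilibrium_constant(k_open: float, k_close: float) -> float:
    return k_open / k_close


def order_of_magnitude_ratio(k1: float, k2: float) -> int:
    """Nearest-integer number of decades separating two rate constants."""
    return round(abs(math.log10(k1 / k2)))
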