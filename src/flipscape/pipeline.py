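"""End-to-end base-flipping pipeline on the coarse-grained duplex.

Chains the stages the package provides: build the duplex, find the
closed state, basin-hop with glycosidic group rotations to discover
flipped minima, connect closed and open endpoint states through the
stationary-point database, extract two-state kinetics by graph
transformation, and compute the disconnectivity tree and CPDb/SASA
order-parameter table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .database import PathDatabase, connect_endpoints
from .disconnectivity import build_tree, color_by_order_param
from .duplex import CGDuplexPotential, Conformation, ModelParams, build_duplex
from .kinetics import KineticsSummary, two_state_kinetics
from .optimize import basin_hop, group_rotation_move, minimize
from .orderparams import OPEN_THRESHOLD_DEG, classify_state, cpdb, cpdb_sasa_table

__all__ = ["FlippingResult", "run_flipping_pipeline"]


@dataclass
class FlippingResult:
    """Everything the duplex base-flipping analysis produces."""

    sequence: str
    target: tuple
    db: PathDatabase
    potential: CGDuplexPotential
    closed_ids: list
    open_ids: list
    cpdb_by_min: dict
    kinetics: KineticsSummary | None
    tree: object | None
    records: list
    connected: bool
    timings: dict = field(default_factory=dict)


def run_flipping_pipeline(sequence: str = "GAGAGAGAGAGA",
                          target: tuple = (0, 5),
                          params: ModelParams | None = None,
                          seed: int = 1,
                          bh_steps: int = 35,
                          bh_temperature: float = 1.5,
                          temperature: float = 0.6,
                          connect_budget: int = 25,
                          n_images: int = 15,
                          gtol: float = 1e-6,
                          n_levels: int = 30,
                          with_sasa: bool = True,
                          verbose: bool = False) -> FlippingResult:
    """Run the full landscape analysis for flipping one base.

    ``target`` is (strand, residue) of the central base to flip.  The
    reactant group (closed) contains every minimum with |CPDb| <= 30 deg
    for the target base; the product group (open) the rest.
    """
    timings = {}
    t0 = time.time()
    conf = build_duplex(sequence, params)
    topo = conf.topology
    pot = CGDuplexPotential(topo, params)
    closed = minimize(conf.flat, pot, gtol=gtol)
    timings["minimize_closed"] = time.time() - t0

    t0 = time.time()
    move = group_rotation_move(topo, "glycosidic_axis", [target],
                               amplitude_deg=180.0)
    minima = basin_hop(closed.coords, pot, move, temperature=bh_temperature,
                       n_steps=bh_steps, seed=seed, gtol=gtol)
    timings["basin_hop"] = time.time() - t0

    db = PathDatabase(beads_3d=True, topology=topo)
    ids = [db.add_minimum(m) for m in minima]

    def angle_of(mid):
        c = Conformation(db.minima[mid].coords.reshape(-1, 3), topo)
        return cpdb(c, target)

    cpdb_by_min = {mid: angle_of(mid) for mid in db.minima}
    closed_ids = [m for m, a in cpdb_by_min.items()
                  if classify_state(a) == "closed"]
    open_ids = [m for m in db.minima if m not in closed_ids]

    connected = False
    kinetics = None
    if open_ids:
        import networkx as nx
        from .optimize import structural_distance

        t0 = time.time()

        def both_classes_linked(current_db):
            g2 = current_db.minima_graph()
            known = dict(cpdb_by_min)
            for mid in current_db.minima:
                if mid not in known:
                    known[mid] = angle_of(mid)
            closed_now = {m for m, ang in known.items()
                          if classify_state(ang) == "closed"}
            for component in nx.connected_components(g2):
                if len(component) < 2:
                    continue
                has_closed = bool(component & closed_now)
                has_open = bool(component - closed_now)
                if has_closed and has_open:
                    return True
            return False

        # attempt closed-open gaps nearest-first, re-classifying after
        # every round so that newly discovered near-boundary minima
        # immediately become candidate endpoints
        remaining = connect_budget
        attempted_pairs: set = set()
        while remaining > 0 and not both_classes_linked(db):
            angles_now = {mid: angle_of(mid) for mid in db.minima}
            closed_now = [m for m, ang in angles_now.items()
                          if classify_state(ang) == "closed"]
            open_now = [m for m in db.minima if m not in closed_now]
            if not open_now:
                break
            candidates = sorted(
                ((c, o) for c in closed_now for o in open_now
                 if frozenset((c, o)) not in attempted_pairs),
                key=lambda p: structural_distance(db.minima[p[0]].coords,
                                                  db.minima[p[1]].coords,
                                                  True))
            if not candidates:
                break
            c, o = candidates[0]
            attempted_pairs.add(frozenset((c, o)))
            chunk = max(min(3, remaining), 1)
            res = connect_endpoints(db, c, o, pot, budget=chunk,
                                    n_images=n_images, gtol=gtol,
                                    stop_when=both_classes_linked,
                                    verbose=verbose)
            remaining -= max(res.attempts, 1)

        timings["connect"] = time.time() - t0
        # classify any minima discovered during connection attempts
        cpdb_by_min = {mid: angle_of(mid) for mid in db.minima}
        closed_ids = [m for m, ang in cpdb_by_min.items()
                      if classify_state(ang) == "closed"]
        open_ids = [m for m in db.minima if m not in closed_ids]
        # the reaction is connected once one component of the minima graph
        # carries both classes; that component's members transport the
        # flux, while occupations are normalized over the full closed and
        # open ensembles (closed states interconvert over far smaller
        # barriers than the opening barrier, so local equilibrium within
        # each group is an excellent approximation)
        comp = None
        g = db.minima_graph()
        for component in nx.connected_components(g):
            if (set(closed_ids) & component) and (set(open_ids) & component):
                if comp is None or len(component) > len(comp):
                    comp = component
        connected = comp is not None
        if connected:
            t0 = time.time()
            a_grp = [m for m in closed_ids if m in comp]
            b_grp = [m for m in open_ids if m in comp]
            kinetics = two_state_kinetics(db, a_grp, b_grp, temperature,
                                          a_ensemble=closed_ids,
                                          b_ensemble=open_ids)
            timings["kinetics"] = time.time() - t0

    tree = None
    records = []
    if db.ts:
        tree = build_tree(db, n_levels=n_levels, energy_kind="potential")
        color_by_order_param(tree, cpdb_by_min)
    if with_sasa:
        records = cpdb_sasa_table(db, target)

    return FlippingResult(sequence=sequence, target=target, db=db,
                          potential=pot, closed_ids=closed_ids,
                          open_ids=open_ids, cpdb_by_min=cpdb_by_min,
                          kinetics=kinetics, tree=tree, records=records,
                          connected=connected, timings=timings)
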