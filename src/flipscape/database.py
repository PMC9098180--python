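"""Stationary-point databases and discrete paths.

A :class:`PathDatabase` holds deduplicated minima and transition states
with their connectivity.  The missing-connection machinery chooses which
unconnected minima pairs to attempt next (Dijkstra with distance-squared
weights on unconnected gaps), and :func:`connect_endpoints` drives the
full double-ended search loop: band -> saddle refinement -> pushoff
connection -> database growth, until the endpoints join.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .optimize import MinimizationError, StationaryPoint, structural_distance
from .potentials import Potential
from .saddle import SaddleSearchError, TransitionState, connect_ts, dneb, hybrid_ef

__all__ = [
    "MinimumRecord", "TSRecord", "PathDatabase", "DiscretePath",
    "missing_connection_pairs", "connect_endpoints", "best_discrete_path",
    "path_profile",
]


@dataclass
class MinimumRecord:
    id: int
    energy: float
    log_prod_freq: float
    coords: np.ndarray
    index: int = 0
    symmetry_number: int = 1


@dataclass
class TSRecord:
    id: int
    energy: float
    log_prod_freq: float
    min1: int
    min2: int
    coords: np.ndarray
    frames_down: list | None = None
    frames_up: list | None = None


class PathDatabase:
    """Deduplicated minima + transition states with connectivity.

    Two stationary points are considered the same iff their energies agree
    within ``etol`` AND their best-superposition RMSD is within ``dtol``.
    """

    def __init__(self, etol: float = 1e-6, dtol: float = 0.05,
                 beads_3d: bool = False, topology=None):
        self.minima: dict[int, MinimumRecord] = {}
        self.ts: dict[int, TSRecord] = {}
        self.etol = etol
        self.dtol = dtol
        self.beads_3d = beads_3d
        self.topology = topology
        self._next_min = 0
        self._next_ts = 0

    # -- insertion -------------------------------------------------------
    def _find_match(self, table, energy, coords):
        for rec in table.values():
            if abs(rec.energy - energy) <= self.etol and structural_distance(
                    rec.coords, coords, self.beads_3d) <= self.dtol:
                return rec.id
        return None

    def add_minimum(self, sp: StationaryPoint) -> int:
        if sp.index != 0:
            raise ValueError("not a minimum (index != 0)")
        match = self._find_match(self.minima, sp.energy, sp.coords)
        if match is not None:
            return match
        mid = self._next_min
        self._next_min += 1
        self.minima[mid] = MinimumRecord(
            id=mid, energy=sp.energy,
            log_prod_freq=sp.log_product_frequencies,
            coords=np.asarray(sp.coords, dtype=float).copy(),
            symmetry_number=sp.symmetry_number)
        return mid

    def add_transition_state(self, ts: TransitionState) -> int:
        if ts.point.index != 1:
            raise ValueError("not a transition state (index != 1)")
        if ts.min_down is None or ts.min_up is None:
            raise ValueError("transition state endpoints are not connected; "
                             "run connect_ts first")
        m1 = self._find_match(self.minima, ts.min_down.energy, ts.min_down.coords)
        m2 = self._find_match(self.minima, ts.min_up.energy, ts.min_up.coords)
        if m1 is None or m2 is None:
            raise ValueError("transition state endpoints are absent from the "
                             "database; add the minima first")
        match = self._find_match(self.ts, ts.energy, ts.coords)
        if match is not None:
            return match
        tid = self._next_ts
        self._next_ts += 1
        self.ts[tid] = TSRecord(
            id=tid, energy=ts.energy,
            log_prod_freq=ts.point.log_product_frequencies,
            min1=m1, min2=m2,
            coords=np.asarray(ts.coords, dtype=float).copy(),
            frames_down=ts.frames_down, frames_up=ts.frames_up)
        return tid

    def add_stationary_point(self, sp) -> int:
        """Dispatch on the point's Hessian index (TS objects carry their
        connected minima and are rejected if those are absent)."""
        if isinstance(sp, TransitionState):
            return self.add_transition_state(sp)
        if sp.index == 0:
            return self.add_minimum(sp)
        raise ValueError(f"cannot store stationary point of index {sp.index}")

    # -- graph views -----------------------------------------------------
    def minima_graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.minima)
        for rec in self.ts.values():
            if rec.min1 != rec.min2:
                g.add_edge(rec.min1, rec.min2, ts_id=rec.id, energy=rec.energy)
        return g

    def connected(self, a: int, b: int) -> bool:
        g = self.minima_graph()
        return nx.has_path(g, a, b)

    # -- persistence -----------------------------------------------------
    FORMAT_VERSION = 1

    def save(self, run_dir) -> None:
        """Plain-text tables + XYZ coordinate files under ``run_dir``."""
        run_dir = Path(run_dir)
        (run_dir / "coords").mkdir(parents=True, exist_ok=True)
        from .io import write_xyz
        labels = (list(self.topology.role) if self.topology is not None
                  else None)

        def coord_file(kind, i):
            return f"coords/{kind}{i:05d}.xyz"

        def write_coords(fn, coords):
            if coords.size % 3 == 0 and coords.size >= 3:
                labs = labels if (labels is not None
                                  and len(labels) == coords.size // 3) \
                    else ["X"] * (coords.size // 3)
                write_xyz(run_dir / fn, coords.reshape(-1, 3), labs)
            else:  # 1-D/2-D model surfaces: one row of coordinates
                (run_dir / fn).write_text(
                    "# raw coordinates\n"
                    + " ".join(f"{v:.17g}" for v in coords.ravel()) + "\n")

        lines = [f"# flipscape minima table v{self.FORMAT_VERSION}",
                 "# id\tV\tlog_prod_freq\tindex\tcoords_file"]
        for rec in sorted(self.minima.values(), key=lambda r: r.id):
            fn = coord_file("min", rec.id)
            write_coords(fn, rec.coords)
            lines.append(f"{rec.id}\t{rec.energy:.17g}\t"
                         f"{rec.log_prod_freq:.17g}\t{rec.index}\t{fn}")
        (run_dir / "minima.tsv").write_text("\n".join(lines) + "\n")

        lines = [f"# flipscape ts table v{self.FORMAT_VERSION}",
                 "# id\tV\tlog_prod_freq\tmin1\tmin2\tcoords_file"]
        for rec in sorted(self.ts.values(), key=lambda r: r.id):
            fn = coord_file("ts", rec.id)
            write_coords(fn, rec.coords)
            lines.append(f"{rec.id}\t{rec.energy:.17g}\t{rec.log_prod_freq:.17g}"
                         f"\t{rec.min1}\t{rec.min2}\t{fn}")
        (run_dir / "ts.tsv").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, run_dir, etol: float = 1e-6, dtol: float = 0.05,
             beads_3d: bool = False, topology=None) -> "PathDatabase":
        run_dir = Path(run_dir)
        db = cls(etol=etol, dtol=dtol, beads_3d=beads_3d, topology=topology)
        from .io import read_xyz

        def load_coords(fn):
            path = run_dir / fn
            first = path.read_text().split("\n", 1)[0].strip()
            if not first.startswith("#"):
                coords, _, _ = read_xyz(path)
                return coords.ravel()
            return np.loadtxt(path).ravel()

        for line in (run_dir / "minima.tsv").read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            sid, v, lpf, idx, fn = line.split("\t")
            rec = MinimumRecord(id=int(sid), energy=float(v),
                                log_prod_freq=float(lpf),
                                coords=load_coords(fn), index=int(idx))
            db.minima[rec.id] = rec
        for line in (run_dir / "ts.tsv").read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            sid, v, lpf, m1, m2, fn = line.split("\t")
            rec = TSRecord(id=int(sid), energy=float(v),
                           log_prod_freq=float(lpf), min1=int(m1),
                           min2=int(m2), coords=load_coords(fn))
            db.ts[rec.id] = rec
        db._next_min = max(db.minima, default=-1) + 1
        db._next_ts = max(db.ts, default=-1) + 1
        return db


# ---------------------------------------------------------------------------
# missing-connection pair selection

def missing_connection_pairs(db: PathDatabase, endpoint_a: int,
                             endpoint_b: int, cap: float = 2.0):
    """Unconnected minima pairs along the current best route from a to b.

    Builds a complete graph over the minima: edges already linked by a
    transition state have weight 0; unconnected pairs get
    min(RMSD, cap)^2.  The unconnected edges on the Dijkstra shortest
    path are returned in path order.
    """
    if endpoint_a not in db.minima or endpoint_b not in db.minima:
        raise KeyError("endpoints must be in the database")
    if endpoint_a == endpoint_b:
        return []
    linked = set()
    for rec in db.ts.values():
        linked.add(frozenset((rec.min1, rec.min2)))
    g = nx.Graph()
    g.add_nodes_from(db.minima)
    for i, j in itertools.combinations(db.minima, 2):
        if frozenset((i, j)) in linked:
            g.add_edge(i, j, weight=0.0)
        else:
            d = structural_distance(db.minima[i].coords, db.minima[j].coords,
                                    db.beads_3d)
            g.add_edge(i, j, weight=min(d, cap) ** 2)
    path = nx.dijkstra_path(g, endpoint_a, endpoint_b)
    return [(u, v) for u, v in zip(path, path[1:])
            if frozenset((u, v)) not in linked]


@dataclass
class DiscretePath:
    """Alternating minimum-ts-minimum-...-minimum sequence with per-segment
    approximate steepest-descent polylines."""

    minima_ids: list
    ts_ids: list
    db: PathDatabase

    def __post_init__(self):
        if len(self.minima_ids) != len(self.ts_ids) + 1:
            raise ValueError("path must alternate min-ts-min")
        for k, tid in enumerate(self.ts_ids):
            rec = self.db.ts[tid]
            if {rec.min1, rec.min2} != {self.minima_ids[k], self.minima_ids[k + 1]}:
                raise ValueError(f"ts {tid} does not connect "
                                 f"{self.minima_ids[k]} and {self.minima_ids[k + 1]}")

    @property
    def highest_ts_energy(self) -> float:
        return max(self.db.ts[t].energy for t in self.ts_ids)


def best_discrete_path(db: PathDatabase, a: int, b: int) -> DiscretePath:
    """Minimum-barrier discrete path: directed Dijkstra where the edge
    through a transition state costs max(V_ts - V_from, 0)."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(db.minima)
    for rec in db.ts.values():
        if rec.min1 == rec.min2:
            continue
        for u, v in ((rec.min1, rec.min2), (rec.min2, rec.min1)):
            w = max(rec.energy - db.minima[u].energy, 0.0)
            g.add_edge(u, v, weight=w, ts_id=rec.id)
    path = nx.dijkstra_path(g, a, b)
    ts_ids = []
    for u, v in zip(path, path[1:]):
        edges = g.get_edge_data(u, v)
        best = min(edges.values(), key=lambda e: e["weight"])
        ts_ids.append(best["ts_id"])
    return DiscretePath(minima_ids=path, ts_ids=ts_ids, db=db)


@dataclass
class ConnectResult:
    path: DiscretePath | None
    attempts: int
    succeeded: bool


def connect_endpoints(db: PathDatabase, a: int, b: int, potential: Potential,
                      budget: int = 30, n_images: int = 15,
                      k_spring: float = 1.0, gtol: float = 1e-6,
                      band_gtol: float = 1e-3, pushoff: float = 0.05,
                      record_frames: bool = True,
                      stop_when=None,
                      verbose: bool = False) -> ConnectResult:
    """Drive double-ended searches until ``a`` and ``b`` are connected or
    the band-search budget is exhausted (the partial database survives).

    ``stop_when(db)``, if given, is an additional early-success test
    (e.g. group-level connectivity between two classes of minima)."""
    from .optimize import minimize as _minimize
    from .optimize import same_stationary_point

    attempts = 0
    tries_per_gap: dict[frozenset, int] = {}
    # repeated attempts on the same gap change the band resolution and
    # stiffness rather than replaying an identical failure
    variants = [(n_images, k_spring), (max(n_images + 6, 21), 2.0 * k_spring),
                (max(n_images - 4, 7), 0.5 * k_spring)]

    def try_candidate(cand):
        """Refine one candidate; returns True only if the database gained
        a transition state it did not already contain."""
        try:
            ts = hybrid_ef(cand, potential, gtol=gtol)
            ts = connect_ts(ts, potential, pushoff=pushoff, gtol=gtol,
                            record_frames=record_frames)
        except (SaddleSearchError, MinimizationError, ValueError):
            return False
        if ts.degenerate:
            return False
        n_ts_before = len(db.ts)
        db.add_minimum(ts.min_down)
        db.add_minimum(ts.min_up)
        db.add_transition_state(ts)
        if len(db.ts) == n_ts_before:
            return False  # rediscovered a known saddle: no progress
        if verbose:
            print(f"  + ts V={ts.energy:.4f} "
                  f"({len(db.minima)} minima, {len(db.ts)} ts)", flush=True)
        return True

    def harvest_band(images):
        """Minimize the band images: distinct new minima become stepping
        stones, and the first adjacent image pair straddling a basin
        boundary is bisected into a near-ridge saddle candidate."""
        basins = []
        for k, img in enumerate(images):
            # every other interior image suffices for stepping stones and
            # boundary bracketing; endpoints are already known minima
            if 0 < k < len(images) - 1 and k % 2 == 0:
                basins.append(None)
                continue
            try:
                basins.append(_minimize(img, potential, gtol=gtol))
            except MinimizationError:
                basins.append(None)
        for m in basins[1:-1]:
            if m is not None and m.index == 0:
                db.add_minimum(m)
        found = 0
        solved = [i for i, m in enumerate(basins) if m is not None]
        for i, j in zip(solved, solved[1:]):
            ma, mb = basins[i], basins[j]
            if ma is None or mb is None:
                continue
            if same_stationary_point(ma, mb, potential.cartesian_beads,
                                     db.etol, db.dtol):
                continue
            lo, hi = 0.0, 1.0
            ref = ma
            for _ in range(7):
                mid = 0.5 * (lo + hi)
                xm = (1 - mid) * images[i] + mid * images[j]
                try:
                    mm = _minimize(xm, potential, gtol=max(gtol, 1e-5))
                except MinimizationError:
                    hi = mid
                    continue
                if same_stationary_point(mm, ref, potential.cartesian_beads,
                                         db.etol, db.dtol):
                    lo = mid
                else:
                    hi = mid
            mid = 0.5 * (lo + hi)
            ridge = (1 - mid) * images[i] + mid * images[j]
            if try_candidate(ridge):
                found += 1
                if found >= 2:
                    break
        return found

    def done():
        if db.connected(a, b):
            return True
        return stop_when is not None and stop_when(db)

    while attempts < budget:
        if done():
            path = (best_discrete_path(db, a, b)
                    if db.connected(a, b) else None)
            return ConnectResult(path, attempts, True)
        pairs = missing_connection_pairs(db, a, b)
        fresh = [p for p in pairs
                 if tries_per_gap.get(frozenset(p), 0) < len(variants)]
        if not fresh:
            # every gap on the best route is exhausted: fall back to the
            # nearest unconnected pairs anywhere in the database
            linked = {frozenset((r.min1, r.min2)) for r in db.ts.values()}
            rest = sorted(
                (p for p in itertools.combinations(db.minima, 2)
                 if frozenset(p) not in linked
                 and tries_per_gap.get(frozenset(p), 0) < len(variants)),
                key=lambda p: structural_distance(
                    db.minima[p[0]].coords, db.minima[p[1]].coords,
                    db.beads_3d))
            fresh = rest[:3]
        if not fresh:
            break
        for (u, v) in fresh:
            if attempts >= budget:
                break
            attempts += 1
            key = frozenset((u, v))
            ni, ks = variants[tries_per_gap.get(key, 0)]
            tries_per_gap[key] = tries_per_gap.get(key, 0) + 1
            try:
                cands, images = dneb(db.minima[u].coords,
                                     db.minima[v].coords, potential,
                                     n_images=ni, k_spring=ks,
                                     gtol=band_gtol, max_iter=500,
                                     return_images=True)
            except (SaddleSearchError, ValueError):
                continue
            new_ts = sum(try_candidate(c) for c in cands[:2])
            if new_ts == 0:
                new_ts = harvest_band(images)
            if new_ts and done():
                break
    if done():
        path = best_discrete_path(db, a, b) if db.connected(a, b) else None
        return ConnectResult(path, attempts, True)
    return ConnectResult(None, attempts, False)


def _path_frames(path: DiscretePath) -> np.ndarray:
    """Concatenated approximate steepest-descent frames along the path."""
    if not path.minima_ids:
        raise ValueError("empty path")
    db = path.db
    frames: list[np.ndarray] = []

    def extend(seq):
        for f in seq:
            if not frames or np.linalg.norm(frames[-1] - f) > 1e-12:
                frames.append(np.asarray(f, dtype=float).ravel())

    if not path.ts_ids:
        frames.append(db.minima[path.minima_ids[0]].coords.ravel())
    for k, tid in enumerate(path.ts_ids):
        rec = db.ts[tid]
        if rec.frames_down is None or rec.frames_up is None:
            raise ValueError(f"ts {tid} has no descent frames; rerun "
                             "connect_ts with record_frames=True")
        start = path.minima_ids[k]
        # frames_down ends at min_down; orient the segment start->ts->next
        down_end = rec.frames_down[-1]
        d_start = structural_distance(db.minima[start].coords, down_end,
                                      db.beads_3d)
        d_other = structural_distance(db.minima[path.minima_ids[k + 1]].coords,
                                      down_end, db.beads_3d)
        if d_start <= d_other:
            first, second = rec.frames_down, rec.frames_up
        else:
            first, second = rec.frames_up, rec.frames_down
        extend(list(reversed(first)))
        extend([rec.coords.ravel()])  # the saddle itself tops the segment
        extend(second)
    return np.array(frames)


def path_profile(path: DiscretePath, potential: Potential,
                 negate_s: bool = False) -> np.ndarray:
    """Two-column array (s, V) along the discrete path.

    s is the cumulative Cartesian arc length over the concatenated
    steepest-descent frames; ``negate_s`` flips its sign so that one
    flipping direction (conventionally the major-groove branch) can be
    drawn toward negative path lengths."""
    frames = _path_frames(path)
    if frames.ndim == 1:
        frames = frames[None, :]
    s = np.zeros(len(frames))
    for i in range(1, len(frames)):
        s[i] = s[i - 1] + np.linalg.norm(frames[i] - frames[i - 1])
    v = np.array([potential.energy(f) for f in frames])
    if negate_s:
        s = -s
    return np.column_stack([s, v])
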