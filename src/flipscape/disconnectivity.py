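"""Disconnectivity graphs: superbasin analysis at equally spaced energy
thresholds, with optional order-parameter coloring and JSON/DOT export.

At each threshold E the minima are partitioned into superbasins: two
minima share a superbasin iff they interconvert over transition states
with energy <= E.  Partitions at successive thresholds are nested, and a
minimum's branch terminates at its own energy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DisconnectivityTree", "build_tree", "color_by_order_param",
           "superbasins_at", "tree_to_json", "tree_to_dot", "plot_tree"]


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, u):
        while self.parent[u] != u:
            self.parent[u] = self.parent[self.parent[u]]
            u = self.parent[u]
        return u

    def union(self, u, v):
        ru, rv = self.find(u), self.find(v)
        if ru != rv:
            self.parent[ru] = rv


def superbasins_at(minima_energies: dict, ts_edges, threshold: float):
    """Partition of all minima into superbasins using only transition
    states with energy <= threshold (union-find).  ``ts_edges`` is an
    iterable of (min1, min2, ts_energy).  Every minimum belongs to a
    superbasin at every threshold (a minimum lying above the threshold is
    its own singleton), which keeps the basin count non-increasing as the
    threshold rises."""
    members = list(minima_energies)
    uf = _UnionFind(members)
    for m1, m2, e in ts_edges:
        if e <= threshold and m1 != m2:
            uf.union(m1, m2)
    groups: dict = {}
    for m in members:
        groups.setdefault(uf.find(m), set()).add(m)
    return sorted(groups.values(), key=lambda s: min(s))


@dataclass
class TreeNode:
    id: int
    threshold_level: int   # -1 for leaves
    energy: float
    members: frozenset
    parent: int | None = None
    color_bin: int | None = None


@dataclass
class DisconnectivityTree:
    thresholds: np.ndarray
    nodes: dict
    leaves: dict          # minimum id -> leaf node id
    energy_kind: str
    temperature: float | None = None

    def superbasin_counts(self):
        out = []
        for lvl in range(len(self.thresholds)):
            out.append(sum(1 for n in self.nodes.values()
                           if n.threshold_level == lvl))
        return out


def build_tree(db, n_levels: int = 30, energy_kind: str = "potential",
               temperature: float | None = None,
               n_modes_min: int | None = None) -> DisconnectivityTree:
    """Disconnectivity tree of a path database.

    ``energy_kind='potential'`` uses V directly; ``'free'`` uses harmonic
    free energies at ``temperature`` (transition states with one fewer
    mode).  Thresholds are equally spaced from the lowest minimum to the
    highest transition state plus one extra interval.
    """
    if not db.minima:
        raise ValueError("empty database")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if energy_kind == "potential":
        e_min = {m: rec.energy for m, rec in db.minima.items()}
        edges = [(r.min1, r.min2, r.energy) for r in db.ts.values()]
    elif energy_kind == "free":
        if temperature is None or temperature <= 0:
            raise ValueError("free-energy tree needs a positive temperature")
        from .kinetics import free_energy_of
        first = next(iter(db.minima.values()))
        if n_modes_min is None:
            n = first.coords.size
            n_modes_min = n - 6 if db.beads_3d else n
        e_min = {m: free_energy_of(rec, temperature, n_modes_min)
                 for m, rec in db.minima.items()}
        edges = [(r.min1, r.min2,
                  free_energy_of(r, temperature, n_modes_min - 1))
                 for r in db.ts.values()]
    else:
        raise ValueError(f"unknown energy kind {energy_kind!r}")

    lo = min(e_min.values())
    hi = max([e for *_, e in edges], default=lo)
    span = max(hi - lo, 1e-12)
    step = span / (n_levels - 1)
    thresholds = lo + step * np.arange(1, n_levels + 1)

    tree = DisconnectivityTree(thresholds=thresholds, nodes={}, leaves={},
                               energy_kind=energy_kind,
                               temperature=temperature)
    next_id = 0
    prev_level: dict = {}  # frozenset(members) -> node id, previous level
    # build top-down so parents exist before children: iterate from the
    # highest threshold downwards, then hang leaves underneath
    levels = []
    for lvl, thr in enumerate(thresholds):
        basins = superbasins_at(e_min, edges, thr)
        levels.append((lvl, thr, [frozenset(b) for b in basins]))
    for lvl, thr, basins in reversed(levels):
        for members in basins:
            nid = next_id
            next_id += 1
            node = TreeNode(id=nid, threshold_level=lvl, energy=float(thr),
                            members=members)
            # parent: the superbasin one level up that contains these members
            if lvl + 1 < len(thresholds):
                for pid, pnode in tree.nodes.items():
                    if (pnode.threshold_level == lvl + 1
                            and members <= pnode.members):
                        node.parent = pid
                        break
            tree.nodes[nid] = node
    for m, e in e_min.items():
        nid = next_id
        next_id += 1
        parent = None
        # deepest (lowest-threshold) node containing m at or above the
        # minimum's own energy
        for pnode in sorted(tree.nodes.values(),
                            key=lambda n: n.threshold_level):
            if (n_is_internal(pnode) and m in pnode.members
                    and pnode.energy >= e):
                parent = pnode.id
                break
        tree.nodes[nid] = TreeNode(id=nid, threshold_level=-1, energy=float(e),
                                   members=frozenset([m]), parent=parent)
        tree.leaves[m] = nid
    return tree


def n_is_internal(node: TreeNode) -> bool:
    return node.threshold_level >= 0


def color_by_order_param(tree: DisconnectivityTree, values: dict,
                         bin_width: float = 40.0,
                         anchor: float = -170.0) -> DisconnectivityTree:
    """Assign each leaf the half-open bin [anchor + k*w, anchor + (k+1)*w)
    of its minimum's order-parameter value.  The default anchor aligns the
    40-degree bin edges with the +-30 degree open/closed threshold (30.0
    falls in [30, 70), not [-10, 30)).  Missing values go to the sentinel
    bin -1 ('unassigned'), never silently dropped."""
    for m, nid in tree.leaves.items():
        if m in values and values[m] is not None:
            tree.nodes[nid].color_bin = int(
                np.floor((values[m] - anchor) / bin_width))
        else:
            tree.nodes[nid].color_bin = -1
    return tree


def tree_to_json(tree: DisconnectivityTree) -> str:
    payload = {
        "energy_kind": tree.energy_kind,
        "temperature": tree.temperature,
        "thresholds": [float(t) for t in tree.thresholds],
        "nodes": [
            {"id": n.id, "level": n.threshold_level, "energy": n.energy,
             "members": sorted(n.members), "parent": n.parent,
             "color_bin": n.color_bin}
            for n in sorted(tree.nodes.values(), key=lambda n: n.id)
        ],
    }
    return json.dumps(payload, indent=1)


def tree_to_dot(tree: DisconnectivityTree) -> str:
    lines = ["graph disconnectivity {", "  rankdir=BT;"]
    for n in sorted(tree.nodes.values(), key=lambda n: n.id):
        if n.threshold_level == -1:
            label = f"min {min(n.members)}\\nE={n.energy:.4g}"
            extra = ' shape=box'
            if n.color_bin is not None and n.color_bin >= 0:
                extra += f' colorbin="{n.color_bin}"'
        else:
            label = f"E<={n.energy:.4g}"
            extra = ""
        lines.append(f'  n{n.id} [label="{label}"{extra}];')
        if n.parent is not None:
            lines.append(f"  n{n.id} -- n{n.parent};")
    lines.append("}")
    return "\n".join(lines)


def plot_tree(tree: DisconnectivityTree, ax=None):
    """Simple rendered disconnectivity graph (vertical energy axis)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    # horizontal positions: order leaves, internal nodes at member mean
    leaf_order = {m: i for i, m in enumerate(sorted(tree.leaves))}

    def xpos(node):
        return float(np.mean([leaf_order[m] for m in node.members]))

    cmap = plt.get_cmap("tab10")
    for n in tree.nodes.values():
        if n.parent is None:
            continue
        p = tree.nodes[n.parent]
        color = "k"
        if n.threshold_level == -1 and n.color_bin is not None and n.color_bin >= 0:
            color = cmap(n.color_bin % 10)
        ax.plot([xpos(n), xpos(n)], [n.energy, p.energy], color=color, lw=1)
        ax.plot([xpos(n), xpos(p)], [p.energy, p.energy], color="k", lw=0.5)
    ax.set_ylabel(f"{tree.energy_kind} energy")
    ax.set_xticks([])
    return ax
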