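"""Base-flipping order parameters: the CPDb pseudodihedral, open/closed
classification, and solvent-accessible surface area.

CPDb is a center-of-mass pseudodihedral built from four point groups:

1. the two base pairs flanking the base of interest (one combined center),
2. the phosphate group on the 3' side of the flipping base,
3. the phosphate group on the 5' side,
4. the ring atoms of the flipping base (for purines, only the
   five-membered ring; the single base bead in the coarse-grained model).

The sign convention is: positive CPDb = flipping toward the minor groove,
negative = major groove (note this is the reverse of the convention used
in some earlier base-flipping literature).  |CPDb| <= 30 deg counts as
closed; beyond that the base is open toward the corresponding groove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duplex import Conformation
from .io import PdbAtom

__all__ = [
    "pseudo_dihedral",
    "cpdb",
    "classify_state",
    "sasa",
    "cpdb_sasa_table",
    "OrderParamRecord",
    "OPEN_THRESHOLD_DEG",
]

OPEN_THRESHOLD_DEG = 30.0

#: phosphate-group atom names for all-atom input; O3' belongs to the
#: preceding residue and is added separately
PHOSPHATE_ATOMS = ("P", "OP1", "OP2", "O5'")
PURINE_FIVE_RING = ("N9", "C8", "N7", "C5", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINES = {"A", "G", "DA", "DG"}

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
           "S": 32.06}


def pseudo_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, range (-180, 180]."""
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-12:
            raise ValueError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("three consecutive points are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def classify_state(angle_deg: float) -> str:
    """closed / open_minor / open_major from the signed CPDb angle.

    The boundary is strict: exactly +-30 deg still counts as closed.
    """
    if angle_deg > OPEN_THRESHOLD_DEG:
        return "open_minor"
    if angle_deg < -OPEN_THRESHOLD_DEG:
        return "open_major"
    return "closed"


def _com(points, weights=None):
    points = np.asarray(points, dtype=float)
    if weights is None:
        return points.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    return (points * w[:, None]).sum(axis=0) / w.sum()


def _cpdb_cg_points(conf: Conformation, strand: int, resid: int):
    topo = conf.topology
    if topo.is_terminal(resid, margin=1):
        raise ValueError(f"residue {resid} is terminal; CPDb needs both "
                         "flanking base pairs")
    x = conf.coords
    flank = []
    for r in (resid - 1, resid + 1):
        ps, pr = topo.partner(strand, r)
        flank.append(x[topo.bead(strand, r, "B")])
        flank.append(x[topo.bead(ps, pr, "B")])
    p1 = _com(flank)
    p2 = x[topo.bead(strand, resid + 1, "P")]  # 3'-side phosphate
    p3 = x[topo.bead(strand, resid, "P")]      # 5'-side phosphate
    p4 = x[topo.bead(strand, resid, "B")]
    return p1, p2, p3, p4


def _group_pdb(atoms: list[PdbAtom], chain: str, resseq: int, names):
    sel = [a for a in atoms
           if a.chain == chain and a.resseq == resseq and a.name in names]
    if not sel:
        raise ValueError(
            f"no atoms {names} found for chain {chain} residue {resseq}")
    pts = [a.xyz for a in sel]
    wts = [_MASSES.get((a.element or a.name[0]).upper(), 12.0) for a in sel]
    return pts, wts


def _cpdb_pdb_points(atoms: list[PdbAtom], chain: str, resseq: int):
    resnames = {a.resseq: a.resname for a in atoms if a.chain == chain}
    if resseq not in resnames:
        raise ValueError(f"residue {resseq} not found in chain {chain}")
    if resseq - 1 not in resnames or resseq + 1 not in resnames:
        raise ValueError(f"residue {resseq} is terminal in chain {chain}")

    def base_atoms(rq):
        ring = (PURINE_FIVE_RING if resnames[rq] in PURINES
                else PYRIMIDINE_RING)
        return _group_pdb(atoms, chain, rq, ring)

    # flanking base pairs: partner chain residues are matched by proximity
    # of ring centers (works for the minimal duplex PDBs this reads)
    flank_pts, flank_wts = [], []
    other_chains = sorted({a.chain for a in atoms} - {chain})
    for rq in (resseq - 1, resseq + 1):
        pts, wts = base_atoms(rq)
        flank_pts += pts
        flank_wts += wts
        center = _com(pts, wts)
        best = None
        for oc in other_chains:
            for orq in sorted({a.resseq for a in atoms if a.chain == oc}):
                ring = (PURINE_FIVE_RING
                        if resnames_oc(atoms, oc)[orq] in PURINES
                        else PYRIMIDINE_RING)
                try:
                    opts, owts = _group_pdb(atoms, oc, orq, ring)
                except ValueError:
                    continue
                d = np.linalg.norm(_com(opts, owts) - center)
                if best is None or d < best[0]:
                    best = (d, opts, owts)
        if best is not None:
            flank_pts += best[1]
            flank_wts += best[2]
    p1 = _com(flank_pts, flank_wts)

    def phosphate(rq):
        pts, wts = _group_pdb(atoms, chain, rq, PHOSPHATE_ATOMS)
        try:
            o3, o3w = _group_pdb(atoms, chain, rq - 1, ("O3'",))
            pts, wts = pts + o3, wts + o3w
        except ValueError:
            pass
        return _com(pts, wts)

    p2 = phosphate(resseq + 1)
    p3 = phosphate(resseq)
    ring = (PURINE_FIVE_RING if resnames[resseq] in PURINES else PYRIMIDINE_RING)
    p4 = _com(*_group_pdb(atoms, chain, resseq, ring))
    return p1, p2, p3, p4


def resnames_oc(atoms, chain):
    return {a.resseq: a.resname for a in atoms if a.chain == chain}


#: orientation factor calibrated on the ideal coarse-grained helix so that
#: rotation of a base into the narrow (minor) groove gives a positive angle
_CG_SIGN = 1.0


def cpdb(structure, target, dialect: str = "cg") -> float:
    """CPDb angle in degrees for ``target``.

    ``dialect="cg"``: structure is a :class:`Conformation`, target is
    ``(strand, resid)``.  ``dialect="allatom"``: structure is a list of
    :class:`PdbAtom`, target is ``(chain, resseq)``; centers of mass are
    mass-weighted.
    """
    if dialect == "cg":
        p1, p2, p3, p4 = _cpdb_cg_points(structure, *target)
        return _CG_SIGN * pseudo_dihedral(p1, p2, p3, p4)
    if dialect == "allatom":
        p1, p2, p3, p4 = _cpdb_pdb_points(structure, *target)
        return pseudo_dihedral(p1, p2, p3, p4)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# solvent-accessible surface area (sphere-sampling)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci
    lattice)."""
    i = np.arange(n, dtype=float) + 0.36  # lattice offset: low worst-case error
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(coords, radii, probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere sampling.

    Deterministic: test points come from a fixed Fibonacci lattice.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    if radii.size != coords.shape[0]:
        raise ValueError("radii/coords length mismatch")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    sphere = _sphere_points(n_points)
    extended = radii + probe
    areas = np.empty(radii.size)
    for i in range(radii.size):
        pts = coords[i] + extended[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(radii.size):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > extended[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * extended[i] ** 2 * accessible.mean()
    return areas


@dataclass
class OrderParamRecord:
    structure_id: int
    target: tuple
    cpdb_deg: float
    state: str
    sasa: dict


def cpdb_sasa_table(db, target, dialect: str = "cg",
                    bead_radius: float = 1.7, probe: float = 1.4,
                    n_points: int = 480) -> list[OrderParamRecord]:
    """One order-parameter record per minimum in a path database.

    For the CG dialect, the per-structure SASA is reported for the target
    base bead (the site carrying the exchangeable imino proton in G/T).
    """
    records = []
    for mid in sorted(db.minima):
        m = db.minima[mid]
        conf = Conformation(m.coords.reshape(-1, 3), db.topology)
        ang = cpdb(conf, target, dialect=dialect)
        radii = np.full(conf.coords.shape[0], bead_radius)
        areas = sasa(conf.coords, radii, probe=probe, n_points=n_points)
        b = db.topology.bead(target[0], target[1], "B")
        records.append(OrderParamRecord(
            structure_id=mid, target=tuple(target), cpdb_deg=ang,
            state=classify_state(ang), sasa={"B": float(areas[b])}))
    return records
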