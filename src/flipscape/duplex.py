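"""Coarse-grained DNA duplex model in which single-base flipping exists.

Each nucleotide is reduced to three beads — phosphate (P), sugar (S) and
base (B) — threaded on an ideal right-handed helix.  The energy contains
harmonic bonds and angles along the backbone, a Morse well between
complementary base beads (deeper for G:C than for A:T, reflecting the third
hydrogen bond), a stacking well between adjacent intrastrand bases, a weak
base-phosphate capture well that stabilizes extrahelical states (flipped
bases are observed to dock against the backbone), and a purely repulsive
WCA excluded-volume term.  Units are internal model units with k_B = 1;
lengths are on an Angstrom-like scale (helical rise 3.4, twist 36 deg).

The two glycosidic attachment directions of a base pair are 120 deg apart,
so the duplex has a narrow (minor) and a wide (major) groove, and a base
can leave the helix through either one.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np

from .potentials import Potential

__all__ = [
    "ModelParams",
    "DuplexTopology",
    "Conformation",
    "build_duplex",
    "CGDuplexPotential",
    "cg_energy",
    "reverse_complement",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: display-only conversion: one model energy unit corresponds to k_B * 300 K,
#: i.e. 0.596 kcal/mol, when the model temperature T = 1.
KCAL_PER_MODEL_UNIT = 0.596


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from None


@dataclass
class ModelParams:
    """Force-field and construction parameters of the bead model.

    Bond/angle equilibrium values are consistent with the ideal-helix
    construction geometry, so a freshly built duplex sits close to a
    minimum.  Defaults are loaded from the versioned config file shipped
    with the package (``data/cg_params_v1.cfg``).
    """

    # harmonic bonds
    k_bond: float = 50.0
    r0_ps: float = 3.988  # P(i)-S(i)
    r0_sb: float = 4.0    # S(i)-B(i)
    r0_sp3: float = 3.988  # S(i)-P(i+1)
    # harmonic angles
    k_angle: float = 20.0
    theta0_psp: float = 0.0  # P(i)-S(i)-P(i+1), radians; 0 = fill from geometry
    theta0_sps: float = 0.0  # S(i)-P(i+1)-S(i+1)
    k_base_angle: float = 3.0
    theta0_psb: float = 0.0  # P(i)-S(i)-B(i)
    # harmonic backbone dihedrals (hold the helical twist; the base-flip
    # coordinate involves no dihedral and stays soft)
    k_dihedral: float = 8.0
    phi0_psps: float = 10.0  # P(i)-S(i)-P(i+1)-S(i+1), radians; 10 = from geometry
    phi0_spsp: float = 10.0  # S(i)-P(i+1)-S(i+1)-P(i+2)
    # complementary-base Morse well
    d_at: float = 3.5
    d_gc: float = 5.0
    morse_a: float = 1.8
    pair_r0: float = 3.4641
    pair_cutoff: float = 5.5  # bookkeeping: H-bond considered intact below this
    # intrastrand stacking well
    d_stack: float = 1.6
    stack_a: float = 1.6
    stack_r0: float = 3.6177
    # base-phosphate capture well between a base and its own flanking
    # phosphates: negligible in the closed helix (they are ~7 length units
    # apart) but stabilizes the docked extrahelical state (~3.6 apart)
    d_basephos: float = 1.2
    basephos_a: float = 2.2
    basephos_r0: float = 3.4
    # excluded volume: smooth finite repulsion e*(1-(r/sigma)^2)^3 inside
    # sigma (value, first and second derivatives all vanish at the cutoff,
    # keeping the landscape twice differentiable for the saddle searches)
    ev_epsilon: float = 20.0
    ev_sigma: float = 2.5
    # helix construction geometry
    rise: float = 3.4
    twist_deg: float = 36.0
    r_base: float = 2.0
    r_sugar: float = 6.0
    r_phos: float = 8.8
    attach_deg: float = 60.0   # glycosidic attachment angle from bp pseudo-axis
    p_offset_deg: float = 18.0  # phosphate angular offset back along the strand
    p_offset_z: float = 1.7

    def __post_init__(self):
        for d in (self.d_at, self.d_gc, self.d_stack, self.d_basephos):
            if d <= 0:
                raise ValueError("all well depths must be positive")
        if self.d_gc <= self.d_at:
            raise ValueError("d_gc must exceed d_at (third hydrogen bond)")

    def depth(self, pair_type: str) -> float:
        return self.d_gc if pair_type == "GC" else self.d_at

    @classmethod
    def default(cls) -> "ModelParams":
        with resources.files("flipscape.data").joinpath("cg_params_v1.cfg").open() as fh:
            return cls.from_config(fh.read())

    @classmethod
    def from_config(cls, text: str) -> "ModelParams":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"line {lineno}: unknown parameter {key!r}")
            kwargs[key] = float(val)
        return cls(**kwargs)

    def to_config(self) -> str:
        lines = ["# coarse-grained duplex model parameters"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name):.12g}")
        return "\n".join(lines) + "\n"


class DuplexTopology:
    """Bead bookkeeping for a two-stranded coarse-grained duplex.

    Beads are ordered strand-major, residue-minor, role order (P, S, B);
    strand 1 carries ``sequence`` 5'->3', strand 2 its reverse complement
    5'->3'.  Strand-2 residue ``n_bp - 1 - i`` pairs with strand-1
    residue ``i``.
    """

    ROLES = ("P", "S", "B")

    def __init__(self, sequence: str):
        sequence = sequence.upper()
        if len(sequence) < 4:
            raise ValueError("sequence must have at least 4 nucleotides")
        bad = set(sequence) - set("ACGT")
        if bad:
            raise ValueError(f"invalid nucleotides: {sorted(bad)}")
        self.sequence = sequence
        self.n_bp = len(sequence)
        self.strand2_sequence = reverse_complement(sequence)
        self.n_beads = 6 * self.n_bp
        strands, resids, roles, bases = [], [], [], []
        for strand, seq in ((0, self.sequence), (1, self.strand2_sequence)):
            for i, base in enumerate(seq):
                for role in self.ROLES:
                    strands.append(strand)
                    resids.append(i)
                    roles.append(role)
                    bases.append(base)
        self.strand = np.array(strands)
        self.resid = np.array(resids)
        self.role = np.array(roles)
        self.base = np.array(bases)

    def bead(self, strand: int, resid: int, role: str) -> int:
        if not 0 <= resid < self.n_bp:
            raise IndexError(f"residue {resid} out of range")
        return strand * 3 * self.n_bp + 3 * resid + self.ROLES.index(role)

    def partner(self, strand: int, resid: int) -> tuple[int, int]:
        """Strand/residue of the Watson-Crick partner."""
        return 1 - strand, self.n_bp - 1 - resid

    def pair_type(self, strand: int, resid: int) -> str:
        seq = self.sequence if strand == 0 else self.strand2_sequence
        return "GC" if seq[resid] in "GC" else "AT"

    def base_pairs(self):
        """(bead_i, bead_j, 'AT'|'GC') for every complementary base pair."""
        out = []
        for i in range(self.n_bp):
            j = self.n_bp - 1 - i
            out.append((self.bead(0, i, "B"), self.bead(1, j, "B"),
                        self.pair_type(0, i)))
        return out

    def is_terminal(self, resid: int, margin: int = 2) -> bool:
        return resid < margin or resid >= self.n_bp - margin


@dataclass
class Conformation:
    """Coordinates plus topology labels of a model system."""

    coords: np.ndarray  # (n_beads, 3)
    topology: DuplexTopology

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] != self.topology.n_beads:
            raise ValueError(
                f"coordinate/topology mismatch: {self.coords.shape[0]} beads "
                f"vs {self.topology.n_beads} expected")

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), self.topology)

    @property
    def flat(self) -> np.ndarray:
        return self.coords.ravel()


def _helix_position(radius, angle_deg, z):
    a = np.deg2rad(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def build_duplex(sequence: str, params: ModelParams | None = None) -> Conformation:
    """Construct an ideal-helix conformation for ``sequence`` paired with
    its reverse complement.  Deterministic."""
    params = params or ModelParams.default()
    topo = DuplexTopology(sequence)
    n = topo.n_bp
    coords = np.zeros((topo.n_beads, 3))
    for i in range(n):
        theta = i * params.twist_deg
        z = i * params.rise
        # strand 1: attachment direction +attach_deg
        a1 = theta + params.attach_deg
        coords[topo.bead(0, i, "B")] = _helix_position(params.r_base, a1, z)
        coords[topo.bead(0, i, "S")] = _helix_position(params.r_sugar, a1, z)
        coords[topo.bead(0, i, "P")] = _helix_position(
            params.r_phos, a1 - params.p_offset_deg, z - params.p_offset_z)
        # strand 2 residue j pairs with strand-1 residue i
        j = n - 1 - i
        a2 = theta - params.attach_deg
        coords[topo.bead(1, j, "B")] = _helix_position(params.r_base, a2, z)
        coords[topo.bead(1, j, "S")] = _helix_position(params.r_sugar, a2, z)
        coords[topo.bead(1, j, "P")] = _helix_position(
            params.r_phos, a2 + params.p_offset_deg, z + params.p_offset_z)
    return Conformation(coords, topo)


class CGDuplexPotential(Potential):
    """Energy/analytic gradient of the coarse-grained duplex model.

    The Hessian is obtained by central finite differences of the analytic
    gradient (step 1e-5), which is accurate enough for harmonic frequencies
    at the model's stiffness scale.
    """

    n_rigid_modes = 6
    cartesian_beads = True

    def __init__(self, topology: DuplexTopology, params: ModelParams | None = None):
        self.topology = topology
        self.params = p = params or ModelParams.default()
        self.dimension = 3 * topology.n_beads
        self.name = f"cg_duplex_{topology.sequence}"
        n = topology.n_bp
        bead = topology.bead

        bonds, br0 = [], []
        angles = []
        for strand in (0, 1):
            for i in range(n):
                bonds.append((bead(strand, i, "P"), bead(strand, i, "S")))
                br0.append(p.r0_ps)
                bonds.append((bead(strand, i, "S"), bead(strand, i, "B")))
                br0.append(p.r0_sb)
                if i + 1 < n:
                    bonds.append((bead(strand, i, "S"), bead(strand, i + 1, "P")))
                    br0.append(p.r0_sp3)
                    angles.append((bead(strand, i, "P"), bead(strand, i, "S"),
                                   bead(strand, i + 1, "P"), p.k_angle, "psp"))
                    angles.append((bead(strand, i, "S"), bead(strand, i + 1, "P"),
                                   bead(strand, i + 1, "S"), p.k_angle, "sps"))
                angles.append((bead(strand, i, "P"), bead(strand, i, "S"),
                               bead(strand, i, "B"), p.k_base_angle, "psb"))
        self._bond_idx = np.array(bonds)
        self._bond_r0 = np.array(br0)

        # equilibrium angles from the ideal construction geometry
        ref = build_duplex(topology.sequence, p).coords
        theta0_geo = {}
        for name in ("psp", "sps", "psb"):
            for (ia, ib, ic, _, nm) in angles:
                if nm == name:
                    theta0_geo[name] = _angle(ref[ia], ref[ib], ref[ic])
                    break
        self._angle_idx = np.array([(a, b, c) for a, b, c, _, _ in angles])
        self._angle_k = np.array([k for *_, k, _ in angles])
        self._angle_t0 = np.array([
            getattr(p, f"theta0_{nm}") or theta0_geo[nm] for *_, nm in angles])

        morse, mD, ma, mr0 = [], [], [], []
        for bi, bj, ptype in topology.base_pairs():
            morse.append((bi, bj))
            mD.append(p.depth(ptype))
            ma.append(p.morse_a)
            mr0.append(p.pair_r0)
        for strand in (0, 1):
            for i in range(n - 1):
                morse.append((bead(strand, i, "B"), bead(strand, i + 1, "B")))
                mD.append(p.d_stack)
                ma.append(p.stack_a)
                mr0.append(p.stack_r0)
        # base-phosphate capture: B(i) with its own 5' and 3' phosphates,
        # central residues only (the flip targets; duplex ends are floppy
        # enough to dock while still paired, which is not the physics the
        # term is meant to capture)
        for strand in (0, 1):
            for i in range(n):
                if topology.is_terminal(i):
                    continue
                b = bead(strand, i, "B")
                for k in (i, i + 1):
                    if k < n:
                        morse.append((b, bead(strand, k, "P")))
                        mD.append(p.d_basephos)
                        ma.append(p.basephos_a)
                        mr0.append(p.basephos_r0)
        self._morse_idx = np.array(morse)
        self._morse_D = np.array(mD)
        self._morse_a = np.array(ma)
        self._morse_r0 = np.array(mr0)

        dihedrals = []
        for strand in (0, 1):
            for i in range(n - 1):
                dihedrals.append((bead(strand, i, "P"), bead(strand, i, "S"),
                                  bead(strand, i + 1, "P"),
                                  bead(strand, i + 1, "S"), "psps"))
                if i + 2 < n:
                    dihedrals.append((bead(strand, i, "S"),
                                      bead(strand, i + 1, "P"),
                                      bead(strand, i + 1, "S"),
                                      bead(strand, i + 2, "P"), "spsp"))
        phi0_geo = {}
        for name in ("psps", "spsp"):
            for (ia, ib, ic, id_, nm) in dihedrals:
                if nm == name:
                    phi0_geo[name] = _dihedral(ref[ia], ref[ib], ref[ic], ref[id_])
                    break
        self._dih_idx = np.array([(a, b, c, d) for a, b, c, d, _ in dihedrals])
        self._dih_phi0 = np.array([
            getattr(p, f"phi0_{nm}") if abs(getattr(p, f"phi0_{nm}")) <= np.pi
            else phi0_geo[nm] for *_, nm in dihedrals])
        self._dih_k = np.full(len(dihedrals), p.k_dihedral)

        excluded = set()
        for i, j in self._bond_idx:
            excluded.add(frozenset((int(i), int(j))))
        for a, b, c in self._angle_idx:
            excluded.add(frozenset((int(a), int(c))))
        for i, j in self._morse_idx:
            excluded.add(frozenset((int(i), int(j))))
        wca = [(i, j) for i in range(topology.n_beads)
               for j in range(i + 1, topology.n_beads)
               if frozenset((i, j)) not in excluded]
        self._wca_idx = np.array(wca)

    # -- energy terms ----------------------------------------------------
    def _pair_vectors(self, x, idx):
        d = x[idx[:, 1]] - x[idx[:, 0]]
        r = np.linalg.norm(d, axis=1)
        return d, r

    def energy_gradient(self, x) -> tuple[float, np.ndarray]:
        x = np.asarray(x, dtype=float).reshape(-1, 3)
        if x.shape[0] != self.topology.n_beads:
            raise ValueError("coordinate/topology length mismatch")
        p = self.params
        grad = np.zeros_like(x)
        energy = 0.0

        d, r = self._pair_vectors(x, self._bond_idx)
        dr = r - self._bond_r0
        energy += float(np.sum(0.5 * p.k_bond * dr * dr))
        f = (p.k_bond * dr / r)[:, None] * d
        _scatter_add(grad, self._bond_idx[:, 1], f)
        _scatter_add(grad, self._bond_idx[:, 0], -f)

        e_ang, g_ang = _angle_energy_gradient(
            x, self._angle_idx, self._angle_k, self._angle_t0)
        energy += e_ang
        grad += g_ang

        e_dih, g_dih = _dihedral_energy_gradient(
            x, self._dih_idx, self._dih_k, self._dih_phi0)
        energy += e_dih
        grad += g_dih

        d, r = self._pair_vectors(x, self._morse_idx)
        ex = np.exp(-self._morse_a * (r - self._morse_r0))
        energy += float(np.sum(self._morse_D * ((1.0 - ex) ** 2 - 1.0)))
        dv = 2.0 * self._morse_D * self._morse_a * (1.0 - ex) * ex
        f = (dv / r)[:, None] * d
        _scatter_add(grad, self._morse_idx[:, 1], f)
        _scatter_add(grad, self._morse_idx[:, 0], -f)

        d, r = self._pair_vectors(x, self._wca_idx)
        mask = r < p.ev_sigma
        if np.any(mask):
            rm = r[mask]
            u = (rm / p.ev_sigma) ** 2
            energy += float(np.sum(p.ev_epsilon * (1.0 - u) ** 3))
            # dV/dr = -6 e r (1-u)^2 / sigma^2
            dv = -6.0 * p.ev_epsilon * rm * (1.0 - u) ** 2 / p.ev_sigma ** 2
            f = (dv / rm)[:, None] * d[mask]
            _scatter_add(grad, self._wca_idx[mask, 1], f)
            _scatter_add(grad, self._wca_idx[mask, 0], -f)

        return energy, grad.ravel()

    def energy(self, x) -> float:
        return self.energy_gradient(x)[0]

    def gradient(self, x) -> np.ndarray:
        return self.energy_gradient(x)[1]

    # -- batched evaluation (vectorized over configurations) -------------
    def gradient_batch(self, xs: np.ndarray,
                       wca_idx: np.ndarray | None = None) -> np.ndarray:
        """Analytic gradients for a batch of configurations, shape (B, n).

        Used to assemble finite-difference Hessians in a handful of
        vectorized sweeps instead of 2n separate gradient calls.
        ``wca_idx`` restricts the excluded-volume pair list (the Hessian
        builder prunes pairs far outside the cutoff).
        """
        p = self.params
        nb = self.topology.n_beads
        x = np.asarray(xs, dtype=float).reshape(len(xs), nb, 3)
        bsz = x.shape[0]
        grad = np.zeros_like(x)

        def scatter(idx, vals):
            # vals: (B, m, 3) accumulated into grad[:, idx]
            flat = (idx[None, :] + nb * np.arange(bsz)[:, None]).ravel()
            for k in range(3):
                acc = np.bincount(flat, weights=vals[:, :, k].ravel(),
                                  minlength=bsz * nb)
                grad[:, :, k] += acc.reshape(bsz, nb)

        def pair_vec(idx):
            d = x[:, idx[:, 1]] - x[:, idx[:, 0]]
            return d, np.linalg.norm(d, axis=2)

        d, r = pair_vec(self._bond_idx)
        f = (p.k_bond * (r - self._bond_r0) / r)[..., None] * d
        scatter(self._bond_idx[:, 1], f)
        scatter(self._bond_idx[:, 0], -f)

        a, b, c = (x[:, self._angle_idx[:, k]] for k in range(3))
        u, v = a - b, c - b
        nu = np.linalg.norm(u, axis=2)
        nv = np.linalg.norm(v, axis=2)
        cos = np.clip(np.einsum("bij,bij->bi", u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos)
        w = np.cross(u, v)
        nw = np.linalg.norm(w, axis=2)
        safe = nw > 1e-12
        ga = np.zeros_like(a)
        gc = np.zeros_like(c)
        ga[safe] = np.cross(u, w)[safe] / (nu * nu * nw)[safe][..., None]
        gc[safe] = -np.cross(v, w)[safe] / (nv * nv * nw)[safe][..., None]
        coeff = (self._angle_k * (theta - self._angle_t0))[..., None]
        scatter(self._angle_idx[:, 0], coeff * ga)
        scatter(self._angle_idx[:, 2], coeff * gc)
        scatter(self._angle_idx[:, 1], -coeff * (ga + gc))

        ri, rj, rk, rl = (x[:, self._dih_idx[:, m]] for m in range(4))
        b1, b2, b3 = rj - ri, rk - rj, rl - rk
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=2)
        m1 = np.cross(n1, b2 / nb2[..., None])
        phi = np.arctan2(np.einsum("bij,bij->bi", m1, n2),
                         np.einsum("bij,bij->bi", n1, n2))
        dphi = (phi - self._dih_phi0 + np.pi) % (2.0 * np.pi) - np.pi
        sn1 = np.einsum("bij,bij->bi", n1, n1)
        sn2 = np.einsum("bij,bij->bi", n2, n2)
        fi = (nb2 / sn1)[..., None] * n1
        fl = -(nb2 / sn2)[..., None] * n2
        s12 = (np.einsum("bij,bij->bi", b1, b2) / (nb2 * nb2))[..., None]
        s32 = (np.einsum("bij,bij->bi", b3, b2) / (nb2 * nb2))[..., None]
        fj = -(1.0 + s12) * fi + s32 * fl
        fk = s12 * fi - (1.0 + s32) * fl
        coeff = (self._dih_k * dphi)[..., None]
        scatter(self._dih_idx[:, 0], coeff * fi)
        scatter(self._dih_idx[:, 1], coeff * fj)
        scatter(self._dih_idx[:, 2], coeff * fk)
        scatter(self._dih_idx[:, 3], coeff * fl)

        d, r = pair_vec(self._morse_idx)
        ex = np.exp(-self._morse_a * (r - self._morse_r0))
        dv = 2.0 * self._morse_D * self._morse_a * (1.0 - ex) * ex
        f = (dv / r)[..., None] * d
        scatter(self._morse_idx[:, 1], f)
        scatter(self._morse_idx[:, 0], -f)

        wca = self._wca_idx if wca_idx is None else wca_idx
        d, r = pair_vec(wca)
        mask = r < p.ev_sigma
        u = np.where(mask, (r / p.ev_sigma) ** 2, 1.0)
        dv = -6.0 * p.ev_epsilon * r * (1.0 - u) ** 2 / p.ev_sigma ** 2
        f = np.where(mask, dv / np.where(mask, r, 1.0), 0.0)[..., None] * d
        scatter(wca[:, 1], f)
        scatter(wca[:, 0], -f)

        return grad.reshape(bsz, -1)

    def hessian(self, x) -> np.ndarray:
        """Dense Hessian from batched central differences of the analytic
        gradient (step 1e-5), symmetrized."""
        x = np.asarray(x, dtype=float).ravel()
        n = x.size
        step = self.hessian_step
        xr = x.reshape(-1, 3)
        d = xr[self._wca_idx[:, 1]] - xr[self._wca_idx[:, 0]]
        near = np.linalg.norm(d, axis=1) < self.params.ev_sigma + 0.05
        active_wca = self._wca_idx[near]
        pert = np.repeat(x[None, :], 2 * n, axis=0)
        rows = np.arange(n)
        pert[2 * rows, rows] += step
        pert[2 * rows + 1, rows] -= step
        g = self.gradient_batch(pert, wca_idx=active_wca)
        h = (g[0::2] - g[1::2]) / (2.0 * step)
        return 0.5 * (h + h.T)

    def paired_fraction(self, x) -> float:
        """Fraction of base pairs with bead distance below the pairing cutoff."""
        x = np.asarray(x, dtype=float).reshape(-1, 3)
        pairs = self.topology.base_pairs()
        dists = [np.linalg.norm(x[i] - x[j]) for i, j, _ in pairs]
        return float(np.mean([d < self.params.pair_cutoff for d in dists]))



def _scatter_add(grad, idx, vals):
    n = grad.shape[0]
    for k in range(3):
        grad[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)

def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _angle_energy_gradient(x, idx, k, theta0):
    """Vectorized harmonic angle term E = 0.5 k (theta - theta0)^2."""
    a, b, c = x[idx[:, 0]], x[idx[:, 1]], x[idx[:, 2]]
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos)
    dtheta = theta - theta0
    energy = float(np.sum(0.5 * k * dtheta * dtheta))
    # dtheta/da etc. via the standard cross-product construction
    w = np.cross(u, v)
    nw = np.linalg.norm(w, axis=1)
    # guard collinear triples (zero gradient direction; theta = 0 or pi)
    safe = nw > 1e-12
    ga = np.zeros_like(a)
    gc = np.zeros_like(c)
    ga[safe] = (np.cross(u, w)[safe] / (nu * nu * nw)[safe, None])
    gc[safe] = (-np.cross(v, w)[safe] / (nv * nv * nw)[safe, None])
    coeff = (k * dtheta)[:, None]
    grad = np.zeros_like(x)
    _scatter_add(grad, idx[:, 0], coeff * ga)
    _scatter_add(grad, idx[:, 2], coeff * gc)
    _scatter_add(grad, idx[:, 1], -coeff * (ga + gc))
    return energy, grad


def _dihedral(a, b, c, d) -> float:
    """Signed dihedral angle in radians, range (-pi, pi]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def _dihedral_energy_gradient(x, idx, k, phi0):
    """Vectorized harmonic dihedral term, E = 0.5 k wrap(phi - phi0)^2."""
    ri, rj, rk, rl = (x[idx[:, m]] for m in range(4))
    b1, b2, b3 = rj - ri, rk - rj, rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.einsum("ij,ij->i", m1, n2),
                     np.einsum("ij,ij->i", n1, n2))
    dphi = phi - phi0
    dphi = (dphi + np.pi) % (2.0 * np.pi) - np.pi
    energy = float(np.sum(0.5 * k * dphi * dphi))
    sn1 = np.einsum("ij,ij->i", n1, n1)
    sn2 = np.einsum("ij,ij->i", n2, n2)
    fi = (nb2 / sn1)[:, None] * n1
    fl = -(nb2 / sn2)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2))[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2))[:, None]
    fj = -(1.0 + s12) * fi + s32 * fl
    fk = s12 * fi - (1.0 + s32) * fl
    coeff = (k * dphi)[:, None]
    grad = np.zeros_like(x)
    _scatter_add(grad, idx[:, 0], coeff * fi)
    _scatter_add(grad, idx[:, 1], coeff * fj)
    _scatter_add(grad, idx[:, 2], coeff * fk)
    _scatter_add(grad, idx[:, 3], coeff * fl)
    return energy, grad


def cg_energy(conf: Conformation, params: ModelParams | None = None):
    """Energy and gradient of a duplex conformation under the bead model."""
    pot = CGDuplexPotential(conf.topology, params)
    return pot.energy_gradient(conf.flat)


def default_params_path() -> Path:
    return Path(str(resources.files("flipscape.data").joinpath("cg_params_v1.cfg")))
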