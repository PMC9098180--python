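"""Local minimization, stationary-point classification, group-rotation
moves and basin-hopping global optimization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .duplex import Conformation, DuplexTopology
from .potentials import Potential

__all__ = [
    "StationaryPoint",
    "MoveSpec",
    "MinimizationError",
    "minimize",
    "classify",
    "group_rotation",
    "basin_hop",
    "metropolis_accept",
    "random_displacement_move",
    "group_rotation_move",
    "structural_distance",
]

#: eigenvalues with |lambda| below this are treated as zero modes when the
#: spectrum is inspected for ambiguity (rigid-body modes themselves are
#: removed by count, not by threshold)
ZERO_MODE_THRESHOLD = 1e-6


class MinimizationError(RuntimeError):
    """Raised when a local minimization fails to converge; carries the last
    iterate in ``last_point``."""

    def __init__(self, message: str, last_point: np.ndarray | None = None):
        super().__init__(message)
        self.last_point = last_point


@dataclass
class StationaryPoint:
    """A converged stationary point of a potential.

    ``index`` counts negative Hessian eigenvalues after removal of the
    ``n_zero_modes`` smallest-magnitude (rigid-body) modes; ``frequencies``
    are sqrt(lambda)/2pi over the retained positive modes (unit masses).
    The Hessian spectrum is computed on first access and cached (a dense
    Hessian of the bead model is much more expensive than the energy).
    """

    coords: np.ndarray
    energy: float
    potential: "Potential" = field(repr=False, default=None)
    symmetry_number: int = 1
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)
    _index: int | None = field(default=None, repr=False)
    _frequencies: np.ndarray | None = field(default=None, repr=False)
    _ambiguous: bool | None = field(default=None, repr=False)

    def _classify(self):
        if self._eigenvalues is None:
            hess = self.potential.hessian(self.coords)
            self._eigenvalues = scipy.linalg.eigvalsh(hess)
            idx, retained, amb = classify(self._eigenvalues,
                                          self.potential.n_rigid_modes)
            self._index = idx
            self._ambiguous = amb
            positive = retained[retained > 0]
            self._frequencies = np.sqrt(positive) / (2.0 * np.pi)

    @property
    def eigenvalues(self) -> np.ndarray:
        self._classify()
        return self._eigenvalues

    @property
    def index(self) -> int:
        self._classify()
        return self._index

    @property
    def frequencies(self) -> np.ndarray:
        self._classify()
        return self._frequencies

    @property
    def ambiguous(self) -> bool:
        self._classify()
        return self._ambiguous

    @property
    def n_zero_modes(self) -> int:
        return self.potential.n_rigid_modes

    @property
    def log_product_frequencies(self) -> float:
        return float(np.sum(np.log(self.frequencies)))

    @property
    def is_minimum(self) -> bool:
        return self.index == 0

    @property
    def is_transition_state(self) -> bool:
        return self.index == 1


def classify(eigenvalues: np.ndarray, n_zero_modes: int,
             threshold: float = ZERO_MODE_THRESHOLD):
    """Hessian index after zero-mode removal.

    The ``n_zero_modes`` smallest-magnitude eigenvalues are removed by
    count (rigid-body translations/rotations); the index is the number of
    remaining eigenvalues below ``-threshold``.  Returns
    ``(index, retained_eigenvalues, ambiguous)`` where ``ambiguous`` flags
    retained eigenvalues inside ``(-threshold, threshold)``.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    if n_zero_modes:
        keep = np.argsort(np.abs(ev))[n_zero_modes:]
        retained = np.sort(ev[keep])
    else:
        retained = ev
    index = int(np.sum(retained < -threshold))
    ambiguous = bool(np.any(np.abs(retained) < threshold))
    return index, retained, ambiguous


def _make_stationary_point(potential: Potential, x: np.ndarray,
                           energy: float | None = None) -> StationaryPoint:
    x = np.asarray(x, dtype=float).ravel()
    if energy is None:
        energy = potential.energy(x)
    return StationaryPoint(coords=x, energy=float(energy),
                           potential=potential)


def minimize(x0, potential: Potential, gtol: float = 1e-6,
             maxiter: int = 20000, trajectory: list | None = None) -> StationaryPoint:
    """L-BFGS local minimization to RMS gradient ``gtol``.

    Raises :class:`MinimizationError` on non-convergence; never returns an
    unconverged point silently.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite starting point")
    if gtol <= 0:
        raise ValueError("gtol must be positive")
    e0 = potential.energy(x0)

    def fun(x):
        e, g = potential.energy_gradient(x)
        return e, g

    cb = None
    if trajectory is not None:
        trajectory.append(x0.copy())
        cb = lambda xk: trajectory.append(xk.copy())
    res = scipy.optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                 "gtol": 0.5 * gtol, "ftol": 1e-14, "maxls": 60})
    x = res.x
    # polish: scipy's criterion is max-norm on the projected gradient; make
    # sure the RMS criterion is genuinely met
    if potential.rms_gradient(x) > gtol:
        for _ in range(5):
            res = scipy.optimize.minimize(
                fun, x, jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": 0.1 * gtol,
                         "ftol": 0.0, "maxls": 100})
            x = res.x
            if potential.rms_gradient(x) <= gtol:
                break
    if potential.rms_gradient(x) > gtol:
        raise MinimizationError(
            f"L-BFGS failed to reach RMS gradient {gtol:g} "
            f"(got {potential.rms_gradient(x):g})", last_point=x)
    # Spectral clean-up.  Two defects can survive an L-BFGS stop at RMS
    # gtol: residual displacements ~g/lambda along very soft modes
    # (spurious tiny negative eigenvalues), and genuinely unstable modes
    # with an exactly-zero gradient component (a symmetric start sits on
    # a ridge between symmetry-broken minima and L-BFGS never leaves it).
    # Newton-polish the former; kick off and re-descend the latter.
    for _ in range(5):
        h = potential.hessian(x)
        w, v = scipy.linalg.eigh(h)
        for _ in range(3):
            g = potential.gradient(x)
            if np.sqrt(np.mean(g * g)) < 1e-11:
                break
            keep = w > 1e-7
            if not np.any(keep):
                break
            dx = -v[:, keep] @ ((v[:, keep].T @ g) / w[keep])
            norm = np.linalg.norm(dx)
            if norm > 0.1:
                dx *= 0.1 / norm
            x_new = x + dx
            if potential.energy(x_new) > potential.energy(x) + 1e-12:
                break
            x = x_new
        h = potential.hessian(x)
        w = scipy.linalg.eigvalsh(h)
        idx, retained, amb = classify(w, potential.n_rigid_modes)
        if idx == 0:
            break
        _, vmin = scipy.linalg.eigh(h, subset_by_index=[0, 0])
        kick = 0.05 * vmin[:, 0]
        x_try = (x + kick if potential.energy(x + kick) <= potential.energy(x - kick)
                 else x - kick)
        res = scipy.optimize.minimize(
            fun, x_try, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": 0.5 * gtol,
                     "ftol": 1e-14, "maxls": 60})
        if potential.rms_gradient(res.x) <= gtol:
            x = res.x
    sp = _make_stationary_point(potential, x)
    sp._eigenvalues = w
    sp._index = idx
    sp._ambiguous = amb
    positive = retained[retained > 0]
    sp._frequencies = np.sqrt(positive) / (2.0 * np.pi)
    if sp.energy > e0 + 1e-10:
        raise MinimizationError("minimization increased the energy", last_point=x)
    return sp


# ---------------------------------------------------------------------------
# group rotation moves

@dataclass
class MoveSpec:
    """Specification of a group-rotation move on one nucleotide.

    ``glycosidic_axis`` rotates only the base bead about the axis through
    the sugar bead directed along the local backbone (5'P -> 3'P); with one
    bead per base this is the coarse-grained analogue of rotation about the
    glycosidic bond and is the flip coordinate.  ``backbone_axis`` rotates
    the whole nucleotide about the axis through its flanking phosphates.
    """

    pivot_kind: str  # "backbone_axis" | "glycosidic_axis"
    strand: int
    resid: int
    amplitude_deg: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.pivot_kind not in ("backbone_axis", "glycosidic_axis"):
            raise ValueError(f"unknown pivot kind {self.pivot_kind!r}")
        if not 0.0 < self.amplitude_deg <= 180.0:
            raise ValueError("amplitude must be in (0, 180] degrees")


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return (np.eye(3) + np.sin(angle_rad) * k
            + (1.0 - np.cos(angle_rad)) * (k @ k))


def _move_geometry(conf: Conformation, move: MoveSpec):
    topo = conf.topology
    if topo.is_terminal(move.resid):
        raise ValueError(
            f"residue {move.resid} is terminal (within 2 bp of a duplex end); "
            "group rotations are restricted to central bases to avoid edge "
            "effects")
    p5 = conf.coords[topo.bead(move.strand, move.resid, "P")]
    p3 = conf.coords[topo.bead(move.strand, move.resid + 1, "P")]
    axis = p3 - p5
    if move.pivot_kind == "glycosidic_axis":
        origin = conf.coords[topo.bead(move.strand, move.resid, "S")]
        moving = [topo.bead(move.strand, move.resid, "B")]
    else:
        origin = p5
        moving = [topo.bead(move.strand, move.resid, r) for r in ("P", "S", "B")]
    return origin, axis, moving


def group_rotation(conf: Conformation, move: MoveSpec,
                   angle_deg: float | None = None) -> Conformation:
    """Rotate the target group by a seeded uniform random angle in
    [-amplitude, +amplitude] (or a fixed ``angle_deg``).  All beads outside
    the rotated group are returned bit-identical."""
    origin, axis, moving = _move_geometry(conf, move)
    if angle_deg is None:
        rng = np.random.default_rng(move.seed)
        angle_deg = float(rng.uniform(-move.amplitude_deg, move.amplitude_deg))
    if angle_deg == 0.0:
        return conf.copy()
    rot = _rotation_matrix(axis, np.deg2rad(angle_deg))
    new = conf.copy()
    for b in moving:
        new.coords[b] = origin + rot @ (conf.coords[b] - origin)
    return new


# ---------------------------------------------------------------------------
# basin-hopping

def random_displacement_move(amplitude: float):
    """Uniform random displacement move for the analytic test surfaces."""

    def move(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return x + rng.uniform(-amplitude, amplitude, size=x.shape)

    return move


def group_rotation_move(topology: DuplexTopology, pivot_kind: str,
                        targets: list[tuple[int, int]],
                        amplitude_deg: float = 150.0):
    """Basin-hopping move: random group rotation of one of ``targets``
    (list of (strand, resid), all non-terminal)."""
    for _, resid in targets:
        if topology.is_terminal(resid):
            raise ValueError(f"residue {resid} is terminal; choose central bases")

    def move(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        strand, resid = targets[rng.integers(len(targets))]
        conf = Conformation(x.reshape(-1, 3).copy(), topology)
        spec = MoveSpec(pivot_kind=pivot_kind, strand=strand, resid=resid,
                        amplitude_deg=amplitude_deg)
        angle = float(rng.uniform(-amplitude_deg, amplitude_deg))
        return group_rotation(conf, spec, angle_deg=angle).flat

    return move


def structural_distance(x: np.ndarray, y: np.ndarray, beads_3d: bool) -> float:
    """Per-coordinate RMS distance; for 3-D bead systems the structures are
    first superimposed (Kabsch, no permutations)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not beads_3d:
        return float(np.linalg.norm(x - y))
    a = x.reshape(-1, 3)
    b = y.reshape(-1, 3)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = b.T @ a
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = a - b @ rot
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def same_stationary_point(a: StationaryPoint, b: StationaryPoint,
                          beads_3d: bool, etol: float = 1e-6,
                          dtol: float = 0.05) -> bool:
    """Deduplication rule: same point iff both the energies and the
    superimposed structures agree within tolerance."""
    if abs(a.energy - b.energy) > etol:
        return False
    return structural_distance(a.coords, b.coords, beads_3d) <= dtol


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion on minimized energies: always accept downhill,
    accept uphill with probability exp(-dE/T)."""
    if delta_e <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_e / temperature))


def basin_hop(x0, potential: Potential, move, temperature: float,
              n_steps: int, seed: int = 0, gtol: float = 1e-6,
              classify_every: bool = True) -> list[StationaryPoint]:
    """Classic basin-hopping: move, minimize, Metropolis-accept on the
    minimized energies.  Returns the distinct minima found (deduplicated),
    sorted by energy; fully reproducible from ``seed``."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    beads_3d = potential.cartesian_beads
    current = minimize(np.asarray(x0, dtype=float).ravel(), potential, gtol=gtol)
    minima = [current]
    for _ in range(n_steps):
        trial_x = move(current.coords.copy(), rng)
        try:
            trial = minimize(trial_x, potential, gtol=gtol)
        except MinimizationError:
            continue
        if not any(same_stationary_point(trial, m, beads_3d) for m in minima):
            if not classify_every or trial.index == 0:
                minima.append(trial)
        if metropolis_accept(trial.energy - current.energy, temperature, rng):
            current = trial
    return sorted(minima, key=lambda m: m.energy)
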