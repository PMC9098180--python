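"""Transition-state location: doubly-nudged elastic band candidates,
hybrid eigenvector-following refinement, and pushoff connection of each
saddle to its two minima."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .optimize import (MinimizationError, StationaryPoint,
                       _make_stationary_point, minimize)
from .potentials import Potential

__all__ = [
    "Band", "TransitionState", "SaddleSearchError",
    "dneb", "hybrid_ef", "connect_ts",
]

#: retained fraction of the perpendicular spring gradient — the "doubly"
#: nudged component that stabilizes the band against corner cutting
DNEB_PERP_SPRING_FRACTION = 0.1


class SaddleSearchError(RuntimeError):
    """Saddle search failure; carries the last iterate in ``last_point``."""

    def __init__(self, message: str, last_point: np.ndarray | None = None):
        super().__init__(message)
        self.last_point = last_point


@dataclass
class Band:
    """Chain of states between two fixed endpoint minima."""

    images: np.ndarray          # (n_images, n_coords), endpoints included
    k_spring: float
    energies: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.images.shape[0] < 3:
            raise ValueError("a band needs at least 3 images")
        if self.k_spring <= 0:
            raise ValueError("spring constant must be positive")


@dataclass
class TransitionState:
    """Index-1 stationary point with its downhill eigenvector and, once
    connected, the ids/energies of the two minima it links."""

    point: StationaryPoint
    downhill: np.ndarray
    min_down: StationaryPoint | None = None
    min_up: StationaryPoint | None = None
    degenerate: bool = False
    frames_down: list | None = None
    frames_up: list | None = None

    @property
    def energy(self) -> float:
        return self.point.energy

    @property
    def coords(self) -> np.ndarray:
        return self.point.coords

    def barriers(self) -> tuple[float, float]:
        if self.min_down is None or self.min_up is None:
            raise ValueError("transition state is not connected yet")
        return (self.energy - self.min_down.energy,
                self.energy - self.min_up.energy)


def _lbfgs_direction(g, s_list, y_list):
    """Two-loop recursion; no line search (the caller caps the step)."""
    q = g.copy()
    alphas = []
    for s, y in zip(reversed(s_list), reversed(y_list)):
        rho = 1.0 / np.dot(y, s)
        a = rho * np.dot(s, q)
        alphas.append((a, rho, s, y))
        q -= a * y
    if y_list:
        s, y = s_list[-1], y_list[-1]
        q *= np.dot(s, y) / np.dot(y, y)
    for a, rho, s, y in reversed(alphas):
        b = rho * np.dot(y, q)
        q += (a - b) * s
    return -q


def lbfgs_gradient_only(grad_fn, x0, gtol_rms: float, max_iter: int = 1000,
                        max_step: float = 0.2, memory: int = 10,
                        n_blocks: int = 1):
    """Minimize a (possibly non-conservative) gradient field by L-BFGS
    with a trust-radius style step cap.  Returns (x, converged).

    With ``n_blocks`` > 1 the step cap applies to the largest per-block
    (per-image) displacement rather than the joint norm, so one
    fast-moving image cannot starve the others of step budget."""
    x = np.asarray(x0, dtype=float).copy()
    g = grad_fn(x)
    if not np.all(np.isfinite(g)):
        return x, False
    s_list, y_list = [], []
    for _ in range(max_iter):
        rms = np.sqrt(np.mean(g * g))
        if rms <= gtol_rms:
            return x, True
        d = _lbfgs_direction(g, s_list, y_list)
        if np.dot(d, g) > 0:  # uphill direction: reset memory
            s_list, y_list = [], []
            d = -g
        step = d
        if n_blocks > 1:
            norm = np.max(np.linalg.norm(step.reshape(n_blocks, -1), axis=1))
        else:
            norm = np.linalg.norm(step)
        if norm > max_step:
            step = step * (max_step / norm)
        x_new = x + step
        g_new = grad_fn(x_new)
        if not np.all(np.isfinite(g_new)):
            return x, False
        s, y = x_new - x, g_new - g
        if np.dot(s, y) > 1e-12:
            s_list.append(s)
            y_list.append(y)
            if len(s_list) > memory:
                s_list.pop(0)
                y_list.pop(0)
        x, g = x_new, g_new
    return x, np.sqrt(np.mean(g * g)) <= gtol_rms


# ---------------------------------------------------------------------------
# DNEB

def _band_tangents(images, energies):
    """Energy-upwind tangent estimates for the interior images."""
    n = images.shape[0]
    tangents = np.zeros_like(images[1:-1])
    for i in range(1, n - 1):
        e_prev, e_here, e_next = energies[i - 1], energies[i], energies[i + 1]
        d_prev = images[i] - images[i - 1]
        d_next = images[i + 1] - images[i]
        if e_next > e_here > e_prev:
            t = d_next
        elif e_next < e_here < e_prev:
            t = d_prev
        else:
            dmax = max(abs(e_next - e_here), abs(e_prev - e_here))
            dmin = min(abs(e_next - e_here), abs(e_prev - e_here))
            if e_next > e_prev:
                t = d_next * dmax + d_prev * dmin
            else:
                t = d_next * dmin + d_prev * dmax
        tangents[i - 1] = t / np.linalg.norm(t)
    return tangents


def dneb(min_a, min_b, potential: Potential, n_images: int = 15,
         k_spring: float = 1.0, gtol: float = 1e-3,
         max_iter: int = 1000, climb: bool = True,
         return_images: bool = False):
    """Relax a doubly-nudged elastic band between two minima and return
    candidate saddle geometries (interior energy maxima along the band).

    The projected band gradient keeps the perpendicular component of the
    true gradient, the parallel component of the spring gradient, and a
    small fraction of the perpendicular spring gradient orthogonalized
    against the true-gradient direction (the doubly-nudged correction).
    With ``climb`` the highest interior image is switched to a climbing
    image (parallel gradient component inverted, springs released) for a
    second relaxation phase, which sharpens flat barrier regions into
    usable saddle candidates.
    """
    a = np.asarray(min_a, dtype=float).ravel()
    b = np.asarray(min_b, dtype=float).ravel()
    if np.linalg.norm(a - b) < 1e-8:
        raise ValueError("endpoints are identical")
    if n_images < 3:
        raise ValueError("n_images must be >= 3")
    frac = np.linspace(0.0, 1.0, n_images)[:, None]
    images = (1.0 - frac) * a + frac * b
    # linear interpolation can create severe excluded-volume clashes;
    # briefly descend any pathological image before the band relaxation
    e_ref = max(potential.energy(a), potential.energy(b))
    for i in range(1, n_images - 1):
        if potential.energy(images[i]) > e_ref + 100.0:
            images[i] = descend(potential, images[i], max_step=0.1,
                                rms_target=1.0, max_iter=200)
    climbing = False

    def band_gradient(flat_interior):
        interior = flat_interior.reshape(n_images - 2, -1)
        imgs = np.vstack([a, interior, b])
        energies = np.empty(n_images)
        grads = np.empty_like(imgs)
        for i in range(n_images):
            energies[i], grads[i] = potential.energy_gradient(imgs[i])
        tangents = _band_tangents(imgs, energies)
        i_climb = 1 + int(np.argmax(energies[1:-1])) if climbing else -1
        out = np.empty_like(interior)
        for i in range(1, n_images - 1):
            t = tangents[i - 1]
            g = grads[i]
            if i == i_climb:
                out[i - 1] = g - 2.0 * np.dot(g, t) * t
                continue
            g_perp = g - np.dot(g, t) * t
            g_spr = k_spring * ((imgs[i] - imgs[i - 1]) - (imgs[i + 1] - imgs[i]))
            spr_par = np.dot(g_spr, t) * t
            spr_perp = g_spr - spr_par
            gp_norm = np.linalg.norm(g_perp)
            if gp_norm > 1e-12:
                ghat = g_perp / gp_norm
                spr_perp = spr_perp - np.dot(spr_perp, ghat) * ghat
            out[i - 1] = g_perp + spr_par + DNEB_PERP_SPRING_FRACTION * spr_perp
        return out.ravel()

    x, _ = lbfgs_gradient_only(band_gradient, images[1:-1].ravel(),
                               max(gtol, 2e-3), max_iter=max_iter // 2,
                               max_step=0.2, n_blocks=n_images - 2)
    if climb:
        climbing = True
        x, _ = lbfgs_gradient_only(band_gradient, x, gtol,
                                   max_iter=max_iter, max_step=0.2,
                                   n_blocks=n_images - 2)
    interior = x.reshape(n_images - 2, -1)
    imgs = np.vstack([a, interior, b])
    seps = np.linalg.norm(np.diff(imgs, axis=0), axis=1)
    if np.any(seps < 1e-8):
        raise SaddleSearchError("band collapsed: adjacent images coincide")
    energies = np.array([potential.energy(im) for im in imgs])
    candidates = [imgs[i].copy() for i in range(1, n_images - 1)
                  if energies[i] >= energies[i - 1] and energies[i] >= energies[i + 1]]
    # highest interior image as fallback: a very asymmetric profile may
    # leave no strict interior maximum
    if not candidates:
        candidates = [imgs[1 + int(np.argmax(energies[1:-1]))].copy()]
    if return_images:
        return candidates, imgs
    return candidates


# ---------------------------------------------------------------------------
# hybrid eigenvector-following

def rigid_body_modes(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis (n, 6) of infinitesimal rigid translations and
    rotations for a 3-D bead system at configuration ``x``."""
    pos = x.reshape(-1, 3)
    com = pos.mean(axis=0)
    rel = pos - com
    modes = []
    for k in range(3):
        t = np.zeros_like(pos)
        t[:, k] = 1.0
        modes.append(t.ravel())
    for axis in np.eye(3):
        modes.append(np.cross(axis, rel).ravel())
    q, _ = np.linalg.qr(np.column_stack(modes))
    return q


def _lowest_mode(potential: Potential, x, dense_limit: int = 400,
                 v0: np.ndarray | None = None):
    """Smallest non-rigid Hessian eigenvalue and eigenvector.

    Dense eigendecomposition for small systems; otherwise
    gradient-difference Rayleigh-quotient minimization (LOBPCG on a
    matrix-free Hessian-vector operator) with the rigid-body modes
    deflated."""
    n = x.size
    nz = potential.n_rigid_modes
    if n <= dense_limit:
        h = potential.hessian(x)
        w, v = scipy.linalg.eigh(h, subset_by_index=[0, min(nz, n - 1)])
        if w[0] < -1e-6 or nz == 0:
            return float(w[0]), v[:, 0]
        # convex region: the lowest modes are the rigid zeros; take the
        # softest genuine mode instead
        return float(w[nz]), v[:, nz]
    return _rayleigh_lowest_mode(potential, x, v0=v0,
                                 deflate=rigid_body_modes(x) if nz else None)


def _rayleigh_lowest_mode(potential: Potential, x, v0=None, h: float = 1e-5,
                          max_iter: int = 100, tol: float = 1e-7,
                          deflate: np.ndarray | None = None):
    """Minimize the Rayleigh quotient v.Hv/v.v using only gradient
    differences Hv = (g(x+hv) - g(x-hv)) / 2h.  Warm-startable via v0."""
    import warnings

    from scipy.sparse.linalg import LinearOperator, lobpcg

    n = x.size
    rng = np.random.default_rng(7)

    def hv(vec):
        vec = np.asarray(vec, dtype=float).ravel()
        nv = np.linalg.norm(vec)
        if nv == 0:
            return vec
        u = vec / nv
        return nv * (potential.gradient(x + h * u)
                     - potential.gradient(x - h * u)) / (2.0 * h)

    op = LinearOperator((n, n), matvec=hv, dtype=float)
    v_start = (v0.copy() if v0 is not None else rng.normal(size=n))
    if deflate is not None:
        v_start -= deflate @ (deflate.T @ v_start)
    v_start /= np.linalg.norm(v_start)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, v = lobpcg(op, v_start[:, None], Y=deflate, largest=False,
                      tol=tol, maxiter=max_iter)
    vec = v[:, 0]
    if deflate is not None:
        vec = vec - deflate @ (deflate.T @ vec)
    vec = vec / np.linalg.norm(vec)
    lam = float(np.dot(vec, hv(vec)))
    return lam, vec


def _newton_polish(potential: Potential, x, gtol: float,
                   max_iter: int = 60, max_step: float = 0.2):
    """Partitioned rational-function (P-RFO) saddle iteration.

    Maximizes along the lowest Hessian eigenvmode and minimizes along all
    remaining non-rigid modes; the shifted denominators keep the step
    well-defined even when several soft modes are slightly negative,
    which plain Newton iteration cannot disentangle.  Returns
    (x, eigenvalues, eigenvectors) at convergence or raises."""
    nz = potential.n_rigid_modes
    x = np.asarray(x, dtype=float).copy()
    trust = max_step  # adapted from the quality of each step
    rms_prev = None
    for _ in range(max_iter):
        g = potential.gradient(x)
        rms = np.sqrt(np.mean(g * g))
        h = potential.hessian(x)
        w, v = scipy.linalg.eigh(h)
        if rms <= gtol:
            return x, w, v
        if rms_prev is not None:
            # trust-radius update: reward genuine gradient reduction
            if rms < 0.9 * rms_prev:
                trust = min(2.0 * trust, 2.0)
            elif rms > rms_prev:
                trust = max(0.5 * trust, 1e-3)
        rms_prev = rms
        keep = np.sort(np.argsort(np.abs(w))[nz:])
        lam = w[keep]
        gi = v[:, keep].T @ g
        # followed mode: the most negative remaining eigenvalue
        l1, g1 = lam[0], gi[0]
        lam_p = 0.5 * (l1 + np.sqrt(l1 * l1 + 4.0 * g1 * g1))
        s = np.empty_like(gi)
        denom1 = l1 - lam_p  # < 0: uphill along the followed mode
        s[0] = -g1 / denom1 if abs(denom1) > 1e-12 else 0.0
        rest_lam = lam[1:]
        lam2 = rest_lam.min() if rest_lam.size else 1.0
        # shift only when other modes are non-positive, and on the scale
        # of the spectrum itself (a fixed shift would swamp soft modes)
        lam_n = 0.0 if lam2 > 1e-9 else 2.0 * lam2 - 1e-9
        s[1:] = -gi[1:] / (rest_lam - lam_n)
        dx = v[:, keep] @ s
        norm = np.linalg.norm(dx)
        if norm > trust:
            dx *= trust / norm
        x = x + dx
    raise SaddleSearchError("P-RFO polish did not converge", last_point=x)


def _minmode_translate(potential: Potential, x0, gtol: float,
                       climb_sign: float, max_grad_calls: int = 900,
                       mode_refresh: int = 25, max_step: float = 0.15):
    """Min-mode-following translation with persistent L-BFGS memory.

    While the lowest non-rigid curvature is negative, minimize the
    effective gradient g - 2(g.v)v (which is locally the gradient of a
    positive-definite problem at an index-1 saddle); while it is positive,
    climb along the softest mode in a consistent direction.  The lowest
    mode v is refreshed from a dense Hessian every ``mode_refresh``
    iterations; the L-BFGS curvature memory survives refreshes, which is
    what lets the very soft duplex modes converge.
    """
    x = np.asarray(x0, dtype=float).copy()
    v = None
    lam = None
    s_list: list = []
    y_list: list = []
    since_refresh = mode_refresh  # force refresh on entry
    for it in range(max_grad_calls):
        if since_refresh >= mode_refresh:
            lam, vnew = _lowest_mode(potential, x, v0=v)
            if v is not None and np.dot(vnew, v) < 0:
                vnew = -vnew
            v = vnew
            since_refresh = 0
        since_refresh += 1
        g = potential.gradient(x)
        rms = np.sqrt(np.mean(g * g))
        if not np.isfinite(rms) or rms > 1e8:
            return x, False
        if rms <= gtol and lam < -1e-8:
            return x, True
        if lam < -1e-8:
            g_eff = g - 2.0 * np.dot(g, v) * v
        else:
            # convex region: steady climb along the softest mode while
            # relaxing perpendicular components
            g_eff = g - np.dot(g, v) * v - climb_sign * 0.05 * v
        d = _lbfgs_direction(g_eff, s_list, y_list)
        if np.dot(d, g_eff) > 0:
            s_list.clear()
            y_list.clear()
            d = -g_eff
        norm = np.linalg.norm(d)
        if norm > max_step:
            d = d * (max_step / norm)
        x_new = x + d
        g_new = potential.gradient(x_new)
        if lam < -1e-8:
            g_eff_new = g_new - 2.0 * np.dot(g_new, v) * v
        else:
            g_eff_new = (g_new - np.dot(g_new, v) * v
                         - climb_sign * 0.05 * v)
        s, y = x_new - x, g_eff_new - g_eff
        if np.dot(s, y) > 1e-12:
            s_list.append(s)
            y_list.append(y)
            if len(s_list) > 15:
                s_list.pop(0)
                y_list.pop(0)
        x = x_new
    return x, False


def hybrid_ef(candidate, potential: Potential, gtol: float = 1e-6,
              max_iter: int = 900, max_uphill_step: float = 0.15,
              newton_rms: float = 5e-3) -> TransitionState:
    """Refine a candidate geometry to an index-1 saddle.

    A min-mode-following walk (uphill along the softest non-rigid Hessian
    eigenvector, quasi-Newton descent on the mode-inverted effective
    gradient once the curvature turns negative) takes the candidate close
    to a saddle; a partitioned rational-function polish finishes the
    convergence.  Both climbing directions are attempted.  Raises
    :class:`SaddleSearchError` (with the last iterate attached) if no
    index-1 point is reached.
    """
    x0 = np.asarray(candidate, dtype=float).ravel()
    last = x0
    # a well-converged climbing-image candidate often sits inside the
    # quadratic basin of the saddle already: try the polish directly
    try:
        xs, w, vecs = _newton_polish(potential, x0, gtol, max_iter=30,
                                     max_step=max_uphill_step)
        sp = _make_stationary_point(potential, xs)
        if sp.index == 1:
            order = np.argsort(w)
            return TransitionState(point=sp, downhill=vecs[:, order[0]])
        last = xs
    except SaddleSearchError as err:
        last = err.last_point
    for climb_sign in (+1.0, -1.0):
        x, ok = _minmode_translate(potential, x0, gtol, climb_sign,
                                   max_grad_calls=max_iter,
                                   max_step=max_uphill_step)
        last = x
        if not ok:
            # walk stalled: if it at least reached a near-saddle region,
            # let the P-RFO polish try to finish
            g = potential.gradient(x)
            if not np.all(np.isfinite(g)):
                continue
            if np.sqrt(np.mean(g * g)) > newton_rms:
                continue
        try:
            xs, w, vecs = _newton_polish(potential, x, gtol,
                                         max_step=max_uphill_step)
        except SaddleSearchError as err:
            last = err.last_point
            continue
        sp = _make_stationary_point(potential, xs)
        if sp.index == 1:
            order = np.argsort(w)
            return TransitionState(point=sp, downhill=vecs[:, order[0]])
        last = xs
    raise SaddleSearchError(
        "hybrid eigenvector-following did not converge to an index-1 "
        "saddle", last_point=last)


def descend(potential: Potential, x0, max_step: float = 0.05,
            rms_target: float = 1e-3, max_iter: int = 400,
            frames: list | None = None) -> np.ndarray:
    """Approximate steepest-descent walk with capped step length.

    Used to settle safely into the basin adjacent to a saddle before
    handing over to the full minimizer (an unconstrained quasi-Newton
    step can overshoot a shallow basin), and to record the descent
    polyline for path profiles."""
    x = np.asarray(x0, dtype=float).copy()
    if frames is not None:
        frames.append(x.copy())
    for _ in range(max_iter):
        g = potential.gradient(x)
        rms = np.sqrt(np.mean(g * g))
        if rms <= rms_target:
            break
        step = -g
        norm = np.linalg.norm(step)
        if norm > max_step:
            step *= max_step / norm
        e0 = potential.energy(x)
        x_new = x + step
        # halve on uphill moves (narrow valleys)
        for _ in range(20):
            if potential.energy(x_new) <= e0 + 1e-12:
                break
            step *= 0.5
            x_new = x + step
        x = x_new
        if frames is not None:
            frames.append(x.copy())
    return x


def connect_ts(ts: TransitionState, potential: Potential,
               pushoff: float = 0.05, gtol: float = 1e-6,
               max_retries: int = 3,
               record_frames: bool = False) -> TransitionState:
    """Minimize from ts +- pushoff * downhill eigenvector to find the two
    connected minima.  If both sides fall into the same minimum the TS is
    flagged degenerate after doubling the pushoff ``max_retries`` times.

    With ``record_frames`` the approximate steepest-descent polylines are
    stored on the transition state as ``frames_down`` / ``frames_up``."""
    if pushoff <= 0:
        raise ValueError("pushoff must be positive")
    v = ts.downhill / np.linalg.norm(ts.downhill)
    push = pushoff
    from .optimize import same_stationary_point
    for _ in range(max_retries + 1):
        frames_a: list | None = [] if record_frames else None
        frames_b: list | None = [] if record_frames else None
        xa = descend(potential, ts.coords + push * v, frames=frames_a)
        xb = descend(potential, ts.coords - push * v, frames=frames_b)
        side_a = minimize(xa, potential, gtol=gtol)
        side_b = minimize(xb, potential, gtol=gtol)
        if not same_stationary_point(side_a, side_b, potential.cartesian_beads):
            if side_a.energy <= side_b.energy:
                ts.min_down, ts.min_up = side_a, side_b
                fd, fu = frames_a, frames_b
            else:
                ts.min_down, ts.min_up = side_b, side_a
                fd, fu = frames_b, frames_a
            if record_frames:
                fd.append(ts.min_down.coords.copy())
                fu.append(ts.min_up.coords.copy())
                ts.frames_down, ts.frames_up = fd, fu
            ts.degenerate = False
            return ts
        push *= 2.0
    ts.min_down = ts.min_up = side_a
    ts.degenerate = True
    return ts
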