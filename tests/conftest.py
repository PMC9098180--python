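"""Shared fixtures: analytic surfaces, oracle stationary points, and the
(expensive, session-scoped) coarse-grained duplex objects."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from flipscape import (CGDuplexPotential, DoubleWell, MullerBrown,
                       PathDatabase, build_duplex, connect_endpoints,
                       minimize)

warnings.filterwarnings("ignore", category=RuntimeWarning)


def newton_refine(potential, x0, max_iter=200):
    """Brute-force oracle helper: damped Newton iteration on the gradient."""
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        g = potential.gradient(x)
        if np.linalg.norm(g) < 1e-12:
            break
        h = potential.hessian(x)
        dx = np.linalg.solve(h, g)
        n = np.linalg.norm(dx)
        if n > 0.5:
            dx *= 0.5 / n
        x = x - dx
    return x


def muller_brown_oracle():
    """Grid scan + Newton refinement enumeration of all Muller-Brown
    stationary points, independent of the package's optimizers."""
    pot = MullerBrown()
    points = []
    for gx in np.linspace(-1.5, 1.5, 25):
        for gy in np.linspace(-0.5, 2.0, 21):
            try:
                x = newton_refine(pot, [gx, gy])
            except np.linalg.LinAlgError:
                continue
            if (np.linalg.norm(pot.gradient(x)) < 1e-9
                    and -1.6 < x[0] < 1.6 and -0.6 < x[1] < 2.1):
                if not any(np.linalg.norm(x - p) < 1e-5 for p, _ in points):
                    ev = np.linalg.eigvalsh(pot.hessian(x))
                    points.append((x, int((ev < 0).sum())))
    minima = sorted([p for p, k in points if k == 0],
                    key=lambda p: pot.energy(p))
    saddles = sorted([p for p, k in points if k == 1],
                     key=lambda p: pot.energy(p))
    return minima, saddles


@pytest.fixture(scope="session")
def mb():
    return MullerBrown()


@pytest.fixture(scope="session")
def dw():
    return DoubleWell()


@pytest.fixture(scope="session")
def mb_oracle():
    return muller_brown_oracle()


@pytest.fixture(scope="session")
def mb_minima(mb):
    return [minimize(g, mb) for g in ([-0.55, 1.44], [-0.05, 0.47],
                                      [0.62, 0.03])]


@pytest.fixture(scope="session")
def mb_database(mb, mb_minima):
    """Fully connected Muller-Brown database (3 minima, 2 saddles)."""
    db = PathDatabase()
    ids = [db.add_minimum(m) for m in mb_minima]
    connect_endpoints(db, ids[0], ids[1], mb, budget=6, n_images=21,
                      pushoff=0.01)
    connect_endpoints(db, ids[1], ids[2], mb, budget=6, n_images=21,
                      pushoff=0.01)
    return db


@pytest.fixture(scope="session")
def dw_database(dw):
    db = PathDatabase()
    a = db.add_minimum(minimize([-0.9], dw))
    b = db.add_minimum(minimize([0.9], dw))
    connect_endpoints(db, a, b, dw, budget=3, n_images=11, pushoff=0.01)
    return db


@pytest.fixture(scope="session")
def duplex6():
    """Small 6-bp duplex: topology, potential and closed minimum."""
    conf = build_duplex("GAGAGA")
    pot = CGDuplexPotential(conf.topology)
    closed = minimize(conf.flat, pot)
    return conf, pot, closed


@pytest.fixture(scope="session")
def duplex12():
    """The 12-bp d(GA)6 duplex of the main analysis."""
    conf = build_duplex("GAGAGAGAGAGA")
    pot = CGDuplexPotential(conf.topology)
    closed = minimize(conf.flat, pot)
    return conf, pot, closed


@pytest.fixture(scope="session")
def flipping_run():
    """Session-scoped end-to-end pipeline run on the 12-bp duplex."""
    from flipscape.pipeline import run_flipping_pipeline
    return run_flipping_pipeline(seed=1, bh_steps=30, connect_budget=12,
                                 with_sasa=True)
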