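# flipscape

Energy-landscape analysis of DNA base flipping: discrete path sampling on
a coarse-grained duplex, with oracle-validated optimizers and kinetics.

## The problem

A base in double-helical DNA occasionally breaks its Watson–Crick
hydrogen bonds, unstacks, and rotates out of the helix toward the major
or the minor groove (base flipping). Repair and modification enzymes act
on flipped-out bases, and experiments (NMR imino-proton exchange,
fluorescence correlation) disagree by orders of magnitude about how often
spontaneous opening happens — plausibly because they monitor different
open states. flipscape is for researchers who want to study this process
from the stationary-point perspective: instead of simulating dynamics, it
maps minima and the index-1 saddles between them, then derives
thermodynamics and kinetics from the resulting network.

The pipeline implements the standard discrete-path-sampling toolchain:

- **basin-hopping** global optimization with *group-rotation moves*
  (rotations of a base about its backbone or glycosidic pivot) to
  discover closed, partially open and flipped-out minima;
- **doubly-nudged elastic band** searches for candidate saddle
  geometries, refined by **hybrid eigenvector-following**, with each
  converged transition state connected to its two minima by
  steepest-descent pushoffs;
- a deduplicated **stationary-point database** with a missing-connection
  algorithm that chooses which gaps to attempt next;
- **harmonic-superposition thermodynamics** (F = V + T·Σ ln(ν/T) − T ln n
  with k_B = h = 1) and **harmonic TST** rates
  k = (Πν^min / Πν^ts)·exp(−ΔV/T), reduced to two-state opening/closing
  rates by exact **graph transformation**
  (P′_vu = P_vu + P_vx P_xu/(1−P_xx), τ′_u = τ_u + P_xu τ_x/(1−P_xx));
- **disconnectivity graphs** (superbasins at equally spaced thresholds)
  colored by the **CPDb** pseudodihedral, the order parameter that
  measures how far and toward which groove a base has flipped
  (positive = minor groove, |CPDb| ≤ 30° = closed), plus sphere-sampling
  **SASA** for the imino positions.

Everything runs on two kinds of systems: analytic test surfaces
(double well, Müller–Brown) whose stationary points a brute-force
grid+Newton oracle enumerates independently, and a bundled coarse-grained
three-beads-per-nucleotide duplex model in which single-base flipping
exists as a genuine minimum-to-minimum transition (see
`docs/methods.md` for the model and all conventions).

## Worked example

Kinetic bookkeeping on the packaged published-rate table (lifetimes and
equilibrium constants are always recomputed from the rate constants):

```python
>>> from flipscape.reference import kinetic_bookkeeping, thymine_decade_ratios
>>> df = kinetic_bookkeeping()
>>> row = df[(df.base == "G") & (df.cpdb_deg == -47.99)].iloc[0]
>>> print(f"K_eq = {row.k_eq:.3g}, closed lifetime = {row.lifetime_closed_s:.3g} s")
K_eq = 3.27e-07, closed lifetime = 67.1 s
>>> thymine_decade_ratios()
{'major_small_vs_major_large': 6, 'minor_small_vs_major_large': 3}
```

The guanine major-groove opening equilibrium constant of 3.3·10⁻⁷ means
the flipped-out state is populated about once per three million duplexes;
the thymine comparison shows small- and large-angle major-groove opening
rates spanning six orders of magnitude — the scale of the discrepancy
between NMR and fluorescence experiments.

A full landscape run on the coarse-grained duplex (5–10 minutes on one
CPU):

```python
>>> from flipscape.pipeline import run_flipping_pipeline
>>> res = run_flipping_pipeline(seed=1, bh_steps=30, connect_budget=12)
>>> len(res.db.minima), len(res.db.ts), res.connected
(9, 2, True)
>>> sorted(round(res.cpdb_by_min[m], 1) for m in res.open_ids)
[-78.7, 147.9]
>>> k = res.kinetics
>>> print(f"K_eq = {k.equilibrium_constant:.2e}, barriers: "
...       f"open {k.barrier_open:.2f}, close {k.barrier_close:.2f}")
K_eq = 1.64e-02, barriers: open 7.92, close 5.46
```

The database contains open minima toward both grooves (negative CPDb =
major, positive = minor); the equilibrium constant below one says the
closed duplex is the stable state, and the free-energy barriers (model
units, T = 0.6) are positive in both directions. Exact numbers vary with
the seed since basin-hopping and the connection order are stochastic.

The same stages are available from the shell for scripted runs:

```bash
flipscape build-duplex run.cfg
flipscape basinhop run.cfg --target 0:5
flipscape connect run.cfg
flipscape rates run.cfg
flipscape tree run.cfg --energy free --T 0.6
flipscape cpdb run.cfg
flipscape profile run.cfg
```

where `run.cfg` is a flat key = value file (`flipscape.io.RunConfig`);
every stage writes its outputs plus a JSON log into the configured output
directory and reruns bit-for-bit from the same config and seed.

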