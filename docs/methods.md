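# Methods

## Scope and model system

flipscape studies spontaneous base flipping — the rotation of a single
nucleobase out of a DNA double helix into an extrahelical state — from the
potential-energy-landscape perspective: stationary points (minima and
index-1 saddles) are located explicitly, assembled into a database, and
thermodynamics and kinetics are derived from harmonic theory on that
database. The machinery is exercised on two kinds of systems:

1. **Analytic test surfaces** (1-D quartic double well; the Müller–Brown
   two-dimensional four-Gaussian surface) whose stationary points can be
   enumerated independently by grid scans plus Newton refinement. Every
   pipeline stage is validated against these brute-force oracles.
2. **A coarse-grained DNA duplex** in which single-base flipping toward
   either groove exists as a minimum-to-minimum transition. The default
   analysis flips a central guanine of the 12-bp alternating
   purine–pyrimidine duplex d(GA)₆.

## The coarse-grained duplex model

Each nucleotide is three beads — phosphate (P), sugar (S), base (B) — on an
ideal right-handed helix (rise 3.4, twist 36°/bp in model length units on an
Ångström-like scale). The two glycosidic attachment directions of a base
pair subtend 120°, giving the duplex a narrow (minor) and a wide (major)
groove. Energy terms (all parameters frozen in
`src/flipscape/data/cg_params_v1.cfg`, versioned):

- **Harmonic bonds** P–S, S–B, S–P(3′) (k = 50) and **harmonic angles**
  P–S–P, S–P–S (k = 20), P–S–B (k = 3), with equilibrium values taken from
  the ideal construction geometry.
- **Harmonic backbone dihedrals** P–S–P–S and S–P–S–P (k = 8) that hold the
  helical twist. The base-flip coordinate involves no dihedral and stays
  soft by design.
- **Complementary-base Morse well**, deeper for G:C (D = 5) than for A:T
  (D = 3.5), reflecting the third hydrogen bond; width a = 1.8; minimum at
  the built pair separation.
- **Stacking well** (Morse form, D = 1.6) between adjacent intrastrand
  bases.
- **Base–phosphate capture well** (D = 1.2, minimum at 3.4) between a
  central base and its own 5′/3′ phosphates. In the closed helix these
  sites are ~7 length units apart and the term is negligible; a flipped
  base docks against its backbone at ~3.4–3.8, so the term gives the
  extrahelical state a genuine basin. Flipped bases interacting with their
  own backbone is a feature reported for real duplexes; terminal residues
  are excluded because duplex ends are floppy enough to dock while still
  paired, which is not the physics the term represents.
- **Excluded volume**: a smooth finite repulsion ε(1−(r/σ)²)³ inside
  σ = 2.5 (ε = 20). Value, first and second derivatives vanish at the
  cutoff, keeping the landscape twice differentiable — a hard-core form
  with a curvature discontinuity at the cutoff destabilizes quasi-Newton
  saddle refinement.

Units: k_B = 1; the display conversion 1 model energy unit ≙ k_B·300 K
(0.596 kcal/mol) maps the default kinetics temperature T = 0.6 to an
effective ~10 k_BT flipping barrier, the regime the method is built for.
Masses are uniform (1), so COMs of bead groups are unweighted.

What the model deliberately does **not** reproduce: sequence-dependent
groove geometry, A-tract physics, solvent and ions, and the absolute
energetics of any real force field. Passing tests on this model validate
the landscape machinery (sampling, saddle searches, kinetics bookkeeping),
not quantitative DNA thermodynamics.

## Pipeline stages

**Local minimization** is L-BFGS (SciPy's implementation) to an RMS
gradient of 1e-6 (default), followed by a spectral clean-up: a few Newton
steps along well-conditioned Hessian modes remove the residual
displacements that L-BFGS leaves in very soft modes, and genuinely
unstable modes with zero gradient component (the ideally built duplex is a
symmetric ridge between two slightly bent conformers) are kicked off and
re-descended. Dense Hessians of the duplex are affordable because the
analytic gradient is evaluated in a single vectorized batch over all 2n
finite-difference displacements (step 1e-5), with far-field
excluded-volume pairs pruned.

**Stationary-point classification** removes the six smallest-magnitude
eigenvalues by count (rigid-body modes) and counts the remaining
eigenvalues below −1e-6 (model units). Retained eigenvalues inside
±1e-6 set an `ambiguous` flag rather than being dropped. Frequencies are
√λ/2π with unit masses; a transition state retains κ−1 positive modes.

**Group-rotation moves**: the backbone pivot rotates a whole nucleotide
about the axis through its flanking phosphates (the analogue of a
C5′/O3′ pivot); the glycosidic pivot rotates the single base bead about
the axis through the sugar directed along the local backbone — with one
bead per base a literal glycosidic-bond axis degenerates, and this choice
makes the move the flip coordinate, sweeping the base through either
groove depending on the sign of the rotation. Only central bases (≥ 2 bp
from each end) may be targets, to limit edge effects. Basin-hopping
accepts minimize-after-move steps with a Metropolis test on the minimized
energies (default move amplitude ±180°, basin-hopping temperature 1.5).

**Saddle searches**: a doubly-nudged elastic band (linear-interpolation
initial path, per-image step caps, a short pre-descent for images with
severe excluded-volume clashes, and a climbing-image second phase)
produces candidate geometries; hybrid eigenvector-following refines them.
The refinement first tries a partitioned rational-function (P-RFO) polish
with an adaptive trust radius directly from the candidate, then a
min-mode-following walk: uphill along the softest non-rigid eigenvector
while the lowest curvature is positive, quasi-Newton descent on the
mode-inverted effective gradient g − 2(g·v)v once it turns negative, with
L-BFGS curvature memory kept across periodic mode refreshes (that
persistence is what lets the very soft duplex modes converge). The lowest
mode comes from a dense eigendecomposition up to 400 coordinates and from
LOBPCG on a matrix-free Hessian-vector operator (gradient differences,
rigid modes deflated) beyond. Each converged saddle is connected to its
two minima by capped-step descents from ±pushoff along the downhill
eigenvector (an unconstrained quasi-Newton descent can overshoot a
shallow adjacent basin), recording the descent polylines for path
profiles.

**Database and connection**: minima and transition states are
deduplicated by the joint rule |ΔV| ≤ 1e-6 AND best-superposition RMSD
≤ 0.05 (Kabsch, no permutational alignment). The missing-connection
choice of which gap to attempt next is Dijkstra on the complete minima
graph with weight 0 for linked pairs and min(RMSD, 2.0)² for unlinked
ones. Repeated attempts on one gap vary the band resolution and spring
constant; when a band yields no saddle its images are minimized and any
new basins join the database as stepping stones, and the first
adjacent-image pair straddling a basin boundary is bisected into a
near-ridge candidate. For the duplex analysis, the reactant (closed) and
product (open) states are *groups* classified by the target base's CPDb.
The connection phase attempts closed-open gaps nearest-first,
re-classifying after every round so newly discovered near-boundary minima
immediately become candidate endpoints, and the reaction counts as
connected once any component of the minima graph contains members of both
groups. Occupation weights in the two-state rates are normalized over the
full closed and open ensembles rather than only the connected members:
closed states interconvert over barriers of order 0.5-1 model units while
opening crosses ~5.5, so local equilibrium within each group is an
excellent approximation; ensemble members without sampled reactive
pathways contribute occupation but no flux, which can only bias the rates
downward.

**Thermodynamics and kinetics**: classical harmonic superposition,
F = V + T·Σ ln(ν/T) − T·ln n (k_B = h = 1, symmetry numbers default 1);
harmonic TST for minimum-to-minimum rates; exact graph-transformation
elimination of all intermediate nodes of the branching-probability /
waiting-time network; the phenomenological rate is the
equilibrium-occupation-weighted escape rate from the reduced reactant
group (steady-state formulation — validated against mean-first-passage
times from dense linear solves, which the package also implements as an
independent oracle). Free-energy barriers are quoted against the group
free energy of the reactants and the highest-F transition state on the
lowest-F path (union-find minimax). By construction the TST network obeys
detailed balance, so K_eq from rates equals the partition-function ratio;
the test suite checks both routes agree to 1e-8.

**Disconnectivity graphs**: equally spaced thresholds from the lowest
minimum to the highest transition state plus one interval (30 levels by
default); superbasins are union-find components over transition states at
or below each threshold, with every minimum a (possibly singleton) basin
at every threshold so the basin count is non-increasing; leaves terminate
at their minima energies. Free-energy trees use harmonic F (κ−1 modes for
saddles). Leaves can be colored by CPDb in 40° half-open bins; the default
bin anchor (−170°) aligns bin edges with the ±30° open/closed threshold.

**Order parameters**: CPDb is the signed pseudodihedral over four
center-of-mass points — both flanking base pairs combined (a switchable
convention; the combined form is the default), the 3′-side phosphate
group, the 5′-side phosphate group, and the ring atoms of the flipping
base (five-membered ring only for purines; the single B bead in the CG
dialect; mass-weighted COMs for all-atom PDB input, where "phosphate
group" means P, OP1, OP2, O5′ plus the preceding residue's O3′). Sign
convention: positive = minor groove, negative = major (the reverse of
part of the earlier literature). Closed means |CPDb| ≤ 30° with a strict
boundary. SASA uses deterministic sphere sampling on a Fibonacci lattice
(offset 0.36; 960 points and probe 1.4 by default) — for the imino sites
(guanine N1 / thymine N3 in all-atom terms; the base bead in the CG
model) whose solvent exchange NMR monitors.

## Published-rate bookkeeping

The packaged table `data/reference_kinetics.csv` carries published
opening/closing rate constants, CPDb angles and 300 K free-energy barriers
for flipped-out states of the four central bases of a d(GA)₆ duplex, per
groove pathway. Only the rate columns are inputs: state lifetimes
(reciprocal rates), equilibrium constants (rate ratios) and the
order-of-magnitude separations between thymine opening rates (six decades
between small- and large-angle major-groove flipping; three decades
between small-angle minor and large-angle major) are always recomputed by
`flipscape.reference`.

## Problem sizes and defaults

The shipped analysis runs at desk scale: 30 basin-hopping steps and a
connection budget of 10–12 band attempts on the 12-bp duplex (≈ 200–700
stationary-point optimizations in total), 21-image bands on the
Müller–Brown surface, 50-network kinetics oracles up to 50 nodes, and
randomized disconnectivity oracles up to 100 minima. These sizes give
stable results for the properties the package asserts (existence and
classification of open states, K_eq < 1, positive barriers, oracle
agreement); they are not converged samplings of the duplex landscape, and
absolute CG rate values should not be over-interpreted.

## Known limitations

- Saddle refinement on the duplex has a finite per-candidate success
  rate; the connection loop compensates with retries, band harvesting and
  stepping stones, so connectivity is reached at the group level rather
  than necessarily between the two lowest endpoints. Rates from these
  partially sampled databases carry a systematic downward bias (unsampled
  pathways count as zero flux) and K_eq no longer equals the two-route
  partition ratio exactly when flux groups are proper subsets of the
  ensembles.
- The harmonic superposition ignores anharmonicity of the very soft
  duplex modes; rates are meaningful relative to each other, not
  absolutely.
- Permutational isomers are out of scope (symmetry numbers default to 1;
  RMSD deduplication uses no atom permutations).
- The all-atom CPDb/SASA dialect reads minimal single-model PDB files
  (ATOM/TER/END) and pairs flanking bases across chains by ring-center
  proximity; it is meant for post-processing small duplex structures, not
  arbitrary crystallographic files.
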