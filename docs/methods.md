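# Methods

`flextail` models a flexible, charged C-terminal tail attached to a rigid
repeat-protein core, under distance restraints from crosslinking mass
spectrometry (XL-MS), validates candidate conformations against small-angle
X-ray scattering (SAXS), and selects representative models through a
filtering-and-clustering cascade.  Alongside the structural pipeline it
implements the binding and stability analyses that accompany such studies:
1:1 biolayer-interferometry (BLI) kinetics, steady-state binding, thermal
melts, and one-phase association.  This note records the models, the
defaults and why they were chosen, and what the synthetic benchmarks do and
do not demonstrate.

## Coordinate model and I/O

All structural computation happens on an ordered atom list addressed by
`(chain_id, res_num)` in author numbering — residue numbering within a
chain is not assumed contiguous, since deposited structures have
unmodelled loop gaps.  The PDB reader is a strict fixed-column
ATOM/HETATM/TER subset: altloc 'A' or blank kept, other altlocs dropped,
insertion codes rejected, first MODEL only.  Strictness is deliberate; the
formats the pipeline consumes are simple enough that silent coercion is
worse than an error naming the line.

## Crosslink restraints

A lysine-reactive crosslinker with spacer length `s` bridging side chains of
reach `r` caps the Cα–Cα distance of a linked pair at `s + 2r` — 24.2 Å for
DSS/Lys (11.4 + 6.4 + 6.4), conventionally relaxed to a <30 Å working
threshold to absorb conformational dynamics.  Restraints enter the sampler
as a flat-harmonic penalty

    f(d) = 0                          if d <= x0 + tol
    f(d) = ((d - x0 - tol) / sigma)^2  otherwise

with defaults x0 = 15 Å, tol = 15 Å, sigma = 1 — i.e. zero penalty below
30 Å and a quadratic wall beyond.  The penalty is one-sided: with these
parameters the lower edge of the tolerance window sits at zero distance, so
no lower bound is ever active, and a one-sided implementation is exact.

Crosslink identification lists are filtered by a decoy-counting FDR: with
the decoy database built from `c` randomized copies of the target sequences,
FDR(s) = (#decoys ≥ s / c) / max(#targets ≥ s, 1), and the loosest score
cutoff with FDR below the requested level (default 5%, c = 10) is applied.
This simple estimator was chosen because the counting convention (divide
decoy hits by the number of appended decoy copies) is the only assumption
needed; no spectral information is consulted.

## Tail sampling

The chain is a Cα trace with fixed 3.8 Å virtual bonds.  The only move is a
pivot: rotate everything downstream of a randomly chosen tail residue about
a random axis through that residue.  Pivots preserve bond lengths exactly
and keep any designated helical segment rigid provided the pivot point is
not inside the segment (the sampler excludes such pivots).  The core never
moves.

Sampling is two-stage, mirroring centroid-then-refinement protocols for
disordered termini: stage 1 (default 2000 steps) uses large pivots
(±60°) under a Metropolis criterion with geometrically cooled temperature
(5.0 → 0.2, dimensionless); stage 2 (default 1000 steps) uses small pivots
(±10°) continuing the cooling, followed by a short greedy minimization
(default 60 moves): a pivot axis is drawn, the energy is evaluated on a
small angle grid, and the best angle is taken if it lowers the energy.
Line searches happen in the pivot-move coordinates rather than Cartesian
space because Cartesian gradients do not preserve the bond constraint.

The energy is a coarse-grained surrogate with three terms: soft-sphere
clash repulsion `(dmin − d)²` for non-bonded pairs under dmin = 4 Å;
screened electrostatics `q_i q_j e^(−d/λ)/d` between charged residues
(±1 by residue type, λ = 10 Å, a Debye length typical of ~100 mM ionic
strength); and the flat-harmonic crosslink term.  All weights default to 1.
The selection cascade treats energy as an opaque sortable score, so the
surrogate's absolute scale is irrelevant downstream — only its ranking
matters.  Each model is sampled independently with seed = base_seed +
model_id, making every ensemble bitwise reproducible.  The default
ensemble size is 200 models, a desk-scale choice (production studies of
this kind use thousands).

The per-move energy kernel is compiled with numba; the public `energy()`
is an independent numpy implementation, and the test suite asserts the two
agree on sampled models to 1e-6 relative.

## SAXS

Theoretical profiles use the Debye equation over point scatterers,

    I(q) = sum_ij f_i f_j sin(q d_ij) / (q d_ij),

with a constant per-residue weight (60 effective electrons) in Cα mode and
per-element electron counts on all-atom input.  No hydration shell or
excluded-volume correction is applied, so absolute chi-square values
against beamline curves reduced with shell-aware software are approximate;
all quantitative claims in the tests compare Debye profiles with Debye
profiles.

Guinier analysis iterates a linear fit of ln I vs q² with the window shrunk
to q·Rg < 1.3 until the estimate stabilizes (0.1% tolerance, 20 iterations).
For globular particles this recovers the coordinate Rg to well under 2%;
for strongly elongated particles the q·Rg < 1.3 convention itself biases
Rg low by several percent — a property of the method, not the
implementation, and the reason recovery tests use compact structures.

Model-experiment agreement is the reduced chi-square with the analytic
least-squares scale `c = Σ(I_e I_m/σ²)/Σ(I_m²/σ²)` and 1/(N−1)
normalization (the convention of the standard profile-fitting tools whose
published values use it).  SEC-SAXS frame stacks reduce as mean(peak) −
mean(buffer), with the uncertainty of each set mean propagated from the
per-frame sigmas.  Multi-state fitting enumerates all candidate subsets of
size 1–3 (pool capped at 50 for exact enumeration) and solves non-negative
weights per subset by active-set NNLS on the sigma-weighted design; the
overall scale folds into the coefficients, which are renormalized to the
weight simplex.

## Selection cascade and clustering

Scored ensembles are narrowed in three deterministic stages: keep the top-N
by energy (default 500, ties by model id); keep chi2 < 2.0; keep models
whose every held-out crosslink (a link deliberately excluded from the
sampling restraints) is under the 30 Å threshold.  An empty survivor set at
any stage is an error naming the stage.

Survivors are partitioned by leader clustering: models are visited in
ascending energy order and join the first cluster whose leader is within
the RMSD cutoff, computed over the tail after superposing on the core
(Kabsch, proper rotations only), else found a new cluster.  Leader
clustering is the documented stand-in for the unpublished clustering tools
used interactively in this field; its cutoff semantics match the
conventional 2.5 Å all-atom usage, which remains the `CascadeConfig`
default.  For the coarse Cα-only pipeline the end-to-end runner clusters at
a 12 Å tail cutoff instead (chosen from pilot runs on the synthetic
system): pairwise tail RMSDs between coarse sampled models are an order of
magnitude larger than between refined all-atom models, and at 2.5 Å every
model is a singleton, which reduces representative choice to raw energy
ranking — exactly what clustering exists to avoid with a weakly calibrated
surrogate energy.  For the same reason the pipeline computes chi-square on
the full instrument-like q-range (0.004–0.388 Å⁻¹, 97 points): the
mid-to-high-q region carries the tail-scale shape information that
separates candidate conformations.  Clusters smaller than
`min_cluster_size` (default 14) are rejected unless they contain one of the
top-10-energy models; each retained cluster is represented by its
lowest-energy member, and clusters are reported largest-first.

## Synthetic study system

The generator builds a Cα-only solenoid core of 32-residue helical repeats
(an 8-residue riser perpendicular to a 12+12 antiparallel hairpin, repeats
stacked with a 24° rotation per repeat along a right-handed superhelical
path; 8 repeats = 256 residues by default).  Helix geometry is ideal (rise
1.5 Å, 100°/residue, 3.8 Å Cα-Cα), and junctions between helices are solved
exactly so every consecutive pair is 3.8 Å apart with no non-bonded pair
under 4 Å.  A 30-residue tail with a 10-residue acidic (D/E) stretch is
grown residue-by-residue with clash avoidance, steered so the acidic
stretch docks within 12 Å of a designated basic (Arg/Lys) patch on the
outer face of the last repeat — emulating an acidic tail that folds back
onto a conserved basic surface.  Every 6th residue is a lysine surrogate;
crosslinks are drawn among surrogate pairs within 24 Å in the truth
conformation (core↔tail by default, since spanning links are the
informative ones), decoys among pairs beyond 40 Å, with disjoint score
ranges (true ~ U(20,40), decoy ~ U(0,20)) so FDR filtering has known ground
truth.

Simulated observables: SAXS curves are Debye profiles with multiplicative
noise sigma_i = 0.02 I_i (chosen for scale invariance of chi-square; the
error model of real beamline reductions is not published with the data);
BLI traces follow the 1:1 model R(t) = R_eq(1 − e^(−k_obs t)) with k_obs =
k_a C + k_d, dissociation R(t_a) e^(−k_d t), at 5 Hz with additive Gaussian
noise; melts are Boltzmann sigmoids.  Reference rate constants for the
simulations (k_a = 1.3e5 M⁻¹s⁻¹, k_d = 0.031 s⁻¹, hence K_D = 0.24 µM;
steady-state K_D = 0.27 µM; a ~9 °C ligand stabilization; a ~96-fold
affinity loss for a binding-site mutant, 2.3 µM vs 24 nM) are the measured
values of the chaperone–Gα system this package was built around, so the
recovery tests exercise realistic magnitudes.

What the synthetic data do not emulate: side chains and real form factors,
hydration, instrument-specific SAXS smearing, BLI mass-transport artifacts,
and non-two-state melting.  Passing tests therefore demonstrate
correctness of the computations and internal consistency of the pipeline,
not instrument-level realism.

## Binding and stability fits

All fits are unweighted least squares (the acquisition software whose
results these analyses mirror does not publish its weighting).  The
dissociation fit includes a free plateau and the association fit a free
baseline, since raw traces carry both.  Replicates aggregate by the
mean-rates convention: K_D = mean k_d / mean k_a, not the mean of
per-trace ratios.  Steady-state data fit one-site specific binding
R = Bmax·C/(K_D + C); a near-linear response over the sampled range trips
a wide-confidence warning.  Melting temperatures are reported two ways —
the midpoint of a Boltzmann sigmoid fit (headline, more noise-robust) and
the argmax of the Savitzky–Golay-smoothed derivative with parabolic peak
refinement — because neither convention is universal across instruments.

## Numerical choices and degenerate inputs

Kabsch superposition enforces det(R) = +1 (mirror images are never
"fit"); collinear point sets are an error.  RMSF aligns every frame to an
iteratively re-estimated mean structure, making the profile invariant to
frame order and to rigid motions of individual frames.  SASA uses
Shrake–Rupley quadrature with Fibonacci sphere points (default 960), probe
1.4 Å, radii C 1.7 / N 1.55 / O 1.52 / S 1.8 Å, and a 3.0 Å pseudo-residue
radius in Cα-only mode; interface burial is (SASA_A + SASA_B − SASA_AB)/2.
Buried-area values depend a few percent on radii and quadrature — an
intrinsic spread among SASA implementations.  Ties in every ranking break
by ascending energy then ascending model id, making the whole cascade a
pure function of its inputs.

## Problem sizes

Default benchmark sizes are desk-scale by design: 200-model ensembles, a
286-residue synthetic system, 50–70-point scattering curves, 25–100
replicate fits.  These sizes make every result reproducible in minutes on
one CPU while remaining large enough for the statistical recovery claims
the tests assert.

## Known limitations

- The energy surrogate ranks coarse conformations; it is not calibrated to
  any physical energy scale, and a lowest-energy model is not guaranteed to
  be the truth-like one — this is precisely why the cascade validates with
  SAXS and held-out crosslinks and why representatives come from the most
  populated cluster.
- Cα-mode SASA with a single pseudo-residue radius approximates burial
  trends, not absolute areas.
- Absolute SAXS chi-square against experimentally reduced curves is not
  comparable to shell-aware fitting programs.
- The decoy FDR estimator assumes decoy scores are exchangeable with
  false-target scores; it inherits the usual small-sample coarseness when
  few matches exist.
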