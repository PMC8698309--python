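# Methods

This note records what `caflex` computes, the defaults it ships with,
and the choices made where the underlying methodology is genuinely open.

## Coordinate handling and units

Coordinates are Angstrom internally (PDB native).  Deviations and
fluctuations are converted to nanometres only at the reporting boundary,
because the calling thresholds are defined in nm: 0.3 nm for high
flexibility, 0.1 nm for wild-type-vs-mutant calls.  PDB parsing and
writing go through biotite's fixed-column reader; alternate locations
keep the first variant per residue, HETATM records are dropped unless
the het-to-standard rename table (currently `MSE → MET`) is explicitly
enabled, and insertion codes are rejected outright because they make
residue ordering ambiguous (none of the structures this toolkit targets
need them).  Trajectories are multi-model PDB or a plain `x y z` table
with an `n=<atoms>` header; frame spacing defaults to 10 ps (a 50 ns run
stored as 5000 frames) and is metadata only — every statistic in the
package is invariant to frame order.

## Ensemble superposition

Structures are mapped onto MSA columns by exact sequence match (the
mapper reports the first mismatching position).  Superposition is the
Kabsch least-squares fit on the proper-rotation branch, computed via
`scipy`'s `Rotation.align_vectors`; fits on fewer than three points or
(near-)collinear point sets are refused.

The **invariant core** is found by iterated exclusion: start from all
columns present in every structure; superpose everything onto the first
structure over the current candidate core; drop the column with the
highest total positional variance; stop when the core "volume" (the
product of the per-axis variance sums, in Å³) drops below 0.5 Å³ or the
core reaches `max(10, L/5)` columns.  Ties drop the lower column index,
so the search is deterministic.  This is the classic volume-threshold
core-finding scheme used for ensembles whose most invariant region
(e.g. a C-terminal domain) is not known a priori; an explicit
residue-range core can be supplied instead.  The reference structure is
the first label in the ensemble and can be overridden.

Pairwise sequence identity is matches / aligned non-gap pairs; form
separation uses single-linkage grouping at a 70% identity threshold.

## PCA

The covariance is the population (1/S) covariance of the flattened
3n-vectors about the sample mean, matching the expectation form of the
definition; samples must already be superposed (the ensemble fitter or
the trajectory mean-fit does this).  Eigenvectors are sign-fixed so the
largest-magnitude component is positive, making projections
reproducible.  For trajectories the conventional analysis window is the
final 80% of frames (dropping the initial fifth as equilibration); the
window is a parameter.  PC-space clustering — used to separate
conformational families — is complete-linkage hierarchical clustering
on the first three projections, cut at k clusters, with labels
renumbered by first appearance; the choice of linkage is a documented
reconstruction, since visual cluster assignments in the literature
rarely state one.

## Elastic-network normal modes

Default force field: cutoff ANM, cutoff 15 Å, uniform spring k = 1.
Off-diagonal 3×3 Hessian blocks are −k·uuᵀ with u the unit inter-bead
vector; diagonal blocks cancel the row sums, so translational
invariance holds by construction.  A Hinsen-style distance-decay
alternative (`force_field="calpha"`) is provided: k(r) linear below
4 Å, r⁻⁶ beyond, the standard C-alpha parameterization up to a global
scale.  Masses are uniform and k is unitless — fluctuation profiles are
relative, which is all the cross-structure comparison needs; no
absolute Å calibration is attempted.

A connected, non-degenerate network has exactly six zero modes.  The
trivial-mode detector uses a 1e-8 relative eigenvalue threshold:
numerical zeros sit near 1e-14 relative, while genuinely soft hinge
modes of floppy structures can come within 1e-6 relative of zero and
must not be swallowed.  More than six near-zeros raises an error that
reports the number of connected components (and flags possible
collinear geometry when there is only one).

Per-residue fluctuations are `f_i = Σ_{m>6} |v_{m,i}|²/λ_m`.  The
implementation is cross-checked in the test suite against frozen
fluctuations from the bio3d R package (`nma(ff="anm", cutoff=15)`) on a
30-residue ideal helix, agreeing to ~1e-4 after normalization.

**Ensemble NMA** computes each structure's modes on its own ungapped
C-alpha set, lays the profiles on alignment columns, scales each
profile to mean 1 over the all-present columns, and averages those into
the consensus.  The unscaled profiles are retained, since normalization
conventions vary between implementations.

## Trajectory analytics

* **RMSD**: each frame Kabsch-fit to the reference (a frame index, a
  model, or raw coordinates) over an optional fit mask, deviation
  measured over a report mask; summary is mean ± SE with SE = sd/√F
  over frames.  Frame-based SE is a deliberate, documented choice —
  block-averaged SE would be larger on autocorrelated data, but the
  generator's frames are i.i.d. (below).
* **RMSF**: frames are superposed on an iterated mean structure
  (fit → mean → fit, two refinement passes) so rigid drift does not
  inflate the profile; `RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)`.
* **DCCM**: Ichiye–Karplus normalized covariance of the 3-vector
  displacements after the same mean-structure fit, full trajectory by
  default (an optional window mirrors the PCA convention).  Atoms with
  zero displacement variance get NaN rows/columns and a warning rather
  than a silent 0, so degenerate blocks cannot bias region averages.
* **Calling rules**: flexible regions are maximal runs, contiguous in
  author numbering, with RMSF ≥ 0.3 nm (inclusive, singletons allowed);
  profile comparisons call residues whose RMSF moved by ≥ 0.1 nm in
  either direction and merge contiguous calls into ranges; correlation
  banding is closed toward the extremes (C ≥ 0.5 correlated, C ≤ −0.5
  anticorrelated).

## Synthetic data and what it does (not) show

The generator emulates the statistical structure the estimators assume,
not the physics that produces it:

* toy geometries — ideal α-helix (1.5 Å rise, 100°/residue, 2.3 Å
  radius, Cα–Cα ≈ 3.8 Å), fixed-step random coil, and a two-domain
  helix-linker-helix hinge (the linker zig-zags; a collinear linker
  would leave a free torsional mechanism and a seventh zero mode);
* planted-mode ensembles — base + Σ a_m·mode_m + noise with
  orthonormal internal mode fields (rigid-body subspace projected out)
  and Gaussian amplitudes, so PCA has an exact recovery target;
* Gaussian trajectories — i.i.d. frames from a known 3n×3n covariance
  (optionally the pseudo-inverse covariance of an elastic network,
  rescaled to a target mean RMSF), returned with the analytic DCCM
  (block-trace normalization) and RMSF.

Frames are i.i.d. because every statistic here is frame-order
invariant; kinetic quantities (autocorrelation times, transition
sampling) are out of scope, so passing tests certify estimator
correctness, not the convergence behaviour of real, autocorrelated MD
output.  Likewise the toy geometries lack tertiary packing, so absolute
fluctuation scales do not transfer to real proteins — only the
estimator contracts do.

Default study conditions used by the verification suite and the
acceptance script: planted-mode ensembles of 500 structures with 3 Å /
1 Å mode amplitudes (a 9:1 variance split); DCCM convergence at 20,000
frames; RMSF closed-form checks at 50,000 frames; end-to-end pipeline
runs at 2,000 frames of a 30-residue helix — sizes at which sampling
error is comfortably inside each check's tolerance on a single CPU.

## Numerical choices

* Covariance symmetrized and eigendecomposed with `scipy.linalg.eigh`;
  PSD sampling uses the eigen square root with negative eigenvalues
  clipped at zero.
* Collinearity in fits: second singular value < 1e-8 of the first.
* Coincident beads (< 0.01 Å apart) are a geometry error in the ENM.
* All stochastic generators take a mandatory integer seed
  (`numpy.random.default_rng`); ground truth is emitted next to the
  data, never recomputed downstream.
* Determinism: core finding, clustering labels and eigenvector signs
  are all tie-broken explicitly, so repeated runs produce byte-identical
  CSV output.

## Known limitations

* PDB only (no mmCIF, XTC/DCD); single-conformer altloc handling;
  insertion codes rejected.
* The invariant-core search and the PC-space clustering are documented
  reconstructions of common practice, not unique definitions; on real
  ensembles their output should be inspected (both are exported).
* ENM fluctuation scale is relative; comparisons to experimental
  B-factors or Å-scale plots require an external calibration.
* SE of the mean RMSD is frame-based and underestimates the error on
  autocorrelated trajectories.
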