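# Methods

## Representation

Everything operates on one Cα per residue.  The statistics computed here
are residue-level quantities and the virtual backbone bond vectors are
defined between successive Cα atoms, so heavier atom sets would change
nothing structural about the method while complicating the I/O contract.
A `Topology` fixes the residue order (chains contiguous, author numbering
preserved, insertion codes rejected); a `Trajectory` is frames × residues
× 3 in Å with strictly increasing frame times in ns.  Frame times are
1-based (the first snapshot sits at one frame interval), so the default
equilibration marker of 0 ns flags nothing.  Equilibration frames are
flagged, never deleted: one file serves both full and equilibrated
analyses, and each statistic filters on the flag.

## Superposition and chain-pivot RMSD

Rigid-body fits are mass-unweighted least squares solved by SVD with the
reflection branch forbidden (proper rotation, det = +1).  The fitted RMSD
is recomputed from the transformed coordinates rather than taken from the
solver's residual, which is only √ε-accurate near a perfect fit.  Fits
require at least three non-collinear residues.  `rmsd_timeseries`
separates the fit mask from the measure mask: with the two equal it is the
ordinary self-aligned RMSD; with the fit on one chain and the measure on
another it reports quaternary (relative-orientation) change.  In the
planted rotation-event scenario the pre-event cross-pivot level is not
zero but a noise floor amplified by the lever arm between the fit chain's
centroid and the measured chain; the post-event level equals the analytic
RMSD of the planted transform, and tests assert exactly that.

## Fluctuations

msf_i = ⟨|R_i(t) − ⟨R_i⟩|²⟩ over usable frames, after superposing every
frame on the fit selection onto the first usable frame (any fixed
reference gives the same msf up to the fit's noise; the first frame keeps
the choice deterministic and shared across windows).  The superposition
absorbs 6 rigid-body degrees of freedom out of 3N, deflating recovered
variances by ≈ 6/3N — visible on short chains, negligible for
protein-sized ones; the validation uses a 100-residue chain for this
reason.  Per-chain fitting (the recommended use for complexes) prevents
quaternary rearrangements from inflating internal fluctuations, and an
exclude mask removes flexible segments (e.g. a disordered N-terminal tail)
from the fit.  "Center-of-mass" distances are unweighted Cα centroids — an
approximation documented as such, since masses are not carried.

## Cross-correlation maps

C_ij = ⟨ΔR_i·ΔR_j⟩ / √(⟨ΔR_i²⟩⟨ΔR_j²⟩) with ΔR taken from the analysed
frames' own mean.  Per-frame alignment (caller's fit mask, default the
whole selection) removes global motion first — the statistic is
meaningless under unremoved rigid-body rotation.  Windowed maps are
self-contained: each window uses its own mean (a global-mean flag exists),
but all windows share one alignment reference so they live in a common
frame.  Residues with zero variance produce NaN rows/columns, never silent
zeros, and are excluded from summaries.  A window pair can be reduced to a
single number — the mean absolute difference of the two maps over a chosen
residue-block pair (e.g. catalytic-site rows × target-recognition
columns) — for comparing correlation regimes across time windows.
The optimized einsum path is tested to 1e-10 against a literal double-loop
implementation of the definition.

## Bond-vector autocorrelation

A_i(τ) = ⟨M_i(t)·M_i(t+τ)⟩ over all usable snapshot pairs, with M_i the
unit Cα(i−1)→Cα(i) vector and bonds never spanning chain boundaries.
τ = 0 gives exactly 1 for every bond.  This is computed on **raw,
unaligned** coordinates: bond vectors are internal directions, and
per-frame realignment would change the result (a test constructs rigidly
tumbling frames and asserts the decay that realignment would erase).  It is
invariant under a single static rigid transform of the whole trajectory.
Delays must be nonnegative multiples of the frame interval and leave at
least two frame pairs; a shipped preset uses the delay grid
{0, 0.4, 1, 5, 30} ns with the guidance that the largest delay stay near
half the trajectory span (longer delays average too few pairs to be
stable — the pipeline logs a warning past half-span, and errors only when
fewer than two pairs remain).

## Clustering

Radius-seeded k-means with coordinate RMSD to the centroid as the metric:
frames are first aligned once to a fixed reference (never re-aligned to
moving centroids), then (1) seeding scans frames in order and any frame
farther than the radius from every existing centroid founds a new one;
(2) Lloyd iterations alternate nearest-centroid assignment (ties to the
lowest cluster index) with coordinate-mean centroid updates until
assignments stabilise; empty clusters are dropped.  The radius controls
cluster count (nonincreasing in radius, by the seeding rule), and the
procedure is deterministic — the seed argument only drives an optional
seeding-order shuffle, off by default.  Occupancy tables are computed per
source trajectory over post-equilibration frames and each row sums to
100%.  Centroids are coordinate means; representative structures are
medoids (member frame nearest its centroid, ties to the earliest frame),
kept distinct because exemplar conformations and occupancy machinery
answer different questions.  The exact seeding order of the original
clustering tools this emulates is not public, so cluster boundaries on
identical data may differ; the occupancy statistics recovered from planted
ensembles are the tested contract.

## PCA

Eigendecomposition of the 3N-coordinate covariance of the joined, aligned
usable frames (delegated to a full-SVD PCA; an independent eigh-on-
covariance oracle checks the spectrum in the tests).  The model stores
per-component variance proportions and cumulative proportions — the
numbers quoted on projection axes — and projections are dot products of
mean-centered aligned coordinates with the eigenvectors, in Å.  The trace
identity (Σ eigenvalues = total coordinate variance) and full-rank
reconstruction are asserted to 1e-8.

## Synthetic trajectories

The generator is the validation substrate and defines the test conditions:

- **Reference geometry**: an idealized helical Cα trace (2.3 Å radius,
  100° twist, rise chosen for exactly 3.8 Å Cα spacing), chains offset by
  30 Å.  Not a real protein — chosen so every expectation is closed-form
  and no external files are needed.
- **Gaussian fluctuations**: per-residue per-axis variance (default
  0.25 Å², i.e. msf 0.75 Å²) with a planted residue–residue correlation
  structure.  A correlation block is compound-symmetric — every
  off-diagonal pair within the union of the two groups gets ρ — because a
  constant *cross*-block ρ with unit diagonal is not positive semidefinite
  once ρ²·|A|·|B| > 1 (ρ = 0.8 with 3+3 residues already is not); the
  compound-symmetric form is PSD for ρ ∈ (−1/(k−1), 1] and still yields
  inter-group entries ≈ ρ and ≈ 0 elsewhere.  Specs are PSD-validated.
- **Temporal structure**: white noise, or an OU process via the exact
  autoregressive update d_{t+1} = a·d_t + √(1−a²)·ε with a = exp(−Δt/θ),
  so the lag-τ autocorrelation is exp(−τ/θ) exactly on the frame grid (no
  Euler discretization error).
- **Rotational diffusion**: bond directions rotated each step by a random
  rotation vector with variance 2DΔt per axis, coordinates rebuilt by
  chaining 3.8 Å bonds; first-rank orientational correlation exp(−2Dτ).
  The per-step small-angle bias is O((2DΔt)²); at the default Δt = 0.01 ns
  it is far below the 0.03 validation tolerance.
- **Rotation event**: after the event time one chain's reference is
  rigidly transformed (rotation about the chain centroid plus translation);
  `event_chain_rmsd` returns the analytic RMSD of that transform.
- **Multi-basin ensembles**: basin centers are the reference plus mutually
  orthogonal random displacement patterns with the rigid-body modes (net
  translation and linearized rotations) projected out, scaled so each
  center's RMSD from the reference equals its planted offset — pure
  rigid-body offsets would be erased by the pre-clustering superposition.
  Frames draw a basin i.i.d. from the planted weights with isotropic
  within-basin spread.

All randomness flows from one seeded generator per trajectory; identical
(spec, seed) is bit-identical.  What the generator does **not** emulate:
anharmonicity and fat-tailed fluctuations, coupling between positional and
orientational noise, solvent and force-field physics, and kinetically
ordered (non-i.i.d.) basin visits.  Passing tests therefore demonstrate
the estimators recover known statistical structure at realistic sampling
depths — not that any particular biological system behaves this way.

## Pipeline

A single YAML config names inputs, selections and analyses; validation
collects *all* schema violations before reporting.  Span-dependent delay
checks happen at run time (half-span advisory as a log warning, hard error
only when a delay leaves fewer than two pairs), since the file is not read
at validation.  The bundle manifest records package version, config hash,
seeds and a sha256 per output; reruns of an identical config are
bit-identical, and disabling a stage changes no other stage's outputs.

## Problem sizes used in validation

Parameter-recovery checks run at the depths quoted with their tolerances:
5000 frames for correlation (±0.05), OU and rotational-diffusion decay
(±0.03–0.05), and msf (±5%); 2500-frame halves for the windowed
correlation switch (±0.07); 1000 frames for occupancy recovery (±3
points); 2000 frames for PCA proportions (±0.03).  Chains of 10–100
residues cover the estimators' size dependence; oracle-agreement checks
(1e-10) run on 10 residues × 100 frames where the double-loop reference is
exact and cheap.

## Known limitations

- Cα-only; no mass weighting anywhere (documented where it matters).
- No binary trajectory formats (DCD/XTC) — multi-model PDB and the text
  frame table are the supported inputs.
- Insertion codes are rejected rather than disambiguated.
- The clustering is a deterministic stand-in for radius-controlled k-means
  tools whose internal seeding order is unpublished; occupancies, not
  cluster labels, are the comparable quantity.
- Second-rank (P2/S²-style) orientational correlations and
  mutual-information generalized correlations are out of scope.
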