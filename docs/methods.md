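# Methods

This note documents the models implemented in `allostate`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions a user should know before trusting results.

## Kinetic modelling

**Features.** Backbone φ/ψ and sidechain χ₁ torsions of a configurable
residue window are the default feature set for kinetic modelling. Every
angle is emitted as a (cos θ, sin θ) pair. This removes the −180°/180°
wrap; the covariance estimators downstream assume Euclidean features, and a
raw angle trajectory crossing the period would masquerade as a fast
process. χ₁ is defined as N–CA–CB–Xγ with the standard γ heavy atom per
residue type; Gly and Ala contribute φ/ψ only.

**TICA.** Instantaneous and time-lagged covariances are pooled over all
(t, t + τ) pairs across trajectories, with the mean taken over the union of
head and tail frames and the lagged covariance symmetrized,
(C + Cᵀ)/2 — the reversible estimate, which guarantees real eigenvalues.
The projection solves C_τ v = λ C₀ v with a ridge (default
10⁻⁶ · tr C₀ / n) added to C₀ for conditioning; with ridge 0 a singular C₀
raises rather than silently regularizing. Components are C₀-orthonormal,
sorted by descending eigenvalue, with the deterministic sign convention
that each component's largest-magnitude loading is positive. Physical lag
times are converted to frame lags exactly; a non-integer ratio is an error,
not a rounding.

**Discretization.** k-means (k-means++ initialization, 10 restarts, best
inertia kept, fixed seed; relative inertia tolerance 10⁻⁶, ≤500
iterations) in the TICA space; assignment is nearest-center with ties to
the lowest index. The number of centers is chosen by shuffle-split
cross-validation on the VAMP-2 score (default rank 10, 5 folds): whole
trajectories are the split units, or contiguous blocks when there are
fewer trajectories than folds. The cross-validated score applies
singular functions estimated on the training split to test covariances; it
includes the constant function, so 1 ≤ score ≤ rank.

**Markov state model.** Sliding-window transition counts at lag τ are
trimmed to the largest strongly connected component of the count graph
(tie-break: the component containing the lowest state index; the trimmed
fraction is warned about), then row-normalized. No detailed-balance
constraint is imposed — the estimator is exactly the count-matrix row
normalization. The stationary distribution is the left eigenvector with
eigenvalue closest to 1; imaginary parts above 10⁻¹⁰ are an error,
negative entries below that tolerance are clipped. Implied timescales use
−τ / ln |λ| with complex eigenvalue pairs scored by magnitude; non-positive
(or numerically zero, <10⁻¹²) real eigenvalues yield an undefined (NaN)
timescale.

**Equilibrium resampling.** Ensemble statistics are computed on n draws
(default 30,000) made by sampling a state from π and then a frame uniformly
from that state's assigned frames, with replacement, reproducibly under a
seed. A state with positive weight but no assigned frames is an error.

## Structural statistics

**Superposition.** Kabsch SVD with the determinant correction (proper
rotations only); fewer than three or collinear fitting points raise. RMSD
takes independent alignment and measurement subsets, so "align on the
structured core, measure the linchpin" is a first-class operation.

**Linchpin RMSD.** A frame is aligned to the active-state reference on the
Cα atoms of the structured core — when a residue range is given, "structured"
is decided by the package's own secondary-structure assignment *on the
reference structure* and frozen into the reference model, which keeps the
definition reproducible — then the RMSD of the linchpin residue's heavy
atoms is measured without re-alignment. Atoms are matched between frame
and reference by (chain, residue, atom name); the target set is the
name intersection, so a Lys→Arg linchpin substitution is handled by the
shared atom names.

**SASA.** Shrake–Rupley with Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å), probe 1.4 Å, 960 quasi-uniform sphere points by default
(golden-spiral construction; ≥92 required). The bundle SASA sums
sidechain-heavy atomwise areas over a configured interface residue set;
partner chains must be stripped beforehand so burial reflects the bundle
alone. Single-frame and vectorized multi-frame paths share the same
arithmetic (tested equal); the sphere-point grid is fixed in the lab frame,
so areas carry a small (<1% at 960 points) orientation jitter.

**Secondary structure.** A simplified DSSP: backbone H-bonds by the
Kabsch–Sander energy E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol, bond iff E < −0.5, with amide hydrogens reconstructed at 1.01 Å
on the bisector of (N − C_prev) and (N − CA) when absent. Helix (H)
requires two consecutive i → i+4 turns; sheet (E) uses the minimal
parallel/antiparallel bridge rules; everything else is C, including 3₁₀/π
helices and isolated turns — a deliberate simplification relative to full
DSSP, adequate for "structured vs not" probabilities (agreement with a
reference DSSP implementation is tested on the ideal-helix fixture).
Geometric hydrogen-bond tests use d(H···A) < 2.5 Å and ∠D–H···A > 120°
(strict inequality at the angle boundary) by default; both are
configurable since no single criterion is canonical.

**Primed/collapsed classification.** The cutoff between high-SASA (primed)
and low-SASA (collapsed) bundles is placed at the density minimum between
the two largest modes of a Gaussian KDE (Silverman bandwidth) on the pooled
values; unimodal data raise an error advising a manual cutoff rather than
inventing one. Classification is strict: values exactly at the cutoff are
collapsed. Conditional distributions report per-label histograms on shared
edges, means/medians, P(value < 2.5 Å) as a "primed linchpin" probability
(the 2.5 Å threshold is a reporting convenience alongside the full
distributions, not a fitted constant), and the two-sample KS statistic.

## Label model

The ensemble-comparison model is a supervised autoencoder trained jointly
on frames of two ensembles: two affine layers with tanh to a latent space
(default dimension 10, mirroring the TICA dimension), a mirrored decoder,
and a sigmoid label head on the latent code. The loss is per-element
reconstruction MSE plus binary cross-entropy of the label against its
current target, weighted 3:1 in favour of the label term so the activity
coordinate is not drowned by reconstruction; optimization is Adam at
3 × 10⁻³, batch 256, 50 epochs, fully deterministic under the seed. After
each epoch the targets are replaced by the model's own label outputs
clamped into per-ensemble EM bounds (defaults [0.2, 0.8] and [0.6, 0.8];
initial targets 0.5 and 1.0). Inputs are standardized internally; identical
frames appearing in both ensembles are an error. With degenerate bounds
[0, 0] / [1, 1] the procedure reduces to an ordinary classifier.
Attribution is post hoc: Pearson correlation of each candidate distance
with the final labels, ranked by |r| with sign retained; zero-variance
columns report NaN.

## Synthetic generators and what passing tests mean

The generators plant a known answer and are the package's test bed:

- **Markov chains + Gaussian emissions** validate the estimator chain.
  The default planted scenario uses a 4-state matrix with two slow
  processes and emission means on orthogonal axes at 6 within-state SDs —
  clearly metastable basins, so discretization error does not confound the
  kinetic recovery being tested.
- **Ideal helices** built from standard internal coordinates (N–CA 1.458,
  CA–C 1.525, C–N 1.329, C=O 1.231 Å; trans ω) validate torsion and
  secondary-structure code by round trip.
- **Toy allosteric ensembles**: a latent open/closed variable (P(open) =
  0.5 by default) sets a hinge angle between two rigid 5-residue
  pseudo-helices whose sidechain beads bury each other when closed, and the
  linchpin displacement follows
  max(0, δ + (1 − g·[open]) · base + N(0, σ)) with base 3 Å and σ 0.5 Å.
  The planted scenario table is wild type (δ = 0, g = 1), a
  pathogenic-like variant (δ = +2 Å) and a hyperactive-like variant
  (δ = −1 Å, g = 0, i.e. equally primed in both bundle states). The
  mutant-ordering check reads the **collapsed-conditional** median, where
  the planted ordering hyperactive < WT < pathogenic lives; in the primed
  state the wild type is already fully primed, so a constitutively primed
  variant cannot undercut it there.

What the toys do **not** emulate: chemically valid sidechain geometry,
solvent, realistic SASA magnitudes, kinetics in the coordinate ensembles
(frames are i.i.d. given the latent state), or the dimensionality of real
heavy-atom coordinate spaces. Passing tests therefore demonstrate that the
estimators recover what they claim to estimate under their own model
assumptions — not that a particular biological system behaves this way.

## Problem sizes and determinism

Validation runs use desk-scale sizes chosen so each check is statistically
decisive: 10⁵ steps for transition-matrix recovery (entrywise error ≲ 0.003
vs the 0.01 bound), 8 × 20,000 steps for implied-timescale flatness,
5,000-frame toy ensembles × 10 seeds for coupling and ordering recovery,
1,000 frames per ensemble × 10 seeds for attribution. Every stochastic
stage takes an explicit seed and is bit-reproducible under it; the
acceptance script derives all of its seeds from a single `--seed`.

## Known limitations

- The MSM estimator is non-reversible by design; π can be complex-sensitive
  for nearly periodic chains (guarded by the imaginary-part check).
- The simplified DSSP under-calls helix termini and does not distinguish
  helix subtypes.
- The PDB reader handles the fixed-column dialect only (no mmCIF, no
  insertion codes); binary trajectory formats are out of scope.
- The label model is a small dense network; for very high-dimensional
  coordinate inputs, feature pre-selection (e.g. the distance pool used for
  attribution) is the intended route.
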