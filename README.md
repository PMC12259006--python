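# allostate

Ensemble inference for **allosteric conformational selection** in RING-domain
E3 ubiquitin ligases — and, more generally, for any protein where a binding
partner is suspected of selecting rare, pre-organized active conformations
rather than inducing them.

The motivating system is the BRCA1 RING domain: BARD1 binds BRCA1's helix
bundle, and catalytic activity requires that the conserved "linchpin" lysine
(K65 in BRCA1) sit close to its productive pose at the E2~ubiquitin
interface. The package implements the complete analysis chain needed to ask,
from conformational ensembles alone, whether bundle geometry and linchpin
priming are allosterically coupled and how mutations shift that coupling:

1. **Featurization** — φ/ψ/χ₁ dihedrals of a residue window, encoded as
   (cos θ, sin θ) pairs; inter-atomic distances; heavy-atom contacts.
2. **Kinetic modelling** — TICA (generalized eigenproblem
   C_τ v = λ C₀ v), k-means discretization, Markov state models by row
   normalization of sliding-window transition counts
   T_ij = c_ij / Σ_j c_ij on the largest strongly connected state set,
   implied timescales t_i(τ) = −τ / ln λ_{i+1}(τ), and rank-r VAMP-2
   cross-validation for choosing the number of cluster centers.
3. **Equilibrium resampling** — ensemble statistics are computed over
   samples drawn state-wise from the stationary distribution π (πT = π),
   frame-uniform within states.
4. **Structural statistics** — Kabsch superposition and RMSD (independent
   alignment and measurement subsets), linchpin RMSD against an active-state
   reference model, Shrake–Rupley SASA (bundle SASA = Σ sidechain-heavy
   atomwise SASA over the interface residues, partner chains removed), a
   simplified DSSP (Kabsch–Sander H-bond energy + minimal turn/bridge
   rules), geometric hydrogen-bond tests, and 2-D free-energy landscapes
   F = −ln(P / P_max).
5. **Ensemble comparison** — a self-labelling supervised autoencoder
   ("DiffNet"-style): per-frame labels in [0, 1] are iteratively re-targeted
   to the model's own outputs clamped into per-ensemble EM bounds; learned
   labels are then attributed to inter-residue distances by Pearson
   correlation.
6. **Synthetic ground truth** — generators for Markov chains with Gaussian
   emissions, ideal helices, and toy allosteric ensembles in which a latent
   open/closed bundle variable controls both interface burial and linchpin
   displacement with tunable coupling and mutation shift, so every stage is
   testable without molecular-dynamics data.

Structures are interchanged as multi-model PDB; feature matrices and
discrete trajectories use a small documented binary container
(`allostate.matio`); tabular outputs are pandas DataFrames.

## Worked example

`examples/allosteric_coupling.py` generates three toy ensembles (planted
wild-type coupling, a loss-of-function shift, and a constitutively primed
variant), classifies frames as primed/collapsed from bundle SASA alone, and
conditions the linchpin RMSD on that classification:

```
primed/collapsed SASA cutoff (wild-type ensemble): 389 A^2

scenario      primed median  collapsed median
WT                   0.13 A            2.99 A
pathogenic           2.00 A            4.99 A
hyperactive          2.00 A            1.99 A
```

Reading the numbers: in the wild-type ensemble, frames whose bundle is open
(primed) have their linchpin essentially on the reference pose (median
0.13 Å) while collapsed frames sit ~3 Å away — the planted allosteric
coupling, recovered without ever looking at the latent state. The
loss-of-function scenario shifts both conditional medians up by the planted
2 Å; the constitutively primed scenario shows almost no difference between
bundle states. The other example scripts (`msm_pipeline.py`,
`label_attribution.py`, `structure_metrics.py`) demonstrate the kinetics
branch, the label model, and the geometry primitives the same way.

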