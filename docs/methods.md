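# Methods

## The representation model

A molecule is presented to the network as three linked graphs built from
its heavy-atom skeleton and one 3D conformer:

* **G = (V, E)** — atoms are nodes, chemical bonds are edges;
* **H = (E, A)** — bonds are nodes; a *bond angle* (u, v, w), i.e. a pair
  of bonds (u,v), (v,w) sharing the apex atom v, is an edge;
* **I = (A, D)** — bond angles are nodes; a *dihedral* (u, v, w, x), i.e. a
  pair of angles (u,v,w), (v,w,x) sharing the central bond (v,w), is an
  edge.

Every element is stored once in a canonical orientation and its edges are
emitted in both directions, so message passing is symmetric.  The
continuous geometry enters as initial features: bond lengths l_uv (Å),
bond angles φ_uvw ∈ [0, π], and *signed* torsions θ_uvwx ∈ [−π, π),
each expanded in a 20-center Gaussian radial basis (lengths on [0, 5] Å,
angles on [0, π], torsions on [−π, π) with *periodic* distance — see
"Numerical choices").  Categorical atom/bond attributes (element, degree,
formal charge, implicit-H count, hybridisation, aromaticity, ring
membership, chirality tag; bond order, ring flag, stereo tag) are one-hot
encoded with a reserved "other" bucket per vocabulary.

One iteration t updates the levels top-down so each lower level consumes
the current iteration's higher-level states as edge features:

    a_uvw^t = Σ over neighbouring angles through dihedrals ( h_angle + x_dihedral )
    h_uvw^t = Comb_I( h_uvw^{t−1}, a_uvw^t )
    a_uv^t  = Σ over neighbouring bonds through angles    ( h_bond  + h_angle^t )
    h_uv^t  = Comb_H( h_uv^{t−1}, a_uv^t )
    a_u^t   = Σ over neighbouring atoms through bonds     ( h_atom  + h_bond^t )
    h_u^t   = Comb_G( h_u^{t−1}, a_u^t )

Aggregation/combination are GIN-style: sum aggregation and a two-layer
perceptron combine `MLP((1+ε)h + a)` with learnable ε, followed by a
residual connection and layer normalisation; graph normalisation divides
each level's aggregate by √(node count of that level's graph).  After K
iterations the atom states are mean-pooled into the molecule vector h_G;
the per-atom states h_u^K feed atom-level heads.

Because all inputs are internal coordinates, h_G is invariant to rigid
motions and atom relabeling but **not** to reflection: mirroring a
conformer negates every torsion while lengths and angles are unchanged, so
enantiomeric conformers receive different embeddings — unless the molecule
is achiral, in which case the mirrored geometry is reachable by a proper
rotation plus a symmetry relabeling and the embedding coincides, as it
must.  Ablation flags reduce the model to a bond-angle-only network
(dihedral channel zeroed) or a plain atom-bond GNN, which is how the
dihedral channel's contribution is isolated in the discrimination
experiments.

Defaults: hidden width 32, K = 8 iterations, dropout 0.2 (applied only
when a training RNG is supplied; inference is deterministic).  These
sizes are judgement calls, so they are configuration values, not
constants.

## Self-supervised tasks

**Masking.** Per molecule, max(1, ⌈0.15·|V|⌉) atoms are drawn uniformly
without replacement.  Masked input features are replaced by a learned
per-level mask token.  The geometric stage hides the selected atoms'
features plus every bond, angle and dihedral containing a selected atom;
the adjacent atoms *define* this neighbourhood but keep their own features
visible — hiding them too turns out to make the masked-length target
statistically unrecoverable (a conditional-mean oracle on the visible
context then sits at the global-variance floor), which defeats the purpose
of the task.  The electronic stage hides only the selected atoms and their
bonds.

**Geometric losses.** From the final atom states, four heads predict: bond
length (MSE over masked bonds), bond angle (MSE over masked,
non-collinear angles), torsion as its (sin θ, cos θ) pair (squared error,
respecting 2π-periodicity; a raw-θ mode exists behind a flag), and the
binned atom-pair distance — 30 equal-width classes on [0, 15] Å, clamped —
as a categorical cross-entropy over ≤ 500 sampled ordered pairs per
molecule.  All pair heads are symmetric (f(h_u, h_v) = f(h_v, h_u)); the
angle and dihedral heads are symmetric under the tuple reversals that fix
the element.

**Electronic losses.** MSE of per-atom partial charge over masked atoms
and of per-bond Wiberg-style order over masked bonds.  Molecules lacking
labels are skipped with a warning.

**Two-stage recipe.** Geometry stage first (cheap force-field conformers,
no labels needed), then the electronic stage warm-started from it
(conformers with quantum-chemistry-style labels).  Geometry-only,
electronic-only, and no-pretraining variants are constructible from the
same entry point, which is what the strategy-comparison test exercises.

**Optimisation.** Adam, trunk learning rate 1e-3, prediction heads at 3×
the trunk rate; global gradient-norm clipping at 5; per-batch Polyak/EMA
weight averaging with decay 0.9, the returned model carrying the average.
The six loss terms are combined with inverse-variance weights computed
from the training targets ("auto"): each regression term is effectively
trained on standardised residuals, so millimetre-scale length errors are
not drowned by the O(1) cross-entropy gradients.  Reported loss values are
always the unweighted per-term means.  This recipe exists because the
naive alternative (single rate, equal weights) leaves the regression terms
oscillating at the mean-predictor baseline within a 20-epoch budget while
the distance classifier monopolises the trunk; with it, the masked
bond-length MSE lands reliably below that baseline.  Fresh masks are drawn
per molecule per epoch; every random draw derives from the run seed, and
training is single-threaded, so runs are bit-reproducible.

## Fine-tuning and evaluation

Datasets are partitioned by Bemis–Murcko scaffold (generic carbon-skeleton
variant behind a flag): scaffold groups sorted by descending size then
scaffold string are assigned whole to train until the train fraction
(default 0.8/0.1/0.1) is reached, then valid, then test.  A two-layer
perceptron head on h_G (molecule tasks) or h_u^K (atom tasks) is trained
end-to-end with the encoder; the checkpoint with the best validation
metric is kept (early stopping patience 10, up to 100 epochs); if a tiny
validation split is single-class, selection falls back to validation
loss.  Reported scores are mean ± sd over 4 repeats with distinct seeds.
Metrics: ROC-AUC (rank statistic; multi-task means skip single-class
columns), RMSE, MAE.

## Discrimination experiments

`perturb_conformer` adds independent uniform(0, noise_max) draws to every
coordinate — one-sided, exactly as specified, so it induces a net
translation that alignment later removes.  `kabsch_rmsd` superposes by
centroid removal plus the SVD-optimal *proper* rotation (reflections
excluded, so enantiomeric geometries keep a nonzero RMSD); under
uniform(0, 0.5) noise the expected aligned RMSD is
0.25·√(1 − 2/n) Å for an n-atom molecule (per-coordinate variance 1/48,
minus the 6 rigid degrees of freedom), ≈ 0.235 averaged over the
drug-like fixture set — this closed form is also why the aligned
convention is the right reading of the reference statistic.  The
Davies–Bouldin index is implemented from its definition (mean over
clusters of the worst (S_i + S_j)/M_ij) and cross-checked against
scikit-learn in tests; coincident centroids raise rather than return
infinity.  The experiment driver embeds original and perturbed conformers
under dihedral-aware and dihedral-ablated encoders and reports per-pair
embedding distances, the DB index over the two conformer groups, and the
mean aligned RMSD.  Enantiomer pairs for the chirality checks are built by
mirroring a conformer's coordinates, which guarantees identical internal
lengths/angles with all torsions negated; re-embedding the enumerated
isomeric SMILES independently does not (different rotamers may be found),
so it is used only in the isomer-enumeration experiments.

## Synthetic data

`fixtures` supplies ~290 curated SMILES: named drugs and natural products,
templated amide/sulfonamide/biphenyl/piperazine series typical of
screening libraries (the drug-like subset, ≥ 12 heavy atoms, has ≥ 200
members averaging ~17 heavy atoms), molecules with 1–4 stereocenters, and
degenerate graph cases (single atom, diatomics, a linear nitrile whose
collinear angle exercises the degeneracy flags).  Conformers come from
RDKit embedding + MMFF94 optimisation, lowest of n candidates, seeded.

Surrogate electronic labels emulate quantum-chemistry targets while
keeping the generating process known:

* charge(u) = κ·(EN(u) − mean EN of bonded neighbours) + ε, κ = −0.2,
  Pauling electronegativities, ε ~ N(0, 0.02), clipped to [−1, 1], then
  re-centred so charges sum to the molecule's formal charge;
* order(u,v) = nominal order − c·(l_uv − reference length for that order)
  + ε, c = 1.0 Å⁻¹, references 1.50/1.40/1.33/1.20 Å for orders
  1/1.5/2/3.

The charge signal is deliberately topological (so learning checks isolate
the model machinery from conformer noise); the bond-order signal depends
on the actual bond length on purpose, exercising the geometric input
path.  Toy property targets are a documented linear form
0.5·(heteroatoms) + 0.3·(rings) − 0.2·(rotatable bonds) + N(0, 0.1), with
the classification threshold 1.3 pinned at the builtin set's median score.
None of this emulates real electronic structure, conformer ensembles, or
the chemical-space breadth of public libraries — passing tests demonstrate
that the machinery learns recoverable signal under known conditions, not
chemical accuracy.

## Numerical choices

* Torsions use the atan2-of-cross-products convention, signed, folded to
  [−π, π); a collinear bonded triple has no defined torsion — the value is
  0 with a degeneracy flag, and flagged elements are excluded from SSL
  targets and have their RBF features zeroed.  Angles clamp the normalised
  dot product into [−1, 1] before arccos; collinearity within 1e-7 flags
  the angle.  Coincident bonded atoms (< 1e-6 Å) are an error.
* The torsion RBF measures *angular* distance to its centers.  With a
  linear grid, θ = π − ε and θ = −π + ε (the same physical geometry
  family) sit at opposite ends of the basis, and a near-planar molecule
  spuriously separates from its mirror image; the periodic basis removes
  the seam while staying 1 at each center and within (0, 1].
* Hydrogens are explicit only during conformer embedding; the graphs are
  heavy-atom with implicit-H counts as atom features.
* The networks run on a small reverse-mode autodiff core over NumPy
  arrays (`trigraph.nn`): tape-based, float64, single-threaded, with row
  gather and segment-sum as the two graph primitives.  Every primitive's
  gradient is tested against central finite differences.
* Checkpoints store a versioned JSON header (config + feature dimensions)
  beside the arrays and refuse to load on any dimension mismatch.

## Problem sizes used in the shipped tests

Learning checks run at 200 drug-like molecules: the geometry stage for 20
epochs, the electronic stage for 30, hidden width 32, K = 8, dropout 0 (a
deterministic training path keeps the checks reproducible); the
strategy-comparison check fine-tunes surrogate-charge regression on 50
labelled molecules over 4 seeds.  These sizes are the package's chosen
desk-scale study conditions; the molecule pool is shuffled before
train/held-out splitting so splits are not confounded with the fixture
list's template-family ordering.

## Known limitations

* Embedding distances under untrained (random) weights establish the
  geometric separation property, but their magnitudes are arbitrary; only
  signs/thresholds and relative comparisons are meaningful.
* One conformer per molecule; conformer-ensemble effects are out of scope
  beyond lowest-energy selection among n candidates.
* The surrogate labels are linear and local; they cannot reward models for
  capturing genuine exchange/correlation physics.
* Mean pooling makes h_G size-intensive; very large molecules dilute
  per-atom signals.
* The distance task's 0.5 Å bins are deliberately coarse (classification,
  not regression); they stabilise pretraining but carry no sub-bin
  information.
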