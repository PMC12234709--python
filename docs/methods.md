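# Methods

This note documents the models implemented in `vardyn`, the parameters and
their defaults, the role of the synthetic data, and known limitations. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Variant enumeration

A coding sequence (validated: length divisible by 3, alphabet ACGT) is
scanned over every position × 3 alternative nucleotides. Each substitution is
translated with the standard codon table (Biopython) and classified as
synonymous, missense, stop gain, stop loss, or start loss; these five
classes partition all substitutions. Missense enumeration deduplicates at the
protein level (one entry per unique `p.<ref><pos><alt>`) while retaining the
number of distinct nucleotide changes that produce it. Codon 1 changes of an
ATG start are start-loss, not missense, and are excluded by default
(`include_start_codon=False`). Coordinates are 1-based throughout.

## Trajectory descriptors

Input is a trajectory of T frames × N atoms in Ångström with a topology
carrying element, residue, and backbone-role assignments. Ten descriptors are
computed per frame and then summarized over a stable window:

- **Radius of gyration** — mass-weighted RMS distance from the centre of
  mass.
- **RMSD** — to a reference frame after optimal rigid superposition (Kabsch
  SVD with reflection correction), so global rotation/translation never
  contributes.
- **SASA** — Shrake–Rupley with a golden-spiral point grid (default 960
  points per atom, probe 1.4 Å, van der Waals radii per element); a surface
  point is buried only if strictly inside a neighbouring expanded sphere.
  The point grid is expressed in a molecule-fixed principal-axes frame so
  the point-sampled area is invariant to global orientation.
- **Inertia** — trace of the inertia tensor about the centre of mass
  (amu·Å²), a rotation-invariant size/shape scalar.
- **Stability surrogate** — a single-point energy: Lennard-Jones 12-6 with
  per-element parameters and Lorentz–Berthelot mixing, a distance-dependent
  dielectric Coulomb term `332·q_i·q_j/(4 r²)` kcal/mol, and a surface term
  `γ·SASA` with γ = 0.00542 kcal/(mol·Å²), over atom pairs at least two
  residues apart within 12 Å. This tracks relative conformational
  (de)stabilization along a trajectory; it is **not** an MM-GBSA free energy
  and its absolute value has no thermodynamic meaning.
- **Contacts** — residue pairs (sequence separation ≥ 3) whose closest
  heavy-atom distance is ≤ 5.0 Å.
- **Hydrogen bonds** — donor–acceptor ≤ 3.5 Å and donor–H···acceptor angle
  ≥ 120°; missing backbone amide hydrogens are rebuilt 1.01 Å from N opposite
  the bisector of its bonded heavy neighbours.
- **Helix/sheet/coil fractions** — a three-state DSSP-style assignment from
  backbone H-bonds scored with the electrostatic energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol (bond if
  E < −0.5), n-turns (n = 3, 4, 5) giving helix and parallel/antiparallel
  bridges giving sheet; the three fractions sum to 1 by construction.

**Stable window.** Descriptor time series are summarized over the latest
window of length `max(5, ⌊0.25·T⌋)` in which at least 70 % of the features
have a windowed standard deviation ≤ 0.75 × their full-series value; if no
window qualifies, the last half of the trajectory is used (with a warning for
T < 10). This avoids averaging over the initial relaxation.

## Labeling

Evidence per variant: a ClinVar-style assertion (B/LB/VUS/LP/P/conflicting/
absent), a population homozygote count with allele frequency, a
disease-mutation–database flag, and a clinical-panel call. Under the
recessive early-onset disease model (the only one implemented), the decision
rule is, in order of precedence:

1. A variant observed in ≥ 1 healthy adult homozygote with allele frequency
   ≥ 1e-4 cannot cause a severe recessive early-onset disease. If damaging
   evidence coexists with such an observation, the variant is **ambiguous**;
   otherwise it is **benign** (this is how a VUS with homozygotes is rescued).
2. Damaging evidence (ClinVar P/LP, disease-mutation flag, or panel) together
   with benign evidence → **ambiguous**.
3. Damaging evidence alone → **damaging**; benign evidence alone →
   **benign**; a conflicting ClinVar assertion → **ambiguous**.
4. No evidence → **unknown**.

Labels are encoded benign = 0, damaging = 1, unknown = 2, ambiguous = 3, and
every assignment records which rule fired (provenance).

## Balancing and class weights

SMOTE is implemented from its definition: each synthetic minority sample is
`x_i + u·(x_nn − x_i)` with `u ~ U(0,1)` and `x_nn` one of the k = 5 nearest
same-class neighbours (k capped at class size − 1; nearest-neighbour search
via scikit-learn). Every synthetic point therefore lies on a segment between
two same-class originals — a property the tests verify directly. Plain
oversampling/downsampling and inverse-frequency class weights
`n_total/(n_classes·n_c)` are provided as alternatives.

## Models and evaluation

Eight presets: random forest (100 trees, depth 7), a 64-64-64 feed-forward
network (Adam), semi-supervised label spreading (RBF kernel, α = 0.2,
γ = 20), decision tree (depth 5, min split 20), gradient boosting (learning
rate 0.05, 200 stages, depth 4), RBF SVM (γ = 20, C = 1), 4-NN, and logistic
regression. Label spreading additionally consumes the unknown-class rows as
an unlabeled block (labels masked to −1).

Evaluation machinery implemented from definitions:

- stratified k-folds (per-class round-robin; per-fold class counts within ±1
  of proportional) and a stratified 80:20 split (test size `ceil(0.2·n)`,
  largest-remainder per-class quotas, default seed 42);
- one-vs-rest ROC by threshold sweep with tied scores grouped into single
  steps, AUC by trapezoid;
- confusion matrix, accuracy, per-class precision/recall/F1, macro-F1, and
  micro-F1 (identically equal to accuracy for single-label multiclass — kept
  as an internal consistency check);
- Gini feature importance of the depth-limited decision tree, averaged over
  stratified folds and renormalized to sum to 1;
- pooled out-of-fold scoring (`cross_validated_scores`) so every row is
  scored exactly once by a model that never saw it.

The benchmark suite supports two protocols: **leakage_safe** (default —
split first, SMOTE only inside the training portion) and **paper_compat**
(balance the full labeled set, then split; kept for comparability with
workflows that balance before splitting, at the cost of synthetic points in
the test set leaking minority structure).

## Synthetic data

The generators emulate the *statistical shape* of a single-gene cohort
study, not its biology:

- **Coding sequences** — random ATG…stop sequences with non-stop internal
  codons; used to exercise enumeration against a brute-force oracle.
- **Trajectories** — an ideal poly-alanine α-helix (φ = −57°, ψ = −47°,
  standard bond geometry, backbone + CB + amide H built by internal
  coordinates) perturbed per frame by a progressive hinge bend (*drift*,
  raising superposed RMSD monotonically), a radial breathing mode
  (*breathing*, modulating Rg), and Gaussian positional noise (*disorder*,
  degrading the helical H-bond pattern), plus a random global rigid motion
  every frame so descriptors are always exercised against non-trivial
  rotation/translation.
- **Feature tables** — class-conditional Gaussians over the ten descriptors
  with benign dispersion < damaging < ambiguous and an rmsd-dominant damaging
  mean shift; `effect_scale` scales both the shifts and the dispersion
  departures, so 0 gives fully exchangeable classes (a null design under
  which every AUC must sit near 0.5). Default class sizes are 54/97/6/1297.
- **Evidence tables** — planted triggers for every labeling rule with known
  expected labels, and a cohort-composition table (2 ClinVar benign + 11
  homozygote-rescued + 41 panel-benign; 60 ClinVar P/LP + 37 other damaging;
  6 ambiguous; 1297 without evidence).

What the synthetic data does **not** emulate: real force-field dynamics,
solvent, side-chain packing, any sequence-to-structure mapping (feature
tables are not derived from the synthetic trajectories), or the empirical
evidence distribution of any particular gene.

## Numerical choices

- All stochastic steps take explicit integer seeds (NumPy `default_rng`);
  derived seeds stay below 2³¹.
- Angströms, kcal/mol, amu throughout; PDB I/O (biotite) converts to the
  file's conventions.
- SASA points default to 960 — at that density the point-sampled sphere area
  is within ~0.1 % of analytic; the molecule-fixed grid frame removes the
  residual orientation dependence.
- The contact cutoff is 5.0 Å on closest heavy-atom distance — a standard
  residue-contact definition; sub-Ångström cutoffs would count only clashes.
- `np.trapezoid` integrates ROC curves; tied score groups prevent
  order-dependent staircase artifacts.

## Limitations

- The stability surrogate is a screened single-point energy, suitable for
  relative comparisons along a trajectory only.
- The secondary-structure assignment is a three-state reduction of the
  H-bond-pattern method; 3₁₀/π helices merge into helix, and bends/turns into
  coil.
- Only the recessive early-onset disease model is implemented; dominant
  or late-onset genes need different homozygote logic.
- SMOTE interpolates linearly in descriptor space and cannot generate truly
  novel minority structure; the ambiguous class (n = 6) is particularly
  extrapolation-limited, and `paper_compat` evaluation optimistically leaks
  its synthetic neighbours into the test set.
- Classifier hyperparameters are fixed presets, not tuned per dataset.
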