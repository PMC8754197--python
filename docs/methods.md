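# Methods

This note documents the models, algorithmic choices, parameters and
limitations of `savpred`, in the order data flows through the pipeline.

## Variation number

**Model.** Conservation of a reference position is quantified as the
minimal number of substitutions (small-parsimony score) of its alignment
column on a tree over the protein's orthologs, then min–max scaled to
[0, 1] within the protein. The realization is fixed as: p-distance →
neighbor joining → per-column Fitch count. Parsimony change-counting on an
ortholog tree is the canonical reading of a "number of variations" per
position, and per-protein min–max scaling makes profiles comparable across
proteins with different ortholog depths.

**p-distance.** For a pair of rows, mismatches over columns where neither
row carries a gap (`-`) or unknown (`X`); a pair with no comparable column
gets distance 1 (maximal ignorance). Entries lie in [0, 1]; no
multiple-hit correction is applied — NJ only needs a roughly additive
dissimilarity, and tests show topology recovery on additive inputs.

**Neighbor joining.** Standard Saitou–Nei agglomeration. Determinism is
pinned down: ties in the Q criterion resolve to the lowest (i, j) index
pair (row-major argmin); negative branch-length estimates are clamped to
zero; two taxa yield a single edge with the distance split evenly. The
output is always an unrooted binary tree.

**Fitch counts.** The unrooted tree is rooted at the lexicographically
smallest leaf, making every internal node binary, and the classic
intersect/union sweep runs bottom-up; the score is root-invariant (checked
against exhaustive enumeration over internal labelings on random trees).
Gap is an ordinary 21st character state, so deletions in orthologs count
as events. True polytomies are rejected rather than silently mis-scored:
the sequential intersect/union rule is not exact on them, and NJ never
produces them.

**Coordinates.** Columns where the reference row has a gap are skipped, so
profile positions index the ungapped reference sequence, 1-based, matching
SAV notation (R15K). Degenerate profiles (all counts equal) scale to all
zeros — an uninformative protein reads as maximally conserved rather than
injecting noise. No ortholog-quality filtering is applied before tree
building; the evaluation protocol instead checks that accuracy is stable
when training is restricted by ortholog count.

## Anisotropic network model features

Cα atoms within a cutoff r_c are connected by springs of constant γ. The
3N×3N Hessian has off-diagonal superblocks −γ r̂ᵢⱼ r̂ᵢⱼᵀ and diagonal
superblocks equal to minus the row sums. Defaults r_c = 15 Å, γ = 1,
zero-mode tolerance λ < 1e-8·λ_max — standard elastic-network practice;
results feed a tree-based classifier, which is monotone-invariant, so the
overall scale (including the absent kT factor: MSD is reported in 1/γ
units) is immaterial.

- **MSD**: trace of the residue's 3×3 diagonal superblock of the Hessian
  pseudo-inverse, computed mode-wise with zero modes excluded.
- **Stiffness**: κᵢⱼ = [Σₖ λₖ⁻¹((u_{k,j}−u_{k,i})·r̂ᵢⱼ)²]⁻¹, i.e. the
  inverse mean-square fluctuation of the i–j distance; a residue's value is
  the mean of κ over **all** partners, not only those within the cutoff.
  For a two-bead dimer this gives κ = γ (the single-spring stat-mech value
  ⟨Δd²⟩ = kT/γ), which the dense-covariance oracle confirms.
- **PRS effectiveness/sensitivity**: response of residue j to a unit
  perturbation at i is the squared Frobenius norm of the (i, j) covariance
  superblock; rows are normalized by their diagonal and self-terms are
  excluded from the row (effectiveness) and column (sensitivity) means.

A connected, non-collinear structure has exactly six zero modes. A
collinear N-bead chain has 2N+1 (transverse displacements cost no energy
in the pairwise-projection form), which equals the familiar five
rigid-body-like modes only at N = 2; the degenerate-network warning
(more than six zero modes) therefore fires for collinear chains as well as
for genuinely disconnected ones, which is intended — both invalidate the
usual rigid-body accounting.

## Solvent accessibility and the remaining structure features

SASA uses Shrake–Rupley with a golden-spiral point lattice: per atom,
points on the sphere of radius r_atom + r_probe are tested against all
neighbours' inflated spheres; the accessible fraction times the inflated
area is the atom's SASA and residues sum their atoms. Defaults: probe
1.4 Å (water), 960 points (isolated-sphere error is at quadrature noise
level; occlusion error is a fraction of a percent). Element radii: C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, Se 1.90 Å, overridable. Bare
Cα traces (the synthetic fixtures) use a single coarse bead radius,
default 1.9 Å.

Active-site probabilities binarize at a strict > 0.5. Unfolded-state
reference energies come from a 20-entry table shipped as
`data/reference_energies_synthetic.tsv` — a synthetic stand-in with a
plausible spread, since these constants are tool-internal; users supply
their own table for production use. The remaining tool-derived features
(ΔΔG_fold, PSIC scores, ΔE, FIS, mutant SSF) are ingested from TSV, with
unparseable cells treated as missing (counted and logged) and duplicate
SAV keys rejected.

## Feature table, labels and validation statistics

Labels: the three benign clinical-significance categories map to 0, the
three pathogenic ones to 1 (case-insensitive); rows with fewer than one
review star are dropped, as are unrecognized significance strings (with a
logged count). Assembly records absent provider values as NaN — never
silently zero — and collects per-row problems (e.g. a variant position
beyond the protein length) into a report instead of aborting.

Imputation fills missing cells with the per-feature **median of training
rows only**; the median is robust to the heavy-tailed energy features, and
restricting to training rows keeps test information out of the fill values.
Cross-validation refits the medians inside every fold.

Welch's unequal-variance t-test is used for the two-class comparison of
variation numbers (the two classes have visibly unequal variances, 0.017
vs 0.04 under the default generator); the sign convention is pathogenic
minus neutral, so stronger conservation of pathogenic variants yields
t < 0. Features are z-scored before PCA; tree-based classification uses
raw features.

## Classifier and evaluation protocol

XGBoost binary classifier, learning rate 0.1, defaults n_estimators = 200,
max_depth = 6, single-threaded histogram trees for determinism; remaining
hyperparameters are exposed in `TrainParams`. Class calls use a strict
probability > 0.5. Ten-fold cross-validation is stratified (the label
balance of real variant sets is uneven; stratification stabilizes per-fold
metrics) with deterministic fold assignment per seed. The five confusion
statistics are evaluated exactly as written; any zero-denominator metric
reports 0 with an explicit flag so ablation tables have no holes. AUROC is
the trapezoid over the tie-grouped ROC (equal to the pair-ordering
statistic with half-credit ties, which the tests verify exhaustively);
AUPR is the step-interpolated average precision.

Ablation retrains with each feature left out on the same folds and sorts
by accuracy drop. Ortholog-count stratification shares one fold split and
restricts only the training rows of each fold to proteins at or above the
threshold, evaluating on full test folds. The DMS benchmark reports the
absolute Spearman correlation (average-rank ties) between predictions and
fitness scores over shared variants, the MSE, and the coverage fraction;
constant inputs leave the correlation undefined and are reported as 0 with
a flag.

## Synthetic study conditions

The generator's defaults are the study conditions the tests and the
acceptance script run under:

- variation numbers per class are beta draws moment-matched to pathogenic
  mean 0.12 / variance 0.017 and neutral mean 0.32 / variance 0.04;
- three tool-derived features are planted as informative, with pathogenic
  class shifts of 1.2 (ΔPSIC), 0.8 (FIS) and 0.6 (wild-type PSIC) feature
  standard deviations; all other features are class-independent unit
  normals (the binary active-site flag is Bernoulli(0.2) in both classes
  unless shifted);
- missingness is planted uniformly at random in the seven tool-derived
  columns only — the natively computed features cannot be missing for a
  structure that parsed;
- ortholog families evolve along a random binary join tree with a
  per-site, per-branch substitution probability of 0.05 and a designated
  conserved fraction of 0.3 that never mutates; the generator returns the
  realized per-site event counts and the true tree, since parsimony
  lower-bounds the event count only on the generating tree;
- structures are ideal α-helices (rise 1.5 Å, 100° turn, radius 2.3 Å),
  straight 3.8 Å chains, or 3.8 Å-step random coils.

Problem sizes used by the test suite and acceptance script: 2000 SAVs per
class for the cross-validation conditions, 1000 per class for the
permutation null, the empirical class sizes (10 564 / 9 743) for the
variation-number t-statistic, 500 random trees for the parsimony oracle,
and structures of at most a few dozen residues for the dense-oracle
dynamics checks.

**What passing on synthetic data does and does not show.** The generator
reproduces the class-conditional marginals and missingness pattern the
pipeline assumes, so tests demonstrate that the machinery — tree building,
parsimony, spectral dynamics, quadrature, imputation, cross-validation —
is correct and that the classifier recovers planted signal at the stated
effect sizes. It does not emulate feature correlations found in real
variant data, rate heterogeneity or indel processes in ortholog evolution,
real side-chain packing (fixtures are Cα beads), or curation biases of
clinical databases; absolute metric values on real data will differ.

## Known limitations

- The elastic-network model is harmonic: anharmonic motions and
  multi-state transitions are outside its scope by construction.
- Per-position (not per-mutant) variation numbers; nucleotide-level
  effects and splice-region variants are invisible.
- The alignment is an input; alignment errors propagate into the
  conservation feature.
- Tool-derived features are ingested, not recomputed; their quality bounds
  the classifier's ceiling on real data.
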