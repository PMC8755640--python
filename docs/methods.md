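# Methods

## Block decomposition and conventions

A labeled ROI is a square float image rescaled to [0, 1] at load time
(independent of on-disk bit depth, so the residual tolerance ε is comparable
across sources).  Decomposition into m×n blocks requires exact divisibility —
no implicit padding — and uses one fixed convention, single-sourced in
`block_model`: blocks traverse the grid row-major, pixels within a block are
vectorized column-major.  `reassemble` is the exact inverse; the round trip is
bit-identical (tested over all side ∈ {32, 64, 128} × block ∈ {4, 8, 16, 32}).

ROI extraction supports the two selection policies used with annotated
mammography data: a *minimum-size* rule (masses whose bounding square
2·radius is below the minimum ROI side are rejected; qualifying masses are
center-cropped at that fixed side, so blocks mostly cover mass interior) and
a *resample* rule (the full bounding square, including background, bilinearly
resampled to a fixed side).  Crops that overrun the image border are
mirror-padded: reflection preserves local texture statistics better than zero
fill, which would inject an artificial step edge.  Labels are encoded
benign = −1, malignant = +1 so sign-based decisions map directly onto class
labels; malignant is the positive class in all metrics.

## Sparse coding

All coding uses orthogonal matching pursuit with a dual stopping rule: stop
at |support| = T or at residual norm ≤ ε.  ε is an absolute threshold applied
after the test block has been unit-normalized (atoms are always unit-norm);
zero-norm blocks get an all-zero code and neutral scores.  Equal-correlation
ties select the lowest atom index; the least-squares refit uses a
rank-tolerant (minimum-norm) solver so exactly collinear selected atoms stay
deterministic.  A brute-force oracle (all supports of size ≤ T, bounded to
n ≤ 12, T ≤ 2) backs the tests: greedy T = 1 must equal the oracle exactly,
and the oracle's T = 2 residual can never exceed the greedy one.  An external
OMP implementation (scikit-learn's `orthogonal_mp`) is used in the test suite
as an independent cross-check of supports and coefficients, never in the
pipeline.

## Dictionary learning

KSVD alternates batch OMP coding with atom-by-atom updates: for atom k, the
residual excluding atom k's contribution, restricted to the samples using it,
is given to an SVD; the atom becomes the leading left singular vector (sign
fixed so its largest-magnitude entry is positive, for run-to-run
reproducibility) and the coefficients σ₁ times the leading right singular
vector.  That update is the Frobenius-optimal rank-1 replacement, so a sweep
with fixed supports never increases ‖Y − DX‖_F (asserted in the tests).
Unused and near-duplicate atoms (|⟨dᵢ, dⱼ⟩| > 1 − 1e−6) are replaced by the
currently worst-represented training samples in a separate step after each
sweep.  Initialization draws distinct nonzero training columns (seeded RNG,
kept in original column order, so a full-budget, zero-iteration dictionary is
exactly the normalized raw-sample dictionary).

Label-separated (LS) mode runs KSVD per class and concatenates benign atoms
first.  The atom budget is split equally between classes; an odd total gives
the extra atom to the benign class.  Label-consistent (LC) mode optimizes the
LC-KSVD2 objective by the standard stacked reduction: KSVD on
[Y; √α·Q; √β·H] with the augmented dictionary [D; √α·A; √β·W].  D is
initialized by a few (5) per-class KSVD iterations; A and W by ridge
regression of Q and H on the initial codes (λ = 1e−4).  After learning, each
augmented column is split and the D-part normalized to a unit atom, with the
corresponding columns of A and W divided by the same norm — the scaling that
keeps W directly applicable to codes computed over D.  α weights the
discriminative-code term and β the classification term, matching the tuning
grid pairing larger α with smaller β.  With α = β = 0 the procedure reduces
exactly to the KSVD core run on Y from the LC initialization.  The full
objective at the final (D, A, W, X) is asserted never to exceed its value at
initialization; per-iteration monotonicity is *not* asserted, because
re-coding between sweeps can transiently raise the objective.

Default iteration count is 50 (used by the planted-dictionary recovery
protocol).  The end-to-end cross-validation experiments use 10 iterations
with 60 atoms (30 per class): on the synthetic study set the learned
dictionaries converge well within that budget, and it keeps a full
three-mode, 10-fold run comfortably fast on one core.

## Ensemble decisions

Per-block scores are signed log-likelihoods with positive = malignant:

* sparsity (−S): log ‖δ_mal(x̂)‖₁ − log ‖δ_ben(x̂)‖₁ — the class whose atoms
  carry more coefficient mass wins;
* residual (−R): −(log ‖D δ_mal(x̂) − y‖₂ − log ‖D δ_ben(x̂) − y‖₂) — the
  class whose atoms reconstruct the block better wins.

Masses and residuals are floored at κ = 1e−12 before the logs, which keeps
degenerate blocks finite without materially affecting ranking; scores are
computed as differences of logs so class-swap antisymmetry is bit-exact.
BBLL averages the NB block scores (with a correctly rounded sum, making the
mean exactly permutation-invariant) and squashes the shifted mean through
tanh — the canonical sigmoid onto [−1, 1].  The shift τ defaults to 0 and can
optionally be calibrated on the training fold only, by maximizing balanced
accuracy over a 101-point grid of training-ELL quantiles.  BBMAP takes a
majority vote of per-block hard labels; its posterior is the empirical vote
fraction, a tie falls back to the sign of the summed block scores, and an
exact zero maps to benign — the conservative choice with respect to false
positives, applied consistently wherever a decision boundary is hit.  With
one block (block size = ROI size) the whole pipeline reduces exactly to
conventional single-dictionary sparse representation classification.

## Synthetic data

Each generated ROI is a mid-gray background (0.35) plus a centered soft-edged
disc (cosine rolloff over the outer 20 % of the disc radius, default contrast
0.3, radius 0.6·side/2) modulated by an oriented sinusoid (amplitude 0.18,
random phase per ROI) and i.i.d. Gaussian intensity noise, clipped to [0, 1].
The two classes share every default except texture frequency — 4 vs 14
cycles per ROI side — so class separation is controlled along a single,
analytically transparent axis, and the texture is block-stationary, matching
the block-dictionary assumption.  The reference study conditions are 36
benign + 37 malignant 64×64 ROIs at noise σ = 0.05.

What this emulates — and does not: the generator reproduces the *structure*
of the classification problem (two texture classes of square ROIs with a
central mass and noise), not mammographic appearance.  Real masses differ in
shape, margin, and background tissue, and their class difference is far
subtler than a frequency gap.  Passing the end-to-end tests therefore
demonstrates that the pipeline is correctly assembled and can exploit
class-conditional texture; it does not predict clinical performance.  The
perfect scores on the default conditions reflect the deliberately large
frequency gap — the monotonicity test shows accuracy falling toward chance as
the gap shrinks.

## Evaluation

Folds are stratified, seeded, and deterministic (per-fold class counts within
one of proportionality).  Dictionaries and τ are learned strictly inside each
training fold; every trained model records the source ids of its training
ROIs and classification of a test ROI whose id appears there is rejected — a
hard audit against leakage.  AUC is the trapezoidal area under the ROC of the
continuous score, which equals the Mann–Whitney concordance with ties counted
½ (asserted to 1e−12 against a brute-force pair count).  DeLong's paired AUC
comparison uses placement values and a two-sided normal approximation;
degenerate variance returns p = 1 with a warning.  Grid search evaluates the
full Cartesian grid with nested per-fold training and selects by AUC with ACC
as tie-break; defaults are ε ∈ {0.001, 0.01, 0.1, 0.5}, T ∈ {1, 5, 10, 30,
60}, 60 atoms (small sets; {300, 500} for large ones), and (α, β) ∈
{(4e−4, 2e−4), (4e−3, 2e−3), (0.04, 0.02), (0.4, 0.2)}.  Hyperparameters are
selected once per search on pooled cross-validated metrics, not per fold.

## Problem sizes and numerical choices

The cross-validation experiments in the tests and the acceptance script use
the 73-ROI study set with 8×8 blocks (64 block dictionaries per fold), T = 5,
ε = 0.01, and 10 folds; KSVD recovery uses the 16×32/600-sample protocol at
50 iterations over three seeds.  Model persistence is a single `.npz` archive
(float64 arrays plus a JSON manifest) and reload is bit-exact.  All RNG flows
through `numpy.random.Generator` seeded from explicit integers; per-block and
per-class streams are spawned via `SeedSequence` so results are independent
of execution order.

## Known limitations

No mass detection or segmentation (ROIs come from annotations); two classes
only; no basis-pursuit/LASSO coding path; no LC-KSVD1 variant; the synthetic
generator does not model scanner physics, spiculation, or tissue background;
τ calibration is a single scalar shift, not a full probability calibration.
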