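# slesa — spatially localized ensemble sparse analysis

`slesa` is a two-class classifier for square grayscale regions of interest
(ROIs), built for computer-aided diagnosis settings such as characterizing an
annotated mammographic mass as benign or malignant.  Instead of classifying
the whole ROI with one dictionary, it divides every ROI into a grid of small
blocks, learns a *separate labeled dictionary for each block position*, sparse
codes each test block with orthogonal matching pursuit (OMP), and fuses the
per-block evidence into a single decision.

## The model

Each training ROI *I* is split into *NB* blocks of *m×n* pixels,
*I = [B¹, …, B^NB]*.  For block position *j* the training matrix stacks that
block across all *s* training images, *Dʲ = [B₁ʲ, …, B_sʲ]*, and becomes a
dictionary in one of three ways:

* **slesa** — the normalized training blocks themselves are the atoms
  (no learning; blockwise sparse representation classification);
* **ls** (label-separated) — one KSVD dictionary per class,
  `argmin ‖Yⱼ − DⱼXⱼ‖² s.t. ‖x‖₀ ≤ T`, concatenated with per-atom labels;
* **lc** (label-consistent, the LC-KSVD2 objective) —
  `argmin ‖Y − DX‖² + α‖Q − AX‖² + β‖H − WX‖² s.t. ‖x‖₀ ≤ T`,
  where *Q* ties atoms to samples of the same class and *H* holds the one-hot
  labels; solved by KSVD on the row-augmented system
  `[Y; √α·Q; √β·H]` with dictionary `[D; √α·A; √β·W]`.

At test time each block *yʲ* is unit-normalized and coded by OMP with the dual
stop ‖support‖ = *T* or ‖yʲ − Dʲx‖₂ ≤ ε.  Per-block evidence is a signed
log-likelihood, from coefficient masses (suffix **-S**)
`LLS = log ‖δ_mal(x̂)‖₁ − log ‖δ_ben(x̂)‖₁` or from class-restricted residuals
(suffix **-R**) `LLR = −(log ‖D δ_mal(x̂) − y‖₂ − log ‖D δ_ben(x̂) − y‖₂)`,
where δ_c zeroes the coefficients of the other class and positive values
favor the malignant class.  Fusion is either a majority vote over per-block
hard labels (**BBMAP**, posterior = vote fraction) or the mean block
log-likelihood *ELL* passed through a shifted tanh (**BBLL**,
score = tanh(ELL − τ) ∈ [−1, 1]); the decision is the sign of the score, with
an exact zero mapped to benign.

A synthetic-data module generates two-class textured-mass ROIs (soft-edged
disc plus an oriented sinusoid with class-conditional frequency, plus Gaussian
noise), so the whole pipeline is testable without any clinical data.  The
evaluation module provides stratified k-fold cross-validation, TPR/TNR/ACC,
trapezoidal ROC AUC, DeLong's paired AUC test, and grid search over
(ε, T, dictionary size, α, β).

## Worked example

```python
from slesa import (BENIGN, MALIGNANT, SyntheticConfig,
                   cross_validate, generate_dataset)

cfg = SyntheticConfig(side_px=64, noise_sigma=0.05,
                      n_per_class={BENIGN: 36, MALIGNANT: 37}, seed=1)
rois = generate_dataset(cfg)                       # 73 labeled 64x64 ROIs
result = cross_validate(rois, mode="slesa", block_shape=(8, 8),
                        T=5, eps=0.01, k=10, seed=1,
                        rules=("bbll-s", "bbmap-s"))
for rule, rep in result.reports.items():
    print(f"{rule}: TPR {rep.tpr:.3f}  TNR {rep.tnr:.3f}  "
          f"ACC {rep.acc:.3f}  AUC {rep.auc:.3f}")
```

```
bbll-s: TPR 1.000  TNR 1.000  ACC 1.000  AUC 1.000
bbmap-s: TPR 1.000  TNR 1.000  ACC 1.000  AUC 1.000
```

The two synthetic classes differ only in texture frequency (4 vs 14
cycles/ROI); at noise σ = 0.05 that separation is easy, so every held-out ROI
is ranked and labeled correctly — TPR/TNR/ACC/AUC of 1.000 mean zero
cross-validated errors, and the BBLL scores saturate near ±1.  Shrinking the
frequency gap degrades the metrics toward chance (see
`tests/test_synthetic_data.py`).

The same pipeline is scriptable from the shell:

```sh
slesa simulate --roi-size 64 --n-benign 36 --n-malignant 37 --seed 1 --out data/
slesa crossval data/annotations.csv --mode lc --block-size 8 \
      --policy resample --roi-size 64 --folds 10 --rule bbll-s --out runs/lc
```

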