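"""Cross-validated evaluation: stratified folds, TPR/TNR/ACC/AUC metrics,
DeLong's paired AUC comparison, and hyperparameter grid search.

Malignant is the positive class throughout.  AUC is the area under the
trapezoidal ROC of the continuous decision score (BBLL: tanh-squashed shifted
mean log-likelihood; BBMAP: signed vote margin), which equals the
Mann-Whitney concordance with ties counted 1/2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .block_model import BENIGN, MALIGNANT, LabeledROI
from .dictionary_learning import LCConfig
from .ensemble import RULES, ell, fuse, score_blocks
from .model import SlesaModel, train_model

#: Hyperparameter grids used in the reference experiments.
DEFAULT_GRIDS: dict[str, list] = {
    "eps": [0.001, 0.01, 0.1, 0.5],
    "T": [1, 5, 10, 30, 60],
    "n_atoms_total": [60],  # {300, 500} for large datasets
    "alpha_beta": [(4e-4, 2e-4), (4e-3, 2e-3), (0.04, 0.02), (0.4, 0.2)],
}


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment: one fold index per ROI."""

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class MetricReport:
    tpr: float
    tnr: float
    acc: float
    auc: float
    roc: np.ndarray  # (n_points, 2) columns (fpr, tpr)
    counts: dict[str, int] = field(default_factory=dict)
    per_fold: pd.DataFrame | None = None


def make_folds(labels: Sequence[int], k: int, seed: int, allow_small: bool = False) -> FoldPlan:
    """Seeded stratified k-fold plan over the ROI labels."""
    labels = np.asarray(list(labels), dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    class_min = min(np.sum(labels == c) for c in np.unique(labels))
    if k > class_min and not allow_small:
        raise ValueError(f"k={k} exceeds the smallest class count {class_min}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def compute_metrics(
    true_labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.0,
    pred_labels: Sequence[int] | None = None,
) -> MetricReport:
    """Confusion metrics at the operating point plus trapezoidal ROC AUC.

    Predictions default to ``score > threshold`` => malignant (an exact-zero
    margin is benign); pass ``pred_labels`` to use the classifier's own hard
    decisions instead.
    """
    y = np.asarray(list(true_labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present")
    if pred_labels is None:
        pred = np.where(s > threshold, MALIGNANT, BENIGN)
    else:
        pred = np.asarray(list(pred_labels), dtype=int)
    tp = int(np.sum((pred == MALIGNANT) & (y == MALIGNANT)))
    tn = int(np.sum((pred == BENIGN) & (y == BENIGN)))
    fp = int(np.sum((pred == MALIGNANT) & (y == BENIGN)))
    fn = int(np.sum((pred == BENIGN) & (y == MALIGNANT)))
    from sklearn.metrics import roc_curve

    fpr, tpr_curve, _ = roc_curve(y, s, pos_label=MALIGNANT)
    auc = float(np.trapezoid(tpr_curve, fpr))
    return MetricReport(
        tpr=tp / (tp + fn),
        tnr=tn / (tn + fp),
        acc=(tp + tn) / len(y),
        auc=auc,
        roc=np.column_stack([fpr, tpr_curve]),
        counts={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    true_labels: Sequence[int],
) -> tuple[float, float, float]:
    """DeLong's paired comparison of two correlated AUCs.

    Uses the placement-value covariance estimator and a two-sided normal
    approximation on the AUC difference.  Returns ``(auc_a, auc_b, p)``;
    degenerate variance gives p = 1 with a warning.
    """
    y = np.asarray(list(true_labels), dtype=int)
    A = np.asarray(list(scores_a), dtype=float)
    B = np.asarray(list(scores_b), dtype=float)
    if not (A.shape == B.shape == y.shape):
        raise ValueError("scores and labels must be paired on identical samples")
    pos, neg = y == MALIGNANT, y == BENIGN
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")

    def placements(s):
        x, z = s[pos], s[neg]
        # psi(x_i, y_j): 1 if x > y, 1/2 if tied
        cmp = (x[:, None] > z[None, :]).astype(float) + 0.5 * (x[:, None] == z[None, :])
        return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0), cmp.mean()

    v10_a, v01_a, auc_a = placements(A)
    v10_b, v01_b, auc_b = placements(B)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if not np.allclose(A, B):
            warnings.warn("degenerate DeLong variance; returning p = 1")
        return float(auc_a), float(auc_b), 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


@dataclass
class CVResult:
    """Pooled held-out predictions and per-rule metric reports."""

    plan: FoldPlan
    table: pd.DataFrame  # one row per ROI: source_id, fold, label, per-rule score/pred
    reports: dict[str, MetricReport]
    models: list[SlesaModel] | None = None


def cross_validate(
    rois: Sequence[LabeledROI],
    mode: str = "slesa",
    block_shape: tuple[int, int] = (8, 8),
    cfg: LCConfig | None = None,
    T: int = 5,
    eps: float = 0.01,
    k: int = 10,
    seed: int = 0,
    rules: Sequence[str] = ("bbll-s",),
    calibrate: bool = False,
    keep_models: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Dictionaries (and tau, when calibration is on) are learned strictly on the
    training folds; an audit assertion rejects any model whose training
    provenance contains a test ROI.  Held-out scores are pooled over folds.
    """
    rules = [r.lower() for r in rules]
    for r in rules:
        if r not in RULES:
            raise ValueError(f"unknown rule {r!r}")
    labels = [r.label for r in rois]
    plan = make_folds(labels, k, seed)
    rows = []
    models = []
    for fold in range(k):
        train = [rois[i] for i in plan.train_indices(fold)]
        test_idx = plan.test_indices(fold)
        model = train_model(
            train, mode=mode, block_shape=block_shape, cfg=cfg, T=T, eps=eps,
            calibrate=calibrate,
        )
        if keep_models:
            models.append(model)
        train_ids = set(model.train_source_ids)
        for i in test_idx:
            roi = rois[i]
            if roi.source_id in train_ids:  # leak audit
                raise AssertionError(f"test ROI {roi.source_id} leaked into training")
            scores = score_blocks(roi, model.dictionaries, model.block_shape, model.T, model.eps)
            row = {"source_id": roi.source_id, "fold": fold, "label": roi.label}
            for rule in rules:
                decision = fuse(scores, rule, tau=model.tau_for(rule))
                row[f"score_{rule}"] = decision.score
                row[f"pred_{rule}"] = decision.label
            rows.append(row)
    table = pd.DataFrame(rows)
    reports = {
        rule: compute_metrics(
            table["label"], table[f"score_{rule}"], pred_labels=table[f"pred_{rule}"]
        )
        for rule in rules
    }
    return CVResult(plan=plan, table=table, reports=reports, models=models or None)


def grid_search(
    rois: Sequence[LabeledROI],
    mode: str = "slesa",
    grids: Mapping[str, Sequence] | None = None,
    k: int = 10,
    seed: int = 0,
    rule: str = "bbll-s",
    block_shape: tuple[int, int] = (8, 8),
    n_iter: int = 10,
    calibrate: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search by cross-validated AUC (ACC tie-break).

    The grid keys are ``eps``, ``T``, ``n_atoms_total`` and ``alpha_beta``;
    keys irrelevant to the mode are collapsed to a single point.  Returns the
    winning configuration and the full results table.
    """
    grid = dict(DEFAULT_GRIDS)
    if grids:
        grid.update({key: list(v) for key, v in grids.items()})
    for key in grid:
        if not grid[key]:
            raise ValueError(f"empty grid for {key!r}")
    if mode == "slesa":
        grid["n_atoms_total"] = [None]
        grid["alpha_beta"] = [(0.0, 0.0)]
    elif mode == "ls":
        grid["alpha_beta"] = [(0.0, 0.0)]

    rows = []
    best = None
    for eps, T, atoms, (alpha, beta) in itertools.product(
        grid["eps"], grid["T"], grid["n_atoms_total"], grid["alpha_beta"]
    ):
        cfg = None
        if atoms is not None:
            cfg = LCConfig.from_total_atoms(
                atoms, T=T, alpha=alpha, beta=beta, n_iter=n_iter, seed=seed
            )
        result = cross_validate(
            rois, mode=mode, block_shape=block_shape, cfg=cfg, T=T, eps=eps,
            k=k, seed=seed, rules=(rule,), calibrate=calibrate,
        )
        rep = result.reports[rule]
        row = {
            "mode": mode, "rule": rule, "eps": eps, "T": T,
            "n_atoms_total": atoms, "alpha": alpha, "beta": beta,
            "tpr": rep.tpr, "tnr": rep.tnr, "acc": rep.acc, "auc": rep.auc,
        }
        rows.append(row)
        key = (rep.auc, rep.acc)
        if best is None or key > best[0]:
            best = (key, row)
    return best[1], pd.DataFrame(rows)
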