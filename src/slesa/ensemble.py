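"""Block-ensemble decision functions.

Each block of a test ROI is sparse-coded over its position's dictionary and
scored by a signed log-likelihood, either from the per-class l1 coefficient
masses (sparsity score, LLS) or from the per-class reconstruction residuals
(residual score, LLR).  A positive block score is evidence for the malignant
class.  The NB block scores are fused either by majority vote over the
per-block hard labels (BBMAP) or by averaging the scores into an expected
log-likelihood that is shifted by a bias term tau and squashed by tanh into a
[-1, 1] classification score (BBLL).  Suffix -S/-R names the block score used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .block_model import BENIGN, MALIGNANT, decompose
from .sparse_coding import BlockDictionary, SparseCode, omp

#: Floor applied to l1 masses and residuals before the log ratio.
KAPPA = 1e-12

RULES = ("bbmap-s", "bbmap-r", "bbll-s", "bbll-r")


@dataclass
class BlockScore:
    """Per-block evidence: signed sparsity and residual log-likelihoods."""

    block_index: int
    lls: float
    llr: float

    def hard_label(self, kind: str) -> int:
        s = self.lls if kind == "s" else self.llr
        return MALIGNANT if s > 0 else BENIGN  # exact zero is benign


@dataclass
class EnsembleDecision:
    """Fused ROI-level decision with its audit trail."""

    label: int
    score: float  # tanh(ell - tau) for BBLL; signed vote margin for BBMAP
    rule: str
    ell: float | None = None
    posterior: float | None = None  # malignant vote fraction (BBMAP)
    tau: float = 0.0
    block_scores: tuple[BlockScore, ...] = ()


def _log_ratio(num: float, den: float) -> float:
    # difference of logs (not log of the ratio) so that swapping the class
    # roles negates the score bit-exactly
    return math.log(max(num, KAPPA)) - math.log(max(den, KAPPA))


def lls_score(code: SparseCode, class_m: int = MALIGNANT, class_n: int = BENIGN) -> float:
    """Signed sparsity log-likelihood of one block.

    Positive means the class-m atoms carry the larger l1 coefficient mass,
    i.e. the block is evidence for class m; negative favors class n.  Both
    masses are floored at kappa so the score stays finite, and an all-zero
    code scores exactly 0.
    """
    if class_m not in code.per_class_l1 or class_n not in code.per_class_l1:
        raise ValueError("code lacks per-class l1 masses for the requested classes")
    return _log_ratio(code.per_class_l1[class_m], code.per_class_l1[class_n])


def llr_score(code: SparseCode, class_m: int = MALIGNANT, class_n: int = BENIGN) -> float:
    """Signed residual log-likelihood: -log(resid_m / resid_n), floored at kappa.

    Positive when the class-m atoms reconstruct the block with the smaller
    residual, i.e. evidence for class m.
    """
    if class_m not in code.per_class_residual or class_n not in code.per_class_residual:
        raise ValueError("code lacks per-class residuals for the requested classes")
    return -_log_ratio(code.per_class_residual[class_m], code.per_class_residual[class_n])


def ell(scores: Sequence[float]) -> float:
    """Expected block log-likelihood: the arithmetic mean of the block scores.

    Summed with ``math.fsum`` (correctly rounded), so the result is exactly
    invariant to the block ordering.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("ell of an empty score sequence")
    return math.fsum(scores) / scores.size


def bbll_decide(ell_value: float, tau: float = 0.0, rule: str = "bbll-s") -> EnsembleDecision:
    """BBLL fusion: score = tanh(ell - tau); the label is its sign (0 -> benign)."""
    if not math.isfinite(tau):
        raise ValueError("tau must be finite")
    score = math.tanh(ell_value - tau)
    label = MALIGNANT if score > 0 else BENIGN
    return EnsembleDecision(label=label, score=score, rule=rule, ell=ell_value, tau=tau)


def bbmap_decide(
    block_labels: Sequence[int],
    block_scores: Sequence[float] | None = None,
    rule: str = "bbmap-s",
) -> EnsembleDecision:
    """BBMAP fusion: majority vote; posterior = malignant vote fraction.

    A tied vote falls back to the sign of the summed block scores, and to
    benign if that is also zero.
    """
    labels = np.asarray(list(block_labels), dtype=int)
    if labels.size == 0:
        raise ValueError("bbmap over an empty label sequence")
    posterior = float((labels == MALIGNANT).mean())
    if posterior > 0.5:
        label = MALIGNANT
    elif posterior < 0.5:
        label = BENIGN
    else:
        total = float(np.sum(block_scores)) if block_scores is not None else 0.0
        label = MALIGNANT if total > 0 else BENIGN
    # signed margin in [-1, 1]; used as the continuous score for ROC purposes
    score = 2.0 * posterior - 1.0
    return EnsembleDecision(label=label, score=score, rule=rule, posterior=posterior)


def score_blocks(
    pixels_or_roi,
    dictionaries: Sequence[BlockDictionary],
    block_shape: tuple[int, int],
    T: int,
    eps: float,
) -> list[BlockScore]:
    """Decompose an ROI, code each block over its dictionary, score it.

    Test block vectors are scaled to unit norm before coding (zero-norm
    blocks yield all-zero codes and neutral scores).
    """
    grid = decompose(pixels_or_roi, block_shape)
    if grid.n_blocks != len(dictionaries):
        raise ValueError(
            f"ROI yields {grid.n_blocks} blocks but the model has {len(dictionaries)}"
        )
    out = []
    for j, dic in enumerate(dictionaries):
        y = grid.blocks[j]
        nrm = np.linalg.norm(y)
        if nrm > 0:
            y = y / nrm
        code = omp(dic, y, T=T, eps=eps)
        out.append(BlockScore(block_index=j, lls=lls_score(code), llr=llr_score(code)))
    return out


def fuse(block_scores: Sequence[BlockScore], rule: str, tau: float = 0.0) -> EnsembleDecision:
    """Apply one of the four decision rules to a set of block scores."""
    rule = rule.lower()
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    kind = rule[-1]
    values = [bs.lls if kind == "s" else bs.llr for bs in block_scores]
    if rule.startswith("bbmap"):
        decision = bbmap_decide([bs.hard_label(kind) for bs in block_scores], values, rule=rule)
    else:
        decision = bbll_decide(ell(values), tau=tau, rule=rule)
    decision.block_scores = tuple(block_scores)
    return decision


def classify_roi(
    pixels_or_roi,
    model,
    rule: str = "bbll-s",
    tau: float | None = None,
    T: int | None = None,
    eps: float | None = None,
) -> EnsembleDecision:
    """End-to-end ROI classification against a trained model.

    ``tau``/``T``/``eps`` default to the model's trained/configured values.
    """
    rule = rule.lower()
    if tau is None:
        tau = model.tau_for(rule)
    scores = score_blocks(
        pixels_or_roi,
        model.dictionaries,
        model.block_shape,
        T=model.T if T is None else T,
        eps=model.eps if eps is None else eps,
    )
    return fuse(scores, rule, tau=tau)


def calibrate_tau(ell_values: Sequence[float], true_labels: Sequence[int]) -> float:
    """Pick the shift tau maximizing balanced accuracy of sign(ell - tau).

    The candidate grid is 101 evenly spaced quantiles of the training ELL
    values; ties keep the earliest grid point (deterministic).
    """
    ells = np.asarray(list(ell_values), dtype=float)
    labels = np.asarray(list(true_labels), dtype=int)
    pos = labels == MALIGNANT
    neg = ~pos
    if not pos.any() or not neg.any():
        return 0.0
    best_tau, best_bacc = 0.0, -1.0
    for tau in np.quantile(ells, np.linspace(0.0, 1.0, 101)):
        pred_pos = (ells - tau) > 0
        tpr = float(pred_pos[pos].mean())
        tnr = float((~pred_pos[neg]).mean())
        bacc = 0.5 * (tpr + tnr)
        if bacc > best_bacc + 1e-12:
            best_bacc, best_tau = bacc, float(tau)
    return best_tau
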