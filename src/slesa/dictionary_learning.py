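"""Dictionary learning for block-position dictionaries.

Three modes feed the classifier:

* predefined ("no learning"): normalized raw training blocks as atoms;
* label-separated (LS): an independent KSVD dictionary per class, then
  concatenated with per-atom class labels;
* label-consistent (LC): the LC-KSVD2 objective

  ``||Y - D X||^2 + alpha ||Q - A X||^2 + beta ||H - W X||^2,  ||x_k||_0 <= T``

  solved by the stacked-KSVD reduction: run KSVD on the row-augmented data
  ``[Y; sqrt(alpha) Q; sqrt(beta) H]`` with the augmented dictionary
  ``[D; sqrt(alpha) A; sqrt(beta) W]`` and split/renormalize afterwards.

KSVD alternates batch OMP coding with atom-by-atom rank-1 SVD updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .block_model import BENIGN, MALIGNANT, BlockTrainingMatrix
from .sparse_coding import BlockDictionary, normalize_columns, omp_batch

#: Ridge regularizer for the A/W initialization regressions.
_RIDGE_LAMBDA = 1e-4
#: Per-class KSVD iterations used to initialize LC learning.
_LC_INIT_ITERS = 5
#: Atoms more coherent than this are treated as duplicates and replaced.
_COHERENCE_LIMIT = 1.0 - 1e-6


@dataclass(frozen=True)
class LCConfig:
    """Configuration shared by all dictionary-learning modes.

    ``alpha`` weights the discriminative sparse-code (Q) term and ``beta`` the
    linear-classification (H) term; both are ignored outside LC mode.
    """

    n_atoms_per_class: int = 30
    T: int = 5
    alpha: float = 0.04
    beta: float = 0.02
    n_iter: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms_per_class < 1 or self.T < 1:
            raise ValueError("n_atoms_per_class and T must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")

    @classmethod
    def from_total_atoms(cls, n_atoms_total: int, **kwargs) -> "LCConfig":
        """Split a total atom budget equally; an odd remainder goes benign."""
        per_class = split_atom_budget(n_atoms_total)
        return cls(n_atoms_per_class=max(per_class), **kwargs)


def split_atom_budget(n_atoms_total: int) -> dict[int, int]:
    """Equal split of the atom budget; the extra atom of an odd total is benign."""
    half = n_atoms_total // 2
    return {BENIGN: n_atoms_total - half, MALIGNANT: half}


@dataclass(frozen=True)
class LabelMatrices:
    """Q: binary atom-sample class agreement (n_atoms x N); H: one-hot labels (2 x N)."""

    Q: np.ndarray
    H: np.ndarray


def build_label_matrices(column_labels, atom_labels) -> LabelMatrices:
    column_labels = np.asarray(column_labels, dtype=int)
    atom_labels = np.asarray(atom_labels, dtype=int)
    if column_labels.size == 0 or atom_labels.size == 0:
        raise ValueError("column_labels and atom_labels must be nonempty")
    classes = sorted(set(atom_labels.tolist()))
    if not set(column_labels.tolist()) <= set(classes):
        raise ValueError("sample label outside the atom class set")
    Q = (atom_labels[:, None] == column_labels[None, :]).astype(float)
    H = np.stack([(column_labels == c).astype(float) for c in classes], axis=0)
    return LabelMatrices(Q=Q, H=H)


def _init_dictionary(Y: np.ndarray, n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded init: distinct nonzero training columns (original order), padded
    with random unit vectors if there are not enough usable columns."""
    norms = np.linalg.norm(Y, axis=0)
    usable = np.flatnonzero(norms > 0)
    if usable.size >= n_atoms:
        chosen = np.sort(rng.choice(usable, size=n_atoms, replace=False))
        D = Y[:, chosen] / norms[chosen]
    else:
        warnings.warn("fewer usable training columns than atoms; padding with random atoms")
        D = np.empty((Y.shape[0], n_atoms))
        D[:, : usable.size] = Y[:, usable] / norms[usable]
        extra = rng.standard_normal((Y.shape[0], n_atoms - usable.size))
        D[:, usable.size :] = normalize_columns(extra)
    return D


def dictionary_update_sweep(
    Y: np.ndarray, D: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One KSVD atom-update pass with the code supports held fixed.

    For each atom in turn, the residual excluding that atom's contribution is
    restricted to the samples using it; the atom becomes the leading left
    singular vector and its coefficients sigma_1 times the right one.  Unused
    atoms are left untouched here (replacement is a separate step), so the
    sweep never increases ``||Y - D X||_F``.
    """
    D = D.copy()
    X = X.copy()
    R = Y - D @ X
    for k in range(D.shape[1]):
        users = np.flatnonzero(X[k, :])
        if users.size == 0:
            continue
        Ek = R[:, users] + np.outer(D[:, k], X[k, users])
        U, s, Vt = np.linalg.svd(Ek, full_matrices=False)
        u = U[:, 0]
        # deterministic sign: largest-magnitude entry of the atom positive
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
            Vt = -Vt
        D[:, k] = u
        X[k, users] = s[0] * Vt[0]
        R[:, users] = Ek - np.outer(u, s[0] * Vt[0])
    return D, X


def _replace_degenerate_atoms(
    Y: np.ndarray, D: np.ndarray, X: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Replace unused or duplicated atoms by the worst-represented samples."""
    D = D.copy()
    replaced: list[int] = []
    residuals = np.linalg.norm(Y - D @ X, axis=0)
    order = np.argsort(-residuals)  # worst first
    next_pick = 0
    usage = np.count_nonzero(X, axis=1)
    G = np.abs(D.T @ D)
    np.fill_diagonal(G, 0.0)
    for k in range(D.shape[1]):
        duplicated = np.any(G[k, :k] > _COHERENCE_LIMIT)
        if usage[k] > 0 and not duplicated:
            continue
        replaced.append(k)
        while next_pick < order.size:
            cand = Y[:, order[next_pick]]
            next_pick += 1
            nrm = np.linalg.norm(cand)
            if nrm > 0:
                D[:, k] = cand / nrm
                break
        else:  # all samples are zero: random unit atom
            v = rng.standard_normal(D.shape[0])
            D[:, k] = v / np.linalg.norm(v)
        G = np.abs(D.T @ D)
        np.fill_diagonal(G, 0.0)
    return D, replaced


def ksvd(
    Y: np.ndarray,
    n_atoms: int,
    T: int,
    n_iter: int,
    seed: int | np.random.Generator = 0,
    D_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """KSVD dictionary learning: min ||Y - D X||_F^2 s.t. ||x_k||_0 <= T.

    Alternates OMP coding of all columns with the atom-by-atom SVD update.
    Returns the final unit-norm dictionary and the codes from the last sweep.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("Y must be d x N with N >= 1")
    if not np.any(Y):
        raise ValueError("all-zero training matrix")
    if Y.shape[1] < n_atoms:
        warnings.warn(f"fewer samples ({Y.shape[1]}) than atoms ({n_atoms})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    D = normalize_columns(D_init) if D_init is not None else _init_dictionary(Y, n_atoms, rng)
    if n_iter == 0:
        return D, omp_batch(D, Y, T)
    X = np.zeros((n_atoms, Y.shape[1]))
    for _ in range(n_iter):
        X = omp_batch(D, Y, T)
        D, X = dictionary_update_sweep(Y, D, X)
        D, stale = _replace_degenerate_atoms(Y, D, X, rng)
        X[stale, :] = 0.0
    return D, X


def predefined_dictionary(blockY: BlockTrainingMatrix) -> BlockDictionary:
    """No-learning mode: normalized raw training blocks as labeled atoms."""
    D = blockY.columns.astype(float).copy()
    norms = np.linalg.norm(D, axis=0)
    zero = norms == 0
    if zero.any():  # constant-zero blocks become a flat unit atom
        D[:, zero] = 1.0 / np.sqrt(D.shape[0])
        norms[zero] = 1.0
    D /= norms
    return BlockDictionary(
        block_index=blockY.block_index, atoms=D, atom_labels=blockY.column_labels.copy()
    )


def _class_columns(blockY: BlockTrainingMatrix) -> dict[int, np.ndarray]:
    out = {}
    for c in (BENIGN, MALIGNANT):
        cols = blockY.columns[:, blockY.column_labels == c]
        if cols.shape[1] == 0:
            raise ValueError(f"class {c} has no training samples")
        out[c] = cols
    return out


def ls_learn(blockY: BlockTrainingMatrix, cfg: LCConfig) -> BlockDictionary:
    """Label-separated learning: KSVD per class, then concatenate the
    class dictionaries (benign atoms first) with per-atom labels."""
    per_class = _class_columns(blockY)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    parts, labels = [], []
    for c, ss in zip((BENIGN, MALIGNANT), seeds):
        D_c, _ = ksvd(
            per_class[c],
            cfg.n_atoms_per_class,
            cfg.T,
            cfg.n_iter,
            seed=np.random.default_rng(ss),
        )
        parts.append(D_c)
        labels.extend([c] * cfg.n_atoms_per_class)
    return BlockDictionary(
        block_index=blockY.block_index,
        atoms=np.concatenate(parts, axis=1),
        atom_labels=np.array(labels, dtype=int),
    )


def _ridge_fit(target: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Ridge regression of target on codes X: target Xt (X Xt + lambda I)^-1."""
    G = X @ X.T + _RIDGE_LAMBDA * np.eye(X.shape[0])
    return np.linalg.solve(G.T, X @ target.T).T


def initialize_lc(blockY: BlockTrainingMatrix, cfg: LCConfig):
    """LC initialization: per-class KSVD atoms, codes over the concatenated
    dictionary, and ridge-regressed A (codes -> Q) and W (codes -> H).

    Returns ``(D0, atom_labels, A0, W0, X0, lm)``.
    """
    per_class = _class_columns(blockY)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    parts, labels = [], []
    for c, ss in zip((BENIGN, MALIGNANT), seeds):
        D_c, _ = ksvd(
            per_class[c],
            cfg.n_atoms_per_class,
            cfg.T,
            min(_LC_INIT_ITERS, cfg.n_iter),
            seed=np.random.default_rng(ss),
        )
        parts.append(D_c)
        labels.extend([c] * cfg.n_atoms_per_class)
    D0 = np.concatenate(parts, axis=1)
    atom_labels = np.array(labels, dtype=int)
    lm = build_label_matrices(blockY.column_labels, atom_labels)
    X0 = omp_batch(D0, blockY.columns, cfg.T)
    A0 = _ridge_fit(lm.Q, X0)
    W0 = _ridge_fit(lm.H, X0)
    return D0, atom_labels, A0, W0, X0, lm


def lc_objective(
    Y: np.ndarray,
    Q: np.ndarray,
    H: np.ndarray,
    D: np.ndarray,
    A: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """The LC-KSVD2 objective value at (D, A, W, X)."""
    val = np.linalg.norm(Y - D @ X) ** 2
    val += alpha * np.linalg.norm(Q - A @ X) ** 2
    val += beta * np.linalg.norm(H - W @ X) ** 2
    return float(val)


def lc_learn(blockY: BlockTrainingMatrix, cfg: LCConfig) -> BlockDictionary:
    """Label-consistent learning via the stacked-KSVD reduction.

    With ``alpha = beta = 0`` this degenerates to the KSVD core run on Y from
    the LC initialization (atom labels kept from the initialization).
    """
    D0, atom_labels, A0, W0, _, lm = initialize_lc(blockY, cfg)
    Y = blockY.columns
    d = Y.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])

    if cfg.alpha == 0 and cfg.beta == 0:
        D, X = ksvd(Y, D0.shape[1], cfg.T, cfg.n_iter, seed=rng, D_init=D0)
        A = _ridge_fit(lm.Q, X)
        W = _ridge_fit(lm.H, X)
        return BlockDictionary(
            block_index=blockY.block_index, atoms=D, atom_labels=atom_labels,
            learned_A=A, learned_W=W,
        )

    sa, sb = np.sqrt(cfg.alpha), np.sqrt(cfg.beta)
    Y_aug = np.vstack([Y, sa * lm.Q, sb * lm.H])
    D_aug = np.vstack([D0, sa * A0, sb * W0])
    D_aug, _ = ksvd(Y_aug, D_aug.shape[1], cfg.T, cfg.n_iter, seed=rng, D_init=D_aug)

    n_q = lm.Q.shape[0]
    Dp = D_aug[:d]
    Ap = D_aug[d : d + n_q] / sa if sa > 0 else A0
    Wp = D_aug[d + n_q :] / sb if sb > 0 else W0
    norms = np.linalg.norm(Dp, axis=0)
    norms[norms == 0] = 1.0
    return BlockDictionary(
        block_index=blockY.block_index,
        atoms=Dp / norms,
        atom_labels=atom_labels,
        learned_A=Ap / norms,
        learned_W=Wp / norms,
    )
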