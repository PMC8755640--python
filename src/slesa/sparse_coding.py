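"""Greedy sparse approximation over labeled block dictionaries.

Implements orthogonal matching pursuit (OMP) with the dual stopping rule used
throughout the classifier: stop when the support reaches the sparsity cap ``T``
or the residual norm drops to ``eps``.  Also provides the class-restricted
coefficient operator delta_c and the per-class residuals that feed the
ensemble decision functions, plus a brute-force oracle used only by tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BlockDictionary:
    """Unit-norm atoms for one block position, with per-atom class labels.

    ``learned_A`` (discriminative-code transform) and ``learned_W`` (linear
    classifier) are populated only by label-consistent learning.
    """

    block_index: int
    atoms: np.ndarray  # (d, n_atoms)
    atom_labels: np.ndarray  # (n_atoms,)
    learned_A: np.ndarray | None = None
    learned_W: np.ndarray | None = None

    def __post_init__(self):
        D = np.asarray(self.atoms, dtype=float)
        labels = np.asarray(self.atom_labels, dtype=int)
        if D.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix")
        if labels.shape != (D.shape[1],):
            raise ValueError("atom_labels must have one entry per atom")
        norms = np.linalg.norm(D, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("dictionary atoms must be unit-norm")
        for M, name in ((self.learned_A, "learned_A"), (self.learned_W, "learned_W")):
            if M is not None and M.shape[1] != D.shape[1]:
                raise ValueError(f"{name} must have one column per atom")
        self.atoms = D
        self.atom_labels = labels

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def classes(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.atom_labels.tolist())))


@dataclass
class SparseCode:
    """The OMP solution for one block vector, with per-class score masses."""

    coefficients: np.ndarray
    support: tuple[int, ...]
    residual_norm: float
    residual_path: tuple[float, ...] = ()  # ||r|| after each greedy step
    per_class_l1: dict[int, float] = field(default_factory=dict)
    per_class_residual: dict[int, float] = field(default_factory=dict)


def normalize_columns(M: np.ndarray) -> np.ndarray:
    """Scale each column to unit Euclidean norm; zero columns are left zero."""
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=0)
    out = M.copy()
    nz = norms > 0
    out[:, nz] /= norms[nz]
    return out


def _omp_greedy(D: np.ndarray, y: np.ndarray, T: int, eps: float):
    """Core greedy loop; returns (coefficient vector, support list, residual)."""
    n_atoms = D.shape[1]
    x = np.zeros(n_atoms)
    support: list[int] = []
    path: list[float] = []
    residual = y.copy()
    res_norm = float(np.linalg.norm(residual))
    available = np.ones(n_atoms, dtype=bool)
    while len(support) < T and res_norm > eps:
        corr = D.T @ residual
        corr[~available] = 0.0
        k = int(np.argmax(np.abs(corr)))  # ties: lowest index wins
        if corr[k] == 0.0:
            break  # residual orthogonal to every remaining atom
        support.append(k)
        available[k] = False
        sub = D[:, support]
        coef, *_ = np.linalg.lstsq(sub, y, rcond=None)  # min-norm on rank deficiency
        residual = y - sub @ coef
        res_norm = float(np.linalg.norm(residual))
        path.append(res_norm)
        x[:] = 0.0
        x[support] = coef
    return x, support, res_norm, path


def omp(
    D: BlockDictionary | np.ndarray,
    y: np.ndarray,
    T: int,
    eps: float = 0.0,
) -> SparseCode:
    """Orthogonal matching pursuit with dual stopping (|support| = T or
    residual <= eps).

    Each step selects the atom with the largest absolute correlation with the
    current residual and refits all selected coefficients by least squares.
    When ``D`` is a :class:`BlockDictionary`, the returned code carries the
    per-class l1 masses and per-class reconstruction residuals used by the
    ensemble scores.
    """
    dic = D if isinstance(D, BlockDictionary) else None
    A = dic.atoms if dic is not None else np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != (A.shape[0],):
        raise ValueError(f"signal length {y.shape} does not match atom length {A.shape[0]}")
    if np.isnan(y).any():
        raise ValueError("signal contains NaN")
    if T < 1:
        raise ValueError("sparsity cap T must be >= 1")
    if eps < 0:
        raise ValueError("eps must be nonnegative")

    if np.linalg.norm(y) == 0.0:
        x, support, res, path = np.zeros(A.shape[1]), [], 0.0, []
    else:
        x, support, res, path = _omp_greedy(A, y, T, eps)

    code = SparseCode(
        coefficients=x, support=tuple(support), residual_norm=res, residual_path=tuple(path)
    )
    if dic is not None:
        for c in dic.classes:
            xc = class_restrict(x, dic.atom_labels, c)
            code.per_class_l1[c] = float(np.abs(xc).sum())
            code.per_class_residual[c] = float(np.linalg.norm(A @ xc - y))
    return code


def omp_batch(D: np.ndarray, Y: np.ndarray, T: int, eps: float = 0.0) -> np.ndarray:
    """Code every column of ``Y`` over raw atom matrix ``D``; returns X (n x N)."""
    X = np.empty((D.shape[1], Y.shape[1]))
    for i in range(Y.shape[1]):
        y = Y[:, i]
        if np.linalg.norm(y) == 0.0:
            X[:, i] = 0.0
        else:
            X[:, i] = _omp_greedy(D, y, T, eps)[0]
    return X


def class_restrict(x: np.ndarray, atom_labels: np.ndarray, c: int) -> np.ndarray:
    """delta_c: zero every coefficient whose atom does not belong to class c."""
    atom_labels = np.asarray(atom_labels)
    if c not in atom_labels:
        raise ValueError(f"class {c} not present among atom labels")
    out = np.array(x, dtype=float, copy=True)
    out[atom_labels != c] = 0.0
    return out


def class_residual(D: BlockDictionary | np.ndarray, x: np.ndarray, y: np.ndarray, c: int) -> float:
    """Euclidean norm of the class-c-only reconstruction error ||D delta_c(x) - y||."""
    dic = D if isinstance(D, BlockDictionary) else None
    A = dic.atoms if dic is not None else np.asarray(D, dtype=float)
    labels = dic.atom_labels if dic is not None else None
    if labels is None:
        raise ValueError("class_residual needs a BlockDictionary with atom labels")
    y = np.asarray(y, dtype=float)
    if y.shape != (A.shape[0],):
        raise ValueError("dimension mismatch between y and dictionary")
    return float(np.linalg.norm(A @ class_restrict(x, labels, c) - y))


def exhaustive_oracle(D: np.ndarray, y: np.ndarray, T: int) -> SparseCode:
    """Minimum-residual code over ALL supports of size <= T (test oracle only)."""
    D = D.atoms if isinstance(D, BlockDictionary) else np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    n_atoms = D.shape[1]
    if n_atoms > 12 or T > 2:
        raise ValueError("exhaustive oracle limited to n_atoms <= 12, T <= 2")
    best_x = np.zeros(n_atoms)
    best_support: tuple[int, ...] = ()
    best_res = float(np.linalg.norm(y))
    for size in range(1, T + 1):
        for support in itertools.combinations(range(n_atoms), size):
            sub = D[:, list(support)]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            res = float(np.linalg.norm(y - sub @ coef))
            if res < best_res - 1e-15:
                best_res = res
                best_support = support
                best_x = np.zeros(n_atoms)
                best_x[list(support)] = coef
    return SparseCode(coefficients=best_x, support=best_support, residual_norm=best_res)
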