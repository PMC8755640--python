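import numpy as np
import pytest

from slesa import (
    BENIGN,
    MALIGNANT,
    LCConfig,
    build_block_training_matrices,
    build_label_matrices,
    ksvd,
    lc_learn,
    ls_learn,
    predefined_dictionary,
)
from slesa.dictionary_learning import (
    dictionary_update_sweep,
    initialize_lc,
    lc_objective,
    split_atom_budget,
)
from slesa.sparse_coding import normalize_columns, omp, omp_batch
from slesa.block_model import BlockTrainingMatrix


def two_class_matrix(seed=0, d=16, n_per_class=12):
    """Two linearly separated Gaussian clusters as block training columns."""
    rng = np.random.default_rng(seed)
    base_a = rng.standard_normal(d)
    base_b = rng.standard_normal(d)
    cols, labels = [], []
    for base, lab in ((base_a, BENIGN), (base_b, MALIGNANT)):
        for _ in range(n_per_class):
            cols.append(base + 0.15 * rng.standard_normal(d))
            labels.append(lab)
    return BlockTrainingMatrix(
        block_index=0, columns=np.array(cols).T, column_labels=np.array(labels)
    )


class TestKSVD:
    def test_rank_one_data_learns_the_single_direction(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.tile(v[:, None], (1, 5))
        D, X = ksvd(Y, n_atoms=1, T=1, n_iter=3, seed=0)
        assert np.allclose(D[:, 0], v / np.linalg.norm(v))
        assert np.allclose(X, np.linalg.norm(v) * np.ones((1, 5)))

    def test_update_sweep_never_increases_frobenius_error(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((10, 40))
            D = normalize_columns(rng.standard_normal((10, 14)))
            X = omp_batch(D, Y, T=3)
            before = np.linalg.norm(Y - D @ X)
            D2, X2 = dictionary_update_sweep(Y, D, X)
            after = np.linalg.norm(Y - D2 @ X2)
            assert after <= before + 1e-10

    def test_update_sweep_preserves_code_supports(self, rng):
        Y = rng.standard_normal((8, 30))
        D = normalize_columns(rng.standard_normal((8, 12)))
        X = omp_batch(D, Y, T=2)
        _, X2 = dictionary_update_sweep(Y, D, X)
        assert np.array_equal(X != 0, X2 != 0)

    def test_atoms_are_unit_norm_and_decorrelated(self):
        mat = two_class_matrix()
        D, _ = ksvd(mat.columns, n_atoms=8, T=3, n_iter=10, seed=1)
        assert np.allclose(np.linalg.norm(D, axis=0), 1.0, atol=1e-8)
        G = np.abs(D.T @ D)
        np.fill_diagonal(G, 0.0)
        assert G.max() < 1 - 1e-6

    def test_reproducible_across_runs(self):
        mat = two_class_matrix(3)
        D1, X1 = ksvd(mat.columns, n_atoms=6, T=2, n_iter=8, seed=9)
        D2, X2 = ksvd(mat.columns, n_atoms=6, T=2, n_iter=8, seed=9)
        assert np.array_equal(D1, D2) and np.array_equal(X1, X2)

    def test_all_zero_training_matrix_raises(self):
        with pytest.raises(ValueError):
            ksvd(np.zeros((4, 5)), n_atoms=2, T=1, n_iter=1)


class TestLabelMatrices:
    def test_identity_case(self):
        lm = build_label_matrices([BENIGN, MALIGNANT], [BENIGN, MALIGNANT])
        assert np.array_equal(lm.Q, np.eye(2))

    def test_single_sample_column(self):
        lm = build_label_matrices([MALIGNANT], [BENIGN, BENIGN, MALIGNANT, MALIGNANT])
        assert np.array_equal(lm.Q[:, 0], [0, 0, 1, 1])

    def test_one_hot_class_rows(self):
        lm = build_label_matrices([BENIGN, MALIGNANT, MALIGNANT], [BENIGN, MALIGNANT])
        assert np.array_equal(lm.H, [[1, 0, 0], [0, 1, 1]])
        assert (lm.H.sum(axis=0) == 1).all()

    def test_unknown_sample_label_raises(self):
        with pytest.raises(ValueError):
            build_label_matrices([7], [BENIGN, MALIGNANT])


class TestLSLearn:
    def test_own_class_residual_smaller_on_held_out_blocks(self):
        train = two_class_matrix(seed=0)
        test = two_class_matrix(seed=1)
        cfg = LCConfig(n_atoms_per_class=6, T=3, n_iter=10, seed=0)
        dic = ls_learn(train, cfg)
        own, cross = [], []
        for i in range(test.columns.shape[1]):
            y = test.columns[:, i]
            y = y / np.linalg.norm(y)
            code = omp(dic, y, T=3)
            c = test.column_labels[i]
            own.append(code.per_class_residual[c])
            cross.append(code.per_class_residual[-c])
        assert np.mean(own) < np.mean(cross)

    def test_atom_budget_and_labels(self):
        dic = ls_learn(two_class_matrix(), LCConfig(n_atoms_per_class=4, T=2, n_iter=3))
        assert dic.n_atoms == 8
        assert (dic.atom_labels[:4] == BENIGN).all()
        assert (dic.atom_labels[4:] == MALIGNANT).all()
        assert dic.learned_A is None and dic.learned_W is None

    def test_zero_iterations_with_full_budget_is_raw_sample_dictionary(self):
        mat = two_class_matrix(n_per_class=5)
        cfg = LCConfig(n_atoms_per_class=5, T=2, n_iter=0, seed=0)
        dic = ls_learn(mat, cfg)
        raw = predefined_dictionary(mat)
        # same atoms per class, in training-column order
        assert np.allclose(dic.atoms[:, :5], raw.atoms[:, mat.column_labels == BENIGN])
        assert np.allclose(dic.atoms[:, 5:], raw.atoms[:, mat.column_labels == MALIGNANT])

    def test_single_class_input_raises(self):
        mat = two_class_matrix()
        bad = BlockTrainingMatrix(
            block_index=0,
            columns=mat.columns,
            column_labels=np.full_like(mat.column_labels, BENIGN),
        )
        with pytest.raises(ValueError):
            ls_learn(bad, LCConfig(n_atoms_per_class=2, T=1, n_iter=1))

    def test_odd_atom_total_gives_extra_atom_to_benign(self):
        split = split_atom_budget(61)
        assert split[BENIGN] == 31 and split[MALIGNANT] == 30


class TestLCLearn:
    def test_zero_weights_reduce_to_ksvd_from_lc_initialization(self):
        mat = two_class_matrix(seed=2)
        cfg = LCConfig(n_atoms_per_class=4, T=2, alpha=0.0, beta=0.0, n_iter=6, seed=5)
        dic = lc_learn(mat, cfg)
        D0, labels, *_ = initialize_lc(mat, cfg)
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
        D_ref, _ = ksvd(mat.columns, D0.shape[1], cfg.T, cfg.n_iter, seed=rng, D_init=D0)
        assert np.array_equal(dic.atoms, D_ref)
        assert np.array_equal(dic.atom_labels, labels)

    def test_learned_matrices_have_one_column_per_atom(self):
        mat = two_class_matrix(seed=4)
        cfg = LCConfig(n_atoms_per_class=4, T=2, alpha=0.04, beta=0.02, n_iter=6, seed=1)
        dic = lc_learn(mat, cfg)
        assert dic.learned_A.shape == (8, 8)
        assert dic.learned_W.shape == (2, 8)
        assert np.allclose(np.linalg.norm(dic.atoms, axis=0), 1.0, atol=1e-8)

    def test_within_class_codes_more_correlated_than_between(self):
        mat = two_class_matrix(seed=6, n_per_class=14)
        cfg = LCConfig(n_atoms_per_class=5, T=3, alpha=0.04, beta=0.02, n_iter=10, seed=2)
        dic = lc_learn(mat, cfg)
        X = omp_batch(dic.atoms, normalize_columns(mat.columns), T=3)
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        Xn = X / norms
        C = Xn.T @ Xn
        same = mat.column_labels[:, None] == mat.column_labels[None, :]
        off_diag = ~np.eye(len(mat.column_labels), dtype=bool)
        assert C[same & off_diag].mean() > C[~same].mean()

    def test_objective_does_not_exceed_initial_value(self):
        mat = two_class_matrix(seed=8)
        cfg = LCConfig(n_atoms_per_class=4, T=2, alpha=0.04, beta=0.02, n_iter=10, seed=3)
        D0, labels, A0, W0, X0, lm = initialize_lc(mat, cfg)
        initial = lc_objective(
            mat.columns, lm.Q, lm.H, D0, A0, W0, X0, cfg.alpha, cfg.beta
        )
        dic = lc_learn(mat, cfg)
        X = omp_batch(dic.atoms, mat.columns, cfg.T)
        final = lc_objective(
            mat.columns, lm.Q, lm.H, dic.atoms, dic.learned_A, dic.learned_W, X,
            cfg.alpha, cfg.beta,
        )
        assert final <= initial

    def test_linear_classifier_separates_training_codes(self):
        mat = two_class_matrix(seed=10, n_per_class=15)
        cfg = LCConfig(n_atoms_per_class=5, T=3, alpha=0.04, beta=0.02, n_iter=10, seed=4)
        dic = lc_learn(mat, cfg)
        X = omp_batch(dic.atoms, normalize_columns(mat.columns), cfg.T)
        pred = np.where(np.argmax(dic.learned_W @ X, axis=0) == 1, MALIGNANT, BENIGN)
        acc = (pred == mat.column_labels).mean()
        assert acc >= 0.9
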