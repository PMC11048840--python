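import numpy as np
import pytest

from flavoromics.chemometrics import (
    OPLSDA,
    cross_validate_q2,
    fit_oplsda,
    hcluster,
    permutation_test,
    scale_matrix,
    vip,
)
from flavoromics.io_core import ValidationError
from flavoromics.synthetic_data import PlantedEffect, SyntheticDesign, generate_intensity_dataset


def separated_clouds(seed=11, n=6, p=20, delta=6.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.0, 1.0, (n, p)), rng.normal(delta, 1.0, (n, p))])
    y = ["a"] * n + ["b"] * n
    return X, y


class TestScaling:
    def test_unit_variance(self):
        X = np.array([[1.0, 5.0], [2.0, 5.5], [3.0, 6.0]])
        Xs, record = scale_matrix(X, "unit_variance")
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_none_only_centers(self):
        X = np.array([[1.0, 5.0], [3.0, 7.0]])
        Xs, _ = scale_matrix(X, "none")
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs[1] - Xs[0], X[1] - X[0])

    def test_pareto_round_trip(self, rng):
        X = rng.lognormal(1.0, 0.5, (8, 5))
        Xs, record = scale_matrix(X, "pareto")
        np.testing.assert_allclose(record.undo(Xs), X, atol=1e-10)

    def test_zero_variance_dropped_with_warning(self):
        X = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            Xs, record = scale_matrix(X, "unit_variance")
        assert Xs.shape == (3, 1)
        assert record.dropped == ("var1",)


class TestOplsdaFit:
    def test_separated_clouds_fit_well(self):
        X, y = separated_clouds()
        model = fit_oplsda(X, y)
        assert model.r2y_ > 0.95
        assert model.q2_ > 0.9

    def test_perfectly_predictive_variable(self):
        # X carries the class code itself (plus a constant column)
        y_code = np.array([1.0] * 4 + [-1.0] * 4)
        X = np.column_stack([y_code, np.ones(8)])
        model = fit_oplsda(X, ["a"] * 4 + ["b"] * 4, n_orthogonal=0)
        assert model.r2y_ == pytest.approx(1.0, abs=1e-6)

    def test_zero_orthogonal_equals_pls1(self, rng):
        X = rng.normal(0, 1, (10, 6))
        y = ["a"] * 5 + ["b"] * 5
        model = fit_oplsda(X, y, n_orthogonal=0)
        # independent PLS1 oracle
        Xs, _ = scale_matrix(X)
        ypm = np.array([1.0] * 5 + [-1.0] * 5)
        yc = ypm - ypm.mean()
        w = Xs.T @ yc
        w /= np.linalg.norm(w)
        t = Xs @ w
        np.testing.assert_allclose(
            np.abs(model.predictive_scores_.ravel()), np.abs(t), atol=1e-8
        )

    def test_three_classes_rejected(self, rng):
        X = rng.normal(0, 1, (9, 4))
        with pytest.raises(ValidationError, match="pairwise"):
            fit_oplsda(X, ["a", "a", "a", "b", "b", "b", "c", "c", "c"])

    def test_constant_labels_rejected(self, rng):
        X = rng.normal(0, 1, (6, 4))
        with pytest.raises(ValidationError):
            fit_oplsda(X, ["a"] * 6)

    def test_score_orthogonality(self):
        X, y = separated_clouds(seed=2)
        model = fit_oplsda(X, y, n_orthogonal=2)
        if model.n_orthogonal_:
            dots = model.predictive_scores_.T @ model.orthogonal_scores_
            assert np.abs(dots).max() < 1e-8

    def test_r2_bounds_and_q2_below_r2y(self):
        X, y = separated_clouds(seed=5)
        model = fit_oplsda(X, y)
        assert 0.0 <= model.r2x_ <= 1.0
        assert 0.0 <= model.r2y_ <= 1.0
        assert model.q2_ <= model.r2y_ + 1e-9

    def test_label_swap_leaves_statistics_unchanged(self):
        X, y = separated_clouds(seed=7)
        m1 = fit_oplsda(X, y, positive_label="a")
        m2 = fit_oplsda(X, y, positive_label="b")
        assert m1.r2x_ == pytest.approx(m2.r2x_, abs=1e-9)
        assert m1.r2y_ == pytest.approx(m2.r2y_, abs=1e-9)
        assert m1.q2_ == pytest.approx(m2.q2_, abs=1e-9)
        np.testing.assert_allclose(m1.vip_, m2.vip_, atol=1e-9)

    def test_r2y_nondecreasing_then_q2_declines(self, rng):
        """More orthogonal components always fit the training labels better,
        but cross-validated Q2 eventually drops (overfitting)."""
        X = rng.normal(0, 1, (12, 40))
        X[:6] += 0.8  # weak signal, lots of noise
        y = ["a"] * 6 + ["b"] * 6
        r2ys, q2s = [], []
        for n_ortho in range(0, 5):
            m = fit_oplsda(X, y, n_orthogonal=n_ortho)
            r2ys.append(m.r2y_)
            q2s.append(m.q2_)
        assert all(b >= a - 1e-9 for a, b in zip(r2ys, r2ys[1:]))
        assert min(q2s[1:]) < q2s[0]  # some orthogonal inflation hurts CV

    def test_predict_recovers_training_labels(self):
        X, y = separated_clouds(seed=13)
        model = fit_oplsda(X, y)
        assert list(model.predict(X)) == y

    def test_sklearn_param_interface(self):
        est = OPLSDA(n_orthogonal=2, scaling="pareto")
        params = est.get_params()
        assert params["n_orthogonal"] == 2
        est.set_params(scaling="none")
        assert est.scaling == "none"


class TestCrossValidation:
    def test_loo_equals_explicit_enumeration(self, rng):
        X = rng.normal(0, 1, (8, 5))
        X[:4] += 2.0
        y = ["a"] * 4 + ["b"] * 4
        q2 = cross_validate_q2(X, y, folds=8, n_orthogonal=0)
        # explicit leave-one-out PRESS oracle
        ypm = np.array([1.0] * 4 + [-1.0] * 4)
        press = 0.0
        for i in range(8):
            mask = np.ones(8, bool)
            mask[i] = False
            Xs, record = scale_matrix(X[mask])
            yc = ypm[mask] - ypm[mask].mean()
            w = Xs.T @ yc
            w /= np.linalg.norm(w)
            t = Xs @ w
            q = float(yc @ t / (t @ t))
            t_new = record.apply(X[i : i + 1]) @ w
            press += float((ypm[i] - (t_new[0] * q + ypm[mask].mean())) ** 2)
        ss = float(((ypm - ypm.mean()) ** 2).sum())
        assert q2 == pytest.approx(1.0 - press / ss, abs=1e-10)

    def test_pure_noise_q2_low(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (12, 30))
        y = ["a"] * 6 + ["b"] * 6
        assert cross_validate_q2(X, y) <= 0.2

    def test_perfectly_predictive_q2_high(self):
        X, y = separated_clouds(seed=11, delta=20.0)
        assert cross_validate_q2(X, y) > 0.99

    def test_small_design_falls_back_to_loo(self, rng):
        X = rng.normal(0, 1, (6, 5))
        X[:3] += 3
        y = ["a"] * 3 + ["b"] * 3
        with pytest.warns(UserWarning, match="leave-one-out"):
            cross_validate_q2(X, y, folds=7)


class TestPermutation:
    def test_label_invariant_data_gives_p_one(self):
        X = np.ones((8, 5))
        y = ["a"] * 4 + ["b"] * 4
        res = permutation_test(X, y, n_permutations=20, seed=1)
        assert res.p_r2y == 1.0
        assert res.p_q2 == 1.0

    def test_strong_structure_gives_minimal_p(self):
        X, y = separated_clouds(seed=11)
        res = permutation_test(X, y, n_permutations=50, seed=4)
        assert res.p_q2 == pytest.approx(1 / 51)

    def test_determinism(self):
        X, y = separated_clouds(seed=9, p=5)
        r1 = permutation_test(X, y, n_permutations=10, seed=5)
        r2 = permutation_test(X, y, n_permutations=10, seed=5)
        assert r1.permuted_q2 == r2.permuted_q2
        assert r1.permuted_r2y == r2.permuted_r2y

    def test_add_one_formula(self):
        X, y = separated_clouds(seed=9, p=5)
        res = permutation_test(X, y, n_permutations=19, seed=2)
        n_ge = sum(v >= res.observed_q2 - 1e-12 for v in res.permuted_q2)
        assert res.p_q2 == pytest.approx((1 + n_ge) / 20)
        assert len(res.permuted_q2) == 19

    def test_null_p_super_uniform(self):
        """Under a true null, P[p <= alpha] <= alpha with the add-one estimator."""
        rng = np.random.default_rng(8)
        hits = 0
        n_sims, n_perm, alpha = 20, 9, 0.2
        for _ in range(n_sims):
            X = rng.normal(0, 1, (8, 6))
            y = ["a"] * 4 + ["b"] * 4
            res = permutation_test(X, y, n_permutations=n_perm, seed=int(rng.integers(2**31)))
            hits += res.p_q2 <= alpha
        # binomial(20, 0.2) upper tail: allow generous slack above the mean
        assert hits <= 10


class TestVip:
    def test_single_variable_vip_is_one(self, rng):
        X = np.column_stack([np.array([1.0, 1.2, -1.0, -1.1, 0.9, -0.8])])
        model = fit_oplsda(X, ["a", "a", "b", "b", "a", "b"], n_orthogonal=0)
        assert vip(model)["var0"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_formula_on_toy(self):
        """Three variables, hand-computed: VIP_j = sqrt(3) |w_j| / ||w||."""
        X = np.array(
            [[2.0, 0.1, 0.0], [1.8, -0.2, 0.1], [2.2, 0.0, -0.1],
             [-2.0, 0.1, 0.05], [-1.9, -0.1, 0.0], [-2.1, 0.2, -0.05]]
        )
        y = ["a"] * 3 + ["b"] * 3
        model = fit_oplsda(X, y, n_orthogonal=0)
        Xs, _ = scale_matrix(X)
        ypm = np.array([1.0] * 3 + [-1.0] * 3)
        w = Xs.T @ (ypm - ypm.mean())
        expected = np.sqrt(3) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(model.vip_, expected, atol=1e-10)

    def test_sum_of_squares_equals_variable_count(self, rng):
        for seed in (1, 2, 3):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (10, 17))
            model = fit_oplsda(X, ["a"] * 5 + ["b"] * 5)
            assert float((model.vip_**2).sum()) == pytest.approx(17.0, abs=1e-8)


class TestHcluster:
    def test_line_points_cut(self):
        tree = hcluster(np.array([[0.0], [1.0], [10.0]]))
        cut = tree.cut(2)
        assert cut["sample0"] == cut["sample1"] != cut["sample2"]

    def test_shifted_group_isolated(self):
        """Three synthetic cultivars, one shifted: k=2 isolates the outlier
        group, mirroring the QYX vs {HZ, HMZ} split."""
        effects = tuple(
            PlantedEffect(f"M{i + 1:04d}", "QYX", 3.0) for i in range(0, 120, 2)
        )
        design = SyntheticDesign(n_compounds=200, planted_effects=effects, seed=5)
        matrix, _ = generate_intensity_dataset(design)
        tree = hcluster(matrix)
        cut = tree.cut(2)
        qyx = {cut[s] for s in matrix.samples_of("QYX")}
        rest = {cut[s] for g in ("HZ", "HMZ") for s in matrix.samples_of(g)}
        assert len(qyx) == 1
        assert len(rest) == 1
        assert qyx != rest

    def test_duplicate_samples_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        tree = hcluster(X)
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_nan_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            hcluster(X)

    def test_monotone_merge_heights(self, rng):
        X = rng.normal(0, 1, (10, 4))
        heights = hcluster(X, linkage="average").linkage_matrix[:, 2]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_ward_requires_euclidean(self):
        with pytest.raises(ValidationError):
            hcluster(np.eye(3), distance="correlation", linkage="ward")
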