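import numpy as np
import pandas as pd
import pytest

from spaceskin import pair_models, simdata
from spaceskin._utils import ValidationError


class TestAUC:
    def test_perfect_reversed_and_tied(self):
        y = [0, 0, 1, 1]
        assert pair_models.auc([1, 2, 3, 4], y) == 1.0
        assert pair_models.auc([4, 3, 2, 1], y) == 0.0
        assert pair_models.auc([1, 1, 1, 1], y) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            pair_models.auc([1, 2], [1, 1])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        assert pair_models.auc(s, y) == pytest.approx(
            pair_models.auc(np.exp(s), y))


class TestAUCProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    scores = st.lists(st.floats(-5, 5, allow_nan=False, allow_infinity=False,
                                width=32), min_size=1, max_size=15)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(pos=scores, neg=scores)
    def test_matches_pair_counting(self, pos, neg):
        """Midrank AUC equals direct enumeration of score pairs."""
        s = np.array(pos + neg)
        y = np.array([1] * len(pos) + [0] * len(neg))
        expect = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg) \
            / (len(pos) * len(neg))
        assert pair_models.auc(s, y) == pytest.approx(expect, abs=1e-12)


class TestFitPair:
    def test_separated_single_gene_reaches_auc_one(self):
        a = np.concatenate([np.zeros(10), np.ones(10) * 5])
        y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        m = pair_models.fit_pair(a, None, y, form="single", compute_cv=False)
        assert m.auc_train == 1.0

    def test_synergy_needs_interaction_terms(self):
        cv = {"interaction": [], "product": [], "additive": []}
        for seed in range(10):
            X, y, _ = simdata.simulate_synergy_dataset(200, 0, 3.0,
                                                       seed=seed)
            a, b = X.loc["SYN_A"].to_numpy(), X.loc["SYN_B"].to_numpy()
            for form in cv:
                m = pair_models.fit_pair(a, b, y, form=form, seed=seed)
                cv[form].append(m.auc_cv)
        assert np.mean(cv["interaction"]) >= 0.85
        assert np.mean(cv["product"]) >= 0.85
        assert np.mean(cv["additive"]) <= 0.7

    def test_permuted_labels_near_chance(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y, _ = simdata.simulate_synergy_dataset(200, 0, 3.0,
                                                       seed=seed)
            y_perm = rng.permutation(y)
            if y_perm.sum() < 4 or y_perm.sum() > len(y_perm) - 4:
                continue
            m = pair_models.fit_pair(X.loc["SYN_A"].to_numpy(),
                                     X.loc["SYN_B"].to_numpy(), y_perm,
                                     form="interaction", seed=seed)
            aucs.append(m.auc_cv)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_constant_feature_rejected(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValidationError, match="constant"):
            pair_models.fit_pair(np.ones(8), np.arange(8.0), y,
                                 form="additive", compute_cv=False)

    def test_affine_rescaling_leaves_cv_auc_unchanged(self):
        X, y, _ = simdata.simulate_synergy_dataset(100, 0, 3.0, seed=2)
        a, b = X.loc["SYN_A"].to_numpy(), X.loc["SYN_B"].to_numpy()
        m1 = pair_models.fit_pair(a, b, y, form="product", seed=0)
        m2 = pair_models.fit_pair(a * 100 + 7, b, y, form="product", seed=0)
        assert m1.auc_cv == pytest.approx(m2.auc_cv, abs=1e-9)


class TestSklearnEstimator:
    def test_get_params_clone_and_predict(self):
        from sklearn.base import clone

        X, y, _ = simdata.simulate_synergy_dataset(60, 0, 3.0, seed=1)
        Xmat = np.column_stack([X.loc["SYN_A"], X.loc["SYN_B"]])
        est = pair_models.PairClassifier(form="product", seed=0)
        est2 = clone(est)
        assert est2.get_params()["form"] == "product"
        est.fit(Xmat, y)
        proba = est.predict_proba(Xmat)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(Xmat)) <= {0, 1}


class TestSearch:
    def test_candidate_count_combinatorics(self):
        X, y, _ = simdata.simulate_synergy_dataset(40, 4, 3.0, seed=0)
        # m=6 genes, 5 two-gene forms + single per gene
        models = pair_models.search_pairs(X, y, seed=0, top_k=10**6,
                                          cv_top=10**6)
        m = 6
        expect = m * (m - 1) // 2 * len(pair_models.TWO_GENE_FORMS) + m
        assert len(models) == expect

    def test_deterministic_ranking(self):
        X, y, _ = simdata.simulate_synergy_dataset(60, 10, 3.0, seed=3)
        r1 = pair_models.search_pairs(X, y, seed=9, top_k=5)
        r2 = pair_models.search_pairs(X, y, seed=9, top_k=5)
        assert [(m.gene_a, m.gene_b, m.form) for m in r1] == \
            [(m.gene_a, m.gene_b, m.form) for m in r2]
        assert [m.auc_cv for m in r1] == [m.auc_cv for m in r2]

    def test_planted_pair_found(self):
        X, y, pair = simdata.simulate_synergy_dataset(80, 20, 3.0, seed=0)
        models = pair_models.search_pairs(X, y, seed=0)
        assert {models[0].gene_a, models[0].gene_b} == set(pair)

    def test_tractability_cap_error_names_candidate_count(self):
        genes = [f"g{i}" for i in range(pair_models.TRACTABILITY_CAP + 1)]
        mat = pd.DataFrame(np.zeros((len(genes), 4)), index=genes)
        with pytest.raises(ValidationError, match="candidates"):
            pair_models.search_pairs(mat, [0, 0, 1, 1], gene_pool=genes)


class TestSelection:
    def _model(self, ga, gb, cv):
        return pair_models.PairModel(gene_a=ga, gene_b=gb, form="product",
                                     theta=np.zeros(2), auc_train=cv,
                                     logloss=0.5, complexity=2, auc_cv=cv)

    def test_disjoint_preferred_within_tolerance(self):
        models = [self._model("a", "b", 0.90),
                  self._model("a", "c", 0.895),
                  self._model("d", "e", 0.89)]
        out = pair_models.select_mrmr(models, k=2, auc_tolerance=0.02)
        assert [(m.gene_a, m.gene_b) for m in out] == [("a", "b"),
                                                       ("d", "e")]

    def test_k_one_returns_best(self):
        models = [self._model("a", "b", 0.9), self._model("c", "d", 0.8)]
        out = pair_models.select_mrmr(models, k=1)
        assert (out[0].gene_a, out[0].gene_b) == ("a", "b")

    def test_shared_gene_fallback(self):
        models = [self._model("a", "b", 0.9), self._model("a", "c", 0.89),
                  self._model("a", "d", 0.88)]
        out = pair_models.select_mrmr(models, k=3, auc_tolerance=0.02)
        assert len(out) == 3  # proceeds by AUC order when unavoidable


class TestDecisionBoundary:
    def _fitted(self, form="additive"):
        X, y, _ = simdata.simulate_synergy_dataset(80, 0, 3.0, seed=4)
        a, b = X.loc["SYN_A"].to_numpy(), X.loc["SYN_B"].to_numpy()
        m = pair_models.fit_pair(a, b, y, form=form, compute_cv=False,
                                 gene_a="SYN_A", gene_b="SYN_B")
        return m, a, b

    def test_raster_equals_direct_evaluation(self):
        m, a, b = self._fitted("product")
        grid = pair_models.decision_boundary(m, a, b, grid_resolution=21)
        direct = m.predict_proba(grid["a"].to_numpy(), grid["b"].to_numpy())
        assert np.allclose(grid["probability"], direct, atol=1e-12)
        assert grid["a"].min() < a.min() and grid["a"].max() > a.max()

    def test_additive_contour_is_straight_line(self):
        m, a, b = self._fitted("additive")
        t0, t1, t2 = m.theta
        if abs(t2) > 1e-9:
            za = np.linspace(-2, 2, 11)
            zb = -(t0 + t1 * za) / t2
            orig_a = za * m.standardize["std_a"] + m.standardize["mean_a"]
            orig_b = zb * m.standardize["std_b"] + m.standardize["mean_b"]
            p = m.predict_proba(orig_a, orig_b)
            assert np.allclose(p, 0.5, atol=1e-9)

    def test_product_contour_hyperbola(self):
        m, a, b = self._fitted("product")
        t0, t1 = m.theta
        # 0.5 contour satisfies za*zb = -t0/t1 in standardized units
        target = -t0 / t1
        za = np.array([0.5, 1.0, 2.0, -0.5, -1.0])
        zb = target / za
        orig_a = za * m.standardize["std_a"] + m.standardize["mean_a"]
        orig_b = zb * m.standardize["std_b"] + m.standardize["mean_b"]
        assert np.allclose(m.predict_proba(orig_a, orig_b), 0.5, atol=1e-9)

    def test_single_gene_model_rejected(self):
        X, y, _ = simdata.simulate_synergy_dataset(40, 0, 3.0, seed=5)
        m = pair_models.fit_pair(X.loc["SYN_A"].to_numpy(), None, y,
                                 form="single", compute_cv=False)
        with pytest.raises(ValidationError, match="2-D"):
            pair_models.decision_boundary(m, [0, 1], [0, 1])
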