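import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcscore.classify import (
    confusion_stats,
    evaluate,
    hcluster_features,
    loocv,
    nb_predict,
    nb_train,
    permutation_null_aucs,
    rf_importance_select,
    roc_auc,
    welch_filter,
    welch_test,
)
from tcscore.errors import ConfigurationError, DataError


def labelled_matrix(x_pos, x_neg, columns=None):
    x = np.vstack([x_pos, x_neg])
    columns = columns or [f"VJ{i:02d}" for i in range(x.shape[1])]
    idx = [f"s{i}" for i in range(x.shape[0])]
    labels = pd.Series(["GO"] * len(x_pos) + ["GH"] * len(x_neg), index=idx)
    return pd.DataFrame(x, index=idx, columns=columns), labels


class TestWelch:
    def test_hand_computed_t_and_dof(self):
        m, labels = labelled_matrix([[1], [2], [3]], [[2], [4], [6]])
        res = welch_test(m, labels)
        assert res["t"].iloc[0] == pytest.approx(-1.549, abs=1e-3)
        assert res["dof"].iloc[0] == pytest.approx(2.941, abs=1e-3)

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        m, labels = labelled_matrix(rng.normal(0, 1, (8, 6)), rng.normal(0.4, 2, (11, 6)))
        res = welch_test(m, labels)
        ref = stats.ttest_ind(
            m[labels == "GO"], m[labels == "GH"], equal_var=False
        )
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res["p"], ref.pvalue, rtol=1e-10)

    def test_reduces_to_student_t_for_equal_n_and_variance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (10, 1))
        b = -a + 0.3  # same sample variance by construction
        m, labels = labelled_matrix(a, b)
        res = welch_test(m, labels)
        student = stats.ttest_ind(a, b, equal_var=True)
        assert res["t"].iloc[0] == pytest.approx(student.statistic[0])
        assert res["dof"].iloc[0] == pytest.approx(18.0)

    def test_identical_groups_give_t0_p1_and_are_filtered(self):
        m, labels = labelled_matrix([[1.0], [2.0]], [[1.0], [2.0]])
        res, kept = welch_filter(m, labels, alpha=0.999)
        assert res["t"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0
        assert kept == []

    def test_zero_variance_different_means_kept_with_p0(self):
        m, labels = labelled_matrix([[1.0], [1.0]], [[2.0], [2.0]])
        res, kept = welch_filter(m, labels, alpha=0.05)
        assert res["p"].iloc[0] == 0.0
        assert kept == list(m.columns)

    def test_single_class_rejected(self):
        m = pd.DataFrame({"f": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(DataError):
            welch_test(m, pd.Series(["GO", "GO"], index=m.index))

    def test_top_n_mode_forces_count(self):
        rng = np.random.default_rng(2)
        m, labels = labelled_matrix(rng.normal(0, 1, (5, 10)), rng.normal(0, 1, (5, 10)))
        _, kept = welch_filter(m, labels, mode="top_n", top_n=4)
        assert len(kept) == 4


class TestRFSelect:
    def setup_method(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, (30, 21))
        noise[:15, 0] += 4.0  # one perfectly separating feature among 20 noise ones
        self.m, self.labels = labelled_matrix(noise[:15], noise[15:])

    def test_planted_feature_ranks_first(self):
        sel = rf_importance_select(self.m, self.labels, list(self.m.columns), n_trees=200, k=3, seed=0)
        assert sel.selected[0] == "VJ00"

    def test_k_equals_filtered_returns_everything(self):
        sel = rf_importance_select(self.m, self.labels, list(self.m.columns), n_trees=50,
                                   k=len(self.m.columns), seed=0)
        assert set(sel.selected) == set(self.m.columns)

    def test_fixed_seed_reproducible(self):
        a = rf_importance_select(self.m, self.labels, list(self.m.columns), n_trees=100, k=5, seed=7)
        b = rf_importance_select(self.m, self.labels, list(self.m.columns), n_trees=100, k=5, seed=7)
        assert a.selected == b.selected

    def test_k_too_large_rejected(self):
        with pytest.raises(ConfigurationError):
            rf_importance_select(self.m, self.labels, ["VJ00"], k=2)


class TestNaiveBayes:
    def two_class_model(self, prior_pos=0.5):
        n_pos = 10
        n_neg = int(round(n_pos * (1 - prior_pos) / prior_pos))
        x_pos = np.zeros((n_pos, 1))
        x_neg = np.full((n_neg, 1), 2.0)
        m, labels = labelled_matrix(x_pos, x_neg)
        model = nb_train(m, labels)
        # overwrite with exact unit variances for the closed-form checks
        model.variances = {c: [1.0] for c in model.classes}
        model.means = {"GO": [0.0], "GH": [2.0]}
        return model

    def test_midpoint_is_half(self):
        assert nb_predict(self.two_class_model(), [[1.0]])[0] == pytest.approx(0.5)

    def test_closed_form_log_odds(self):
        # x=0: log-odds = 2 in favor of the mean-0 class -> 1/(1+e^-2)
        assert nb_predict(self.two_class_model(), [[0.0]])[0] == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-12
        )

    def test_priors_returned_at_equidistant_point(self):
        model = self.two_class_model(prior_pos=0.2)
        assert nb_predict(model, [[1.0]])[0] == pytest.approx(0.2)

    def test_matches_sklearn_gaussian_nb(self):
        rng = np.random.default_rng(4)
        m, labels = labelled_matrix(rng.normal(1, 1, (12, 3)), rng.normal(0, 2, (9, 3)))
        model = nb_train(m, labels)
        ours = nb_predict(model, m)
        from sklearn.naive_bayes import GaussianNB

        sk = GaussianNB(var_smoothing=0.0)
        # sklearn uses ddof=0 variances; refit our model the same way for comparison
        for cls in model.classes:
            x = m[labels == cls].to_numpy()
            model.variances[cls] = x.var(axis=0, ddof=0).tolist()
        ours = nb_predict(model, m)
        sk.fit(m.to_numpy(), labels.to_numpy())
        theirs = sk.predict_proba(m.to_numpy())[:, list(sk.classes_).index("GO")]
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)

    def test_zero_variance_feature_floored(self):
        m, labels = labelled_matrix([[1.0, 5.0], [1.0, 6.0]], [[2.0, 1.0], [2.0, 2.0]])
        model = nb_train(m, labels)
        assert min(min(v) for v in model.variances.values()) >= 1e-9
        assert np.isfinite(nb_predict(model, [[1.5, 3.0]])[0])

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m, labels = labelled_matrix(rng.normal(0, 1, (5, 2)), rng.normal(1, 1, (5, 2)))
        model = nb_train(m, labels)
        model.to_json(tmp_path / "model.json")
        from tcscore.classify import NBModel

        back = NBModel.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(nb_predict(back, m), nb_predict(model, m))


class TestConfusionStats:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,sens,spec",
        [
            (12, 5, 13, 5, 70.59, 72.22),
            (29, 7, 30, 4, 87.88, 81.08),
            (10, 0, 10, 0, 100.0, 100.0),
        ],
    )
    def test_reference_tables(self, tp, fp, tn, fn, sens, spec):
        assert confusion_stats(tp, fp, tn, fn) == (sens, spec)

    def test_empty_margin_rejected(self):
        with pytest.raises(DataError):
            confusion_stats(0, 5, 5, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], ["GO", "GO", "GH", "GH"])
        assert auc == 1.0

    def test_hand_counted_pairs(self):
        auc, _ = roc_auc([0.9, 0.4, 0.5, 0.1], ["GO", "GO", "GH", "GH"])
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 6, ["GO", "GO", "GO", "GH", "GH", "GH"])
        assert auc == pytest.approx(0.5)

    def test_equals_concordant_pair_fraction(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n_pos, n_neg = rng.integers(2, 8, 2)
            pos = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n_pos)
            neg = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n_neg)
            auc, _ = roc_auc(
                np.concatenate([pos, neg]), ["GO"] * n_pos + ["GH"] * n_neg
            )
            pairs = [(p > q) + 0.5 * (p == q) for p in pos for q in neg]
            assert auc == pytest.approx(sum(pairs) / len(pairs))

    def test_roc_monotone(self):
        rng = np.random.default_rng(7)
        _, roc = roc_auc(rng.uniform(0, 1, 30), ["GO", "GH"] * 15)
        assert (np.diff(roc["fpr"]) >= 0).all() and (np.diff(roc["tpr"]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], ["GO", "GO"])


class TestLoocvAndEvaluate:
    def separated(self, n=8):
        rng = np.random.default_rng(8)
        return labelled_matrix(
            rng.normal(3, 0.3, (n, 1)), rng.normal(0, 0.3, (n, 1))
        )

    def test_perfect_separation_scores_one(self):
        m, labels = self.separated()
        res = loocv(m, labels, selection=list(m.columns))
        assert res.auc == 1.0
        assert (res.sensitivity, res.specificity) == (100.0, 100.0)

    def test_confusion_counts_sum_to_n(self):
        m, labels = self.separated(5)
        res = loocv(m, labels, selection=list(m.columns))
        assert res.n == len(labels)

    def test_requires_selection_or_nested(self):
        m, labels = self.separated(4)
        with pytest.raises(ConfigurationError):
            loocv(m, labels)

    def test_nested_mode_runs_and_scores_separable_data(self):
        m, labels = self.separated(6)
        res = loocv(m, labels, nested=True, n_trees=25, k=1)
        assert res.auc == 1.0

    def test_evaluate_held_out_cohort(self):
        m, labels = self.separated(10)
        model = nb_train(m, labels)
        res = evaluate(model, m, labels)
        assert res.auc == 1.0 and res.n == 20

    def test_permutation_null_centers_at_half(self):
        rng = np.random.default_rng(9)
        m, labels = labelled_matrix(rng.normal(0, 1, (30, 5)), rng.normal(0, 1, (30, 5)))
        aucs = permutation_null_aucs(m, labels, list(m.columns)[:2], n_perm=10, seed=0)
        assert 0.3 < float(np.mean(aucs)) < 0.7


class TestHCluster:
    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(10)
        m, labels = labelled_matrix(rng.normal(5, 0.2, (10, 4)), rng.normal(0, 0.2, (10, 4)))
        order, cut = hcluster_features(m)
        groups = {lbl: set(cut[[i for i, s in enumerate(m.index) if labels[s] == lbl]])
                  for lbl in ("GO", "GH")}
        assert groups["GO"].isdisjoint(groups["GH"])

    def test_duplicate_samples_merge_first(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]], index=["a", "a2", "b"], columns=["f1", "f2"]
        )
        order, cut = hcluster_features(m)
        assert cut[0] == cut[1] != cut[2]
        assert abs(order.index("a") - order.index("a2")) == 1  # adjacent leaves

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(0, 1, (8, 3)), index=[f"s{i}" for i in range(8)])
        assert hcluster_features(m)[0] == hcluster_features(m)[0]

    def test_constant_matrix_warns(self):
        m = pd.DataFrame(np.ones((4, 2)), index=list("abcd"))
        with pytest.warns(UserWarning, match="degenerate"):
            hcluster_features(m)
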