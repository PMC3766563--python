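import numpy as np
import pytest

from antioxseq import evaluate
from antioxseq._utils import stratified_fold_indices
from antioxseq.evaluate import (
    EvaluationError,
    confusion_metrics,
    independent_test,
    jackknife,
    kfold,
    roc_auroc,
    roc_points,
)
from antioxseq.features import FeatureMatrix
from antioxseq.naive_bayes import GaussianNaiveBayes


def fm_of(values, ids=None):
    values = np.asarray(values, dtype=float)
    names = [f"f{i}" for i in range(values.shape[1])]
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return FeatureMatrix(values, tuple(names), tuple(ids))


def rank_auroc(scores, truth):
    """Pairwise rank oracle: (#[pos>neg] + 0.5 #[pos==neg]) / (n1*n0)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture()
def tiny_separable():
    """n=6, 1-D, trivially separable by a margin."""
    fm = fm_of([[0.10], [0.20], [0.15], [0.80], [0.90], [0.85]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    return fm, labels


class TestConfusionMetrics:
    def test_direct_arithmetic(self):
        truth = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        m = confusion_metrics(pred, truth)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (9, 1, 8, 2)
        assert m["sn"] == pytest.approx(0.90)
        assert m["sp"] == pytest.approx(0.80)
        assert m["acc"] == pytest.approx(0.85)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 0, 1])
        m = confusion_metrics(truth, truth)
        assert m["sn"] == m["sp"] == m["acc"] == 1.0

    def test_all_predicted_positive(self):
        truth = np.array([0, 1, 0, 1])
        m = confusion_metrics(np.ones(4, dtype=int), truth)
        assert m["sn"] == 1.0 and m["sp"] == 0.0

    def test_absent_class_rate_is_none_not_nan(self):
        m = confusion_metrics(np.array([1, 0]), np.array([1, 1]))
        assert m["sp"] is None and m["sn"] is not None

    def test_identities_hold_on_random_tables(self, rng):
        # TP+FN = #pos, TN+FP = #neg, Acc = (TP+TN)/N exactly
        for _ in range(50):
            n = int(rng.integers(2, 30))
            truth = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            m = confusion_metrics(pred, truth)
            assert m["tp"] + m["fn"] == (truth == 1).sum()
            assert m["tn"] + m["fp"] == (truth == 0).sum()
            assert m["acc"] == (m["tp"] + m["tn"]) / n
            if m["sn"] is not None:
                assert m["sn"] == m["tp"] / (m["tp"] + m["fn"])
            if m["sp"] is not None:
                assert m["sp"] == m["tn"] / (m["tn"] + m["fp"])


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 5.0, 6.0])
        truth = np.array([0, 0, 1, 1])
        _, auc = roc_auroc(scores, truth)
        assert auc == pytest.approx(1.0)

    def test_identical_scores_are_chance(self):
        scores = np.zeros(10)
        truth = np.array([0, 1] * 5)
        _, auc = roc_auroc(scores, truth)
        assert auc == pytest.approx(0.5)

    def test_enumerated_four_pair_example(self):
        # pos {2, 3}, neg {1, 2.5}: 3 winning pairs of 4
        scores = np.array([2.0, 3.0, 1.0, 2.5])
        truth = np.array([1, 1, 0, 0])
        _, auc = roc_auroc(scores, truth)
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=50)
        truth = rng.integers(0, 2, size=50)
        pts = roc_points(scores, truth)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= -1e-12).all()
        assert (np.diff(pts[:, 1]) >= -1e-12).all()

    def test_trapezoid_equals_pairwise_rank_oracle(self, rng):
        # 50 random score sets, discrete values to force ties
        for _ in range(50):
            n = int(rng.integers(4, 40))
            truth = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
            scores = rng.integers(0, 6, size=n).astype(float)
            _, auc = roc_auroc(scores, truth)
            assert auc == pytest.approx(rank_auroc(scores, truth), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            truth = np.concatenate([[0, 1], rng.integers(0, 2, size=30)])
            scores = rng.normal(size=32).round(1)
            _, auc = roc_auroc(scores, truth)
            assert auc == pytest.approx(roc_auc_score(truth, scores),
                                        abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auroc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestJackknife:
    def test_separable_data_is_perfect(self, tiny_separable):
        rep = jackknife(*tiny_separable)
        assert rep.acc == 1.0 and rep.auroc == 1.0

    def test_per_sample_has_one_row_per_input(self, tiny_separable):
        fm, labels = tiny_separable
        rep = jackknife(fm, labels)
        assert len(rep.per_sample) == len(labels)
        assert set(rep.per_sample["id"]) == set(fm.sample_ids)

    def test_deterministic(self, tiny_separable):
        a = jackknife(*tiny_separable).to_json()
        b = jackknife(*tiny_separable).to_json()
        assert a == b

    def test_permutation_invariance(self, rng):
        X = rng.random((12, 3))
        labels = np.array([0, 1] * 6)
        fm = fm_of(X)
        rep = jackknife(fm, labels)
        perm = rng.permutation(12)
        rep_p = jackknife(fm.rows(perm), labels[perm])
        a = rep.per_sample.set_index("id")["score"]
        b = rep_p.per_sample.set_index("id")["score"]
        np.testing.assert_allclose(a[b.index], b, atol=1e-12)
        assert rep.acc == rep_p.acc and rep.auroc == pytest.approx(rep_p.auroc)

    def test_duplicated_samples_score_identically(self, rng):
        # exchangeability: in a dataset where every sample appears twice,
        # both copies are held out against identical training sets (up to
        # row order) and must receive the same scores and predictions
        X = rng.random((8, 2))
        labels = np.array([0, 1] * 4)
        dup = fm_of(np.vstack([X, X]),
                    ids=[f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)])
        rep_dup = jackknife(dup, np.tile(labels, 2))
        scores = rep_dup.per_sample["score"].to_numpy()
        preds = rep_dup.per_sample["pred"].to_numpy()
        np.testing.assert_allclose(scores[:8], scores[8:], atol=1e-9)
        np.testing.assert_array_equal(preds[:8], preds[8:])

    def test_too_small_inputs_rejected(self, tiny_separable):
        fm, labels = tiny_separable
        with pytest.raises(EvaluationError):
            jackknife(fm.rows([0, 1]), labels[:2])
        with pytest.raises(EvaluationError):
            jackknife(fm.rows([0, 1, 3]), np.array([0, 0, 1]))

    def test_tuned_theta_policy_runs(self, tiny_separable):
        rep = jackknife(*tiny_separable, theta="tune")
        assert rep.theta_used == "per-fold-tuned"
        assert len(rep.per_fold_thetas) == 6
        assert rep.acc == 1.0


class TestKfold:
    def test_k_equal_n_reduces_to_jackknife(self, rng):
        X = rng.random((10, 3))
        labels = np.array([0, 1] * 5)
        fm = fm_of(X)
        jk = jackknife(fm, labels)
        kf = kfold(fm, labels, k=10, seed=0)
        a = jk.per_sample.set_index("id")["score"]
        b = kf.per_sample.set_index("id")["score"]
        np.testing.assert_allclose(a, b[a.index], atol=1e-12)

    def test_seed_determinism_and_seed_sensitivity(self, rng):
        X = rng.random((30, 4))
        labels = np.array([0, 1] * 15)
        fm = fm_of(X)
        assert (kfold(fm, labels, k=5, seed=3).to_json()
                == kfold(fm, labels, k=5, seed=3).to_json())
        a = kfold(fm, labels, k=5, seed=3).per_sample["score"]
        b = kfold(fm, labels, k=5, seed=4).per_sample["score"]
        assert not np.allclose(a, b)

    def test_each_sample_tested_exactly_once(self, rng):
        labels = np.array([0] * 13 + [1] * 7)
        folds = stratified_fold_indices(labels, 4, seed=0)
        combined = np.concatenate(folds)
        assert sorted(combined) == list(range(20))

    def test_fold_sizes_differ_by_at_most_one_per_class(self):
        labels = np.array([0] * 13 + [1] * 7)
        folds = stratified_fold_indices(labels, 4, seed=1)
        for cls in (0, 1):
            sizes = [int((labels[f] == cls).sum()) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_fold_indices(np.array([0, 1, 0, 1]), 5, seed=0)


class TestIndependentTest:
    def test_all_positive_set(self, tiny_separable):
        fm, labels = tiny_separable
        res = GaussianNaiveBayes(fm, labels).fit()
        ind = fm_of([[0.88], [0.12], [0.95]], ids=["q1", "q2", "q3"])
        rep = independent_test(res, ind)
        assert rep.sp is None  # no negatives in an all-positive set
        assert rep.n_correct == rep.tp == 2
        assert rep.per_sample["call"].tolist() == [
            "Antioxidant", "Nonantioxidant", "Antioxidant",
        ]

    def test_input_order_preserved(self, tiny_separable):
        fm, labels = tiny_separable
        res = GaussianNaiveBayes(fm, labels).fit()
        ind = fm_of([[0.9], [0.1]], ids=["z", "a"])
        rep = independent_test(res, ind)
        assert rep.per_sample["id"].tolist() == ["z", "a"]

    def test_empty_set_rejected(self, tiny_separable):
        fm, labels = tiny_separable
        res = GaussianNaiveBayes(fm, labels).fit()
        with pytest.raises(EvaluationError, match="empty"):
            independent_test(res, fm_of(np.empty((0, 1))))

    def test_feature_mismatch_surfaces(self, tiny_separable):
        from antioxseq.naive_bayes import ModelError

        fm, labels = tiny_separable
        res = GaussianNaiveBayes(fm, labels).fit()
        with pytest.raises(ModelError):
            independent_test(res, fm_of(np.zeros((2, 3))))


class TestEvalReport:
    def test_summary_and_json(self, tiny_separable):
        rep = jackknife(*tiny_separable)
        text = rep.summary()
        assert "jackknife" in text and "auROC" in text
        payload = rep.to_dict()
        assert payload["tp"] + payload["fn"] == 3

    def test_roc_tsv_export(self, tmp_path, tiny_separable):
        rep = jackknife(*tiny_separable)
        path = tmp_path / "roc.tsv"
        rep.roc_to_tsv(path)
        header = path.read_text().splitlines()[0]
        assert header == "fpr\ttpr"

    def test_plot_roc_returns_axes(self, tiny_separable):
        import matplotlib

        matplotlib.use("Agg")
        rep = jackknife(*tiny_separable)
        ax = rep.plot_roc()
        assert ax.get_xlabel().startswith("false positive")
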