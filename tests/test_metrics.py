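import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protstab.dataset import Dataset
from protstab.encoding import EncodingSpec
from protstab.metrics import (
    ConfusionCounts,
    EvalReport,
    MetricsError,
    accuracy,
    auc,
    confusion,
    crossvalidate,
    mcc,
    prediction_strength,
    roc_auc,
    roc_curve,
    sensitivity,
    specificity,
    stratified_folds,
)
from protstab.model import TrainConfig


def pair_count_auc(scores, y):
    """Independent oracle: Mann-Whitney pair counting, ties scored 1/2."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion(np.array([1, 1, -1, -1]), np.array([1, 1, -1, -1]))
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        c = confusion(np.array([1, -1]), np.array([1, 1]))
        assert (c.tp, c.fp) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricsError):
            confusion(np.array([1, -1]), np.array([1]))

    def test_total_matches_input_size(self):
        rng = np.random.default_rng(0)
        y = rng.choice([-1, 1], 37)
        p = rng.choice([-1, 1], 37)
        assert confusion(y, p).total == 37


class TestRates:
    def test_perfect(self):
        c = ConfusionCounts(tp=1, tn=1, fp=0, fn=0)
        assert accuracy(c) == 100.0
        assert sensitivity(c) == 100.0
        assert specificity(c) == 100.0

    def test_all_wrong(self):
        assert accuracy(ConfusionCounts(0, 0, 1, 1)) == 0.0

    def test_hand_computed_cells(self):
        c = ConfusionCounts(tp=3, tn=1, fp=1, fn=1)
        assert accuracy(c) == pytest.approx(100 * 4 / 6)
        assert sensitivity(c) == pytest.approx(75.0)
        assert specificity(c) == pytest.approx(50.0)

    def test_undefined_rates_are_none_not_zero(self):
        assert sensitivity(ConfusionCounts(0, 3, 1, 0)) is None
        assert specificity(ConfusionCounts(2, 0, 0, 1)) is None


class TestPredictionStrength:
    # published sensitivity/specificity pairs with their tabulated averages
    @pytest.mark.parametrize(
        "sn,sp,expected",
        [
            (75.62, 84.94, 80.28),
            (72.19, 87.15, 79.67),
            (74.83, 73.49, 74.16),
            (76.43, 82.83, 79.63),
            (74.10, 86.98, 80.54),
            (68.00, 90.30, 79.15),
        ],
    )
    def test_tabulated_rows(self, sn, sp, expected):
        assert round(prediction_strength(sn, sp), 2) == expected

    @given(st.floats(0, 100))
    def test_identity_when_balanced(self, x):
        assert prediction_strength(x, x) == x


class TestMcc:
    def test_perfect_classifier(self):
        assert mcc(ConfusionCounts(5, 5, 0, 0)) == 1.0

    def test_inverted_classifier(self):
        assert mcc(ConfusionCounts(0, 0, 5, 5)) == -1.0

    def test_uninformative_classifier(self):
        assert mcc(ConfusionCounts(5, 5, 5, 5)) == 0.0

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 5, 0, 5)) == 0.0

    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30),
            st.integers(0, 30), st.integers(0, 30),
        )
    )
    def test_bounded(self, cells):
        tp, tn, fp, fn = cells
        if tp + tn + fp + fn == 0:
            return
        assert -1.0 <= mcc(ConfusionCounts(tp, tn, fp, fn)) <= 1.0

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(3)
        y = rng.choice([-1, 1], 60)
        p = rng.choice([-1, 1], 60)
        ours = mcc(confusion(y, p))
        assert ours == pytest.approx(matthews_corrcoef(y, p))


class TestRoc:
    def test_perfect_separation_passes_through_top_left(self):
        pts = roc_curve(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, -1, -1]))
        coords = {(p.fpr, p.tpr) for p in pts}
        assert (0.0, 1.0) in coords
        assert auc(pts) == 1.0

    def test_all_tied_scores_give_diagonal(self):
        pts = roc_curve(np.zeros(6), np.array([1, 1, 1, -1, -1, -1]))
        assert [(p.fpr, p.tpr) for p in pts] == [(0.0, 0.0), (1.0, 1.0)]
        assert auc(pts) == 0.5

    def test_four_instance_sweep(self):
        # pos scores {0.9, 0.4}, neg {0.5, 0.1}: enumerated by hand
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        y = np.array([1, 1, -1, -1])
        pts = roc_curve(scores, y)
        coords = [(p.fpr, p.tpr) for p in pts]
        assert (0.0, 0.5) in coords
        assert (0.5, 1.0) in coords
        assert auc(pts) == pytest.approx(0.75)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40).round(1)  # force ties
        y = np.array([1] * 20 + [-1] * 20)
        pts = roc_curve(scores, y)
        assert (pts[0].fpr, pts[0].tpr) == (0.0, 0.0)
        assert (pts[-1].fpr, pts[-1].tpr) == (1.0, 1.0)
        assert all(b.fpr >= a.fpr and b.tpr >= a.tpr
                   for a, b in zip(pts, pts[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(MetricsError):
            roc_curve(np.array([1.0, 2.0]), np.array([1, 1]))

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_trapezoid_auc_equals_pair_counting(self, data):
        n = data.draw(st.integers(4, 50))
        # coarse grid scores force frequent ties
        scores = np.array(
            data.draw(st.lists(st.integers(-5, 5), min_size=n, max_size=n)),
            dtype=float,
        )
        n_pos = data.draw(st.integers(1, n - 1))
        y = np.array([1] * n_pos + [-1] * (n - n_pos))
        assert roc_auc(scores, y) == pytest.approx(pair_count_auc(scores, y))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.normal(size=80)
        y = rng.choice([-1, 1], 80)
        assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))


class TestEvalReport:
    def test_st_is_mean_of_sn_sp(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=100)
        y = rng.choice([-1, 1], 100)
        rep = EvalReport.from_scores(scores, y)
        assert rep.st == (rep.sn + rep.sp) / 2

    def test_score_zero_is_positive_call(self):
        rep = EvalReport.from_scores(
            np.array([0.0, -0.1]), np.array([1, -1])
        )
        assert rep.counts.tp == 1 and rep.counts.tn == 1


class TestCrossvalidate:
    def test_partition_and_determinism(self, registry, small_dataset):
        spec = EncodingSpec(window_size=5, features=("Co", "No"))
        cfg = TrainConfig(seed=11)
        rep1, tab1 = crossvalidate(small_dataset, spec, cfg, registry, k=5)
        rep2, tab2 = crossvalidate(small_dataset, spec, cfg, registry, k=5)
        # every instance predicted exactly once, in dataset order
        assert list(tab1["index"]) == list(range(len(small_dataset)))
        assert rep1.n == len(small_dataset)
        # same seed -> identical folds and report
        assert tab1.equals(tab2)
        assert rep1.to_row() == rep2.to_row()

    def test_fold_sizes_stratified(self, registry, small_dataset):
        spec = EncodingSpec(window_size=1, features=("Co",))
        cfg = TrainConfig(seed=2)
        _, tab = crossvalidate(small_dataset, spec, cfg, registry, k=5)
        for cls in (1, -1):
            sizes = tab[tab["label"] == cls].groupby("fold").size()
            assert len(sizes) == 5
            assert sizes.max() - sizes.min() <= 1

    def test_k_larger_than_class_rejected(self, registry, small_dataset):
        y = np.array([1] * 3 + [-1] * 10)
        with pytest.raises(MetricsError):
            stratified_folds(y, 5, seed=0)
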