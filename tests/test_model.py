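import numpy as np
import pandas as pd
import pytest

from protstab.dataset import MutationInstance
from protstab.encoding import EncodingSpec, encode_dataset
from protstab.model import (
    ModelError,
    Prediction,
    StabilityModel,
    StabilityResults,
    TrainConfig,
    confidence_table_from_scores,
    lookup_confidence,
    rbf_kernel,
    train_svc,
)


class TestRbfKernel:
    def test_zero_distance_gives_one(self):
        x = np.array([0.3, 0.7, 0.1])
        for gamma in (0.1, 0.8, 5.0):
            assert rbf_kernel(x, x, gamma) == 1.0

    def test_hand_computed_value(self):
        # ||(0,0)-(1,1)||^2 = 2, gamma 0.5 -> exp(-1)
        v = rbf_kernel(np.zeros(2), np.ones(2), 0.5)
        assert v == pytest.approx(np.exp(-1.0))

    def test_small_gamma_limit(self):
        x1, x2 = np.array([0.0, 0.0]), np.array([5.0, -3.0])
        assert rbf_kernel(x1, x2, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(size=6)
            k = rbf_kernel(a, b, 0.8)
            assert k == rbf_kernel(b, a, 0.8)
            assert 0.0 < k <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelError):
            rbf_kernel(np.zeros(2), np.zeros(3), 0.5)


class TestTrainSvc:
    def separable(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [np.ones((20, 4)) + rng.normal(0, 0.05, (20, 4)),
             np.zeros((20, 4)) + rng.normal(0, 0.05, (20, 4))]
        )
        y = np.array([1] * 20 + [-1] * 20)
        return X, y

    def test_separable_toy_set_reaches_full_training_accuracy(self):
        X, y = self.separable()
        svc = train_svc(X, y, TrainConfig())
        assert (svc.predict(X) == y).all()

    def test_retraining_reproduces_decision_values(self):
        X, y = self.separable()
        cfg = TrainConfig(seed=5)
        probe = np.random.default_rng(2).random((10, 4))
        d1 = train_svc(X, y, cfg).decision_function(probe)
        d2 = train_svc(X, y, cfg).decision_function(probe)
        assert np.array_equal(d1, d2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ModelError, match="single class"):
            train_svc(X, np.ones(10, dtype=int), TrainConfig())

    def test_nan_features_rejected(self):
        X, y = self.separable()
        X[0, 0] = np.nan
        with pytest.raises(ModelError, match="non-finite"):
            train_svc(X, y, TrainConfig())

    def test_threshold_semantics(self):
        X, y = self.separable()
        svc = train_svc(X, y, TrainConfig())
        d = svc.decision_function(X)
        # +inf threshold -> nothing positive; -inf -> everything positive
        assert np.sum(d >= np.inf) == 0
        assert np.sum(d >= -np.inf) == len(d)
        # predicted-positive set shrinks monotonically as threshold rises
        counts = [np.sum(d >= t) for t in np.sort(d)]
        assert counts == sorted(counts, reverse=True)


class TestConfidenceTable:
    def table(self):
        scores = np.array([2.0, 1.0, 0.5, -0.5, -1.0, -2.0])
        y = np.array([1, 1, -1, 1, -1, -1])
        return confidence_table_from_scores(scores, y)

    def test_monotonicity_invariants(self):
        t = self.table()
        thr = t["threshold"].to_numpy()
        assert np.all(np.diff(thr) < 0)
        assert np.all(np.diff(t["sn"].to_numpy()) >= 0)
        assert np.all(np.diff(t["sp"].to_numpy()) <= 0)

    def test_boundary_confidences(self):
        t = self.table()
        # below every tabulated threshold: SN = 1 -> confidence 0
        assert lookup_confidence(t, -10.0, positive=True) == 0.0
        # above every threshold: SP = 1 -> confidence 0 for a negative call
        assert lookup_confidence(t, 10.0, positive=False) == 0.0
        # deep positive score -> SN at that threshold is small -> high conf
        assert lookup_confidence(t, 2.0, positive=True) == pytest.approx(1 - 1 / 3)

    def test_interior_formula(self):
        t = self.table()
        # score 0.5 as positive call: nearest threshold <= 0.5 is 0.5,
        # where SN = 2/3 -> confidence 1/3
        assert lookup_confidence(t, 0.5, positive=True) == pytest.approx(1 / 3)
        # score -0.7 as negative call: nearest threshold >= -0.7 is -0.5,
        # where SP = 2/3 -> confidence 1/3
        assert lookup_confidence(t, -0.7, positive=False) == pytest.approx(1 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            confidence_table_from_scores(np.array([1.0]), np.array([1]))


@pytest.fixture(scope="module")
def fitted(registry, small_dataset):
    spec = EncodingSpec(window_size=5, features=("Co", "No"))
    model = StabilityModel(
        small_dataset, spec=spec, config=TrainConfig(seed=3), registry=registry
    )
    return model.fit(k=5)


class TestStabilityResults:
    def test_fit_carries_cv_report_and_calibration(self, fitted, small_dataset):
        assert fitted.calibrated
        assert fitted.cv_report.n == len(small_dataset)
        assert fitted.metadata["n"] == len(small_dataset)

    def test_predict_returns_direction_confidence_value(self, fitted, small_dataset):
        pred = fitted.predict(small_dataset[0])
        assert isinstance(pred, Prediction)
        assert pred.direction in ("increased", "decreased")
        assert 0.0 <= pred.confidence <= 1.0
        sign_dir = "increased" if pred.decision_value >= 0 else "decreased"
        assert pred.direction == sign_dir

    def test_uncalibrated_model_still_predicts_direction(
        self, registry, small_dataset
    ):
        spec = EncodingSpec(window_size=1, features=("Co",))
        res = StabilityModel(
            small_dataset, spec=spec, registry=registry
        ).fit(calibrate=False)
        pred = res.predict(small_dataset[1])
        assert pred.confidence is None
        assert pred.direction in ("increased", "decreased")

    def test_summary_mentions_key_quantities(self, fitted):
        text = fitted.summary()
        assert "gamma" in text and "AUC" in text and "Co, No" in text

    def test_save_load_round_trip(self, fitted, small_dataset, registry, tmp_path):
        path = tmp_path / "model.joblib"
        fitted.save(path)
        loaded = StabilityResults.load(path)
        spec = fitted.spec
        X, _ = encode_dataset(small_dataset, spec, registry)
        probe = X[:100]
        assert np.array_equal(
            loaded.decision_values(probe), fitted.decision_values(probe)
        )
        p1 = fitted.predict(small_dataset[5])
        p2 = loaded.predict(small_dataset[5])
        assert p1 == p2

    def test_load_rejects_wrong_format_version(self, fitted, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        fitted.save(path)
        payload = joblib.load(path)
        payload["format_version"] = 99
        joblib.dump(payload, path)
        with pytest.raises(ModelError, match="format version"):
            StabilityResults.load(path)
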