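"""The stability-direction classifier: model and results objects.

:class:`StabilityModel` is built from a labelled mutation dataset together
with an encoding specification (window size, feature scales) and training
configuration (RBF kernel width ``gamma``, soft-margin cost ``C``).  Its
:meth:`~StabilityModel.fit` runs the pooled cross-validation for an honest
performance report, calibrates the score -> confidence table from the
out-of-fold decision values, trains a final support-vector classifier on the
full dataset, and returns a :class:`StabilityResults`.

The RBF kernel is ``K(x1, x2) = exp(-gamma * ||x1 - x2||^2)``; smaller
``gamma`` gives a smoother decision boundary, and ``C`` trades training
error against margin.  Defaults ``gamma = 0.8``, ``C = 1.0``.

Prediction confidence follows the ROC-based rule: for a query whose decision
value is ``s``, confidence is ``1 - SN(s)`` for a positive (increased
stability) call and ``1 - SP(s)`` for a negative call, where SN/SP are the
cross-validated sensitivity/specificity when ``s`` is used as the decision
threshold.  A call far into its own class's score region therefore gets
confidence near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .dataset import Dataset, MutationInstance
from .encoding import EncodingSpec, encode, encode_dataset
from .metrics import EvalReport, crossvalidate
from .scales import ScaleRegistry, load_registry

MODEL_FORMAT_VERSION = 1

#: The feature subset used by default: the six scales found to be jointly
#: optimal for this task (alpha-helix propensity, buried area, beta-sheet
#: propensity, composition, codon number, polarity).
DEFAULT_FEATURES: tuple[str, ...] = ("A", "Aa", "B", "Co", "No", "P")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """RBF-SVM training parameters."""

    gamma: float = 0.8
    C: float = 1.0
    seed: int = 1480
    class_weight: str | dict | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ModelError(f"gamma must be positive, got {self.gamma}")
        if self.C <= 0:
            raise ModelError(f"C must be positive, got {self.C}")


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, gamma: float) -> float:
    """``exp(-gamma * ||x1 - x2||^2)``; symmetric, in (0, 1]."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ModelError(f"vector length mismatch: {x1.shape} vs {x2.shape}")
    if gamma <= 0:
        raise ModelError("gamma must be positive")
    d2 = float(np.sum((x1 - x2) ** 2))
    return float(np.exp(-gamma * d2))


def train_svc(X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> SVC:
    """Fit the underlying RBF support-vector classifier.

    Requires both classes and finite features.  The libsvm solver is
    deterministic for fixed data, so retraining with the same inputs
    reproduces decision values exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ModelError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ModelError("non-finite entries in feature matrix")
    if len(np.unique(y)) < 2:
        raise ModelError("training data contains a single class")
    svc = SVC(
        kernel="rbf",
        gamma=cfg.gamma,
        C=cfg.C,
        class_weight=cfg.class_weight,
        cache_size=256,
        random_state=cfg.seed,
    )
    svc.fit(X, y)
    return svc


def confidence_table_from_scores(
    scores: np.ndarray, y_true: np.ndarray
) -> pd.DataFrame:
    """Score -> (SN, SP) table from pooled cross-validation decision values.

    One row per distinct score, thresholds strictly decreasing; predicting
    positive when ``score >= threshold``.  SN is non-decreasing and SP
    non-increasing as the threshold drops.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == -1))
    if n_pos == 0 or n_neg == 0:
        raise ModelError("confidence calibration needs both classes")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = y_true[order]
    rows = []
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            if y_sorted[j] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        rows.append(
            (float(s_sorted[i]), tp / n_pos, (n_neg - fp) / n_neg)
        )
        i = j
    return pd.DataFrame(rows, columns=["threshold", "sn", "sp"])


def lookup_confidence(table: pd.DataFrame, score: float, positive: bool) -> float:
    """Confidence of a call with decision value ``score``.

    Positive call: ``1 - SN(t)`` at the nearest tabulated threshold not
    exceeding the score (no such threshold -> SN would be 1 -> confidence 0).
    Negative call: ``1 - SP(t)`` at the nearest threshold not below the
    score (none -> SP = 1 -> confidence 0).
    """
    thr = table["threshold"].to_numpy()  # strictly decreasing
    if positive:
        idx = np.nonzero(thr <= score)[0]
        if len(idx) == 0:
            return 0.0
        return float(1.0 - table["sn"].iloc[idx[0]])
    idx = np.nonzero(thr >= score)[0]
    if len(idx) == 0:
        return 0.0
    return float(1.0 - table["sp"].iloc[idx[-1]])


@dataclass(frozen=True)
class Prediction:
    """Outcome of one query: direction, ROC-calibrated confidence (``None``
    on an uncalibrated model), and the raw decision value."""

    direction: str  # "increased" | "decreased"
    confidence: float | None
    decision_value: float


class StabilityModel:
    """Direction-of-stability-change classifier specification.

    Parameters
    ----------
    dataset : Dataset
        Labelled mutation records.
    spec : EncodingSpec, optional
        Encoding layout; defaults to an 11-residue window over the six
        default scales.
    config : TrainConfig, optional
        Kernel/regularization parameters; defaults gamma=0.8, C=1.0.
    registry : ScaleRegistry, optional
        Scale tables; defaults to the bundled registry.
    """

    def __init__(
        self,
        dataset: Dataset,
        spec: EncodingSpec | None = None,
        config: TrainConfig | None = None,
        registry: ScaleRegistry | None = None,
    ) -> None:
        self.dataset = dataset
        self.registry = registry if registry is not None else load_registry()
        self.spec = (
            spec
            if spec is not None
            else EncodingSpec(window_size=11, features=DEFAULT_FEATURES)
        )
        self.spec.validate_against(self.registry)
        self.config = config if config is not None else TrainConfig()
        self._X, self._y = encode_dataset(self.dataset, self.spec, self.registry)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        sequences: dict[str, str] | None = None,
        **kwargs,
    ) -> "StabilityModel":
        """Build from a mutation table (columns as in the TSV format)."""
        from .dataset import _build_instance, from_records

        records = [
            _build_instance(row, sequences) for row in frame.to_dict("records")
        ]
        return cls(from_records(records), **kwargs)

    @property
    def exog(self) -> np.ndarray:
        return self._X

    @property
    def endog(self) -> np.ndarray:
        return self._y

    def fit(self, k: int = 5, calibrate: bool = True) -> "StabilityResults":
        """Cross-validate, calibrate confidence, and train the final SVC."""
        cv_report = None
        cv_scores = None
        conf_table = None
        if calibrate:
            cv_report, cv_scores = crossvalidate(
                self.dataset,
                self.spec,
                self.config,
                self.registry,
                k=k,
                seed=self.config.seed,
                X=self._X,
                y=self._y,
            )
            conf_table = confidence_table_from_scores(
                cv_scores["score"].to_numpy(), cv_scores["label"].to_numpy()
            )
        svc = train_svc(self._X, self._y, self.config)
        n_pos = int(np.sum(self._y == 1))
        metadata = {
            "n": len(self._y),
            "n_positive": n_pos,
            "n_negative": len(self._y) - n_pos,
            "package_version": _pkg_version,
        }
        return StabilityResults(
            model=self,
            svc=svc,
            spec=self.spec,
            config=self.config,
            cv_report=cv_report,
            cv_scores=cv_scores,
            confidence_table=conf_table,
            metadata=metadata,
        )


@dataclass
class StabilityResults:
    """A fitted classifier plus its cross-validated diagnostics."""

    svc: SVC
    spec: EncodingSpec
    config: TrainConfig
    metadata: dict
    cv_report: EvalReport | None = None
    cv_scores: pd.DataFrame | None = field(repr=False, default=None)
    confidence_table: pd.DataFrame | None = field(repr=False, default=None)
    model: StabilityModel | None = field(repr=False, default=None)
    registry: ScaleRegistry | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.registry is None:
            self.registry = (
                self.model.registry if self.model is not None else load_registry()
            )

    @property
    def calibrated(self) -> bool:
        return self.confidence_table is not None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Signed distance-like classifier outputs; >= 0 means a positive
        (increased-stability) call, and larger is more confidently positive."""
        return self.svc.decision_function(np.asarray(X, dtype=float))

    def decision_value(self, instance: MutationInstance) -> float:
        x = encode(instance, self.spec, self.registry)
        return float(self.decision_values(x[None, :])[0])

    def predict(self, instance: MutationInstance) -> Prediction:
        """Direction (tie at score exactly 0 -> "increased", mirroring the
        ddG = 0 -> positive labelling rule) plus calibrated confidence."""
        s = self.decision_value(instance)
        positive = s >= 0
        direction = "increased" if positive else "decreased"
        conf = (
            lookup_confidence(self.confidence_table, s, positive)
            if self.calibrated
            else None
        )
        return Prediction(direction=direction, confidence=conf, decision_value=s)

    def predict_many(self, instances) -> list[Prediction]:
        return [self.predict(inst) for inst in instances]

    def summary(self) -> str:
        """Plain-text summary table of the fit and its CV performance."""
        lines = [
            "Stability direction classifier (RBF-SVM)",
            "=" * 46,
            f"features:        {', '.join(self.spec.features)}",
            f"window size:     {self.spec.window_size}",
            f"vector length:   {self.spec.vector_length}",
            f"gamma:           {self.config.gamma}",
            f"C:               {self.config.C}",
            f"training set:    {self.metadata.get('n')} instances "
            f"({self.metadata.get('n_positive')} positive / "
            f"{self.metadata.get('n_negative')} negative)",
            f"support vectors: {int(self.svc.n_support_.sum())}",
        ]
        if self.cv_report is not None:
            row = self.cv_report.to_row()
            lines += [
                "-" * 46,
                "pooled 5-fold cross-validation:",
                f"  AC  = {row['AC']:.2f} %",
                f"  SN  = {row['SN']:.2f} %",
                f"  SP  = {row['SP']:.2f} %",
                f"  ST  = {row['ST']:.2f} %",
                f"  MCC = {row['MCC']:.4f}",
                f"  AUC = {row['AUC']:.4f}",
            ]
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: str | None = None):
        """Plot the cross-validated ROC curve (matplotlib axes returned)."""
        if self.cv_report is None:
            raise ModelError("no cross-validation report to plot")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.cv_report.roc_frame()
        ax.plot(
            frame["FPR"],
            frame["TPR"],
            label=label or f"AUC = {self.cv_report.auc:.4f}",
        )
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("False positive rate (1 - SP)")
        ax.set_ylabel("True positive rate (SN)")
        ax.legend()
        return ax

    def save(self, path: str | Path) -> None:
        """Persist as a single versioned archive (joblib)."""
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "spec": self.spec,
            "config": self.config,
            "svc": self.svc,
            "confidence_table": self.confidence_table,
            "cv_report": self.cv_report,
            "metadata": self.metadata,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "StabilityResults":
        payload = joblib.load(path)
        version = payload.get("format_version") if isinstance(payload, dict) else None
        if version != MODEL_FORMAT_VERSION:
            raise ModelError(
                f"unsupported model file format version {version!r} "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        return cls(
            svc=payload["svc"],
            spec=payload["spec"],
            config=payload["config"],
            confidence_table=payload["confidence_table"],
            cv_report=payload["cv_report"],
            metadata=payload["metadata"],
        )
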