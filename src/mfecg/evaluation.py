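"""Feature assembly, cross-validated evaluation, and classifier comparison.

Each denoised segment is summarized by four features — first- and
second-moment multiscale entropy averaged over scales 10..20 (MSEN1,
MSEN2) and the singularity exponents alpha_0 and alpha_min of the
wavelet-leaders spectrum — or by the per-scale variant (11 + 11 entropies
plus the two exponents). A stratified K-fold split (K=5) trains an extreme
learning machine on 4/5 of the segments and tests on the held-out fifth;
per-fold confusion matrices are pooled and the five headline metrics
(accuracy, precision, sensitivity, specificity, F1) are computed from the
pooled matrix with the normal-sinus-rhythm class as positive.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .elm import ELMClassifier
from .entropy import MultiscaleEntropyExtractor
from .leaders import MultifractalSpectrumExtractor

__all__ = [
    "FeatureConfig",
    "SegmentFeaturizer",
    "extract_features",
    "kfold_split",
    "ConfusionMatrix",
    "evaluate",
    "EvaluationReport",
    "run_pipeline",
    "compare_classifiers",
    "POSITIVE_CLASS",
]

#: The positive class of the confusion matrix. Fixed by the published
#: tables' arithmetic: sensitivity is computed over the Normal (NSR) row.
POSITIVE_CLASS = "NSR"


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters (defaults follow the reference setup)."""

    scale_lo: int = 10
    scale_hi: int = 20
    m: int = 2
    r_frac: float = 0.15
    wavelet: str = "db3"
    qmax: float = 5.0
    dq: float = 0.25
    j1: int = 1
    mode: str = "aggregated"  # or "per-scale"

    @property
    def scales(self) -> tuple:
        return tuple(range(self.scale_lo, self.scale_hi + 1))

    @property
    def n_features(self) -> int:
        per = len(self.scales)
        return 4 if self.mode == "aggregated" else 2 * per + 2


class SegmentFeaturizer:
    """Transformer assembling (MSEN1, MSEN2, alpha_0, alpha_min) per segment.

    Accepts a list of 1-D sample arrays (or objects with a ``samples``
    attribute). Rows with undefined entropy features carry NaN and should
    be dropped (with logging) before classification.
    """

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config or FeatureConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self.config
        agg = cfg.mode == "aggregated"
        mse1 = MultiscaleEntropyExtractor(scales=cfg.scales, m=cfg.m,
                                          r_frac=cfg.r_frac, moment=1,
                                          aggregate=agg)
        mse2 = MultiscaleEntropyExtractor(scales=cfg.scales, m=cfg.m,
                                          r_frac=cfg.r_frac, moment=2,
                                          aggregate=agg)
        mfa = MultifractalSpectrumExtractor(wavelet=cfg.wavelet,
                                            qmax=cfg.qmax, dq=cfg.dq,
                                            j1=cfg.j1,
                                            features=("alpha_0", "alpha_min"))
        arrays = [np.asarray(getattr(x, "samples", x), dtype=float)
                  for x in X]
        return np.hstack([mse1.fit_transform(arrays),
                          mse2.fit_transform(arrays),
                          mfa.fit_transform(arrays)])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)


def extract_features(seg, config: FeatureConfig | None = None) -> np.ndarray:
    """Feature vector of one denoised segment (see :class:`SegmentFeaturizer`)."""
    return SegmentFeaturizer(config).transform([seg])[0]


def kfold_split(n: int, K: int = 5, seed: int | None = None,
                labels=None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold partition of ``range(n)``.

    Folds are disjoint, exhaustive, and per-class sizes differ by at most
    one; identical seed gives identical folds.
    """
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    labels = np.zeros(n) if labels is None else np.asarray(labels)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    return [(train, test) for train, test in skf.split(np.zeros((n, 1)),
                                                       labels)]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is Normal (NSR)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _pct(num: float, den: float) -> float | None:
    """Percentage rounded half-up to 2 decimals; None on zero denominator."""
    if den == 0:
        return None
    return float(Decimal(100.0 * num / den).quantize(Decimal("0.01"),
                                                     rounding=ROUND_HALF_UP))


def evaluate(cm: ConfusionMatrix) -> dict:
    """ACC, PPV, SEN, SPE, F1 (percent, 2 decimals) from a confusion matrix.

    Undefined ratios (zero denominator) are reported as None, never as 0.
    """
    if min(cm.tp, cm.tn, cm.fp, cm.fn) < 0:
        raise ValueError("confusion-matrix counts must be non-negative")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "ACC": _pct(cm.tp + cm.tn, cm.total),
        "PPV": _pct(cm.tp, cm.tp + cm.fp),
        "SEN": _pct(cm.tp, cm.tp + cm.fn),
        "SPE": _pct(cm.tn, cm.fp + cm.tn),
        "F1": _pct(2 * cm.tp, 2 * cm.tp + cm.fn + cm.fp),
    }


def confusion_from_labels(y_true, y_pred,
                          positive: str = POSITIVE_CLASS) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(tp=int(np.sum(pos_t & pos_p)),
                           tn=int(np.sum(~pos_t & ~pos_p)),
                           fp=int(np.sum(~pos_t & pos_p)),
                           fn=int(np.sum(pos_t & ~pos_p)))


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-fold and pooled matrices and metrics."""

    fold_matrices: list
    pooled: ConfusionMatrix
    metrics: dict
    fold_metrics: list = field(default_factory=list)
    fold_accuracy: list = field(default_factory=list)
    mean_fold_metrics: dict = field(default_factory=dict)
    n_dropped: int = 0
    runtime_s: float = 0.0
    config: dict = field(default_factory=dict)


def _drop_undefined(X: np.ndarray, y: np.ndarray):
    defined = ~np.isnan(X).any(axis=1)
    n_dropped = int((~defined).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} segments with undefined "
                      "features", stacklevel=3)
    return X[defined], y[defined], n_dropped


def run_pipeline(X, y, K: int = 5, n_hidden: int = 60,
                 seed: int | None = None,
                 config: FeatureConfig | None = None) -> EvaluationReport:
    """Stratified K-fold ELM evaluation of a feature matrix.

    ``X`` is either a precomputed feature matrix (2-D) or a list of raw
    segments, which are featurized first with ``config``. Per-fold
    confusion matrices are pooled before computing the headline metrics;
    per-fold metrics and their plain averages are reported alongside.
    """
    t0 = time.perf_counter()
    if K < 2:
        raise ValueError(f"cross-validation needs K >= 2 folds, got {K}")
    y = np.asarray(y)
    X = np.asarray(X, dtype=float) if not isinstance(X, np.ndarray) else X
    if X.ndim != 2:
        X = SegmentFeaturizer(config).transform(X)
    X, y, n_dropped = _drop_undefined(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {list(classes)}")
    if counts.min() < K:
        raise ValueError("need at least K segments per class")
    folds = kfold_split(len(y), K=K, seed=seed, labels=y)
    fold_matrices, fold_metrics, fold_acc = [], [], []
    for train, test in folds:
        if len(np.unique(y[train])) < 2:  # pragma: no cover - stratified
            raise RuntimeError("a training fold lost a class (stratification bug)")
        model = ELMClassifier(n_hidden=n_hidden, random_state=seed).fit(
            X[train], y[train])
        cm = confusion_from_labels(y[test], model.predict(X[test]))
        fold_matrices.append(cm)
        met = evaluate(cm)
        fold_metrics.append(met)
        fold_acc.append(met["ACC"])
    pooled = sum(fold_matrices[1:], fold_matrices[0])
    keys = ("ACC", "PPV", "SEN", "SPE", "F1")
    mean_fold = {
        k: float(np.mean([fm[k] for fm in fold_metrics
                          if fm[k] is not None])) for k in keys}
    return EvaluationReport(
        fold_matrices=fold_matrices, pooled=pooled, metrics=evaluate(pooled),
        fold_metrics=fold_metrics, fold_accuracy=fold_acc,
        mean_fold_metrics=mean_fold, n_dropped=n_dropped,
        runtime_s=time.perf_counter() - t0,
        config={"K": K, "n_hidden": n_hidden, "seed": seed})


def compare_classifiers(X, y, K: int = 5, n_hidden: int = 60,
                        seed: int | None = None,
                        svm_gamma: float = 0.05) -> dict:
    """Per-fold accuracies of ELM, RBF-SVM and KNN on identical folds.

    The SVM uses an RBF kernel with the given gamma; KNN uses
    K = round(sqrt(training-fold size)) neighbours. Features are z-scored
    with training-fold statistics for every classifier.
    """
    from sklearn.svm import SVC
    from sklearn.neighbors import KNeighborsClassifier

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X, y, _ = _drop_undefined(X, y)
    folds = kfold_split(len(y), K=K, seed=seed, labels=y)
    results: dict[str, dict] = {}
    for name in ("ELM", "SVM", "KNN"):
        accs, cms = [], []
        for train, test in folds:
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr, Xte = (X[train] - mu) / sd, (X[test] - mu) / sd
            if name == "ELM":
                clf = ELMClassifier(n_hidden=n_hidden, random_state=seed)
            elif name == "SVM":
                clf = SVC(kernel="rbf", gamma=svm_gamma)
            else:
                clf = KNeighborsClassifier(
                    n_neighbors=int(round(np.sqrt(len(train)))))
            clf.fit(Xtr, y[train])
            cm = confusion_from_labels(y[test], clf.predict(Xte))
            cms.append(cm)
            accs.append(evaluate(cm)["ACC"])
        pooled = sum(cms[1:], cms[0])
        results[name] = {"fold_accuracy": accs,
                         "overall_accuracy": evaluate(pooled)["ACC"]}
    return results
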