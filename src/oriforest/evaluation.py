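"""Confusion accounting, the Chou metric set, cross-validation, ROC/AUC.

Metrics follow the Chou miscount formulation: with N+ positives and N-
negatives investigated, N-+ positives missed (predicted negative) and N+-
negatives falsely called positive,

    Sn  = 1 - N-+ / N+
    Sp  = 1 - N+- / N-
    Acc = 1 - (N-+ + N+-) / (N+ + N-)
    MCC = [1 - (N-+/N+ + N+-/N-)] /
          sqrt[(1 + (N+- - N-+)/N+) (1 + (N-+ - N+-)/N-)]

which is algebraically equivalent to the classical TP/TN/FP/FN forms.
MCC is undefined (returned as ``None``, not raised) when a denominator
factor vanishes, i.e. when TP + FP = 0 or TN + FN = 0.

Cross-validation carries an explicit, mandatory *leakage policy*:

``fold-safe``
    The propensity matrix AND the forest are re-estimated from the
    training fold only; the held-out samples are encoded with that
    fold-internal matrix.  Methodologically clean; the default for new
    data.
``global``
    One propensity matrix is estimated from the full dataset and only
    the forest is re-fitted per fold.  The held-out sample leaks into
    its own encoding; this matches treating the matrix as a fixed object
    of the benchmark.

Per-fold forest seeds are derived deterministically from (master seed,
fold index) so an entire cross-validation is reproducible from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .dpsp import DPSPEncoder
from .errors import ConfigError, InputDataError, LengthMismatchError
from .model import ModelConfig, OriginForestClassifier
from .sequence_io import BenchmarkDataset

__all__ = [
    "ConfusionCounts",
    "MetricsSet",
    "CrossValResult",
    "confusion",
    "metrics",
    "jackknife",
    "kfold",
    "roc",
    "POLICIES",
]

POLICIES = ("global", "fold-safe")


@dataclass(frozen=True)
class ConfusionCounts:
    """Miscount bookkeeping in the Chou convention.

    n_minus_plus is the number of positives incorrectly predicted
    negative (missed origins); n_plus_minus the number of negatives
    incorrectly predicted positive (false alarms).
    """

    n_plus: int
    n_minus: int
    n_minus_plus: int
    n_plus_minus: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_minus_plus <= self.n_plus):
            raise InputDataError(
                f"missed-positive count {self.n_minus_plus} outside 0..{self.n_plus}"
            )
        if not (0 <= self.n_plus_minus <= self.n_minus):
            raise InputDataError(
                f"false-positive count {self.n_plus_minus} outside 0..{self.n_minus}"
            )

    # Classical aliases
    @property
    def tp(self) -> int:
        return self.n_plus - self.n_minus_plus

    @property
    def fn(self) -> int:
        return self.n_minus_plus

    @property
    def tn(self) -> int:
        return self.n_minus - self.n_plus_minus

    @property
    def fp(self) -> int:
        return self.n_plus_minus


@dataclass
class MetricsSet:
    """Sn, Sp, Acc in [0, 1]; MCC in [-1, 1] or None when undefined; AUC optional."""

    sn: float
    sp: float
    acc: float
    mcc: float | None
    auc: float | None = None

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        out = {
            "sn": self.sn * scale,
            "sp": self.sp * scale,
            "acc": self.acc * scale,
            "mcc": None if self.mcc is None else self.mcc * scale,
        }
        if self.auc is not None:
            out["auc"] = self.auc  # AUC stays on [0, 1] at every scale
        return out


def confusion(true_labels, pred_labels, *, positive=1) -> ConfusionCounts:
    """Tally Chou miscounts from aligned true/predicted binary labels."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise LengthMismatchError(
            f"true labels {t.shape} and predictions {p.shape} differ in length"
        )
    if t.size == 0:
        raise InputDataError("cannot tally an empty prediction list")
    is_pos = t == positive
    return ConfusionCounts(
        n_plus=int(is_pos.sum()),
        n_minus=int((~is_pos).sum()),
        n_minus_plus=int((is_pos & (p != positive)).sum()),
        n_plus_minus=int((~is_pos & (p == positive)).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricsSet:
    """Evaluate the Chou metric set on one set of confusion counts."""
    if c.n_plus < 1 or c.n_minus < 1:
        raise InputDataError(
            f"Sn/Sp need at least one sample per class, got "
            f"N+={c.n_plus}, N-={c.n_minus}"
        )
    sn = 1.0 - c.n_minus_plus / c.n_plus
    sp = 1.0 - c.n_plus_minus / c.n_minus
    acc = 1.0 - (c.n_minus_plus + c.n_plus_minus) / (c.n_plus + c.n_minus)
    f1 = 1.0 + (c.n_plus_minus - c.n_minus_plus) / c.n_plus
    f2 = 1.0 + (c.n_minus_plus - c.n_plus_minus) / c.n_minus
    if f1 <= 0.0 or f2 <= 0.0 or math.isclose(f1 * f2, 0.0, abs_tol=1e-15):
        mcc = None
    else:
        mcc = (1.0 - (c.n_minus_plus / c.n_plus + c.n_plus_minus / c.n_minus)) / math.sqrt(f1 * f2)
        mcc = max(-1.0, min(1.0, mcc))  # guard rounding at the exact bounds
    return MetricsSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc(scores, true_labels, *, positive=1) -> tuple[np.ndarray, float]:
    """ROC staircase and trapezoidal AUC from continuous scores.

    Points are swept over all distinct score thresholds; tied scores are
    grouped into one threshold step, so the AUC equals the Mann-Whitney
    concordance probability with ties counted half.  Returns an (m, 3)
    array of (threshold, false-positive rate, true-positive rate) rows
    and the AUC.
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise LengthMismatchError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise InputDataError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(
        y, s, pos_label=positive, drop_intermediate=False
    )
    points = np.column_stack([thresholds, fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclass
class CrossValResult:
    """Per-sample cross-validated scores plus the aggregated metric set."""

    ids: list[str]
    true_labels: np.ndarray
    scores: np.ndarray
    pred_labels: np.ndarray
    counts: ConfusionCounts
    metric_set: MetricsSet
    roc_points: np.ndarray
    policy: str
    protocol: str
    config: ModelConfig

    def summary(self, percent: bool = True) -> dict:
        out = self.metric_set.as_dict(percent=percent)
        out.update(
            policy=self.policy,
            protocol=self.protocol,
            n_pos=self.counts.n_plus,
            n_neg=self.counts.n_minus,
        )
        return out


def _fold_seed(master_seed: int, fold_index: int) -> int:
    """Deterministic per-fold forest seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(fold_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_folds(
    dataset: BenchmarkDataset,
    folds: Sequence[np.ndarray],
    config: ModelConfig,
    policy: str,
    protocol: str,
) -> CrossValResult:
    if policy not in POLICIES:
        raise ConfigError(f"unknown leakage policy {policy!r}; choose from {POLICIES}")
    records = dataset.records()
    y = np.asarray(dataset.labels())
    n = len(records)
    scores = np.full(n, np.nan, dtype=np.float64)

    if policy == "global":
        global_encoder = DPSPEncoder().fit(records, y)
        features_all = global_encoder.transform(records)

    for fold_index, test_idx in enumerate(folds):
        test_idx = np.asarray(test_idx)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_train = y[train_mask]
        if len(np.unique(y_train)) < 2:
            raise InputDataError(
                "a training fold lost one class entirely; "
                "use fewer folds or more samples per class"
            )
        if policy == "fold-safe":
            train_records = [records[i] for i in np.flatnonzero(train_mask)]
            encoder = DPSPEncoder().fit(train_records, y_train)
            x_train = encoder.transform(train_records)
            x_test = encoder.transform([records[i] for i in test_idx])
        else:
            x_train = features_all[train_mask]
            x_test = features_all[test_idx]
        clf = OriginForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            threshold=config.decision_threshold,
            random_state=_fold_seed(config.random_seed, fold_index),
        ).fit(x_train, y_train)
        scores[test_idx] = clf.vote_fractions(x_test)

    assert not np.isnan(scores).any(), "every sample must be predicted exactly once"
    preds = (scores >= config.decision_threshold).astype(int)
    counts = confusion(y, preds)
    mset = metrics(counts)
    points, auc_value = roc(scores, y)
    mset.auc = auc_value
    return CrossValResult(
        ids=[r.id for r in records],
        true_labels=y,
        scores=scores,
        pred_labels=preds,
        counts=counts,
        metric_set=mset,
        roc_points=points,
        policy=policy,
        protocol=protocol,
        config=config,
    )


def jackknife(
    dataset: BenchmarkDataset,
    config: ModelConfig,
    policy: Literal["global", "fold-safe"] = "fold-safe",
) -> CrossValResult:
    """Leave-one-out cross-validation over the whole benchmark.

    Each sample is singled out in dataset order and scored by a forest
    trained on all remaining samples; under the fold-safe policy the
    propensity matrix is also re-estimated without the held-out sample.
    Yields a unique result for a given dataset, config and policy.
    """
    if dataset.n_pos < 2 or dataset.n_neg < 2:
        raise InputDataError(
            "jackknife needs at least 2 samples per class, got "
            f"{dataset.n_pos}/{dataset.n_neg}"
        )
    n = dataset.n_pos + dataset.n_neg
    folds = [np.array([i]) for i in range(n)]
    return _run_folds(dataset, folds, config, policy, protocol="jackknife")


def kfold(
    dataset: BenchmarkDataset,
    K: int,
    config: ModelConfig,
    policy: Literal["global", "fold-safe"] = "fold-safe",
    seed: int | None = None,
) -> CrossValResult:
    """Stratified K-fold cross-validation; K = n reduces exactly to jackknife.

    ``seed`` shuffles the stratified partition (defaults to the forest
    master seed).  For K strictly between 2 and n the folds are produced
    by :class:`~sklearn.model_selection.StratifiedKFold`.
    """
    n = dataset.n_pos + dataset.n_neg
    if not 2 <= K <= n:
        raise ConfigError(f"K must lie in 2..{n}, got {K}")
    if K == n:
        result = jackknife(dataset, config, policy)
        result.protocol = f"kfold({K})"
        return result
    y = np.asarray(dataset.labels())
    splitter = StratifiedKFold(
        n_splits=K,
        shuffle=True,
        random_state=(config.random_seed if seed is None else seed) % (2**31),
    )
    folds = [test for _, test in splitter.split(np.zeros(n), y)]
    return _run_folds(dataset, folds, config, policy, protocol=f"kfold({K})")
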