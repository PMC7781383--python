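"""Nearest-zero classification, confusion metrics, ROC and repeated hold-out CV.

A fitted sPLS-DA model summarizes its training scores per class as
(mean, SD).  A new sample's component-1 score is standardized against each
class — z_c = (score - mean_c) / sd_c — and called to the class with the
smaller |z| (ties to positive: for a screening assay sensitivity is
preferred, and exact ties have probability zero on continuous data).

Repeated hold-out cross-validation mirrors the study design: draw a random
train/test partition (54/15 by default), standardize with training
parameters only, fit the model on the training side and score the held-out
side, five times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .features import FeatureStandardizer
from .splsda import SparsePLSDA

__all__ = [
    "PredictionOutcome",
    "ConfusionMatrix",
    "CvReport",
    "classify",
    "evaluate",
    "roc",
    "cross_validate",
]

NEG, POS = "neg", "pos"


@dataclass(frozen=True)
class PredictionOutcome:
    """One sample's score, per-class z-scores and final call."""

    sample_id: str
    score: float
    z_neg: float
    z_pos: float
    call: str


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts (positive = amyloid/PET positive) and metrics."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)


@dataclass
class CvReport:
    """Per-repeat confusion matrices and their arithmetic mean metrics."""

    n_repeats: int
    matrices: list[ConfusionMatrix]
    seed: int | None
    loadings: list[pd.Series] = field(default_factory=list, repr=False)
    n_resampled: int = 0

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([m.sensitivity for m in self.matrices]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([m.specificity for m in self.matrices]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.matrices]))

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "n_resampled_splits": self.n_resampled,
            "repeats": [
                {
                    "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                }
                for m in self.matrices
            ],
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "mean_accuracy": self.mean_accuracy,
        }


def classify(
    score: float,
    class_stats: dict,
    sample_id: str = "",
) -> PredictionOutcome:
    """Call one score with the nearest-zero z-score rule.

    ``class_stats`` maps class name ("neg"/"pos") to (mean, sd) of the
    training scores.  Equal |z| goes to "pos" (documented tie rule).
    """
    (m_neg, s_neg), (m_pos, s_pos) = class_stats[NEG], class_stats[POS]
    if s_neg == 0 or s_pos == 0:
        raise ValueError("degenerate training class: zero score SD")
    z_neg = (score - m_neg) / s_neg
    z_pos = (score - m_pos) / s_pos
    call = POS if abs(z_pos) <= abs(z_neg) else NEG
    return PredictionOutcome(
        sample_id=sample_id, score=float(score),
        z_neg=float(z_neg), z_pos=float(z_pos), call=call,
    )


def evaluate(calls, truth) -> ConfusionMatrix:
    """Confusion matrix and metrics from calls against true classes.

    ``calls`` may be PredictionOutcome objects or plain class labels; it is
    aligned positionally with ``truth``.  Both classes must occur in the
    truth so sensitivity and specificity are defined.
    """
    call_labels = [c.call if isinstance(c, PredictionOutcome) else c for c in calls]
    truth = list(truth)
    if len(call_labels) == 0:
        raise ValueError("no calls to evaluate")
    if len(call_labels) != len(truth):
        raise ValueError("calls and truth differ in length")
    present = set(truth)
    if present != {NEG, POS}:
        raise ValueError(
            f"truth must contain both classes, got {sorted(present)}"
        )
    tp = sum(1 for c, t in zip(call_labels, truth) if t == POS and c == POS)
    fn = sum(1 for c, t in zip(call_labels, truth) if t == POS and c == NEG)
    tn = sum(1 for c, t in zip(call_labels, truth) if t == NEG and c == NEG)
    fp = sum(1 for c, t in zip(call_labels, truth) if t == NEG and c == POS)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def roc(scores, truth) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep) and trapezoidal AUC.

    Higher score means more positive-class-like (model sign convention).
    """
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        raise ValueError("ROC needs both classes present")
    y = (truth == POS).astype(int)
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return points, float(_sk_auc(fpr, tpr))


def cross_validate(
    features: pd.DataFrame,
    labels,
    n_repeats: int = 5,
    n_train: int = 54,
    n_test: int = 15,
    keep_x=None,
    n_components: int = 1,
    seed: int | None = None,
    missing: str = "drop",
    exclude=(),
    max_resample: int = 100,
) -> CvReport:
    """Repeated random hold-out cross-validation of the full model chain.

    Per repeat: draw ``n_train`` training and ``n_test`` test samples;
    standardize both with the training means/SDs; fit
    :class:`SparsePLSDA`; call the test samples with the nearest-zero rule;
    record the confusion matrix.  A split leaving either side single-class
    is redrawn (with a warning).  ``missing`` handles no-call features:
    ``"drop"`` removes samples with any missing feature, ``"median"``
    imputes the column median.  ``exclude`` lists sample ids to leave out
    entirely (e.g. known outliers).
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    if exclude:
        keepers = ~features.index.isin(list(exclude))
        features, labels = features[keepers], labels[keepers]
    if features.isna().any().any():
        if missing == "drop":
            bad = features.index[features.isna().any(axis=1)]
            warnings.warn(
                f"dropping {len(bad)} sample(s) with missing features: "
                f"{list(map(str, bad))}",
                stacklevel=2,
            )
            features = features.drop(index=bad)
            labels = labels.drop(index=bad)
        elif missing == "median":
            features = features.fillna(features.median(axis=0))
        else:
            raise ValueError(f"unknown missing-value policy {missing!r}")
    n = features.shape[0]
    if n_train + n_test > n:
        raise ValueError(
            f"cannot split {n} samples into {n_train} train + {n_test} test"
        )
    rng = np.random.default_rng(seed)
    y = labels.to_numpy()
    matrices: list[ConfusionMatrix] = []
    loadings: list[pd.Series] = []
    n_resampled = 0
    for _ in range(n_repeats):
        for _try in range(max_resample):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train : n_train + n_test]
            if np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2:
                break
            n_resampled += 1
            warnings.warn(
                "single-class train or test split; resampling", stacklevel=2
            )
        else:
            raise RuntimeError("could not draw a two-class split")
        std = FeatureStandardizer().fit(features.iloc[tr])
        Xtr = std.transform(features.iloc[tr])
        Xte = std.transform(features.iloc[te])
        model = SparsePLSDA(
            n_components=n_components, keep_x=keep_x
        ).fit(Xtr, y[tr])
        scores = model.decision_function(Xte)
        calls = [
            classify(s, model.class_stats_, sample_id=str(features.index[j]))
            for s, j in zip(scores, te)
        ]
        matrices.append(evaluate(calls, y[te]))
        loadings.append(model.loadings_series(0))
    return CvReport(
        n_repeats=n_repeats,
        matrices=matrices,
        seed=seed,
        loadings=loadings,
        n_resampled=n_resampled,
    )
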