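"""Cq + pairwise-ratio feature matrix and train-set standardization.

For a panel of p aptamers the feature matrix holds the p raw Cq values
followed by the p(p-1)/2 one-direction pairwise ratios Cq_i / Cq_j (i < j in
panel order), 990 features for the 44-aptamer panel.  The ratio direction is
fixed by lexicographic aptamer id — numerator earlier, denominator later —
so no "B/A" feature ever coexists with "A/B"; any consistent convention is
equivalent for the model but it must be deterministic and serializable.

Standardization (zero mean, unit sample SD per feature) is fit on the
training set only and applied verbatim to test samples; zero-variance
features are dropped rather than divided by zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RatioFeatureBuilder",
    "FeatureStandardizer",
    "build_features",
    "fit_standardizer",
    "apply_standardizer",
    "cq_long_to_wide",
]


def cq_long_to_wide(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long Cq table (sample_id, aptamer_id, cq) to samples x aptamers."""
    wide = cq_table.pivot(index="sample_id", columns="aptamer_id", values="cq")
    wide.columns.name = None
    wide.index.name = "sample_id"
    return wide


class RatioFeatureBuilder(TransformerMixin, BaseEstimator):
    """Append one-direction pairwise Cq ratios to the raw Cq columns.

    ``fit`` records the panel order (sorted aptamer ids); ``transform`` maps
    a samples x aptamers Cq frame to the combined Cq + ratio frame.  A
    missing Cq (no-call, NaN) propagates to every feature involving it.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples x aptamers DataFrame")
        if X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError("need >= 2 samples and >= 1 aptamer")
        self.panel_ = sorted(map(str, X.columns))
        p = len(self.panel_)
        self.feature_names_out_ = list(self.panel_) + [
            f"{self.panel_[i]}/{self.panel_[j]}"
            for i in range(p)
            for j in range(i + 1, p)
        ]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [a for a in self.panel_ if a not in X.columns]
        if missing:
            raise ValueError(f"Cq table missing panel aptamers: {missing}")
        X = X[self.panel_].astype(float)
        p = len(self.panel_)
        denom_cols = self.panel_[1:]  # every column but the first divides
        if (X[denom_cols] == 0).any().any():
            bad = [c for c in denom_cols if (X[c] == 0).any()]
            raise ValueError(
                f"Cq of exactly 0 in denominator aptamer(s) {bad}: "
                "impossible for real cycle values, upstream data corrupt"
            )
        cols = {a: X[a] for a in self.panel_}
        for i in range(p):
            for j in range(i + 1, p):
                cols[f"{self.panel_[i]}/{self.panel_[j]}"] = (
                    X[self.panel_[i]] / X[self.panel_[j]]
                )
        out = pd.DataFrame(cols, index=X.index)
        return out[self.feature_names_out_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_)


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Per-feature (x - mean) / sd with sample SD (ddof=1), fit on training data.

    Zero-variance features are recorded in ``dropped_features_`` and removed
    from the output instead of being scaled.  ``transform`` applies the
    *training* parameters — test columns are never recentred on themselves —
    and raises if a trained feature is absent from the input.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples to standardize")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        self.feature_names_in_ = list(map(str, X.columns))
        self.dropped_features_ = [str(c) for c in X.columns[~keep]]
        self.features_ = [str(c) for c in X.columns[keep]]
        self.mean_ = mean[keep]
        self.scale_ = sd[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X, columns=self.feature_names_in_)
        missing = [f for f in self.features_ if f not in X.columns]
        if missing:
            raise ValueError(f"input lacks trained feature(s): {missing}")
        return (X[self.features_] - self.mean_) / self.scale_

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z[self.features_] * self.scale_ + self.mean_

    def to_dict(self) -> dict:
        return {
            "features": list(self.features_),
            "mean": self.mean_.tolist(),
            "sd": self.scale_.tolist(),
            "dropped_features": list(self.dropped_features_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStandardizer":
        obj = cls()
        obj.features_ = list(d["features"])
        obj.feature_names_in_ = list(d["features"]) + list(d["dropped_features"])
        obj.dropped_features_ = list(d["dropped_features"])
        obj.mean_ = pd.Series(d["mean"], index=obj.features_)
        obj.scale_ = pd.Series(d["sd"], index=obj.features_)
        return obj


def build_features(cq_wide: pd.DataFrame) -> pd.DataFrame:
    """Combined Cq + one-direction-ratio feature frame (thin wrapper)."""
    return RatioFeatureBuilder().fit(cq_wide).transform(cq_wide)


def fit_standardizer(fm: pd.DataFrame) -> tuple[pd.DataFrame, FeatureStandardizer]:
    """Fit train-set standardization and return (standardized frame, params)."""
    std = FeatureStandardizer().fit(fm)
    if std.dropped_features_:
        warnings.warn(
            f"dropped {len(std.dropped_features_)} zero-variance feature(s)",
            stacklevel=2,
        )
    return std.transform(fm), std


def apply_standardizer(
    fm_new: pd.DataFrame, params: FeatureStandardizer
) -> pd.DataFrame:
    """Standardize new samples with previously fitted training parameters."""
    return params.transform(fm_new)
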