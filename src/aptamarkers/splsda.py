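"""Sparse partial least squares discriminant analysis (sPLS-DA) from scratch.

The two-class response is coded as a single centred -1/+1 column.  Each
latent component is obtained by NIPALS with an L1 soft-thresholding step on
the X-weight vector that retains ``keep_x`` variables (the sparsity
mechanism of sPLS); X and Y are then deflated by regression on the
component score.  For one component with this Y coding the solution is
closed-form (the weight is proportional to X'y soft-thresholded), but the
NIPALS loop is kept for multi-component generality.

The estimator follows scikit-learn conventions (``fit`` / ``transform`` /
``decision_function`` / ``predict``, trailing-underscore attributes) and
classifies with the nearest-zero z-score rule: a test score is assigned to
the class whose training-score mean and SD give the smaller absolute
z-score (ties go to the positive class).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["SparsePLSDA", "soft_threshold_keep", "DEFAULT_KEEPX_GRID"]

#: keep_x grid searched (leave-one-out) when keep_x is not user-set.
DEFAULT_KEEPX_GRID = (10, 25, 50, 100, 250, 500, 961)


def soft_threshold_keep(v, keep: int) -> np.ndarray:
    """Soft-threshold ``v`` so that (at most) ``keep`` entries stay nonzero.

    The threshold is the (keep+1)-th largest absolute value (0 when
    ``keep == len(v)``); each entry shrinks towards zero by that amount and
    the result is scaled to unit Euclidean norm.  With distinct |v| exactly
    ``keep`` entries survive.  Exact ties at the threshold shrink to zero, so
    ties can only reduce the nonzero count; if *all* candidates tie away, the
    first ``keep`` indices (ranking by |v| descending, then index) are kept
    with equal weights.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("v must be 1-D")
    if not np.any(v != 0):
        raise ValueError("cannot soft-threshold an all-zero vector")
    if not 1 <= keep <= v.size:
        raise ValueError(f"keep={keep} outside 1..{v.size}")
    absv = np.abs(v)
    order = np.lexsort((np.arange(v.size), -absv))  # |v| desc, index asc
    lam = absv[order[keep]] if keep < v.size else 0.0
    w = np.sign(v) * np.maximum(absv - lam, 0.0)
    if not np.any(w != 0):  # fully tied at the threshold
        idx = order[:keep]
        w = np.zeros_like(v)
        w[idx] = np.sign(v[idx])
    return w / np.linalg.norm(w)


class SparsePLSDA(ClassifierMixin, BaseEstimator):
    """Sparse PLS-DA with soft-thresholded loadings and nearest-zero calls.

    Parameters
    ----------
    n_components : int, default 1
        Number of latent components.  The decision rule uses component 1.
    keep_x : int, sequence of int, or None
        Nonzero loadings retained per component.  None selects a single
        keep_x for all components by minimizing leave-one-out
        misclassification over ``keepx_grid`` (ties to the sparser model).
    keepx_grid : sequence of int, optional
        Grid for the automatic keep_x search (values > p are dropped; p is
        always appended).
    tol, max_iter :
        NIPALS convergence tolerance on the weight vector and iteration cap.

    Fitted attributes
    -----------------
    x_loadings_ : (p, K) array — unit-norm sparse weight vectors.
    y_loadings_ : (K,) array.
    scores_ : (n, K) array of training component scores.
    class_stats_ : dict class -> (mean, sd) of component-1 training scores.
    keep_x_ : list of int actually used per component.

    X is expected already standardized (see ``FeatureStandardizer``); the
    component-1 sign is fixed so the positive class has the larger training
    score mean.
    """

    def __init__(
        self,
        n_components: int = 1,
        keep_x=None,
        keepx_grid=None,
        tol: float = 1e-9,
        max_iter: int = 500,
    ):
        self.n_components = n_components
        self.keep_x = keep_x
        self.keepx_grid = keepx_grid
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X_arr, names = self._as_array(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"SparsePLSDA is strictly two-class; got classes {classes.tolist()}"
            )
        self.classes_ = classes  # sorted; classes_[1] is the positive class
        self.feature_names_in_ = names
        self.n_features_in_ = X_arr.shape[1]

        keep_list = self._resolve_keep_x(X_arr, y)
        W, P, Q, T = self._nipals(X_arr, y, keep_list)
        self.x_loadings_ = W
        self.x_proj_ = P
        self.y_loadings_ = Q
        self.scores_ = T
        self.keep_x_ = keep_list
        self._X_fit = X_arr
        self._y_fit = y
        self.class_stats_ = self._score_stats(T[:, 0], y)
        return self

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        return X, None

    def _y_column(self, y) -> np.ndarray:
        yc = np.where(y == self.classes_[1], 1.0, -1.0)
        return yc - yc.mean()

    def _resolve_keep_x(self, X, y) -> list[int]:
        p = X.shape[1]
        if self.keep_x is None:
            grid = self.keepx_grid or DEFAULT_KEEPX_GRID
            grid = sorted({min(k, p) for k in grid if k >= 1} | {p})
            best = self._loo_select(X, y, grid)
            return [best] * self.n_components
        if np.isscalar(self.keep_x):
            keep = [int(self.keep_x)] * self.n_components
        else:
            keep = [int(k) for k in self.keep_x]
            if len(keep) != self.n_components:
                raise ValueError("keep_x length must equal n_components")
        out = []
        for k in keep:
            if k > p:
                warnings.warn(
                    f"keep_x={k} exceeds the {p} available features; clamped",
                    stacklevel=3,
                )
                k = p
            if k < 1:
                raise ValueError("keep_x must be >= 1")
            out.append(k)
        return out

    def _loo_select(self, X, y, grid) -> int:
        """Leave-one-out misclassification per keep_x; ties to the sparsest."""
        n = X.shape[0]
        errors = {}
        for keep in grid:
            wrong = 0
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                Xtr, ytr = X[mask], y[mask]
                if np.unique(ytr).size < 2:
                    wrong += 1
                    continue
                # re-standardize the fold so the held-out row sees train stats
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0, ddof=1)
                ok = sd > 0
                sub = SparsePLSDA(
                    n_components=1, keep_x=min(keep, int(ok.sum())),
                    tol=self.tol, max_iter=self.max_iter,
                )
                sub.fit((Xtr[:, ok] - mu[ok]) / sd[ok], ytr)
                call = sub.predict(((X[i, ok] - mu[ok]) / sd[ok])[None, :])[0]
                wrong += int(call != y[i])
            errors[keep] = wrong
        best = min(grid, key=lambda k: (errors[k], k))
        return best

    def _nipals(self, X, y, keep_list):
        n, p = X.shape
        K = self.n_components
        Xk = X.copy()
        yk = self._y_column(y).copy()
        W = np.zeros((p, K))
        P = np.zeros((p, K))
        Q = np.zeros(K)
        T = np.zeros((n, K))
        for k in range(K):
            u = yk.copy()
            if not np.any(u != 0):
                raise ValueError("response deflated to zero; too many components")
            w_old = np.zeros(p)
            for _ in range(self.max_iter):
                w = Xk.T @ u
                if not np.any(w != 0):
                    raise ValueError(
                        "X carries no covariance with the response "
                        f"at component {k + 1}"
                    )
                w = soft_threshold_keep(w, keep_list[k])
                t = Xk @ w
                tt = t @ t
                if tt == 0:
                    raise ValueError(f"degenerate score at component {k + 1}")
                q = (yk @ t) / tt
                if q != 0:
                    u = yk / q
                if np.linalg.norm(w - w_old) < self.tol:
                    break
                w_old = w
            t = Xk @ w
            tt = t @ t
            q = (yk @ t) / tt
            if k == 0:
                # sign convention: positive class scores higher on average
                pos = y == self.classes_[1]
                if t[pos].mean() < t[~pos].mean():
                    w, t, q = -w, -t, -q
            pk = Xk.T @ t / tt
            W[:, k], P[:, k], Q[k], T[:, k] = w, pk, q, t
            Xk = Xk - np.outer(t, pk)
            yk = yk - t * q
        return W, P, Q, T

    @staticmethod
    def _score_stats(scores, y) -> dict:
        stats = {}
        for cls in np.unique(y):
            s = scores[y == cls]
            stats[cls] = (float(s.mean()), float(s.std(ddof=1)))
        return stats

    # ------------------------------------------------------- transformation

    def _check_fitted(self):
        if not hasattr(self, "x_loadings_"):
            raise AttributeError("SparsePLSDA instance is not fitted yet")

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names_in_ is not None:
                missing = [f for f in self.feature_names_in_ if f not in X.columns]
                if missing:
                    raise ValueError(f"X lacks trained feature(s): {missing}")
                X = X[self.feature_names_in_]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Component scores for new (already standardized) samples."""
        self._check_fitted()
        Xc = self._align(X).copy()
        T = np.zeros((Xc.shape[0], self.x_loadings_.shape[1]))
        for k in range(self.x_loadings_.shape[1]):
            t = Xc @ self.x_loadings_[:, k]
            T[:, k] = t
            Xc -= np.outer(t, self.x_proj_[:, k])
        return T

    def decision_function(self, X) -> np.ndarray:
        """Component-1 predicted value (higher = more positive-class-like)."""
        return self.transform(X)[:, 0]

    def predict(self, X) -> np.ndarray:
        """Nearest-zero z-score class calls for new samples."""
        self._check_fitted()
        scores = self.decision_function(X)
        neg, pos = self.classes_
        m_neg, s_neg = self.class_stats_[neg]
        m_pos, s_pos = self.class_stats_[pos]
        if s_neg == 0 or s_pos == 0:
            raise ValueError("degenerate training class: zero score SD")
        z_neg = np.abs((scores - m_neg) / s_neg)
        z_pos = np.abs((scores - m_pos) / s_pos)
        return np.where(z_pos <= z_neg, pos, neg)  # tie -> positive

    # ----------------------------------------------------------- filtering

    def filter_by_loading(self, cutoff: float = 0.04) -> "SparsePLSDA":
        """New model keeping only loadings with |loading| > cutoff.

        Surviving loading vectors are renormalized to unit norm and the
        training scores, deflation chain and class statistics are recomputed
        on the stored training data.  ``n_retained_`` counts the surviving
        variables (union over components).
        """
        self._check_fitted()
        W = self.x_loadings_.copy()
        mask = np.abs(W) > cutoff
        if not mask.any():
            raise ValueError(
                f"loading filter at {cutoff} removes every variable"
            )
        for k in range(W.shape[1]):
            if not mask[:, k].any():
                raise ValueError(
                    f"loading filter at {cutoff} empties component {k + 1}"
                )
            W[~mask[:, k], k] = 0.0
            W[:, k] /= np.linalg.norm(W[:, k])

        new = SparsePLSDA(
            n_components=self.n_components,
            keep_x=self.keep_x,
            keepx_grid=self.keepx_grid,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        new.classes_ = self.classes_
        new.feature_names_in_ = self.feature_names_in_
        new.n_features_in_ = self.n_features_in_
        new.keep_x_ = [int(mask[:, k].sum()) for k in range(W.shape[1])]
        # recompute scores/deflation with the filtered weights
        Xk = self._X_fit.copy()
        yk = new._y_column_like(self._y_fit)
        n, K = Xk.shape[0], W.shape[1]
        P = np.zeros_like(W)
        Q = np.zeros(K)
        T = np.zeros((n, K))
        for k in range(K):
            t = Xk @ W[:, k]
            tt = t @ t
            pk = Xk.T @ t / tt
            Q[k] = (yk @ t) / tt
            T[:, k] = t
            P[:, k] = pk
            Xk = Xk - np.outer(t, pk)
            yk = yk - t * Q[k]
        new.x_loadings_ = W
        new.x_proj_ = P
        new.y_loadings_ = Q
        new.scores_ = T
        new._X_fit = self._X_fit
        new._y_fit = self._y_fit
        new.class_stats_ = self._score_stats(T[:, 0], self._y_fit)
        new.n_retained_ = int(mask.any(axis=1).sum())
        return new

    def _y_column_like(self, y) -> np.ndarray:
        return self._y_column(y)

    # -------------------------------------------------------- serialization

    def loadings_series(self, component: int = 0) -> pd.Series:
        """Loadings of one component as a name-indexed Series."""
        self._check_fitted()
        idx = (
            self.feature_names_in_
            if self.feature_names_in_ is not None
            else range(self.n_features_in_)
        )
        return pd.Series(self.x_loadings_[:, component], index=idx)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "n_components": int(self.x_loadings_.shape[1]),
            "keep_x": [int(k) for k in self.keep_x_],
            "classes": [str(c) for c in self.classes_],
            "feature_names": self.feature_names_in_,
            "x_loadings": self.x_loadings_.tolist(),
            "x_proj": self.x_proj_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "class_stats": {
                str(c): list(v) for c, v in self.class_stats_.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SparsePLSDA":
        obj = cls(n_components=d["n_components"], keep_x=d["keep_x"])
        obj.classes_ = np.array(d["classes"])
        obj.feature_names_in_ = d["feature_names"]
        obj.x_loadings_ = np.asarray(d["x_loadings"], dtype=float)
        obj.x_proj_ = np.asarray(d["x_proj"], dtype=float)
        obj.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        obj.n_features_in_ = obj.x_loadings_.shape[0]
        obj.keep_x_ = list(d["keep_x"])
        obj.class_stats_ = {c: tuple(v) for c, v in d["class_stats"].items()}
        return obj
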