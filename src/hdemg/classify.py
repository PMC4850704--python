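"""Linear discriminant classification and the iterated balanced evaluation.

``ShrinkageLDA`` is a scikit-learn estimator implementing classical LDA with
a pooled within-class covariance ridge-regularised by ``reg * I`` and uniform
priors (training sets are balanced by construction here). Performance is
summarised by one-vs-rest accuracy, sensitivity, precision and specificity
per class; ``evaluate_iterated`` repeats a random balanced 50/50
train/validation split (default 1000 iterations), averaging the indices over
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import BalanceError, ParameterError

INDEX_NAMES = ("Acc", "S", "P", "SP")


class ShrinkageLDA(ClassifierMixin, BaseEstimator):
    """Gaussian linear discriminant with ridge-regularised pooled covariance.

    Parameters
    ----------
    reg : float
        Ridge term added to the pooled within-class covariance diagonal,
        guarding against rank deficiency. Must be > 0 for degenerate
        feature sets.
    priors : 'uniform' or array-like
        Class priors; uniform by default because the evaluation splits are
        balanced.

    Attributes
    ----------
    classes_ : ndarray of class labels, in sorted order (ties in the
        discriminant scores break toward the first label in this order).
    means_ : (n_classes, n_features) class means.
    covariance_ : pooled within-class covariance including the ridge.
    """

    def __init__(self, reg: float = 1e-6, priors="uniform"):
        self.reg = reg
        self.priors = priors

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = self.classes_.size
        if k < 2:
            raise ParameterError("need at least 2 classes")
        counts = np.bincount(y_idx, minlength=k)
        if np.any(counts < 2):
            raise ParameterError("each class needs at least 2 observations")
        n, p = X.shape
        self.means_ = np.vstack([X[y_idx == c].mean(axis=0) for c in range(k)])
        pooled = np.zeros((p, p))
        for c in range(k):
            d = X[y_idx == c] - self.means_[c]
            pooled += d.T @ d
        pooled /= n - k
        self.covariance_ = pooled + self.reg * np.eye(p)
        if isinstance(self.priors, str) and self.priors == "uniform":
            self.priors_ = np.full(k, 1.0 / k)
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
            if self.priors_.shape != (k,) or not np.isclose(self.priors_.sum(), 1.0):
                raise ParameterError("priors must be one probability per class")
        try:
            prec = np.linalg.inv(self.covariance_)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; use reg > 0"
            ) from exc
        self._coef = self.means_ @ prec
        self._intercept = (
            -0.5 * np.einsum("ij,ij->i", self._coef, self.means_)
            + np.log(self.priors_)
        )
        if not np.all(np.isfinite(self.decision_function(X))):
            raise np.linalg.LinAlgError("non-finite discriminant scores; increase reg")
        return self

    def decision_function(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.means_.shape[1]:
            raise ParameterError(
                f"X has {X.shape[1]} features, model expects {self.means_.shape[1]}"
            )
        return X @ self._coef.T + self._intercept

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def train_lda(X, y, reg: float = 1e-6) -> ShrinkageLDA:
    """Functional wrapper over :class:`ShrinkageLDA`."""
    return ShrinkageLDA(reg=reg).fit(X, y)


def predict(model: ShrinkageLDA, X):
    return model.predict(X)


def performance_indices(confusion: np.ndarray) -> pd.DataFrame:
    """One-vs-rest indices per class from a k x k count matrix.

    Per class c: TP = M[c, c]; FN = row-sum - TP; FP = column-sum - TP;
    TN = total - TP - FN - FP; then

        Acc = (TP+TN)/(TP+FP+TN+FN), S = TP/(TP+FN),
        P = TP/(TP+FP),              SP = TN/(TN+FP).

    Precision of a never-predicted class (TP+FP = 0) is NaN and excluded
    from any averaging downstream.
    """
    M = np.asarray(confusion)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ParameterError("confusion matrix must be square")
    if np.any(M < 0):
        raise ParameterError("confusion counts must be non-negative")
    total = M.sum()
    tp = np.diag(M).astype(float)
    fn = M.sum(axis=1) - tp
    fp = M.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = (tp + tn) / np.where(total > 0, total, np.nan)
        s = tp / np.where(tp + fn > 0, tp + fn, np.nan)
        p = np.where(tp + fp > 0, tp / np.where(tp + fp > 0, tp + fp, 1.0), np.nan)
        sp = tn / np.where(tn + fp > 0, tn + fp, np.nan)
    return pd.DataFrame(
        {"TP": tp, "TN": tn, "FP": fp, "FN": fn, "Acc": acc, "S": s, "P": p, "SP": sp}
    )


@dataclass
class ConfusionSummary:
    """Confusions and one-vs-rest indices accumulated over split iterations."""

    classes: np.ndarray
    confusions: np.ndarray          # n_iter x k x k
    indices: dict[str, np.ndarray]  # index name -> n_iter x k
    seed: int | None = None
    train_indices: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_iter(self) -> int:
        return self.confusions.shape[0]

    def mean(self, name: str) -> np.ndarray:
        """Per-class mean of one index over iterations (NaN-aware)."""
        return np.nanmean(self.indices[name], axis=0)

    def sd(self, name: str) -> np.ndarray:
        return np.nanstd(self.indices[name], axis=0, ddof=1)

    def macro(self, name: str) -> float:
        """Headline number: macro-average over classes of the per-class means."""
        return float(np.nanmean(self.mean(name)))

    def table(self) -> pd.DataFrame:
        rows = []
        for i, cls in enumerate(self.classes):
            row = {"class": cls}
            for name in INDEX_NAMES:
                row[f"{name}_mean"] = self.mean(name)[i]
                row[f"{name}_sd"] = self.sd(name)[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "n_iter": int(self.n_iter),
            "seed": self.seed,
            "indices": {
                name: {
                    "mean": self.mean(name).tolist(),
                    "sd": self.sd(name).tolist(),
                    "macro": self.macro(name),
                }
                for name in INDEX_NAMES
            },
            "meta": self.meta,
        }


def _balanced_split(y_idx: np.ndarray, k: int, rng: np.random.Generator, split: float):
    train, val = [], []
    for c in range(k):
        members = np.flatnonzero(y_idx == c)
        perm = rng.permutation(members)
        n_train = int(round(split * members.size))
        train.append(perm[:n_train])
        val.append(perm[n_train:])
    return np.concatenate(train), np.concatenate(val)


def evaluate_iterated(
    X,
    y,
    n_iter: int = 1000,
    split: float = 0.5,
    seed: int | None = None,
    reg: float = 1e-6,
    groups=None,
    track_train: bool = False,
) -> ConfusionSummary:
    """Iterated balanced 50/50 LDA evaluation.

    Per iteration: a random split assigning ``split`` of each class to
    training and the rest to validation (classes must have equal counts, so
    both groups stay balanced), an LDA fit, and a validation confusion
    matrix. Indices are computed per iteration and averaged afterwards. The
    RNG is fully determined by ``seed`` via spawned substreams.

    ``groups`` (optional, per observation) additionally accumulates
    per-group confusions — used for per-effort-level reporting. With
    ``track_train`` the training-set indices are accumulated too (the
    overfitting audit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    k = classes.size
    counts = np.bincount(y_idx, minlength=k)
    if np.any(counts != counts[0]):
        raise BalanceError(
            f"class counts {dict(zip(classes, counts))} unequal; subsample first"
        )
    if not (0 < split < 1):
        raise ParameterError("split fraction must lie in (0, 1)")
    groups = None if groups is None else np.asarray(groups)
    group_labels = None if groups is None else np.unique(groups)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_iter)
    confusions = np.zeros((n_iter, k, k), dtype=np.int64)
    indices = {name: np.empty((n_iter, k)) for name in INDEX_NAMES}
    train_idx_acc = (
        {name: np.empty((n_iter, k)) for name in INDEX_NAMES} if track_train else None
    )
    group_conf = (
        {g: np.zeros((n_iter, k, k), dtype=np.int64) for g in group_labels}
        if groups is not None
        else None
    )

    for it in range(n_iter):
        rng = np.random.default_rng(child_seeds[it])
        tr, va = _balanced_split(y_idx, k, rng, split)
        model = ShrinkageLDA(reg=reg).fit(X[tr], y_idx[tr])
        pred = model.predict(X[va])
        np.add.at(confusions[it], (y_idx[va], pred), 1)
        perf = performance_indices(confusions[it])
        for name in INDEX_NAMES:
            indices[name][it] = perf[name].to_numpy()
        if track_train:
            conf_tr = np.zeros((k, k), dtype=np.int64)
            np.add.at(conf_tr, (y_idx[tr], model.predict(X[tr])), 1)
            perf_tr = performance_indices(conf_tr)
            for name in INDEX_NAMES:
                train_idx_acc[name][it] = perf_tr[name].to_numpy()
        if groups is not None:
            for g in group_labels:
                m = groups[va] == g
                np.add.at(group_conf[g][it], (y_idx[va][m], pred[m]), 1)

    meta = {"split": split, "reg": reg, "aggregation": "per-iteration indices, then mean",
            "headline": "macro one-vs-rest"}
    if groups is not None:
        meta["group_confusions"] = {
            str(g): group_conf[g].sum(axis=0).tolist() for g in group_labels
        }
        with warnings.catch_warnings():
            # classes absent from a group leave all-NaN index columns
            warnings.simplefilter("ignore", RuntimeWarning)
            meta["group_indices"] = {
                str(g): {
                    name: np.nanmean(
                        np.stack(
                            [performance_indices(group_conf[g][i])[name].to_numpy()
                             for i in range(n_iter)]
                        ),
                        axis=0,
                    ).tolist()
                    for name in ("S", "P")
                }
                for g in group_labels
            }
    return ConfusionSummary(
        classes=classes, confusions=confusions, indices=indices, seed=seed,
        train_indices=train_idx_acc, meta=meta,
    )
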