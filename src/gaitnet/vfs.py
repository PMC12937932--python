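"""Voting feature selection (VFS) over four heterogeneous rankers.

Four feature-ranking methods — one-way ANOVA F statistics, |coefficients| of an
L1-penalized logistic regression, gain importances of a gradient-boosted tree
ensemble, and MultiSURF relevance — each cast one vote for their top-k
features.  Votes are aggregated and ties resolved by the sum of min-max
normalized scores across methods, with a final deterministic tie-break on the
feature name.  The retained-set size ``vfs_k`` and the logistic regularization
``vfs_lr_c`` are hyperparameters tuned by the surrounding cross-validation.

MultiSURF is implemented here directly: for each target instance the neighbor
set is defined adaptively as all instances closer than ``mu_i - sigma_i / 2``
(mean and SD of that instance's distances to all others, range-normalized
Manhattan metric); same-class neighbors (hits) decrease a feature's score by
the normalized feature difference and different-class neighbors (misses)
increase it, hits and misses each averaged within the instance so unbalanced
neighborhoods do not dominate, with miss contributions weighted by the class
prior of the miss class relative to the complement of the target's class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

__all__ = ["VFSConfig", "RankerOutput", "rank_features", "rank_multisurf",
           "vote_select", "RANKER_METHODS"]

RANKER_METHODS = ("anova_f", "l1_logistic", "gbt_importance", "multisurf")


@dataclass(frozen=True)
class VFSConfig:
    """Retained-set size, logistic regularization strength and seed."""

    vfs_k: int = 50
    vfs_lr_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vfs_k < 1:
            raise ValueError("vfs_k must be >= 1")
        if self.vfs_lr_c <= 0:
            raise ValueError("vfs_lr_c must be > 0")


@dataclass
class RankerOutput:
    """One method's raw and min-max normalized per-feature scores."""

    method: str
    raw: pd.Series
    normalized: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        raw = self.raw.astype(float)
        shifted = raw - raw.min()
        span = shifted.max()
        self.normalized = shifted / span if span > 0 else shifted * 0.0

    def top_k(self, k: int) -> list[str]:
        """The k best-scoring features (score desc, name asc)."""
        k = min(k, len(self.raw))
        order = sorted(self.raw.index, key=lambda f: (-self.raw[f], f))
        return order[:k]


def _check_labels(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("y must contain two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")


def rank_multisurf(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """MultiSURF relevance scores (adaptive neighbor threshold mu - sigma/2)."""
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y)
    n, f = Xv.shape
    if n < 4:
        raise ValueError("MultiSURF needs >= 4 instances")
    _check_labels(y)

    rng_span = Xv.max(axis=0) - Xv.min(axis=0)
    safe_span = np.where(rng_span > 0, rng_span, 1.0)
    Xn = Xv / safe_span
    Xn[:, rng_span == 0] = 0.0
    D = cdist(Xn, Xn, metric="cityblock")

    classes, counts = np.unique(y, return_counts=True)
    priors = {c: counts[k] / n for k, c in enumerate(classes)}

    scores = np.zeros(f)
    for i in range(n):
        d = np.delete(D[i], i)
        thresh = d.mean() - d.std() / 2.0
        neighbors = np.flatnonzero((D[i] < thresh) &
                                   (np.arange(n) != i))
        if neighbors.size == 0:
            continue
        diffs = np.abs(Xn[neighbors] - Xn[i])        # (n_nbr, f), in [0, 1]
        hits = y[neighbors] == y[i]
        contrib = np.zeros(f)
        if hits.any():
            contrib -= diffs[hits].mean(axis=0)
        misses = ~hits
        if misses.any():
            w = np.array([priors[c] / (1.0 - priors[y[i]])
                          for c in y[neighbors][misses]])
            contrib += (w[:, None] * diffs[misses]).sum(axis=0) / misses.sum()
        scores += contrib
    scores /= n
    return pd.Series(scores, index=X.columns)


def _rank_gbt(X: pd.DataFrame, y: np.ndarray, seed: int) -> pd.Series:
    model = XGBClassifier(n_estimators=300, max_depth=3, learning_rate=0.1,
                          random_state=seed, n_jobs=1, tree_method="hist",
                          verbosity=0, eval_metric="logloss")
    model.fit(X.to_numpy(dtype=float), y)
    gain = model.get_booster().get_score(importance_type="gain")
    scores = np.zeros(X.shape[1])
    for key, val in gain.items():
        scores[int(key[1:])] = val       # booster names features f0, f1, ...
    return pd.Series(scores, index=X.columns)


def rank_features(method: str, X: pd.DataFrame, y: np.ndarray,
                  config: VFSConfig) -> RankerOutput:
    """Score every feature with one ranking method.

    ``X`` is expected cleaned and standardized; ``y`` binary (0/1).
    """
    y = np.asarray(y)
    _check_labels(y)
    if method == "anova_f":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fvals, _ = f_classif(X.to_numpy(dtype=float), y)
        raw = pd.Series(np.nan_to_num(fvals, nan=0.0), index=X.columns)
    elif method == "l1_logistic":
        model = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                   C=config.vfs_lr_c, max_iter=2000,
                                   random_state=config.seed)
        model.fit(X.to_numpy(dtype=float), y)
        raw = pd.Series(np.abs(model.coef_[0]), index=X.columns)
    elif method == "gbt_importance":
        raw = _rank_gbt(X, y, config.seed)
    elif method == "multisurf":
        raw = rank_multisurf(X, y)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    raw = raw - min(raw.min(), 0.0)      # shift so scores are non-negative
    return RankerOutput(method=method, raw=raw)


def vote_select(X: pd.DataFrame, y: np.ndarray, config: VFSConfig
                ) -> tuple[list[str], dict]:
    """Consensus feature selection by vote counting with tie-sum resolution.

    Each method votes for its top ``vfs_k`` features; features are ordered by
    (votes desc, summed normalized score desc, name asc) and the first
    ``vfs_k`` retained.  Returns the ordered selection and an audit record
    (per-method ranks, votes, tie-sums).
    """
    k = config.vfs_k
    if k > X.shape[1]:
        warnings.warn(f"vfs_k={k} exceeds {X.shape[1]} features; clipping")
        k = X.shape[1]
    rankers = {m: rank_features(m, X, y, config) for m in RANKER_METHODS}

    votes = pd.Series(0, index=X.columns, dtype=int)
    for out in rankers.values():
        votes[out.top_k(k)] += 1
    tie_sum = sum((out.normalized for out in rankers.values()),
                  pd.Series(0.0, index=X.columns))

    order = sorted(X.columns, key=lambda f: (-votes[f], -tie_sum[f], f))
    selected = order[:k]

    audit = {
        "vfs_k": k,
        "votes": votes.to_dict(),
        "tie_sum": tie_sum.to_dict(),
        "selected": selected,
        "method_scores": {m: out.raw.to_dict() for m, out in rankers.items()},
        "method_top_k": {m: out.top_k(k) for m, out in rankers.items()},
    }
    return selected, audit
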