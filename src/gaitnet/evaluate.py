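"""Nested cross-validation of the VFS + gradient-boosted-tree pipeline.

The outer loop (stratified 10-fold, repeated 3 times by default) estimates
generalization; within each outer training split a randomized search
(20 candidate configurations by default) is scored by stratified inner
cross-validation (4 folds) on AUC, accuracy, sensitivity and specificity, the
configuration with the best inner mean AUC is refit on the full outer training
split, and evaluated once on the untouched outer test subjects.  Feature
cleaning statistics and the voting feature selection run strictly inside the
training side of each split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .explain import fold_attributions, shap_values
from .features import FeatureTable, clean
from .vfs import VFSConfig, vote_select

__all__ = ["CVConfig", "FoldResult", "nested_cv", "binary_metrics",
           "summarize_folds"]

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class CVConfig:
    """Geometry of the nested cross-validation and the random search space."""

    outer_folds: int = 10
    outer_repeats: int = 3
    inner_folds: int = 4
    search_iterations: int = 20
    vfs_k_range: tuple[int, int] = (25, 100)
    vfs_lr_c_range: tuple[float, float] = (1e-3, 1e3)
    n_estimators_range: tuple[int, int] = (100, 500)
    max_depth_range: tuple[int, int] = (2, 6)
    learning_rate_range: tuple[float, float] = (0.01, 0.3)
    subsample_range: tuple[float, float] = (0.6, 1.0)
    colsample_range: tuple[float, float] = (0.6, 1.0)
    reg_alpha_range: tuple[float, float] = (1e-3, 10.0)
    reg_lambda_range: tuple[float, float] = (1e-3, 10.0)
    cleaning: str = "outer_train"        # or "global" (statistics from all rows)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if self.search_iterations < 1:
            raise ValueError("search_iterations must be >= 1")
        if self.cleaning not in ("outer_train", "global"):
            raise ValueError("cleaning must be 'outer_train' or 'global'")


@dataclass
class FoldResult:
    """One outer fold: tuning outcome, test metrics, per-feature mean |SHAP|."""

    repeat: int
    fold: int
    best_params: dict
    selected_features: list[str]
    metrics: dict[str, float]
    shap_mean_abs: pd.Series
    shap_signed_mean_cases: pd.Series
    test_subjects: list[str] = field(default_factory=list)


def binary_metrics(y_true: np.ndarray, scores: np.ndarray,
                   prob_threshold: float = 0.5) -> dict[str, float]:
    """AUC (rank statistic, ties get half credit), accuracy, sensitivity, specificity.

    ``y_true`` is binary with 1 = positive class; predictions for the
    threshold-based metrics are ``scores >= prob_threshold``.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int(y_true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)                      # midranks: ties share credit
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pred = (scores >= prob_threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    return {
        "auc": float(auc),
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / n_pos,
        "specificity": tn / n_neg,
    }


def _sample_params(rng: np.random.Generator, cfg: CVConfig) -> dict:
    def loguni(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return {
        "vfs_k": int(rng.integers(cfg.vfs_k_range[0], cfg.vfs_k_range[1] + 1)),
        "vfs_lr_c": loguni(*cfg.vfs_lr_c_range),
        "n_estimators": int(rng.integers(cfg.n_estimators_range[0],
                                         cfg.n_estimators_range[1] + 1)),
        "max_depth": int(rng.integers(cfg.max_depth_range[0],
                                      cfg.max_depth_range[1] + 1)),
        "learning_rate": loguni(*cfg.learning_rate_range),
        "subsample": float(rng.uniform(*cfg.subsample_range)),
        "colsample_bytree": float(rng.uniform(*cfg.colsample_range)),
        "reg_alpha": loguni(*cfg.reg_alpha_range),
        "reg_lambda": loguni(*cfg.reg_lambda_range),
    }


def _make_classifier(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=params["n_estimators"], max_depth=params["max_depth"],
        learning_rate=params["learning_rate"], subsample=params["subsample"],
        colsample_bytree=params["colsample_bytree"],
        reg_alpha=params["reg_alpha"], reg_lambda=params["reg_lambda"],
        random_state=seed, n_jobs=1, tree_method="hist", verbosity=0,
        eval_metric="logloss")


def _fit_and_score(X_train: pd.DataFrame, y_train: np.ndarray,
                   X_test: pd.DataFrame, y_test: np.ndarray,
                   params: dict, seed: int) -> tuple[dict, list[str], XGBClassifier]:
    k = min(params["vfs_k"], X_train.shape[1])
    vfs_cfg = VFSConfig(vfs_k=k, vfs_lr_c=params["vfs_lr_c"], seed=seed)
    selected, _ = vote_select(X_train, y_train, vfs_cfg)
    model = _make_classifier(params, seed)
    model.fit(X_train[selected].to_numpy(dtype=float), y_train)
    scores = model.predict_proba(X_test[selected].to_numpy(dtype=float))[:, 1]
    return binary_metrics(y_test, scores), selected, model


def _fold_seed(global_seed: int, repeat: int, fold: int) -> int:
    return int((global_seed * 100003 + repeat * 1009 + fold * 13 + 7) % (2**31 - 1))


def nested_cv(table: FeatureTable, labels: pd.Series, config: CVConfig,
              pos_label: str = "PD") -> tuple[list[FoldResult], dict]:
    """Run the full nested cross-validation; returns per-fold results + summary.

    ``labels`` maps subject id to group label; ``pos_label`` is the case class.
    Preprocessing statistics (median imputation, zero-variance screen,
    z-scoring) are fit on each outer training split by default
    (``config.cleaning``), and feature selection runs only inside training
    rows, so outer test subjects never leak into tuning.
    """
    subjects = np.array(table.subjects)
    y_all = (labels.reindex(subjects).to_numpy() == pos_label).astype(int)
    if y_all.sum() == 0 or y_all.sum() == y_all.size:
        raise ValueError("both classes required")

    results: list[FoldResult] = []
    for repeat in range(config.outer_repeats):
        outer = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                                random_state=_fold_seed(config.seed, repeat, 999))
        for fold, (tr_idx, te_idx) in enumerate(outer.split(subjects, y_all)):
            seed = _fold_seed(config.seed, repeat, fold)
            rng = np.random.default_rng(seed)
            train_subjects = list(subjects[tr_idx])

            fit_rows = table.subjects if config.cleaning == "global" \
                else train_subjects
            cleaned, _ = clean(table, fit_stats_from=fit_rows)
            X = cleaned.values
            X_tr, y_tr = X.loc[train_subjects], y_all[tr_idx]
            X_te, y_te = X.iloc[te_idx], y_all[te_idx]

            candidates = [_sample_params(rng, config)
                          for _ in range(config.search_iterations)]
            inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                                    random_state=seed)
            inner_splits = list(inner.split(X_tr, y_tr))
            best_params, best_auc = None, -np.inf
            for params in candidates:
                fold_metrics = []
                try:
                    for in_tr, in_te in inner_splits:
                        m, _, _ = _fit_and_score(
                            X_tr.iloc[in_tr], y_tr[in_tr],
                            X_tr.iloc[in_te], y_tr[in_te], params, seed)
                        fold_metrics.append(m)
                except ValueError:
                    continue
                mean_auc = float(np.mean([m["auc"] for m in fold_metrics]))
                if mean_auc > best_auc:
                    best_auc, best_params = mean_auc, params

            metrics, selected, model = _fit_and_score(
                X_tr, y_tr, X_te, y_te, best_params, seed)

            all_features = list(X.columns)
            mean_abs = fold_attributions(model, X_te[selected], all_features)
            contribs, _ = shap_values(model, X_te[selected])
            case_rows = y_te == 1
            if case_rows.any():
                signed = pd.Series(contribs[case_rows].mean(axis=0),
                                   index=selected)
            else:
                signed = pd.Series(0.0, index=selected)
            signed = signed.reindex(all_features, fill_value=0.0)

            results.append(FoldResult(
                repeat=repeat, fold=fold, best_params=best_params,
                selected_features=selected, metrics=metrics,
                shap_mean_abs=mean_abs, shap_signed_mean_cases=signed,
                test_subjects=list(subjects[te_idx])))
    return results, summarize_folds(results)


def summarize_folds(results: list[FoldResult]) -> dict:
    """Mean and SD of each test metric across the outer folds."""
    summary: dict[str, dict[str, float]] = {}
    for m in METRIC_NAMES:
        vals = np.array([r.metrics[m] for r in results])
        summary[m] = {"mean": float(vals.mean()),
                      "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0}
    summary["n_folds"] = len(results)
    return summary
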