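"""Shapley-based explainability: per-fold attribution, aggregation, stability.

Per-fold attributions are exact TreeSHAP values of the gradient-boosted
classifier, computed on that fold's held-out subjects through the booster's
native per-feature prediction contributions (which satisfy the local-accuracy
axiom: contributions plus the base value sum to the model margin).  Fold-level
mean |SHAP| vectors are averaged across folds into a global importance vector
s_bar; the cumulative share C(k) of the sorted vector defines the top-95% set
(smallest prefix with C(k) >= 0.95).  Cross-fold stability of feature j is the
percentage of folds whose selected list contains j; the stable set intersects
the >= 95% stability features with the top-95% importance set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost

__all__ = ["ShapSummary", "shap_values", "fold_attributions", "aggregate_global",
           "stability", "export_body_network", "STICKMAN_COORDINATES"]

#: 2D stickman template (lateral, height) for the 23 canonical segments.
STICKMAN_COORDINATES: dict[str, tuple[float, float]] = {
    "Pelvis": (0.0, 1.00), "L5": (0.0, 1.10), "L3": (0.0, 1.20),
    "T12": (0.0, 1.30), "T8": (0.0, 1.40), "Neck": (0.0, 1.55),
    "Head": (0.0, 1.70),
    "Right Shoulder": (-0.20, 1.50), "Left Shoulder": (0.20, 1.50),
    "Right Upper Arm": (-0.25, 1.35), "Left Upper Arm": (0.25, 1.35),
    "Right Forearm": (-0.28, 1.10), "Left Forearm": (0.28, 1.10),
    "Right Hand": (-0.30, 0.95), "Left Hand": (0.30, 0.95),
    "Right Upper Leg": (-0.10, 0.75), "Left Upper Leg": (0.10, 0.75),
    "Right Lower Leg": (-0.10, 0.40), "Left Lower Leg": (0.10, 0.40),
    "Right Foot": (-0.10, 0.08), "Left Foot": (0.10, 0.08),
    "Right Toe": (-0.20, 0.04), "Left Toe": (0.20, 0.04),
}


@dataclass
class ShapSummary:
    """Global importance vector, cumulative curve, top-95% set and stability."""

    s_bar: pd.Series                 # sorted descending (name tie-break)
    cumulative: np.ndarray           # C(k), k = 1..n
    top95_set: list[str]
    stab: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    stable_set: list[str] = field(default_factory=list)


def shap_values(model, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Exact TreeSHAP contributions (n, f) and per-row base values (n,).

    For every row, contributions plus the base value equal the model's margin
    (log-odds) output.
    """
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    dmat = xgboost.DMatrix(X.to_numpy(dtype=float))
    contribs = booster.predict(dmat, pred_contribs=True)
    return contribs[:, :-1], contribs[:, -1]


def fold_attributions(model, X_test: pd.DataFrame,
                      all_features: list[str]) -> pd.Series:
    """Mean |SHAP| per feature on a fold's held-out subjects.

    ``X_test`` holds only the fold's selected features; features outside the
    selection get attribution exactly 0, so the result is defined over the full
    feature space.
    """
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    contribs, _ = shap_values(model, X_test)
    mean_abs = pd.Series(np.abs(contribs).mean(axis=0), index=X_test.columns)
    return mean_abs.reindex(all_features, fill_value=0.0)


def aggregate_global(per_fold: list[pd.Series]) -> ShapSummary:
    """Average fold-level mean |SHAP| vectors and locate the top-95% prefix."""
    if not per_fold:
        raise ValueError("need at least one fold")
    stacked = pd.concat(per_fold, axis=1).fillna(0.0)
    s_bar = stacked.mean(axis=1)
    s_bar = s_bar.iloc[np.lexsort((s_bar.index, -s_bar.to_numpy()))]
    total = float(s_bar.sum())
    if total <= 0:
        raise ValueError("total SHAP mass is zero")
    cumulative = np.cumsum(s_bar.to_numpy()) / total
    k95 = int(np.searchsorted(cumulative, 0.95 - 1e-12) + 1)
    top95 = list(s_bar.index[:k95])
    return ShapSummary(s_bar=s_bar, cumulative=cumulative, top95_set=top95)


def stability(selected_lists: list[list[str]],
              top95_set: list[str] | None = None,
              cutoff: float = 95.0) -> tuple[pd.Series, list[str]]:
    """Selection frequencies stab_j = 100 f_j / N and the stable feature set.

    ``f_j`` counts the folds whose selected list contains feature j; the stable
    set keeps features with stab_j >= cutoff that also belong to the top-95%
    importance set (all high-frequency features if no set is given).
    """
    n_folds = len(selected_lists)
    if n_folds < 1:
        raise ValueError("need at least one fold")
    counts: dict[str, int] = {}
    for lst in selected_lists:
        for f in set(lst):
            counts[f] = counts.get(f, 0) + 1
    stab = pd.Series({f: 100.0 * c / n_folds for f, c in counts.items()})
    stab = stab.iloc[np.lexsort((stab.index, -stab.to_numpy()))]
    eligible = set(top95_set) if top95_set is not None else set(stab.index)
    stable = [f for f in stab.index if stab[f] >= cutoff and f in eligible]
    return stab, stable


def _map_feature(name: str, segments: set[str]) -> tuple[str, object] | None:
    """Classify a feature as node-, edge- or un-mappable."""
    if name.startswith("A_"):
        rest = name[2:]
        for seg in segments:
            if rest.startswith(seg + "_") and rest[len(seg) + 1:] in segments:
                return "edge", (seg, rest[len(seg) + 1:])
        return None
    if "_" in name:
        _, seg = name.split("_", 1)
        if seg in segments:
            return "node", seg
    return None


def export_body_network(summary: ShapSummary,
                        signed_mean: pd.Series | None = None,
                        coordinates: dict[str, tuple[float, float]] | None = None,
                        features: list[str] | None = None) -> dict:
    """Machine-readable body-network document for stickman rendering.

    Per-segment features become weighted nodes and adjacency features become
    edges, each carrying the global importance and the direction of effect
    (sign of the case-conditional mean signed SHAP: positive = associated with
    the case class).  Features that name no segment (global metrics) are listed
    separately.  Importances of several features mapping to one node are summed.
    """
    if coordinates is None:
        coordinates = STICKMAN_COORDINATES
    segments = set(coordinates)
    if features is None:
        features = summary.top95_set

    nodes: dict[str, dict] = {}
    edges: dict[tuple[str, str], dict] = {}
    unmappable: list[dict] = []
    for name in features:
        importance = float(summary.s_bar.get(name, 0.0))
        direction = 0.0
        if signed_mean is not None and name in signed_mean.index:
            direction = float(np.sign(signed_mean[name]))
        mapped = _map_feature(name, segments)
        if mapped is None:
            unmappable.append({"feature": name, "importance": importance,
                               "direction": direction})
        elif mapped[0] == "node":
            seg = mapped[1]
            entry = nodes.setdefault(seg, {"segment": seg, "importance": 0.0,
                                           "direction": 0.0,
                                           "coordinates": list(coordinates[seg])})
            entry["importance"] += importance
            entry["direction"] += direction * importance
        else:
            pair = mapped[1]
            entry = edges.setdefault(pair, {"pair": list(pair),
                                            "importance": 0.0, "direction": 0.0})
            entry["importance"] += importance
            entry["direction"] += direction * importance
    for entry in list(nodes.values()) + list(edges.values()):
        entry["direction"] = float(np.sign(entry["direction"]))
    return {
        "nodes": sorted(nodes.values(), key=lambda e: -e["importance"]),
        "edges": sorted(edges.values(), key=lambda e: -e["importance"]),
        "unmappable": unmappable,
        "template": {seg: list(xy) for seg, xy in coordinates.items()},
    }
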