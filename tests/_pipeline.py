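"""End-to-end pipeline glue shared by the acceptance tests."""

from __future__ import annotations

import pandas as pd

from gaitnet.evaluate import CVConfig, nested_cv
from gaitnet.explain import aggregate_global, stability
from gaitnet.features import compute_cohort_features, residualize
from gaitnet.synthetic import (DISTAL_SEGMENTS, PROXIMAL_SEGMENTS, CohortSpec,
                               generate_cohort)


def run_cohort_pipeline(spec: CohortSpec, cv: CVConfig,
                        stability_cutoff: float = 95.0) -> dict:
    """Generate, featurize, residualize, cross-validate and aggregate SHAP."""
    recordings, metadata = generate_cohort(spec)
    table, _ = compute_cohort_features(recordings)
    meta = metadata.set_index("subject")
    table = residualize(table, meta["age"], meta["sex"])
    results, summary = nested_cv(table, meta["group"], cv)
    shap_summary = aggregate_global([r.shap_mean_abs for r in results])
    stab, stable = stability([r.selected_features for r in results],
                             shap_summary.top95_set, cutoff=stability_cutoff)
    signed = pd.concat([r.shap_signed_mean_cases for r in results],
                       axis=1).mean(axis=1)
    return {"table": table, "metadata": metadata, "results": results,
            "summary": summary, "shap": shap_summary, "stab": stab,
            "stable": stable, "signed": signed}


def is_distal_vel(name: str) -> bool:
    return name.startswith("vel_") and name[4:] in DISTAL_SEGMENTS


def is_proximal_adjacency_or_centrality(name: str) -> bool:
    if name.startswith("A_"):
        rest = name[2:]
        for seg in PROXIMAL_SEGMENTS:
            if rest.startswith(seg + "_") and rest[len(seg) + 1:] in PROXIMAL_SEGMENTS:
                return True
        return False
    for metric in ("degree", "strength", "clustering", "betweenness",
                   "closeness", "eigenvector", "pagerank"):
        if name.startswith(metric + "_") and name[len(metric) + 1:] in PROXIMAL_SEGMENTS:
            return True
    return False
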