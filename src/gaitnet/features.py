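"""Subject-by-feature table assembly, confound residualization and cleaning.

Feature families and naming (with S segments):

* ``pos_<Segment>`` / ``vel_<Segment>`` — position/speed magnitude IQRs (2S),
* ``A_<Seg1>_<Seg2>`` — raw (unthresholded) similarity weights, upper triangle
  in canonical order (S(S-1)/2),
* ``<metric>_<Segment>`` — threshold-averaged local graph metrics (7S),
* ``global_*`` — threshold-averaged global graph metrics (9).

With 23 segments this gives 46 + 253 + 161 + 9 = 469 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import KinematicFeatures, SegmentRecording, \
    compute_magnitudes, extract_features
from .simnet import GLOBAL_METRIC_NAMES, LOCAL_METRIC_NAMES, GraphMetricVector, \
    SubjectNetwork, ThresholdGrid, build_network, metrics_across_thresholds

__all__ = ["FeatureTable", "CleaningReport", "assemble", "residualize", "clean",
           "adjacency_feature_name", "compute_cohort_features"]


def adjacency_feature_name(seg1: str, seg2: str) -> str:
    return f"A_{seg1}_{seg2}"


@dataclass
class FeatureTable:
    """Subjects x named features with provenance flags.

    ``values`` is indexed by subject id; NaN encodes missingness.
    """

    values: pd.DataFrame
    residualized: bool = False
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate feature names: {list(dupes)}")
        all_missing = self.values.isna().all(axis=1)
        if all_missing.any():
            raise ValueError(
                f"subjects with no features: {list(self.values.index[all_missing])}")

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.residualized,
                            self.standardized)


@dataclass
class CleaningReport:
    """Which columns each cleaning rule removed, plus the fit statistics used."""

    dropped_missing: list[str] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)
    imputed: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


def assemble(kin: dict[str, KinematicFeatures],
             nets: dict[str, SubjectNetwork],
             gm: dict[str, GraphMetricVector]) -> FeatureTable:
    """Join the three feature families into one subject x feature table.

    All three inputs must cover exactly the same subjects; the segment order of
    the first subject's network fixes the adjacency column order.
    """
    subj_sets = {"kinematic": set(kin), "network": set(nets), "graph": set(gm)}
    union = set.union(*subj_sets.values())
    problems = {name: sorted(union - s) for name, s in subj_sets.items()
                if union - s}
    if problems:
        raise ValueError(f"subjects missing from inputs: {problems}")
    subjects = sorted(kin)
    ref_nodes = nets[subjects[0]].nodes

    rows = []
    for s in subjects:
        row: dict[str, float] = {}
        for seg in ref_nodes:
            row[f"pos_{seg}"] = kin[s].pos_iqr[seg]
            row[f"vel_{seg}"] = kin[s].vel_iqr[seg]
        net = nets[s]
        if net.nodes != ref_nodes:
            raise ValueError(f"subject {s}: segment set differs from reference")
        for i, a in enumerate(ref_nodes):
            for j in range(i + 1, len(ref_nodes)):
                row[adjacency_feature_name(a, ref_nodes[j])] = net.A[i, j]
        for metric in LOCAL_METRIC_NAMES:
            for seg in ref_nodes:
                row[f"{metric}_{seg}"] = gm[s].local[metric][seg]
        for metric in GLOBAL_METRIC_NAMES:
            row[metric] = gm[s].global_[metric]
        rows.append(row)
    values = pd.DataFrame(rows, index=pd.Index(subjects, name="subject"))
    return FeatureTable(values=values)


def compute_cohort_features(recordings: list[SegmentRecording],
                            grid: ThresholdGrid | None = None,
                            mode: str = "weighted",
                            distance: str = "identity"
                            ) -> tuple[FeatureTable,
                                       dict[str, SubjectNetwork]]:
    """Full per-subject feature extraction: kinematic IQRs, similarity network,
    threshold-averaged graph metrics — assembled into one table."""
    kin: dict[str, KinematicFeatures] = {}
    nets: dict[str, SubjectNetwork] = {}
    gm: dict[str, GraphMetricVector] = {}
    for rec in recordings:
        mags = compute_magnitudes(rec)
        kin[rec.subject_id] = extract_features(rec, mags)
        net = build_network(mags)
        nets[rec.subject_id] = net
        gm[rec.subject_id] = metrics_across_thresholds(net, grid=grid,
                                                       mode=mode,
                                                       distance=distance)
    return assemble(kin, nets, gm), nets


def residualize(table: FeatureTable, age: pd.Series,
                sex: pd.Series) -> FeatureTable:
    """Replace every feature by its residual from OLS on intercept + age + sex.

    Missing feature entries stay missing; the regression for each feature uses
    the subjects where that feature is observed.
    """
    subjects = table.subjects
    if len(subjects) < 3:
        raise ValueError("residualization needs at least 3 subjects")
    age = age.reindex(subjects)
    sex = sex.reindex(subjects)
    if age.isna().any() or sex.isna().any():
        missing = sorted(set(age.index[age.isna()]) | set(sex.index[sex.isna()]))
        raise ValueError(f"age/sex missing for subjects: {missing}")
    X = np.column_stack([np.ones(len(subjects)), age.to_numpy(dtype=float),
                         sex.to_numpy(dtype=float)])
    out = table.values.copy()
    vals = out.to_numpy(dtype=float)
    for k in range(vals.shape[1]):
        y = vals[:, k]
        obs = np.isfinite(y)
        if obs.sum() < 3:
            continue
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        y[obs] = y[obs] - X[obs] @ beta
    out.iloc[:, :] = vals
    return FeatureTable(values=out, residualized=True,
                        standardized=table.standardized)


def clean(table: FeatureTable, fit_stats_from: list[str] | None = None
          ) -> tuple[FeatureTable, CleaningReport]:
    """Missingness screen, median imputation, zero-variance drop, z-scoring.

    All statistics (missing fractions, medians, variances, means, SDs) are
    computed on ``fit_stats_from`` rows only (default: all rows), so inside a
    cross-validation split the held-out rows never influence them.  Columns
    with > 80% missing in the fit subset are dropped, remaining missing values
    imputed with the fit-subset median, zero-variance columns dropped, and each
    column standardized to fit-subset mean 0 / SD 1.
    """
    if fit_stats_from is None:
        fit_stats_from = table.subjects
    if len(fit_stats_from) == 0:
        raise ValueError("fit subset must be non-empty")
    vals = table.values.copy()
    fit = vals.loc[fit_stats_from]
    report = CleaningReport()

    miss_frac = fit.isna().mean(axis=0)
    report.dropped_missing = sorted(miss_frac.index[miss_frac > 0.80])
    vals = vals.drop(columns=report.dropped_missing)
    fit = fit.drop(columns=report.dropped_missing)

    medians = fit.median(axis=0)
    for col in vals.columns:
        if vals[col].isna().any():
            report.imputed[col] = float(medians[col])
            vals[col] = vals[col].fillna(medians[col])
    fit = vals.loc[fit_stats_from]

    variances = fit.var(axis=0, ddof=0)
    report.dropped_zero_variance = sorted(variances.index[variances == 0.0])
    vals = vals.drop(columns=report.dropped_zero_variance)
    fit = fit.drop(columns=report.dropped_zero_variance)

    means = fit.mean(axis=0)
    sds = fit.std(axis=0, ddof=1)
    report.means = {c: float(means[c]) for c in vals.columns}
    report.sds = {c: float(sds[c]) for c in vals.columns}
    vals = (vals - means) / sds
    cleaned = FeatureTable(values=vals, residualized=table.residualized,
                           standardized=True)
    return cleaned, report
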