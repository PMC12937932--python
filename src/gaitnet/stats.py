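"""Univariate group statistics, clinical correlation screening, power analysis.

Per-feature group differences use Welch two-sample t-tests with
Benjamini-Hochberg false-discovery-rate adjustment; demographics are compared
with Fisher's exact test (sex) and the Kruskal-Wallis rank test (age).
Spearman correlations between stable model features and clinical severity
scores flag |rho| >= 0.30 with p < 0.05 as clinically relevant.  Sensitivity
power analysis evaluates achieved power at alpha = 0.05 (two-sided) from
Cohen's w (contingency tables, noncentral chi-square) and Cohen's d (mean
differences, noncentral t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .features import FeatureTable

__all__ = ["CorrelationResult", "PowerReport", "group_tests",
           "demographic_tests", "spearman_screen", "sensitivity_power",
           "cohens_d", "cohens_w", "power_t_two_sample", "power_chi2"]

RHO_RELEVANCE = 0.30
P_RELEVANCE = 0.05


@dataclass
class CorrelationResult:
    feature: str
    clinical_score: str
    rho: float
    p_value: float

    @property
    def relevant(self) -> bool:
        return abs(self.rho) >= RHO_RELEVANCE and self.p_value < P_RELEVANCE


@dataclass
class PowerReport:
    """Achieved power for the categorical (w) and continuous (d) contrasts."""

    cohens_w: float | None = None
    power_w: float | None = None
    cohens_d: float | None = None
    power_d: float | None = None


def group_tests(table: FeatureTable, labels: pd.Series,
                pos_label: str = "PD") -> pd.DataFrame:
    """Welch t-test per feature with BH-FDR adjusted q-values."""
    y = labels.reindex(table.subjects).to_numpy() == pos_label
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    vals = table.values.to_numpy(dtype=float)
    a, b = vals[y], vals[~y]
    t, p = sst.ttest_ind(a, b, equal_var=False, nan_policy="omit")
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=table.feature_names)


def demographic_tests(metadata: pd.DataFrame,
                      pos_label: str = "PD") -> dict[str, float]:
    """Fisher exact p (sex x group) and Kruskal-Wallis p (age)."""
    case = metadata["group"] == pos_label
    tab = np.array([
        [int(((metadata["sex"] == 1) & case).sum()),
         int(((metadata["sex"] == 0) & case).sum())],
        [int(((metadata["sex"] == 1) & ~case).sum()),
         int(((metadata["sex"] == 0) & ~case).sum())],
    ])
    if tab.sum(axis=1).min() == 0:
        raise ValueError("both groups must be present")
    _, fisher_p = sst.fisher_exact(tab, alternative="two-sided")
    age_case = metadata.loc[case, "age"].to_numpy(dtype=float)
    age_ctrl = metadata.loc[~case, "age"].to_numpy(dtype=float)
    _, kw_p = sst.kruskal(age_case, age_ctrl)
    return {"fisher_sex_p": float(fisher_p), "kruskal_age_p": float(kw_p),
            "contingency": tab.tolist()}


def spearman_screen(features: pd.DataFrame,
                    clinical: pd.DataFrame) -> list[CorrelationResult]:
    """Spearman rho (midranks) between each feature and each clinical score.

    Rows are restricted to subjects with the clinical score observed (controls
    carry none); pairs with fewer than 5 complete observations are skipped.
    """
    results: list[CorrelationResult] = []
    common = features.index.intersection(clinical.index)
    for score in clinical.columns:
        sc = clinical.loc[common, score]
        for feat in features.columns:
            fv = features.loc[common, feat]
            ok = fv.notna() & sc.notna()
            if ok.sum() < 5:
                continue
            rho, p = sst.spearmanr(fv[ok], sc[ok])
            results.append(CorrelationResult(feature=feat, clinical_score=score,
                                             rho=float(rho), p_value=float(p)))
    return results


def cohens_w(table: np.ndarray) -> float:
    """Effect size w = sqrt(chi2 / N) from a contingency table (no correction)."""
    table = np.asarray(table, dtype=float)
    chi2, _, _, _ = sst.chi2_contingency(table, correction=False)
    return float(np.sqrt(chi2 / table.sum()))


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((mean1 - mean2) / pooled)


def power_t_two_sample(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Achieved power of a two-sided two-sample t-test at effect size d."""
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sst.t.ppf(1 - alpha / 2, df)
    power = (1 - sst.nct.cdf(tcrit, df, nc)) + sst.nct.cdf(-tcrit, df, nc)
    return float(power)


def power_chi2(w: float, n: int, df: int = 1, alpha: float = 0.05) -> float:
    """Achieved power of a chi-square test with noncentrality w^2 N."""
    crit = sst.chi2.ppf(1 - alpha, df)
    return float(1 - sst.ncx2.cdf(crit, df, w**2 * n))


def sensitivity_power(contingency: np.ndarray | None = None,
                      group_stats: tuple[float, float, int, float, float, int]
                      | None = None,
                      w: float | None = None, d: float | None = None,
                      n_total: int | None = None,
                      n1: int | None = None, n2: int | None = None,
                      alpha: float = 0.05) -> PowerReport:
    """Achieved power from a 2x2 table and/or group summary statistics.

    Effect sizes may also be supplied directly (``w`` with ``n_total``; ``d``
    with ``n1``/``n2``).
    """
    report = PowerReport()
    if contingency is not None:
        contingency = np.asarray(contingency, dtype=float)
        report.cohens_w = cohens_w(contingency)
        report.power_w = power_chi2(report.cohens_w, int(contingency.sum()),
                                    df=1, alpha=alpha)
    elif w is not None:
        if n_total is None:
            raise ValueError("n_total required with w")
        report.cohens_w = float(w)
        report.power_w = power_chi2(w, n_total, df=1, alpha=alpha)
    if group_stats is not None:
        m1, s1, k1, m2, s2, k2 = group_stats
        report.cohens_d = cohens_d(m1, s1, k1, m2, s2, k2)
        report.power_d = power_t_two_sample(report.cohens_d, k1, k2, alpha=alpha)
    elif d is not None:
        if n1 is None or n2 is None:
            raise ValueError("n1 and n2 required with d")
        report.cohens_d = float(d)
        report.power_d = power_t_two_sample(d, n1, n2, alpha=alpha)
    return report
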