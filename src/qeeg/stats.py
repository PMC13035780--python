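"""The trial's statistical battery.

Within-group pre/post paired t-tests, between-group independent t-tests
(pooled variance by default, mirroring the SPSS convention; Welch
selectable), chi-square tests for categorical baseline variables, Pearson
correlations between EEG features and the NIHSS improvement, and
Benjamini-Hochberg FDR correction applied within families of EEG-feature
comparisons.  All tests are two-sided; alpha = 0.05.

Family definition: one family per (contrast type x group) of EEG-feature
tests — within-experimental, within-control, and between-group-at-T1 —
with clinical (NIHSS) and baseline-comparability tests kept in their own
families, since the correction is scoped to the multiplicity of EEG
features (bands x electrodes x complexity measures), not to the clinical
endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError
from .io import SubjectRecord

ALPHA = 0.05

#: EEG feature columns eligible for testing, in reporting order.
EEG_FEATURES = ("delta", "theta", "alpha", "beta",
                "alpha_beta_ratio", "lzc", "apen")

#: Features correlated with the NIHSS improvement (experimental group, T1).
CORRELATION_FEATURES = ("alpha_beta_ratio", "lzc", "apen")


@dataclass
class StatResult:
    feature: str
    contrast: str  # e.g. within_experimental, between_T1, baseline
    statistic: float
    df: float
    p_raw: float
    q_fdr: float | None = None
    family: str = ""
    group_stats: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    # group_stats maps a label (e.g. "experimental_T0") -> (mean, sd)

    def __post_init__(self):
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValidationError(f"p_raw={self.p_raw} outside [0, 1]")


@dataclass
class CorrelationResult:
    feature: str
    r: float
    p: float
    n: int

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"r={self.r} outside [-1, 1]")


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def _mean_sd(x) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0


def paired_t(x_t0, x_t1, feature: str = "", contrast: str = "within_group"
             ) -> StatResult:
    """Classical paired t-test on matched T0/T1 values (df = n - 1)."""
    x0 = np.asarray(x_t0, dtype=float)
    x1 = np.asarray(x_t1, dtype=float)
    if x0.shape != x1.shape or x0.ndim != 1:
        raise ValidationError("paired_t needs two equal-length 1-D arrays")
    n = x0.size
    if n < 2:
        raise ValidationError("paired_t needs n >= 2")
    d = x0 - x1
    if np.std(d, ddof=1) == 0:
        raise DegenerateDataError(
            f"paired_t({feature or 'feature'}): zero-variance differences")
    res = sst.ttest_rel(x0, x1)
    return StatResult(feature, contrast, float(res.statistic), float(n - 1),
                      float(res.pvalue),
                      group_stats={"T0": _mean_sd(x0), "T1": _mean_sd(x1)})


def independent_t(group_a, group_b, pooled: bool = True, feature: str = "",
                  contrast: str = "between_group") -> StatResult:
    """Two-sample t-test; Student's pooled-variance form by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("independent_t needs n >= 2 per group")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        raise DegenerateDataError(
            f"independent_t({feature or 'feature'}): both groups constant")
    res = sst.ttest_ind(a, b, equal_var=pooled)
    df = float(a.size + b.size - 2) if pooled else float(res.df)
    return StatResult(feature, contrast, float(res.statistic), df,
                      float(res.pvalue),
                      group_stats={"a": _mean_sd(a), "b": _mean_sd(b)})


def chi_square(table, yates: bool = False, feature: str = "",
               contrast: str = "baseline") -> StatResult:
    """Pearson chi-square on a 2 x k contingency table (no continuity
    correction by default; Yates selectable)."""
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.all(t == np.rint(t)):
        raise ValidationError("contingency table must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero marginal")
    res = sst.chi2_contingency(t, correction=yates)
    return StatResult(feature, contrast, float(res.statistic),
                      float(res.dof), float(res.pvalue))


def pearson_corr(feature_values, delta_nihss, feature: str = ""
                 ) -> CorrelationResult:
    """Sample Pearson r with the two-sided t-transform p (df = n - 2)."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(delta_nihss, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("pearson_corr needs two equal 1-D arrays, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError(
            f"pearson_corr({feature or 'feature'}): zero variance input")
    res = sst.pearsonr(x, y)
    return CorrelationResult(feature, float(res.statistic),
                             float(res.pvalue), int(x.size))


def bh_fdr(p_values, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed within each family.

    q(i) = min_{j >= i} (m * p(j) / j) on the family's sorted p-values;
    monotone in p within a family and bounded by 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if family_labels is None:
        family_labels = np.zeros(p.size)
    labels = np.asarray(family_labels)
    if labels.shape != p.shape:
        raise ValidationError("family_labels must match p_values in length")
    q = np.empty_like(p)
    for fam in np.unique(labels):
        mask = labels == fam
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def delta_nihss(record: SubjectRecord) -> int:
    """NIHSS improvement, NIHSS_T0 - NIHSS_T1 (negative = worsening)."""
    t0, t1 = record.nihss_t0, record.nihss_t1
    if t0 is None or t1 is None:
        raise ValidationError(f"{record.subject_id}: missing NIHSS score")
    return int(t0) - int(t1)


# ---------------------------------------------------------------------------
# Cohort-level battery
# ---------------------------------------------------------------------------

@dataclass
class StatReport:
    results: list[StatResult]
    correlations: list[CorrelationResult]

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            labels = list(r.group_stats)
            (ma, sa) = r.group_stats.get(labels[0], (np.nan, np.nan)) \
                if labels else (np.nan, np.nan)
            (mb, sb) = r.group_stats.get(labels[1], (np.nan, np.nan)) \
                if len(labels) > 1 else (np.nan, np.nan)
            rows.append({
                "contrast": r.contrast, "feature": r.feature,
                "family": r.family, "stat": r.statistic, "df": r.df,
                "p_raw": r.p_raw, "q_fdr": r.q_fdr,
                "mean_a": ma, "sd_a": sa, "mean_b": mb, "sd_b": sb,
            })
        return pd.DataFrame(rows)

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"feature": c.feature, "r": c.r, "p": c.p, "n": c.n}
             for c in self.correlations])

    def lookup(self, contrast: str, feature: str) -> StatResult:
        for r in self.results:
            if r.contrast == contrast and r.feature == feature:
                return r
        raise KeyError((contrast, feature))


def _paired_frame(hemi: pd.DataFrame, group: str, feature: str):
    sub = hemi[hemi["group"] == group]
    wide = sub.pivot(index="subject_id", columns="session", values=feature)
    wide = wide.dropna()
    return wide["T0"].to_numpy(), wide["T1"].to_numpy()


def analyze_cohort(hemi: pd.DataFrame, subjects: Sequence[SubjectRecord],
                   features: Sequence[str] | None = None,
                   pooled_t: bool = True) -> StatReport:
    """Run the full battery on a hemisphere-summary feature table.

    ``hemi`` is the output of :func:`qeeg.nonlinear.hemisphere_features`;
    ``features`` defaults to every EEG feature column present.
    """
    if features is None:
        features = [f for f in EEG_FEATURES if f in hemi.columns]
    missing = [f for f in features if f not in hemi.columns]
    if missing:
        raise ValidationError(f"features absent from table: {missing}")

    results: list[StatResult] = []

    # Within-group T0 vs T1, one EEG family per group.
    for group in ("experimental", "control"):
        for feat in features:
            x0, x1 = _paired_frame(hemi, group, feat)
            r = paired_t(x0, x1, feature=feat, contrast=f"within_{group}")
            r.family = f"eeg_within_{group}"
            r.group_stats = {f"{group}_T0": _mean_sd(x0),
                             f"{group}_T1": _mean_sd(x1)}
            results.append(r)

    # Between groups at T1, one EEG family.
    t1 = hemi[hemi["session"] == "T1"]
    for feat in features:
        a = t1.loc[t1["group"] == "experimental", feat].to_numpy()
        b = t1.loc[t1["group"] == "control", feat].to_numpy()
        r = independent_t(a, b, pooled=pooled_t, feature=feat,
                          contrast="between_T1")
        r.family = "eeg_between_T1"
        r.group_stats = {"experimental_T1": _mean_sd(a),
                         "control_T1": _mean_sd(b)}
        results.append(r)

    # Clinical endpoints (own family): NIHSS within groups, dNIHSS between.
    cohort = pd.DataFrame(
        [{"subject_id": s.subject_id, "group": s.group, "age": s.age,
          "sex": s.sex, "side": s.infarct_side, "t0": s.nihss_t0,
          "t1": s.nihss_t1, "d": s.delta_nihss} for s in subjects])
    for group in ("experimental", "control"):
        g = cohort[cohort["group"] == group]
        r = paired_t(g["t0"], g["t1"], feature="nihss",
                     contrast=f"within_{group}")
        r.family = "clinical"
        r.group_stats = {f"{group}_T0": _mean_sd(g["t0"]),
                         f"{group}_T1": _mean_sd(g["t1"])}
        results.append(r)
    exp = cohort[cohort["group"] == "experimental"]
    ctl = cohort[cohort["group"] == "control"]
    r = independent_t(exp["d"], ctl["d"], pooled=pooled_t,
                      feature="delta_nihss", contrast="between_groups")
    r.family = "clinical"
    r.group_stats = {"experimental": _mean_sd(exp["d"]),
                     "control": _mean_sd(ctl["d"])}
    results.append(r)

    # Baseline comparability (own family): age, sex, side, NIHSS_T0.
    r = independent_t(exp["age"], ctl["age"], pooled=pooled_t,
                      feature="age", contrast="baseline")
    r.family = "baseline"
    results.append(r)
    r = independent_t(exp["t0"], ctl["t0"], pooled=pooled_t,
                      feature="nihss_t0", contrast="baseline")
    r.family = "baseline"
    results.append(r)
    for feat, col in (("sex", "sex"), ("infarct_side", "side")):
        tab = pd.crosstab(cohort["group"], cohort[col]).to_numpy()
        if tab.shape[1] > 1:  # both levels present
            r = chi_square(tab, feature=feat, contrast="baseline")
            r.family = "baseline"
            results.append(r)

    # FDR within each family.
    p = np.array([r.p_raw for r in results])
    fams = np.array([r.family for r in results])
    q = bh_fdr(p, fams)
    for r, qv in zip(results, q):
        r.q_fdr = float(qv)

    # Correlations with dNIHSS: experimental group, T1 features.
    exp_t1 = hemi[(hemi["group"] == "experimental")
                  & (hemi["session"] == "T1")]
    correlations = []
    for feat in CORRELATION_FEATURES:
        if feat not in exp_t1.columns:
            continue
        try:
            correlations.append(pearson_corr(
                exp_t1[feat].to_numpy(),
                exp_t1["delta_nihss"].to_numpy(), feature=feat))
        except DegenerateDataError:
            continue
    return StatReport(results, correlations)
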