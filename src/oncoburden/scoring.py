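"""Comorbidity scoring: ICD-10 mapping, Charlson score, severity grade.

The scorer maps each patient's deduplicated diagnosis codes onto the
cancer-adapted Charlson roster (14 conditions plus hypertension), applies the
two severity hierarchies (mild vs moderate/severe liver disease, diabetes
with vs without complications), sums the Charlson weights into the CCI
score, and grades severity. The index cancer's own codes (C00-C97 and the
roster exclusions of solid tumours, leukaemias, lymphomas) never appear in
the roster, so they cannot count as comorbidity.

Prevalence and group-comparison tables mirror the usual hospital-cohort
reporting: per-condition counts with row percentages by cancer type,
per-cancer-type comorbidity rates, comorbidity-number and severity
distributions, and with/without-comorbidity baseline comparisons using
Student's t and Pearson chi-square tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .conditions import (
    ConditionMap,
    WeightTable,
    default_condition_map,
    default_weight_table,
    is_valid_icd10,
    normalize_icd10,
)
from .ingest import PatientRecord

logger = logging.getLogger("oncoburden.scoring")

__all__ = [
    "SeverityThresholds",
    "ComorbidityProfile",
    "IndexResult",
    "ComorbidityScorer",
    "map_icd10_to_conditions",
    "compute_cci_score",
    "prevalence_table",
    "PrevalenceTables",
    "compare_groups",
]

SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class SeverityThresholds:
    """CCI score bands: none = 0, mild = 1..mild_max, moderate =
    mild_max+1..moderate_max, severe above. Defaults follow the common
    1-2 / 3-4 / >=5 convention."""

    mild_max: int = 2
    moderate_max: int = 4

    def grade(self, score: int) -> str:
        if score < 0:
            raise ValueError("CCI score must be non-negative")
        if score == 0:
            return "none"
        if score <= self.mild_max:
            return "mild"
        if score <= self.moderate_max:
            return "moderate"
        return "severe"


@dataclass(frozen=True)
class ComorbidityProfile:
    """Binary condition indicators for one patient."""

    patient_id: str
    indicators: dict[str, int]

    @property
    def count(self) -> int:
        return int(sum(self.indicators.values()))

    @property
    def positive(self) -> tuple[str, ...]:
        return tuple(c for c, v in self.indicators.items() if v)


@dataclass(frozen=True)
class IndexResult:
    patient_id: str
    cci_score: int
    severity: str


def map_icd10_to_conditions(
    union_dx: Iterable[str],
    condition_map: ConditionMap | None = None,
    patient_id: str = "",
) -> ComorbidityProfile:
    """Map a set of ICD-10 codes to condition indicators.

    Matching is case- and dot-insensitive prefix matching; syntactically
    invalid codes are skipped with a warning. Severity hierarchies are
    applied: the severe member of a pair masks the mild one.
    """
    cmap = condition_map or default_condition_map()
    indicators = {c: 0 for c in cmap.conditions}
    for code in union_dx:
        if not is_valid_icd10(code):
            logger.warning("patient %s: skipping invalid ICD-10 code %r",
                           patient_id or "<unknown>", code)
            continue
        cond = cmap.match(normalize_icd10(code))
        if cond is not None:
            indicators[cond] = 1
    for mild, severe in cmap.hierarchies:
        if indicators.get(severe) and indicators.get(mild):
            indicators[mild] = 0
    return ComorbidityProfile(patient_id=patient_id, indicators=indicators)


def compute_cci_score(
    profile: ComorbidityProfile | Mapping[str, int],
    weights: WeightTable | None = None,
    thresholds: SeverityThresholds | None = None,
) -> IndexResult:
    """Sum Charlson weights over positive conditions and grade severity."""
    weights = weights or default_weight_table()
    thresholds = thresholds or SeverityThresholds()
    if isinstance(profile, ComorbidityProfile):
        indicators = profile.indicators
        pid = profile.patient_id
    else:
        indicators, pid = dict(profile), ""
    score = 0
    for cond, positive in indicators.items():
        if positive:
            score += weights[cond]  # KeyError -> configuration error
    return IndexResult(patient_id=pid, cci_score=score,
                       severity=thresholds.grade(score))


class ComorbidityScorer(BaseEstimator, TransformerMixin):
    """Transformer from patient records to scored comorbidity profiles.

    Parameters
    ----------
    condition_map : ConditionMap or None
        ICD-10 prefix map; the packaged Quan-dialect roster when None.
    weight_table : WeightTable or None
        Charlson weights; the packaged table when None.
    thresholds : SeverityThresholds or None
        CCI severity bands.
    include_connective_tissue : bool
        Add the optional 16th condition to the default roster.

    ``transform`` accepts a list of :class:`PatientRecord`, a patient-level
    DataFrame with a ``union_dx`` column (';'-joined codes), or a DataFrame
    that already carries one 0/1 column per roster condition (indicators are
    then taken as-is after hierarchy enforcement). It returns a DataFrame
    with passthrough demographic columns, one 0/1 column per condition, and
    ``comorbidity_count``, ``cci_score`` and ``severity`` columns.
    """

    def __init__(self, condition_map: ConditionMap | None = None,
                 weight_table: WeightTable | None = None,
                 thresholds: SeverityThresholds | None = None,
                 include_connective_tissue: bool = False):
        self.condition_map = condition_map
        self.weight_table = weight_table
        self.thresholds = thresholds
        self.include_connective_tissue = include_connective_tissue

    def fit(self, X=None, y=None) -> "ComorbidityScorer":
        self.condition_map_ = self.condition_map or default_condition_map(
            include_connective_tissue=self.include_connective_tissue)
        self.weight_table_ = self.weight_table or default_weight_table()
        self.thresholds_ = self.thresholds or SeverityThresholds()
        self.conditions_ = list(self.condition_map_.conditions)
        for c in self.conditions_:
            self.weight_table_[c]  # fail fast on a missing weight
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "condition_map_"):
            self.fit()
        frame = self._as_frame(X)
        conds = self.conditions_
        if all(c in frame.columns for c in conds):
            out = frame.copy()
            for mild, severe in self.condition_map_.hierarchies:
                out.loc[out[severe] == 1, mild] = 0
        else:
            out = frame.copy()
            indicator_rows = []
            for pid, dx in zip(out["patient_id"], out["union_dx"]):
                codes = [c for c in str(dx).split(";") if c] if dx else []
                prof = map_icd10_to_conditions(
                    codes, self.condition_map_, patient_id=str(pid))
                indicator_rows.append(prof.indicators)
            ind = pd.DataFrame(indicator_rows, index=out.index)
            for c in conds:
                out[c] = ind[c].astype(np.int8)
        w = np.array([self.weight_table_[c] for c in conds])
        mat = out[conds].to_numpy(dtype=int)
        out["comorbidity_count"] = mat.sum(axis=1)
        out["cci_score"] = mat @ w
        out["severity"] = [self.thresholds_.grade(int(s))
                           for s in out["cci_score"]]
        return out

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        if len(X) and isinstance(X[0], PatientRecord):
            from .ingest import patients_to_frame
            return patients_to_frame(list(X))
        raise TypeError(
            "expected a patient DataFrame or a list of PatientRecord")


@dataclass
class PrevalenceTables:
    """Stratified comorbidity summaries (percentages are 0-100 scale)."""

    condition_counts: pd.DataFrame
    comorbidity_rates: pd.DataFrame
    count_distribution: pd.DataFrame
    severity_distribution: pd.DataFrame


def prevalence_table(scored: pd.DataFrame,
                     conditions: Sequence[str] | None = None) -> PrevalenceTables:
    """Condition prevalences and comorbidity-burden distributions.

    ``scored`` is the output of :class:`ComorbidityScorer` (needs
    ``cancer_type``, the condition columns, ``comorbidity_count`` and
    ``severity``). Condition row percentages follow the share-by-cancer-type
    convention: of the patients carrying a condition, what share belongs to
    each cancer type.
    """
    if len(scored) == 0:
        raise ValueError("prevalence_table: empty cohort")
    if conditions is None:
        reserved = {"comorbidity_count", "cci_score", "severity"}
        known = set(default_condition_map(include_connective_tissue=True).conditions)
        conditions = [c for c in scored.columns
                      if c in known and c not in reserved]
    types = [t for t in ("lung", "colon", "rectal", "breast", "gastric")
             if t in set(scored["cancer_type"])]
    n_total = len(scored)

    rows = []
    for c in conditions:
        total = int(scored[c].sum())
        row = {"condition": c, "total": total,
               "prevalence_pct": 100.0 * total / n_total}
        for t in types:
            ct = int(scored.loc[scored["cancer_type"] == t, c].sum())
            row[f"{t}_n"] = ct
            row[f"{t}_row_pct"] = (100.0 * ct / total) if total else 0.0
        rows.append(row)
    condition_counts = pd.DataFrame(rows).set_index("condition")
    condition_counts = condition_counts.sort_values("total", ascending=False)

    with_any = scored["comorbidity_count"] >= 1
    rate_rows = []
    for t in types:
        mask = scored["cancer_type"] == t
        n = int(mask.sum())
        w = int((mask & with_any).sum())
        rate_rows.append({"stratum": t, "n": n, "with_comorbidity": w,
                          "rate_pct": 100.0 * w / n if n else 0.0})
    rate_rows.append({"stratum": "overall", "n": n_total,
                      "with_comorbidity": int(with_any.sum()),
                      "rate_pct": 100.0 * int(with_any.sum()) / n_total})
    comorbidity_rates = pd.DataFrame(rate_rows).set_index("stratum")

    burdened = scored.loc[with_any]
    bins = {"1": burdened["comorbidity_count"] == 1,
            "2": burdened["comorbidity_count"] == 2,
            "3": burdened["comorbidity_count"] == 3,
            ">3": burdened["comorbidity_count"] > 3}
    dist_rows = []
    for label, mask in bins.items():
        row = {"n_comorbidities": label, "total": int(mask.sum()),
               "pct_of_burdened":
                   100.0 * int(mask.sum()) / len(burdened) if len(burdened) else 0.0}
        for t in types:
            row[f"{t}_n"] = int((mask & (burdened["cancer_type"] == t)).sum())
        dist_rows.append(row)
    count_distribution = pd.DataFrame(dist_rows).set_index("n_comorbidities")

    sev_rows = []
    for level in SEVERITY_LEVELS:
        mask = scored["severity"] == level
        row = {"severity": level, "total": int(mask.sum()),
               "pct": 100.0 * int(mask.sum()) / n_total}
        for t in types:
            tmask = mask & (scored["cancer_type"] == t)
            tn = int((scored["cancer_type"] == t).sum())
            row[f"{t}_n"] = int(tmask.sum())
            row[f"{t}_pct"] = 100.0 * int(tmask.sum()) / tn if tn else 0.0
        sev_rows.append(row)
    severity_distribution = pd.DataFrame(sev_rows).set_index("severity")

    return PrevalenceTables(condition_counts, comorbidity_rates,
                            count_distribution, severity_distribution)


_CONTINUOUS_VARS = ("age", "total_cost")
_CATEGORICAL_VARS = ("sex", "insured", "married", "residency",
                     "cancer_type", "cancer_stage")


def compare_groups(scored: pd.DataFrame, grouping: str = "comorbidity",
                   continuous: Sequence[str] = _CONTINUOUS_VARS,
                   categorical: Sequence[str] = _CATEGORICAL_VARS) -> pd.DataFrame:
    """Baseline comparisons between comorbidity groups.

    ``grouping``: ``"comorbidity"`` (any vs none), ``"count_gt3"`` (>3 vs
    <=3), or ``"severity"`` (four ordered grades). Continuous variables get
    mean (SD) per group and a two-sample t test (one-way ANOVA when more
    than two groups); categorical variables get n (%) and a Pearson
    chi-square test. Zero-variance continuous variables are reported as
    undefined.
    """
    if grouping == "comorbidity":
        labels = np.where(scored["comorbidity_count"] >= 1, "with", "without")
    elif grouping == "count_gt3":
        labels = np.where(scored["comorbidity_count"] > 3, ">3", "<=3")
    elif grouping == "severity":
        labels = scored["severity"].to_numpy()
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = pd.Series(labels, index=scored.index, name="group")
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise ValueError("compare_groups: need at least two non-empty groups")

    rows = []
    for var in continuous:
        if var not in scored.columns:
            continue
        samples = [scored.loc[labels == g, var].dropna().to_numpy()
                   for g in group_names]
        summary = {f"{g}": f"{s.mean():.2f}({s.std(ddof=1):.2f})"
                   for g, s in zip(group_names, samples)}
        if any(len(s) < 2 for s in samples) or all(s.std(ddof=1) == 0 for s in samples):
            stat, p, note = np.nan, np.nan, "undefined (zero variance or empty group)"
        else:
            if len(group_names) == 2:
                stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
                note = "t test"
            else:
                stat, p = stats.f_oneway(*samples)
                note = "one-way ANOVA"
        rows.append({"variable": var, "level": "mean(SD)", **summary,
                     "statistic": stat, "p_value": p, "test": note})
    for var in categorical:
        if var not in scored.columns:
            continue
        table = pd.crosstab(scored[var], labels)
        table = table.reindex(columns=group_names, fill_value=0)
        if table.shape[0] < 2:
            stat, p, note = np.nan, np.nan, "undefined (single level)"
        else:
            stat, p, _, _ = stats.chi2_contingency(table.to_numpy(),
                                                   correction=False)
            note = "chi-square"
        for level, counts in table.iterrows():
            summary = {}
            for g in group_names:
                gn = int((labels == g).sum())
                summary[g] = f"{int(counts[g])} ({100.0 * counts[g] / gn:.2f})"
            rows.append({"variable": var, "level": str(level), **summary,
                         "statistic": stat, "p_value": p, "test": note})
    return pd.DataFrame(rows)
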