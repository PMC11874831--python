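"""Cluster-versus-outcome association models.

Treatments are recoded to two binary outcomes (conventional treatment =
surgery or chemotherapy or radiotherapy; targeted therapy on its own),
missing total cost is mean-imputed, and each comorbidity cluster is compared
against the reference group — patients of the same cancer type with no
identified cluster (or, optionally, no comorbidity at all) — using
covariate-adjusted maximum-likelihood logistic regression for the binary
outcomes and least-squares linear regression for cost. Binary-outcome
results report the log-odds coefficient with its Wald 95% CI alongside the
exponentiated odds ratio; cost results are RMB differences. Constant
outcomes, perfect separation and singular designs are flagged as not
estimable rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

logger = logging.getLogger("oncoburden.models")

__all__ = [
    "AssociationResult",
    "ImputationResult",
    "recode_treatments",
    "impute_cost",
    "build_outcome_frame",
    "fit_cluster_models",
    "report_table",
    "ClusterOutcomeRegression",
    "COVARIATE_PRESETS",
]

CONVENTIONAL_FLAGS = ("surgery", "chemotherapy", "radiotherapy")

# "table" follows the reported-model footnote convention; "body" the
# narrative description (living area instead of insurance/stage).
COVARIATE_PRESETS: dict[str, tuple[str, ...]] = {
    "table": ("age", "sex", "education", "insured", "married", "cancer_stage"),
    "body": ("age", "sex", "education", "residency", "married"),
}

_CONTINUOUS_COVARIATES = {"age"}


@dataclass(frozen=True)
class ImputationResult:
    values: np.ndarray
    imputed: np.ndarray  # boolean mask of filled entries
    mean: float


@dataclass(frozen=True)
class AssociationResult:
    """Adjusted effect of one cluster on one outcome vs the reference."""

    stratum: str
    cluster: str
    outcome: str
    kind: str  # "logistic" | "linear"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    exp_estimate: float | None
    n_cluster: int
    n_reference: int
    estimable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.estimable:
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("CI must bracket the estimate")
            if self.exp_estimate is not None and self.exp_estimate <= 0:
                raise ValueError("exponentiated estimate must be positive")


def recode_treatments(data) -> pd.DataFrame:
    """Binary treatment outcomes from per-patient treatment flags.

    Accepts a DataFrame with 0/1 flag columns (``surgery``, ``chemotherapy``,
    ``radiotherapy``, ``targeted``), a DataFrame with a ';'-joined
    ``treatments`` column, or a list of patient records. Absent flags count
    as 0.
    """
    from .ingest import PatientRecord, patients_to_frame

    if not isinstance(data, pd.DataFrame):
        if len(data) and isinstance(data[0], PatientRecord):
            data = patients_to_frame(list(data))
        else:
            data = pd.DataFrame(data)
    if all(f in data.columns for f in CONVENTIONAL_FLAGS + ("targeted",)):
        conv = data[list(CONVENTIONAL_FLAGS)].to_numpy(dtype=int).max(axis=1)
        targ = data["targeted"].to_numpy(dtype=int)
    elif "treatments" in data.columns:
        sets = [set(str(t).split(";")) if isinstance(t, str) and t else set()
                for t in data["treatments"]]
        conv = np.array([int(bool(s & set(CONVENTIONAL_FLAGS))) for s in sets])
        targ = np.array([int("targeted" in s) for s in sets])
    else:
        raise ValueError("no treatment flag columns found")
    return pd.DataFrame({"conventional_treatment": conv,
                         "targeted_therapy": targ}, index=data.index)


def impute_cost(costs) -> ImputationResult:
    """Mean-impute missing costs; the post-imputation mean equals the
    observed mean by construction."""
    values = np.asarray(costs, dtype=float).copy()
    missing = np.isnan(values)
    if missing.all():
        raise ValueError("impute_cost: all costs missing")
    mean = float(values[~missing].mean())
    values[missing] = mean
    return ImputationResult(values=values, imputed=missing, mean=mean)


def build_outcome_frame(scored: pd.DataFrame, cluster_labels: pd.Series,
                        impute: bool = True) -> pd.DataFrame:
    """Assemble the modelling frame: outcomes, covariates, cluster label.

    ``scored`` is a scored patient table (needs treatment information, cost
    and covariate columns); ``cluster_labels`` maps each patient to a
    cluster label or "none".
    """
    frame = scored.copy()
    frame[["conventional_treatment", "targeted_therapy"]] = recode_treatments(scored)
    frame["cluster"] = cluster_labels.reindex(frame.index).fillna("none")
    if "total_cost" in frame.columns:
        if impute:
            imp = impute_cost(frame["total_cost"].to_numpy(dtype=float))
            frame["cost"] = imp.values
            frame["cost_imputed"] = imp.imputed.astype(int)
        else:
            frame["cost"] = frame["total_cost"]
            frame["cost_imputed"] = 0
    return frame


def _design(frame: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=frame.index)
    X["in_cluster"] = frame["in_cluster"].astype(float)
    for cov in covariates:
        if cov in _CONTINUOUS_COVARIATES:
            X[cov] = frame[cov].astype(float)
        else:
            dummies = pd.get_dummies(frame[cov].astype(str), prefix=cov,
                                     drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X


def _rank_deficient_column(X: pd.DataFrame) -> str | None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return None
    cols = list(X.columns)
    kept: list[int] = []
    for j in range(arr.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(arr[:, trial]) < len(trial):
            return cols[j]
        kept.append(j)
    return cols[-1]


def _not_estimable(stratum, cluster, outcome, kind, n1, n0, note):
    return AssociationResult(
        stratum=stratum, cluster=cluster, outcome=outcome, kind=kind,
        estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
        p_value=float("nan"), exp_estimate=None, n_cluster=n1,
        n_reference=n0, estimable=False, note=note)


def _fit_one(sub: pd.DataFrame, outcome: str, kind: str,
             covariates: Sequence[str], stratum: str, cluster: str,
             n1: int, n0: int) -> AssociationResult:
    y = sub[outcome].to_numpy(dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2 and kind == "logistic":
        return _not_estimable(stratum, cluster, outcome, kind, n1, n0,
                              "constant outcome")
    X = _design(sub, covariates)
    bad = _rank_deficient_column(X)
    if bad is not None:
        return _not_estimable(stratum, cluster, outcome, kind, n1, n0,
                              f"singular design (collinear column {bad})")
    try:
        if kind == "logistic":
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=200)
        else:
            res = sm.OLS(y, X, missing="drop").fit()
    except Exception as exc:  # separation and other fit failures
        return _not_estimable(stratum, cluster, outcome, kind, n1, n0,
                              f"fit failed: {exc}")
    est = float(res.params["in_cluster"])
    se = float(res.bse["in_cluster"])
    if kind == "logistic" and (not np.isfinite(se) or se > 50 or abs(est) > 20):
        return _not_estimable(stratum, cluster, outcome, kind, n1, n0,
                              "quasi-separation (unstable estimate)")
    ci = res.conf_int().loc["in_cluster"]
    return AssociationResult(
        stratum=stratum, cluster=cluster, outcome=outcome, kind=kind,
        estimate=est, ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=float(res.pvalues["in_cluster"]),
        exp_estimate=float(np.exp(est)) if kind == "logistic" else None,
        n_cluster=n1, n_reference=n0)


def fit_cluster_models(frame: pd.DataFrame, stratum: str | None = None,
                       covariates: Sequence[str] | str = "table",
                       min_cluster_size: int = 10,
                       reference: str = "no_cluster",
                       outcomes: Sequence[tuple[str, str]] = (
                           ("conventional_treatment", "logistic"),
                           ("targeted_therapy", "logistic"),
                           ("cost", "linear"))) -> list[AssociationResult]:
    """Fit per-cluster adjusted models within one cancer-type stratum.

    ``frame`` is an outcome frame from :func:`build_outcome_frame`.
    ``reference="no_cluster"`` compares against patients with no identified
    cluster; ``"no_comorbidity"`` against patients with zero comorbidities
    (needs a ``comorbidity_count`` column). Clusters smaller than
    ``min_cluster_size`` are skipped with a note.
    """
    if isinstance(covariates, str):
        covariates = COVARIATE_PRESETS[covariates]
    covariates = [c for c in covariates if c in frame.columns]
    sub = frame if stratum is None else frame[frame["cancer_type"] == stratum]
    stratum_name = stratum or "all"
    if reference == "no_cluster":
        ref_mask = sub["cluster"] == "none"
    elif reference == "no_comorbidity":
        ref_mask = sub["comorbidity_count"] == 0
    else:
        raise ValueError(f"unknown reference {reference!r}")
    n0 = int(ref_mask.sum())
    results: list[AssociationResult] = []
    for cluster in [c for c in sub["cluster"].unique() if c != "none"]:
        members = sub["cluster"] == cluster
        n1 = int(members.sum())
        if n0 == 0:
            raise ValueError("reference group is empty")
        for outcome, kind in outcomes:
            if outcome not in sub.columns:
                continue
            if n1 < min_cluster_size:
                results.append(_not_estimable(
                    stratum_name, cluster, outcome, kind, n1, n0,
                    f"cluster smaller than min_cluster_size={min_cluster_size}"))
                continue
            pair = sub[members | ref_mask].copy()
            pair["in_cluster"] = members[members | ref_mask].astype(int)
            results.append(_fit_one(pair, outcome, kind, covariates,
                                    stratum_name, cluster, n1, n0))
    return results


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def report_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Clusters as rows, outcomes as columns, 'estimate(low,high)stars'
    cells; '\\' marks not-estimable cells and a reference row leads."""
    outcomes = []
    for r in results:
        if r.outcome not in outcomes:
            outcomes.append(r.outcome)
    if not outcomes:
        outcomes = ["conventional_treatment", "targeted_therapy", "cost"]
    rows = [{"stratum": "", "cluster": "reference", "n": "",
             **{o: "1.00(reference)" for o in outcomes}}]
    by_key: dict[tuple[str, str], dict] = {}
    for r in results:
        key = (r.stratum, r.cluster)
        row = by_key.setdefault(key, {"stratum": r.stratum,
                                      "cluster": r.cluster,
                                      "n": r.n_cluster})
        if not r.estimable:
            row[r.outcome] = "\\"
        else:
            row[r.outcome] = (f"{r.estimate:.2f}({r.ci_low:.2f},"
                              f"{r.ci_high:.2f}){_stars(r.p_value)}")
    rows.extend(by_key.values())
    return pd.DataFrame(rows, columns=["stratum", "cluster", "n", *outcomes])


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Machine-readable results table."""
    return pd.DataFrame([{
        "stratum": r.stratum, "cluster": r.cluster, "outcome": r.outcome,
        "kind": r.kind, "estimate": r.estimate, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p_value": r.p_value,
        "exp_estimate": r.exp_estimate if r.exp_estimate is not None
        else float("nan"),
        "n_cluster": r.n_cluster, "n_reference": r.n_reference,
        "estimable": r.estimable, "note": r.note} for r in results])


class ClusterOutcomeRegression(BaseEstimator):
    """Estimator wrapper over :func:`fit_cluster_models`.

    Fits one model per (stratum, cluster, outcome) on an outcome frame and
    exposes ``results_`` (list of :class:`AssociationResult`), ``summary_``
    (flat DataFrame) and ``table_`` (formatted report).
    """

    def __init__(self, covariates: str | Sequence[str] = "table",
                 min_cluster_size: int = 10, reference: str = "no_cluster",
                 stratify: str | None = "cancer_type"):
        self.covariates = covariates
        self.min_cluster_size = min_cluster_size
        self.reference = reference
        self.stratify = stratify

    def fit(self, X: pd.DataFrame, y=None) -> "ClusterOutcomeRegression":
        results: list[AssociationResult] = []
        if self.stratify is None:
            strata = [None]
        else:
            strata = sorted(X[self.stratify].unique())
        for s in strata:
            results.extend(fit_cluster_models(
                X, stratum=s, covariates=self.covariates,
                min_cluster_size=self.min_cluster_size,
                reference=self.reference))
        self.results_ = results
        self.summary_ = results_frame(results)
        self.table_ = report_table(results)
        return self
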