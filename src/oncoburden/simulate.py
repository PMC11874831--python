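"""Synthetic inpatient cancer cohort generator.

Emulates the marginal structure of a Chinese tertiary-hospital cancer cohort
(five cancer types; age, sex, insurance, marriage, residency and stage
margins; chronic-condition prevalences) together with planted positive
co-occurrence between condition pairs that are known to cluster in such
cohorts (hypertension-diabetes, cerebrovascular-peripheral vascular, mild
liver-renal, heart failure-COPD).

Co-occurrence mechanism
-----------------------
Each block of conditions shares one latent Bernoulli factor ``F ~ Bern(q)``.
A condition ``c`` with target prevalence ``p_c`` is drawn as

    X_c = M_c * F + (1 - M_c) * Y_c,   M_c ~ Bern(lam_c),  Y_c ~ Bern(r_c)

with ``lam_c = sqrt(rho * p_c (1-p_c) / (q (1-q)))`` and ``r_c`` solved so
that ``E[X_c] = p_c`` exactly. Every within-block pair then has Pearson
correlation exactly ``rho`` while marginals are preserved; ``q`` is chosen
inside the feasibility interval implied by ``lam_c <= 1`` and
``0 <= r_c <= 1``. An infeasible ``rho`` (larger than the maximum correlation
two Bernoulli margins admit) is rejected at validation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import EXEMPLAR_CODES

__all__ = [
    "CohortSpec",
    "CohortSpecError",
    "CohortSimulator",
    "generate_cohort",
    "generate_patient_table",
    "planted_block_correlation",
    "DEFAULT_CONDITION_PREVALENCE",
    "DEFAULT_BLOCKS",
]

CANCER_TYPES = ("lung", "colon", "rectal", "breast", "gastric")
STAGES = ("0", "I", "II", "III", "IV")
TREATMENTS = ("surgery", "chemotherapy", "radiotherapy", "targeted")

# Per-condition prevalences on the scale of the full cohort (N = 4,666 in the
# emulated case study): counts 1495, 1046, 821, 742, 730, 442, 379, 358, 235,
# 90, 77, 49, 5, 2 over 4666; AIDS was not observed.
DEFAULT_CONDITION_PREVALENCE: dict[str, float] = {
    "hypertension": 1495 / 4666,
    "mild_liver_disease": 1046 / 4666,
    "renal_disease": 821 / 4666,
    "diabetes": 742 / 4666,
    "myocardial_infarction": 730 / 4666,
    "peptic_ulcer": 442 / 4666,
    "peripheral_vascular_disease": 379 / 4666,
    "copd": 358 / 4666,
    "cerebrovascular_disease": 235 / 4666,
    "moderate_severe_liver_disease": 90 / 4666,
    "congestive_heart_failure": 77 / 4666,
    "diabetes_with_complications": 49 / 4666,
    "dementia": 5 / 4666,
    "paralysis": 2 / 4666,
    "aids": 0.0,
}

# Condition pairs that co-occur in hospital cancer cohorts; rho = 0.4 gives a
# clearly super-null association that remains feasible for the rarest pair
# (heart failure-COPD margins cap the attainable correlation near 0.45).
DEFAULT_BLOCKS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("hypertension", "diabetes"), 0.4),
    (("cerebrovascular_disease", "peripheral_vascular_disease"), 0.4),
    (("mild_liver_disease", "renal_disease"), 0.4),
    (("congestive_heart_failure", "copd"), 0.4),
)

_DEFAULT_SEX_FEMALE = {
    "lung": 0.35,
    "colon": 0.40,
    "rectal": 0.40,
    "breast": 1.0,
    "gastric": 0.30,
}

_DEFAULT_HISTOLOGY = {
    "lung": {"adenocarcinoma": 0.75, "squamous cell carcinoma": 0.20,
             "small cell lung cancer": 0.05},
    "colon": {"adenocarcinoma": 0.96, "lymphoma": 0.02,
              "squamous cell carcinoma": 0.02},
    "rectal": {"adenocarcinoma": 0.96, "sarcoma": 0.02,
               "squamous cell carcinoma": 0.02},
    "breast": {"invasive ductal carcinoma": 0.95,
               "mucinous adenocarcinoma": 0.03, "Paget's disease": 0.02},
    "gastric": {"adenocarcinoma": 1.0},
}

_CANCER_PRIMARY_DX = {
    "lung": "C34.9",
    "colon": "C18.9",
    "rectal": "C20",
    "breast": "C50.9",
    "gastric": "C16.9",
}

_DEFAULT_TREATMENT_INTERCEPTS = {
    "surgery": 1.2,
    "chemotherapy": 0.4,
    "radiotherapy": -1.0,
    "targeted": -1.6,
}

_HIERARCHY_PAIRS = (
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("diabetes", "diabetes_with_complications"),
)


class CohortSpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


def _check_probs(name: str, probs: Mapping[str, float], keys: Sequence[str]) -> None:
    if set(probs) != set(keys):
        raise CohortSpecError(f"{name}: expected keys {sorted(keys)}, got {sorted(probs)}")
    if any(p < 0 for p in probs.values()):
        raise CohortSpecError(f"{name}: negative probability")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise CohortSpecError(f"{name}: probabilities must sum to 1")


def _block_latent_params(
    prevalences: Sequence[float], rho: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Solve (q, lam_c, r_c) of the shared-factor construction for one block.

    Raises CohortSpecError when ``rho`` is infeasible for the margins.
    """
    p = np.asarray(prevalences, dtype=float)
    if rho == 0.0:
        return 0.5, np.zeros(len(p)), p.copy()
    # feasibility: r_c >= 0 caps q from above, r_c <= 1 and lam_c <= 1 cap
    # it from below
    q_hi = float(np.min(p / (p + rho * (1.0 - p))))
    q_lo_r1 = float(np.max(rho * p / (1.0 - p + rho * p)))
    m = rho * float(np.max(p * (1.0 - p)))
    if m >= 0.25:
        raise CohortSpecError(
            f"cooccurrence_blocks: rho={rho} infeasible for margins {p.tolist()}"
        )
    q_m = (1.0 - math.sqrt(1.0 - 4.0 * m)) / 2.0
    q_lo = max(q_m, q_lo_r1)
    q_hi = min(q_hi, 1.0 - q_m)
    if q_lo > q_hi + 1e-12:
        raise CohortSpecError(
            f"cooccurrence_blocks: rho={rho} exceeds the maximum correlation "
            f"attainable for margins {p.tolist()}"
        )
    q = 0.5 * (q_lo + q_hi)
    lam = np.sqrt(rho * p * (1.0 - p) / (q * (1.0 - q)))
    lam = np.minimum(lam, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(lam < 1.0, (p - lam * q) / (1.0 - lam), p)
    r = np.clip(r, 0.0, 1.0)
    return q, lam, r


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the emulated case-study margins: 4,666 patients across
    lung/colon/rectal/breast/gastric cancer (37.03/12.22/12.47/17.08/21.20%),
    age 62.42 (SD 11.62) truncated to [18, 100], 94.68% insured, 87.74%
    married, 64.96% urban, stage margins 2.66/28.31/21.37/29.10/18.56%, cost
    log-normal matched to mean 73,551.74 / SD 65,287.61 RMB.
    """

    n_patients: int = 4666
    cancer_type_probs: dict[str, float] = field(default_factory=lambda: {
        "lung": 0.3703, "colon": 0.1222, "rectal": 0.1247,
        "breast": 0.1708, "gastric": 0.2120,
    })
    age_mean: float = 62.42
    age_sd: float = 11.62
    age_bounds: tuple[float, float] = (18.0, 100.0)
    sex_female_prob: float | dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEX_FEMALE))
    insured_prob: float = 0.9468
    married_prob: float = 0.8774
    urban_prob: float = 0.6496
    education_probs: dict[str, float] = field(default_factory=lambda: {
        "primary": 0.35, "secondary": 0.45, "tertiary": 0.20,
    })
    stage_probs: dict[str, float] = field(default_factory=lambda: {
        "0": 0.0266, "I": 0.2831, "II": 0.2137, "III": 0.2910, "IV": 0.1856,
    })
    condition_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCE))
    cooccurrence_blocks: Sequence[tuple[Sequence[str], float]] = field(
        default_factory=lambda: tuple(DEFAULT_BLOCKS))
    cost_log_mean: float = 10.915
    cost_log_sd: float = 0.762
    treatment_intercepts: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TREATMENT_INTERCEPTS))
    treatment_effects: dict[tuple[str, ...], dict[str, float]] = field(
        default_factory=dict)
    cost_effects: dict[tuple[str, ...], float] = field(default_factory=dict)
    missing_cost_prob: float = 0.05
    admissions_per_patient_dist: dict[int, float] = field(default_factory=lambda: {
        1: 0.10, 2: 0.30, 3: 0.30, 4: 0.20, 5: 0.10,
    })
    histology_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_HISTOLOGY.items()})
    condition_codes: dict[str, str] = field(
        default_factory=lambda: dict(EXEMPLAR_CODES))
    start_date: str = "2017-01-01"
    end_date: str = "2019-10-31"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_patients, int) or self.n_patients < 0:
            raise CohortSpecError("n_patients: must be a non-negative integer")
        _check_probs("cancer_type_probs", self.cancer_type_probs, CANCER_TYPES)
        _check_probs("stage_probs", self.stage_probs, STAGES)
        _check_probs("education_probs", self.education_probs,
                     tuple(self.education_probs))
        for name, p in (("insured_prob", self.insured_prob),
                        ("married_prob", self.married_prob),
                        ("urban_prob", self.urban_prob),
                        ("missing_cost_prob", self.missing_cost_prob)):
            if not 0.0 <= p <= 1.0:
                raise CohortSpecError(f"{name}: must lie in [0, 1]")
        if self.age_sd <= 0:
            raise CohortSpecError("age_sd: must be positive")
        probs = (self.sex_female_prob.values()
                 if isinstance(self.sex_female_prob, dict)
                 else [self.sex_female_prob])
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise CohortSpecError("sex_female_prob: must lie in [0, 1]")
        for cond, p in self.condition_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise CohortSpecError(
                    f"condition_prevalence[{cond}]: must lie in [0, 1]")
        dist = self.admissions_per_patient_dist
        if any((not isinstance(k, int)) or k < 1 for k in dist):
            raise CohortSpecError(
                "admissions_per_patient_dist: support must be positive integers")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise CohortSpecError(
                "admissions_per_patient_dist: probabilities must sum to 1")
        seen: set[str] = set()
        for conds, rho in self.cooccurrence_blocks:
            if not 0.0 <= rho < 1.0:
                raise CohortSpecError("cooccurrence_blocks: rho must lie in [0, 1)")
            for c in conds:
                if c not in self.condition_prevalence:
                    raise CohortSpecError(
                        f"cooccurrence_blocks: condition {c!r} missing from "
                        "condition_prevalence")
                if c in seen:
                    raise CohortSpecError(
                        f"cooccurrence_blocks: condition {c!r} appears in two blocks")
                seen.add(c)
            # feasibility check (raises with the offending margins)
            _block_latent_params(
                [self.condition_prevalence[c] for c in conds], rho)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.condition_prevalence)


class CohortSimulator:
    """Draws patient- and admission-level tables from a :class:`CohortSpec`.

    All randomness flows from ``spec.seed`` (or the ``seed`` argument of the
    sampling methods); identical spec + seed give identical tables.
    """

    def __init__(self, spec: CohortSpec | None = None):
        self.spec = spec if spec is not None else CohortSpec()

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "CohortSimulator":
        for k, v in params.items():
            if k != "spec":
                raise ValueError(f"unknown parameter {k!r}")
            self.spec = v
        return self

    # ------------------------------------------------------------------
    def sample_indicators(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        """Condition indicator matrix with planted block correlation."""
        spec = self.spec
        conds = list(spec.conditions)
        X = pd.DataFrame(0, index=range(n), columns=conds, dtype=np.int8)
        in_block: set[str] = set()
        for block, rho in spec.cooccurrence_blocks:
            block = list(block)
            in_block.update(block)
            p = [spec.condition_prevalence[c] for c in block]
            q, lam, r = _block_latent_params(p, rho)
            f = rng.random(n) < q
            for j, c in enumerate(block):
                m = rng.random(n) < lam[j]
                y = rng.random(n) < r[j]
                X[c] = np.where(m, f, y).astype(np.int8)
        for c in conds:
            if c not in in_block:
                X[c] = (rng.random(n) < spec.condition_prevalence[c]).astype(np.int8)
        # severity hierarchies: the severe member masks the mild one
        for mild, severe in _HIERARCHY_PAIRS:
            if mild in X.columns and severe in X.columns:
                X.loc[X[severe] == 1, mild] = 0
        return X

    def sample_patients(self, seed: int | None = None) -> pd.DataFrame:
        """One row per patient: demographics, indicators, treatments, cost."""
        spec = self.spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        n = spec.n_patients
        if n == 0:
            cols = ["patient_id", "cancer_type", "histology", "age", "sex",
                    "insured", "married", "residency", "education",
                    "cancer_stage", "n_admissions", "total_cost",
                    *spec.conditions, *TREATMENTS]
            return pd.DataFrame(columns=cols)

        types = rng.choice(CANCER_TYPES, size=n,
                           p=[spec.cancer_type_probs[t] for t in CANCER_TYPES])
        stage = rng.choice(STAGES, size=n,
                           p=[spec.stage_probs[s] for s in STAGES])
        lo, hi = spec.age_bounds
        age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), lo, hi)
        if isinstance(spec.sex_female_prob, dict):
            pf = np.array([spec.sex_female_prob[t] for t in types])
        else:
            pf = np.full(n, spec.sex_female_prob)
        sex = np.where(rng.random(n) < pf, "female", "male")
        edu_levels = list(spec.education_probs)
        education = rng.choice(edu_levels, size=n,
                               p=[spec.education_probs[e] for e in edu_levels])
        histology = np.empty(n, dtype=object)
        for t in CANCER_TYPES:
            mask = types == t
            opts = list(spec.histology_probs[t])
            histology[mask] = rng.choice(
                opts, size=int(mask.sum()),
                p=[spec.histology_probs[t][h] for h in opts])

        X = self.sample_indicators(rng, n)

        # treatment flags from a logistic model with optional planted shifts
        pattern_match = {}
        for pattern in set(spec.treatment_effects) | set(spec.cost_effects):
            cols = list(pattern)
            pattern_match[pattern] = (X[cols].values == 1).all(axis=1)
        flags = {}
        for t in TREATMENTS:
            logit = np.full(n, spec.treatment_intercepts[t], dtype=float)
            for pattern, shifts in spec.treatment_effects.items():
                if t in shifts:
                    logit = logit + shifts[t] * pattern_match[pattern]
            prob = 1.0 / (1.0 + np.exp(-logit))
            flags[t] = (rng.random(n) < prob).astype(np.int8)

        cost = rng.lognormal(spec.cost_log_mean, spec.cost_log_sd, size=n)
        for pattern, shift in spec.cost_effects.items():
            cost = cost + shift * pattern_match[pattern]
        cost = np.maximum(cost, 0.0)
        cost = np.where(rng.random(n) < spec.missing_cost_prob, np.nan, cost)

        adm_k = np.array(sorted(spec.admissions_per_patient_dist))
        adm_p = np.array([spec.admissions_per_patient_dist[k] for k in adm_k])
        n_adm = rng.choice(adm_k, size=n, p=adm_p)

        df = pd.DataFrame({
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "cancer_type": types,
            "histology": histology,
            "age": np.round(age, 1),
            "sex": sex,
            "insured": (rng.random(n) < spec.insured_prob).astype(np.int8),
            "married": (rng.random(n) < spec.married_prob).astype(np.int8),
            "residency": np.where(rng.random(n) < spec.urban_prob,
                                  "urban", "rural"),
            "education": education,
            "cancer_stage": stage,
            "n_admissions": n_adm,
            "total_cost": np.round(cost, 2),
        })
        for c in spec.conditions:
            df[c] = X[c].values
        for t in TREATMENTS:
            df[t] = flags[t]
        return df

    def sample_admissions(self, seed: int | None = None) -> pd.DataFrame:
        """Expand the patient table into one row per admission.

        Dates: the first admission falls uniformly inside the diagnosis
        window; later admissions follow at 14-75 day gaps with 3-14 day
        stays. Secondary diagnoses carry one exemplar ICD-10 code per active
        condition; the primary diagnosis is the cancer's own code.
        """
        spec = self.spec
        patients = self.sample_patients(seed=seed)
        rng = np.random.default_rng(
            (spec.seed if seed is None else seed) + 1_000_003)
        start = pd.Timestamp(spec.start_date)
        end = pd.Timestamp(spec.end_date)
        span = (end - start).days
        rows = []
        for row in patients.itertuples(index=False):
            codes = [spec.condition_codes[c] for c in spec.conditions
                     if getattr(row, c) == 1]
            k = int(row.n_admissions)
            # split total cost across admissions (missing stays missing)
            if np.isnan(row.total_cost):
                costs = [np.nan] * k
            else:
                w = rng.dirichlet(np.ones(k))
                costs = np.round(row.total_cost * w, 2)
                costs[-1] = round(row.total_cost - float(np.sum(costs[:-1])), 2)
            adm = start + pd.Timedelta(days=int(rng.integers(0, span + 1)))
            tx = [t for t in TREATMENTS if getattr(row, t) == 1]
            for j in range(k):
                stay = int(rng.integers(3, 15))
                rows.append({
                    "patient_id": row.patient_id,
                    "admission_date": adm.date().isoformat(),
                    "discharge_date": (adm + pd.Timedelta(days=stay)).date().isoformat(),
                    "age": row.age,
                    "sex": row.sex,
                    "insured": int(row.insured),
                    "married": int(row.married),
                    "residency": row.residency,
                    "education": row.education,
                    "cancer_type": row.cancer_type,
                    "histology": row.histology,
                    "cancer_stage": row.cancer_stage,
                    "department": _department_for(row.cancer_type),
                    "primary_dx": _CANCER_PRIMARY_DX[row.cancer_type],
                    "secondary_dx": ";".join(codes),
                    "treatments": ";".join(tx),
                    "total_cost": costs[j],
                })
                adm = adm + pd.Timedelta(days=stay + int(rng.integers(14, 76)))
        columns = ["patient_id", "admission_date", "discharge_date", "age",
                   "sex", "insured", "married", "residency", "education",
                   "cancer_type", "histology", "cancer_stage", "department",
                   "primary_dx", "secondary_dx", "treatments", "total_cost"]
        return pd.DataFrame(rows, columns=columns)


def _department_for(cancer_type: str) -> str:
    return {
        "lung": "thoracic surgery",
        "colon": "colorectal oncology",
        "rectal": "colorectal oncology",
        "breast": "breast surgery",
        "gastric": "general surgery",
    }[cancer_type]


def generate_patient_table(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Patient-level table (demographics + condition indicators + outcomes)."""
    return CohortSimulator(spec).sample_patients(seed=seed)


def generate_cohort(spec: CohortSpec, seed: int | None = None):
    """Admission-level records for the synthetic cohort.

    Returns a list of :class:`oncoburden.ingest.AdmissionRecord`.
    """
    from .ingest import admissions_from_frame

    frame = CohortSimulator(spec).sample_admissions(seed=seed)
    return admissions_from_frame(frame)


def planted_block_correlation(cohort, block: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations of condition indicators within a block.

    ``cohort`` may be a patient-level indicator DataFrame (as produced by
    :func:`generate_patient_table` or the scorer) or a list of admission
    records, which is then collapsed and scored with the default condition
    map.
    """
    block = list(block)
    if not isinstance(cohort, pd.DataFrame):
        from .ingest import collapse_to_patients
        from .scoring import ComorbidityScorer

        patients = collapse_to_patients(cohort)
        cohort = ComorbidityScorer().fit_transform(patients)
    missing = [c for c in block if c not in cohort.columns]
    if missing:
        raise KeyError(f"unknown condition(s) in block: {missing}")
    sub = cohort[block].astype(float)
    if len(block) == 1:
        return pd.DataFrame([[1.0]], index=block, columns=block)
    return sub.corr(method="pearson")
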