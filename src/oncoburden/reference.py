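"""Published summary counts of the emulated case-study cohort.

The underlying patient-level hospital data are not public; what is public
is the summary arithmetic: 4,666 inpatients across five cancer types,
with/without-comorbidity counts per cancer type, and per-condition counts
overall and by cancer type. This module stores those counts and expands
them into a synthetic patient-level indicator table that realizes every
count exactly, so the ordinary prevalence code path can recompute the
published percentages (overall comorbidity rate, per-cancer-type rates,
per-condition prevalences) from first principles.

The reconstruction reproduces the marginal counts only — the joint
distribution of conditions within patients is an artifact of the cyclic
fill and carries no information.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conditions import default_weight_table
from .scoring import PrevalenceTables, SeverityThresholds, prevalence_table

__all__ = [
    "REFERENCE_TOTAL",
    "REFERENCE_STRATA",
    "REFERENCE_CONDITION_COUNTS",
    "reconstruct_reference_cohort",
    "reference_prevalence_tables",
]

REFERENCE_TOTAL = 4666

# cancer type -> (n patients, n with >=1 comorbidity)
REFERENCE_STRATA: dict[str, tuple[int, int]] = {
    "lung": (1728, 1446),
    "colon": (570, 480),
    "rectal": (582, 457),
    "breast": (797, 385),
    "gastric": (989, 786),
}

# condition -> counts per cancer type (lung, colon, rectal, breast, gastric)
REFERENCE_CONDITION_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "mild_liver_disease": (397, 172, 154, 110, 213),
    "renal_disease": (264, 158, 163, 19, 217),
    "diabetes": (300, 106, 105, 79, 152),
    "myocardial_infarction": (292, 119, 85, 68, 166),
    "peptic_ulcer": (153, 77, 55, 29, 128),
    "peripheral_vascular_disease": (172, 56, 60, 30, 61),
    "copd": (199, 30, 52, 17, 60),
    "cerebrovascular_disease": (110, 36, 24, 13, 52),
    "moderate_severe_liver_disease": (28, 14, 14, 8, 26),
    "congestive_heart_failure": (33, 9, 11, 0, 24),
    "diabetes_with_complications": (29, 7, 4, 2, 7),
    "connective_tissue_disease": (22, 4, 2, 5, 6),
    "dementia": (0, 0, 2, 1, 2),
    "paralysis": (0, 2, 0, 0, 0),
    "hypertension": (601, 222, 196, 171, 305),
}

_TYPE_ORDER = ("lung", "colon", "rectal", "breast", "gastric")


def reconstruct_reference_cohort() -> pd.DataFrame:
    """Patient-level indicator table realizing the published counts.

    Within each cancer type the condition counts are spread cyclically over
    the with-comorbidity patients (total condition slots exceed the
    with-comorbidity count in every stratum, so every such patient receives
    at least one condition); without-comorbidity patients are all-zero rows.
    """
    conditions = list(REFERENCE_CONDITION_COUNTS)
    frames = []
    for ti, t in enumerate(_TYPE_ORDER):
        n, n_with = REFERENCE_STRATA[t]
        X = np.zeros((n, len(conditions)), dtype=np.int8)
        pointer = 0
        for j, cond in enumerate(conditions):
            count = REFERENCE_CONDITION_COUNTS[cond][ti]
            if count > n_with:
                raise ValueError(
                    f"{cond} count {count} exceeds with-comorbidity "
                    f"patients {n_with} in stratum {t}")
            idx = (pointer + np.arange(count)) % n_with
            X[idx, j] = 1
            pointer += count
        df = pd.DataFrame(X, columns=conditions)
        df.insert(0, "cancer_type", t)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "patient_id", [f"R{i:05d}" for i in range(len(out))])

    weights = default_weight_table()
    w = np.array([weights[c] for c in conditions])
    mat = out[conditions].to_numpy(dtype=int)
    out["comorbidity_count"] = mat.sum(axis=1)
    out["cci_score"] = mat @ w
    grade = SeverityThresholds()
    out["severity"] = [grade.grade(int(s)) for s in out["cci_score"]]

    assert len(out) == REFERENCE_TOTAL
    for ti, t in enumerate(_TYPE_ORDER):
        sub = out[out["cancer_type"] == t]
        assert int((sub["comorbidity_count"] >= 1).sum()) == REFERENCE_STRATA[t][1]
        for cond in conditions:
            assert int(sub[cond].sum()) == REFERENCE_CONDITION_COUNTS[cond][ti]
    return out


def reference_prevalence_tables() -> PrevalenceTables:
    """Run the standard prevalence computation on the reconstructed cohort."""
    return prevalence_table(reconstruct_reference_cohort())
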