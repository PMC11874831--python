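"""Condition rosters: ICD-10 prefix maps and Charlson weights.

The cancer-adapted (NCI) Charlson roster drops solid tumours, leukaemias and
lymphomas as comorbid conditions and consolidates the remainder to 14
conditions; hypertension is carried as a 15th condition because of its high
prevalence in hospital cancer cohorts. Connective tissue disease ships as an
optional 16th condition, off by default.

Code lists follow the published Quan et al. ICD-10 enumeration of Charlson
conditions, stored as dot-free uppercase prefixes; membership is decided by
case- and dot-insensitive prefix matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ConditionMap",
    "WeightTable",
    "default_condition_map",
    "default_weight_table",
    "normalize_icd10",
    "is_valid_icd10",
    "EXEMPLAR_CODES",
]

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$")


def normalize_icd10(code: str) -> str:
    """Uppercase an ICD-10 code and strip dots and whitespace."""
    return code.strip().upper().replace(".", "")


def is_valid_icd10(code: str) -> bool:
    """Syntactic check: letter + two digits + up to four alphanumerics."""
    return bool(_ICD10_RE.match(normalize_icd10(code)))


# One exemplar code per condition, used by the cohort simulator when it emits
# diagnosis lists. Overridable through CohortSpec.
EXEMPLAR_CODES: dict[str, str] = {
    "myocardial_infarction": "I21.9",
    "congestive_heart_failure": "I50.9",
    "peripheral_vascular_disease": "I73.9",
    "cerebrovascular_disease": "I63.9",
    "dementia": "F03",
    "copd": "J44.9",
    "connective_tissue_disease": "M32.9",
    "peptic_ulcer": "K25.9",
    "mild_liver_disease": "K73.9",
    "diabetes": "E11.9",
    "diabetes_with_complications": "E11.2",
    "paralysis": "G81.9",
    "renal_disease": "N18.9",
    "moderate_severe_liver_disease": "K72.1",
    "aids": "B20",
    "hypertension": "I10",
}


class ConditionMapError(ValueError):
    """Raised when a condition map violates its structural invariants."""


@dataclass(frozen=True)
class ConditionMap:
    """Mapping condition name -> ICD-10 code prefixes, plus hierarchies.

    Parameters
    ----------
    prefixes : mapping of condition name to list of dot-free uppercase
        ICD-10 prefixes.
    hierarchies : list of (mild, severe) condition-name pairs; a patient with
        codes for both counts only toward the severe member.
    dialect : label recorded in outputs for provenance.
    """

    prefixes: dict[str, tuple[str, ...]]
    hierarchies: tuple[tuple[str, str], ...] = ()
    dialect: str = "custom"

    def __post_init__(self) -> None:
        self._validate()

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.prefixes)

    def _validate(self) -> None:
        hier_sets = [frozenset(pair) for pair in self.hierarchies]
        for mild, severe in self.hierarchies:
            for name in (mild, severe):
                if name not in self.prefixes:
                    raise ConditionMapError(
                        f"hierarchy references unknown condition {name!r}"
                    )
        names = list(self.prefixes)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if frozenset((a, b)) in hier_sets:
                    continue
                for pa in self.prefixes[a]:
                    for pb in self.prefixes[b]:
                        if pa.startswith(pb) or pb.startswith(pa):
                            raise ConditionMapError(
                                f"prefix clash between {a!r} ({pa}) and "
                                f"{b!r} ({pb}); only hierarchy pairs may share codes"
                            )

    def match(self, code: str) -> str | None:
        """Return the condition a single (normalized) code maps to, if any."""
        norm = normalize_icd10(code)
        for condition, prefixes in self.prefixes.items():
            if any(norm.startswith(p) for p in prefixes):
                return condition
        return None

    def severe_counterpart(self, condition: str) -> str | None:
        for mild, severe in self.hierarchies:
            if condition == mild:
                return severe
        return None


@dataclass(frozen=True)
class WeightTable:
    """Condition -> integer Charlson weight.

    Weights for index conditions lie in 1..6; conditions carried outside the
    Charlson index (hypertension by default) may carry weight 0 so that they
    count toward comorbidity number but not the score.
    """

    weights: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, w in self.weights.items():
            if not isinstance(w, int) or not 0 <= w <= 6:
                raise ValueError(
                    f"weight for {cond!r} must be an integer in 0..6, got {w!r}"
                )

    def __getitem__(self, condition: str) -> int:
        try:
            return self.weights[condition]
        except KeyError:
            raise KeyError(
                f"condition {condition!r} missing from the weight table"
            ) from None


def _data_path(name: str) -> Path:
    return Path(str(resources.files("oncoburden").joinpath("data", name)))


def default_condition_map(
    include_connective_tissue: bool = False,
    path: str | Path | None = None,
) -> ConditionMap:
    """Load the packaged Quan-dialect condition map.

    Parameters
    ----------
    include_connective_tissue : add the optional 16th condition.
    path : override the packaged YAML with a user file of the same layout.
    """
    raw = yaml.safe_load(Path(path or _data_path("nci_conditions.yaml")).read_text())
    prefixes = {c: tuple(v) for c, v in raw["conditions"].items()}
    if include_connective_tissue:
        for c, v in raw.get("optional_conditions", {}).items():
            prefixes[c] = tuple(v)
    hier = tuple((m, s) for m, s in raw.get("hierarchies", []))
    return ConditionMap(prefixes=prefixes, hierarchies=hier, dialect=raw["dialect"])


def default_weight_table(path: str | Path | None = None) -> WeightTable:
    """Load the packaged Charlson weight table."""
    raw = yaml.safe_load(Path(path or _data_path("cci_weights.yaml")).read_text())
    return WeightTable(weights={c: int(w) for c, w in raw["weights"].items()})
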