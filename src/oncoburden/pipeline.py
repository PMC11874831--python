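"""End-to-end orchestration: simulate/ingest -> score -> cluster -> associate.

Every run writes a fixed set of artifacts into a run directory — filter
report, scored patients, prevalence tables, per-stratum dendrograms
(Newick + merge table), cluster memberships, association results — plus a
provenance manifest carrying the seed, a canonical hash of the
configuration, the package version and a checksum per artifact. Artifact
names are content-independent and no output embeds a timestamp, so two runs
with the same configuration and seed are byte-identical and diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import CorrelationHierarchicalClustering
from .conditions import default_condition_map, default_weight_table
from .ingest import (
    CsvDialect,
    InclusionRules,
    apply_inclusion_exclusion,
    patients_to_frame,
    read_admissions,
)
from .models import ClusterOutcomeRegression, build_outcome_frame
from .scoring import ComorbidityScorer, compare_groups, prevalence_table
from .simulate import CohortSpec, CohortSimulator

logger = logging.getLogger("oncoburden.pipeline")

__all__ = ["RunConfig", "StageError", "run_pipeline", "simulate_to_csv"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``input_csv`` is None a synthetic cohort is generated from
    ``simulate`` (keyword overrides of :class:`CohortSpec`, seeded with
    ``seed``) and written as the run's own input.
    """

    out_dir: str = "run"
    input_csv: str | None = None
    simulate: dict = field(default_factory=dict)
    condition_map_path: str | None = None
    weight_table_path: str | None = None
    include_connective_tissue: bool = False
    rules: dict = field(default_factory=dict)
    min_count: int = 3
    linkage: str = "average"
    distance: str = "one_minus_r"
    # default cut: keep condition groups whose merge height stays below 0.8,
    # i.e. pairwise correlation above 0.2 under d = 1 - r
    n_clusters: int | None = None
    height: float | None = 0.8
    exclusive: bool = True
    covariates: str = "table"
    min_cluster_size: int = 10
    reference: str = "no_cluster"
    impute_cost: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("input_csv", "condition_map_path", "weight_table_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # location, not content
        return json.loads(json.dumps(d, sort_keys=True, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _inclusion_rules(overrides: dict) -> InclusionRules:
    kw = dict(overrides)
    for key in ("window_start", "window_end"):
        if key in kw and isinstance(kw[key], str):
            kw[key] = pd.Timestamp(kw[key]).date()
    if "cancer_types" in kw:
        kw["cancer_types"] = frozenset(kw["cancer_types"])
    return InclusionRules(**kw)


def simulate_to_csv(spec: CohortSpec, path: str | Path) -> pd.DataFrame:
    """Generate an admissions table and write it in the standard dialect."""
    frame = CohortSimulator(spec).sample_admissions()
    frame.to_csv(path, index=False)
    return frame


def run_pipeline(config: RunConfig) -> Path:
    """Execute all four steps; returns the run directory.

    Stages run in order (simulate/ingest, score, cluster, associate); a
    failure halts the run with :class:`StageError` but leaves the completed
    stages' artifacts in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save_csv(name: str, frame: pd.DataFrame, **kw) -> None:
        path = out / name
        frame.to_csv(path, **kw)
        artifacts[name] = path

    # -- step 1: input + inclusion/exclusion -------------------------------
    try:
        if config.input_csv is None:
            spec = CohortSpec(**{"seed": config.seed, **config.simulate})
            input_path = out / "admissions.csv"
            simulate_to_csv(spec, input_path)
            artifacts["admissions.csv"] = input_path
        else:
            input_path = Path(config.input_csv)
        admissions, errors = read_admissions(input_path, CsvDialect())
        patients, report = apply_inclusion_exclusion(
            admissions, _inclusion_rules(config.rules), parse_errors=errors)
        (out / "filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        artifacts["filter_report.json"] = out / "filter_report.json"
        save_csv("patients.csv", patients_to_frame(patients), index=False)
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    # -- step 2: comorbidity scoring ---------------------------------------
    try:
        cmap = default_condition_map(
            include_connective_tissue=config.include_connective_tissue,
            path=config.condition_map_path)
        weights = default_weight_table(path=config.weight_table_path)
        scorer = ComorbidityScorer(condition_map=cmap,
                                   weight_table=weights).fit()
        scored = scorer.transform(patients_to_frame(patients))
        scored = scored.set_index("patient_id", drop=False)
        save_csv("scored.csv", scored, index=False)
        tables = prevalence_table(scored)
        save_csv("prevalence_conditions.csv", tables.condition_counts)
        save_csv("prevalence_rates.csv", tables.comorbidity_rates)
        save_csv("prevalence_count_distribution.csv", tables.count_distribution)
        save_csv("prevalence_severity.csv", tables.severity_distribution)
        save_csv("baseline_comparison.csv", compare_groups(scored), index=False)
    except Exception as exc:
        raise StageError("score", exc) from exc

    # -- step 3: pattern clustering per cancer-type stratum ----------------
    try:
        conditions = list(cmap.conditions)
        labels = pd.Series("none", index=scored.index, dtype=object)
        summaries = []
        merge_rows = []
        newicks = []
        for stratum in sorted(scored["cancer_type"].unique()):
            sub = scored.loc[scored["cancer_type"] == stratum, conditions]
            try:
                n_leaves = int((sub.sum(axis=0) >= config.min_count).sum())
                if n_leaves < 2:
                    logger.info("stratum %s: fewer than 2 prevalent "
                                "conditions, skipping clustering", stratum)
                    continue
                clusterer = CorrelationHierarchicalClustering(
                    linkage=config.linkage, distance=config.distance,
                    min_count=config.min_count,
                    n_clusters=(min(config.n_clusters, n_leaves)
                                if config.n_clusters is not None else None),
                    height=config.height, exclusive=config.exclusive)
                clusterer.fit(sub)
            except ValueError as exc:
                logger.info("stratum %s: clustering skipped (%s)", stratum, exc)
                continue
            labels.loc[sub.index] = clusterer.labels_
            cs = clusterer.cluster_set_
            cs.stratum = stratum
            summaries.append(cs.summary())
            mf = clusterer.dendrogram_.to_merge_frame()
            mf.insert(0, "stratum", stratum)
            merge_rows.append(mf)
            newicks.append(f"{stratum}\t{clusterer.dendrogram_.to_newick()}")
        (out / "dendrograms.newick").write_text("\n".join(newicks) + "\n")
        artifacts["dendrograms.newick"] = out / "dendrograms.newick"
        merge_frame = (pd.concat(merge_rows, ignore_index=True)
                       if merge_rows else pd.DataFrame(
                           columns=["stratum", "step", "left", "right", "height"]))
        save_csv("dendrogram_merges.csv", merge_frame, index=False)
        summary_frame = (pd.concat(summaries, ignore_index=True)
                         if summaries else pd.DataFrame(
                             columns=["stratum", "cluster", "n_conditions",
                                      "n_patients"]))
        save_csv("cluster_summary.csv", summary_frame, index=False)
        membership = pd.DataFrame({"patient_id": scored["patient_id"],
                                   "cluster": labels})
        save_csv("cluster_membership.csv", membership, index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    # -- step 4: association models ----------------------------------------
    try:
        frame = build_outcome_frame(scored, labels, impute=config.impute_cost)
        model = ClusterOutcomeRegression(
            covariates=config.covariates,
            min_cluster_size=config.min_cluster_size,
            reference=config.reference).fit(frame)
        save_csv("associations.csv", model.summary_, index=False)
        save_csv("association_table.csv", model.table_, index=False)
        (out / "association_table.txt").write_text(
            model.table_.to_string(index=False) + "\n")
        artifacts["association_table.txt"] = out / "association_table.txt"
    except Exception as exc:
        raise StageError("associate", exc) from exc

    canonical = config.canonical()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": canonical,
        "config_sha256": hashlib.sha256(
            json.dumps(canonical, sort_keys=True).encode()).hexdigest(),
        "artifacts": {name: _sha256(path)
                      for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
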