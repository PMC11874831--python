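"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from oncoburden import AdmissionRecord, CohortSpec, CohortSimulator


def make_admission(pid="P1", adm="2018-01-10", dis="2018-01-15",
                   cancer_type="lung", histology="adenocarcinoma",
                   sex="male", stage="II", secondary=(), cost=50000.0,
                   treatments=frozenset({"surgery"}), **kw) -> AdmissionRecord:
    defaults = dict(
        patient_id=pid,
        admission_date=dt.date.fromisoformat(adm),
        discharge_date=dt.date.fromisoformat(dis),
        age=60.0, sex=sex, insured=True, married=True, residency="urban",
        cancer_type=cancer_type, histology=histology, cancer_stage=stage,
        department="oncology", primary_dx="C34.9",
        secondary_dx=tuple(secondary), treatment_flags=treatments,
        total_cost=cost, education="secondary")
    defaults.update(kw)
    return AdmissionRecord(**defaults)


@pytest.fixture
def small_spec() -> CohortSpec:
    return CohortSpec(n_patients=100, seed=42)


@pytest.fixture
def small_admissions(small_spec):
    return CohortSimulator(small_spec).sample_admissions()


def oracle_agglomerate(D: pd.DataFrame, linkage: str):
    """Brute-force agglomeration recomputing every inter-group distance
    from the original matrix at each step (no Lance-Williams updates)."""
    agg = {"average": lambda xs: sum(xs) / len(xs),
           "complete": max, "single": min}[linkage]
    groups: list[tuple[str, ...]] = [(str(c),) for c in D.columns]
    merges = []
    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                d = agg([float(D.loc[x, y]) for x in a for y in b])
                la, lb = sorted((min(a), min(b)))
                key = (d, la, lb)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        a, b = groups[i], groups[j]
        merges.append((frozenset(a), frozenset(b), d))
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(tuple(sorted(a + b)))
    return merges


def merge_signature(dendrogram):
    """Comparable form of a merge sequence: unordered pair of member sets
    plus height, per step."""
    return [(frozenset((frozenset(m.left), frozenset(m.right))), m.height)
            for m in dendrogram.merges]


def oracle_signature(merges):
    return [(frozenset((l, r)), h) for l, r, h in merges]


def assert_same_merges(dendrogram, oracle_merges, atol=1e-10):
    got = merge_signature(dendrogram)
    want = oracle_signature(oracle_merges)
    assert len(got) == len(want)
    for (gp, gh), (wp, wh) in zip(got, want):
        assert gp == wp
        assert gh == pytest.approx(wh, abs=atol)
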