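from __future__ import annotations

import numpy as np
import pytest

from phenoclust import (
    Cohort,
    OntologyDAG,
    OntologyTerm,
    PatientProfile,
    cohort_information_content,
)
from phenoclust import reference


def make_dag(parent_map: dict[str, set[str] | list[str]]) -> OntologyDAG:
    terms = [
        OntologyTerm(t, f"term {t}", frozenset(p)) for t, p in parent_map.items()
    ]
    return OntologyDAG(terms)


@pytest.fixture(scope="session")
def toy_dag() -> OntologyDAG:
    """Small hand-built DAG: R <- A,B; A <- C,D; B <- E; {A,B} <- F (diamond)."""
    return make_dag(
        {
            "R": [],
            "A": ["R"],
            "B": ["R"],
            "C": ["A"],
            "D": ["A"],
            "E": ["B"],
            "F": ["A", "B"],
        }
    )


@pytest.fixture(scope="session")
def fixture_dag() -> OntologyDAG:
    return reference.load_fixture_ontology()


@pytest.fixture(scope="session")
def toy_cohort(toy_dag) -> Cohort:
    """Five-patient cohort over the toy DAG with survival outcomes."""
    profiles = [
        PatientProfile("p1", frozenset({"C", "D"}), time=5.0, event=0),
        PatientProfile("p2", frozenset({"C", "E"}), time=2.0, event=1),
        PatientProfile("p3", frozenset({"D", "E", "F"}), time=7.0, event=0),
        PatientProfile("p4", frozenset({"A"}), time=1.0, event=1),
        PatientProfile("p5", frozenset({"C", "D", "E"}), time=4.0, event=0),
    ]
    return Cohort(profiles, toy_dag)


@pytest.fixture(scope="session")
def toy_ic(toy_cohort):
    return cohort_information_content(toy_cohort, closure_mode="propagated")


def random_cohort(rng: np.random.Generator, dag: OntologyDAG, n: int) -> Cohort:
    """Random cohort: each patient draws 1-6 terms from the DAG."""
    terms = sorted(dag.terms)
    profiles = []
    for i in range(n):
        k = int(rng.integers(1, min(7, len(terms) + 1)))
        chosen = rng.choice(terms, size=k, replace=False)
        profiles.append(PatientProfile(f"r{i:03d}", frozenset(chosen.tolist())))
    return Cohort(profiles, dag)
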