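"""Patient cohorts: loading, validation, term frequencies and information content.

A cohort is an ordered collection of patient phenotype profiles, each a
non-empty set of ontology term ids plus demographic covariates and a
right-censored survival outcome.  From the cohort we derive the annotation
frequency ``p_t`` of each term and its information content
``IC(t) = -log p_t`` — the quantity that drives Resnik-style semantic
similarity: rare phenotypes are informative, ubiquitous ones are not.

Two closure modes are supported when counting term carriers:

``explicit``
    A patient carries exactly the terms written in their record.  This is
    what descriptive frequency tables report.
``propagated``
    Each patient's term set is closed under ontology ancestors (the
    "true path" rule).  This guarantees that an ancestor is never rarer
    than its descendant, hence IC is monotone along is-a paths — the
    property Resnik similarity relies on.  Default for similarity work.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyDAG, UnknownTermError

__all__ = [
    "PatientProfile",
    "Cohort",
    "ICTable",
    "CohortError",
    "load_cohort",
    "term_frequencies",
    "information_content",
    "cohort_information_content",
    "terms_per_patient",
]

ClosureMode = Literal["explicit", "propagated"]

SURGERY_LEVELS = ("repair", "shunts", "repair_plus_shunts")

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


class CohortError(ValueError):
    """Invalid cohort file or profile."""


@dataclass(frozen=True)
class PatientProfile:
    """One patient's phenotype term set, covariates and survival outcome."""

    patient_id: str
    terms: frozenset[str]
    age_at_surgery: float | None = None
    sex: str | None = None  # "female" / "male"
    bmi: float | None = None
    family_history: bool | None = None
    surgery: str | None = None  # one of SURGERY_LEVELS
    time: float | None = None  # years from definitive surgery
    event: int | None = None  # 1 = death, 0 = censored

    def __post_init__(self):
        if not self.terms:
            raise CohortError(
                f"patient {self.patient_id!r} has no phenotype terms; "
                "every patient must carry at least one term"
            )
        if self.time is not None:
            if self.time < 0:
                raise CohortError(
                    f"patient {self.patient_id!r} has negative survival time"
                )
            if self.event is None:
                raise CohortError(
                    f"patient {self.patient_id!r} has a survival time but no "
                    "event indicator"
                )


class Cohort:
    """Ordered list of validated patient profiles tied to an ontology."""

    def __init__(self, patients: Sequence[PatientProfile], dag: OntologyDAG):
        seen: set[str] = set()
        for p in patients:
            if p.patient_id in seen:
                raise CohortError(f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)
            for t in p.terms:
                if t not in dag:
                    extra = (
                        " (obsolete)" if t in dag.obsolete_ids else ""
                    )
                    raise CohortError(
                        f"patient {p.patient_id!r} annotated with unknown "
                        f"term {t!r}{extra}"
                    )
        self.patients: list[PatientProfile] = list(patients)
        self.dag = dag

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __getitem__(self, i: int) -> PatientProfile:
        return self.patients[i]

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def term_sets(self, closure_mode: ClosureMode = "explicit") -> list[frozenset[str]]:
        if closure_mode == "explicit":
            return [p.terms for p in self.patients]
        if closure_mode == "propagated":
            return [
                frozenset().union(*(self.dag.ancestors(t) for t in p.terms))
                for p in self.patients
            ]
        raise ValueError(f"unknown closure_mode {closure_mode!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the cohort TSV column layout."""
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "hpo_terms": "|".join(sorted(p.terms)),
                    "age_at_surgery": p.age_at_surgery,
                    "sex": p.sex,
                    "bmi": p.bmi,
                    "family_history": (
                        "" if p.family_history is None else int(p.family_history)
                    ),
                    "surgery": p.surgery,
                    "time": p.time,
                    "event": p.event,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ICTable:
    """Cohort term frequencies ``p_t`` and information content ``IC(t)``.

    ``ic`` only contains terms with non-zero frequency; ``IC = -log p`` in
    the configured base (natural log by default).
    """

    frequency: dict[str, float]
    counts: dict[str, int]
    n_patients: int
    closure_mode: ClosureMode
    ic: dict[str, float] = field(default_factory=dict)
    log_base: str = "e"

    def get_ic(self, term_id: str) -> float:
        """IC of a term; 0 for terms never observed in the cohort."""
        return self.ic.get(term_id, 0.0)

    def to_frame(self, dag: OntologyDAG | None = None) -> pd.DataFrame:
        rows = []
        for t in sorted(self.frequency):
            rows.append(
                {
                    "term_id": t,
                    "name": dag.terms[t].name if dag and t in dag else "",
                    "count": self.counts[t],
                    "frequency": self.frequency[t],
                    "ic": self.ic.get(t, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def _parse_bool(value: str) -> bool | None:
    if value == "":
        return None
    if value.lower() in {"1", "true", "yes"}:
        return True
    if value.lower() in {"0", "false", "no"}:
        return False
    raise CohortError(f"cannot parse boolean field {value!r}")


def _parse_event(value: str) -> int | None:
    if value == "":
        return None
    mapping = {"1": 1, "death": 1, "0": 0, "censored": 0}
    try:
        return mapping[value.strip().lower()]
    except KeyError:
        raise CohortError(f"cannot parse event indicator {value!r}") from None


def load_cohort(
    path: str | Path,
    dag: OntologyDAG,
    on_unsupported: Literal["error", "drop", "remap"] = "error",
    supported: Iterable[str] | None = None,
) -> Cohort:
    """Load and validate a cohort TSV.

    Expected tab-separated columns: ``patient_id``, ``hpo_terms``
    (pipe-separated term ids), ``age_at_surgery``, ``sex``, ``bmi``,
    ``family_history``, ``surgery``, ``time``, ``event``.  Missing
    covariates are empty fields.  alt_id accessions resolve to their
    primary term.

    ``on_unsupported`` controls what happens when a term is valid in the
    ontology but outside ``supported`` (e.g. the analysis vocabulary of a
    similarity index): raise, silently drop it, or remap it to its nearest
    supported ancestor.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"patient_id", "hpo_terms", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"cohort file missing columns: {sorted(missing)}")
    supported_set = set(supported) if supported is not None else None

    patients: list[PatientProfile] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based with header
        pid = row["patient_id"]
        raw_terms = [t for t in row["hpo_terms"].split("|") if t]
        if not raw_terms:
            raise CohortError(
                f"row {rowno} (patient {pid!r}): empty term field; every "
                "patient must have at least one term"
            )
        terms: set[str] = set()
        for t in raw_terms:
            try:
                t = dag.resolve(t)
            except UnknownTermError as exc:
                raise CohortError(f"row {rowno} (patient {pid!r}): {exc}") from exc
            if supported_set is not None and t not in supported_set:
                if on_unsupported == "drop":
                    continue
                if on_unsupported == "remap":
                    t = dag.remap_to_supported(t, supported_set)
                else:
                    raise CohortError(
                        f"row {rowno} (patient {pid!r}): term {t!r} is not in "
                        "the supported set"
                    )
            terms.add(t)
        if not terms:
            raise CohortError(
                f"row {rowno} (patient {pid!r}): no valid terms remain after "
                "filtering"
            )

        def _float(col: str) -> float | None:
            v = row.get(col, "")
            return float(v) if v != "" else None

        time = _float("time")
        if time is not None and time < 0:
            raise CohortError(f"row {rowno} (patient {pid!r}): negative time")
        surgery = row.get("surgery", "") or None
        if surgery is not None and surgery not in SURGERY_LEVELS:
            raise CohortError(
                f"row {rowno} (patient {pid!r}): surgery must be one of "
                f"{SURGERY_LEVELS}, got {surgery!r}"
            )
        try:
            profile = PatientProfile(
                patient_id=pid,
                terms=frozenset(terms),
                age_at_surgery=_float("age_at_surgery"),
                sex=row.get("sex", "") or None,
                bmi=_float("bmi"),
                family_history=_parse_bool(row.get("family_history", "")),
                surgery=surgery,
                time=time,
                event=_parse_event(row.get("event", "")),
            )
        except CohortError as exc:
            raise CohortError(f"row {rowno}: {exc}") from exc
        patients.append(profile)
    return Cohort(patients, dag)


def term_frequencies(
    cohort: Cohort, closure_mode: ClosureMode = "propagated"
) -> ICTable:
    """Carrier counts and frequencies ``p_t`` for every observed term.

    ``frequency[t]`` is the fraction of patients whose (explicit or
    ancestor-propagated) term set contains ``t``.
    """
    if len(cohort) == 0:
        raise CohortError("cannot compute frequencies on an empty cohort")
    counter: Counter[str] = Counter()
    for terms in cohort.term_sets(closure_mode):
        counter.update(terms)
    n = len(cohort)
    counts = dict(counter)
    freq = {t: c / n for t, c in counts.items()}
    return ICTable(
        frequency=freq, counts=counts, n_patients=n, closure_mode=closure_mode
    )


def information_content(table: ICTable, log_base: str = "e") -> ICTable:
    """Fill ``ic[t] = -log(frequency[t])`` on a frequency table.

    Terms with zero frequency never appear in the table (a term that no
    patient carries has no defined IC and cannot act as a common ancestor).
    """
    if log_base not in _LOG_BASES:
        raise ValueError(f"log_base must be one of {sorted(_LOG_BASES)}")
    base = _LOG_BASES[log_base]
    ic = {}
    for t, p in table.frequency.items():
        if not 0.0 < p <= 1.0:
            raise ValueError(f"frequency of {t!r} outside (0, 1]: {p}")
        ic[t] = -math.log(p, base) if p < 1.0 else 0.0
    table.ic = ic
    table.log_base = log_base
    return table


def cohort_information_content(
    cohort: Cohort,
    closure_mode: ClosureMode = "propagated",
    log_base: str = "e",
) -> ICTable:
    """Frequency counting and IC in one step (the usual entry point)."""
    return information_content(term_frequencies(cohort, closure_mode), log_base)


def terms_per_patient(cohort: Cohort) -> tuple[dict[int, int], float]:
    """Histogram of explicit term-set sizes and their median."""
    if len(cohort) == 0:
        raise CohortError("empty cohort")
    sizes = [len(p.terms) for p in cohort]
    hist = dict(sorted(Counter(sizes).items()))
    return hist, float(np.median(sizes))
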