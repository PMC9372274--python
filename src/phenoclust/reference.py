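"""Published benchmark figures for a pulmonary-atresia cohort (n = 648).

The packaged table ``reference_term_counts.tsv`` carries per-cluster
carrier counts of 47 cardiovascular phenotype terms from a published
single-centre pulmonary-atresia cohort characterisation, keyed to the toy
ontology's term ids.  These counts are *descriptive inputs* — the raw
patient-level data are not public — and serve two purposes: sanity-checking
explicit-mode frequency arithmetic against printed percentages, and shaping
the synthetic cohort generator's archetypes.

Note: the per-cluster counts for PAS sum to 48 while the published overall
count is 49; both are preserved as printed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .ontology import OntologyDAG, parse_obo

__all__ = [
    "CLUSTER_SIZES",
    "N_ANALYSIS",
    "N_ENROLLED",
    "N_FOLLOWUP_REACHED",
    "FEMALE_COUNTS",
    "SURGERY_COUNTS",
    "load_reference_counts",
    "load_fixture_ontology",
    "fixture_ontology_path",
]

CLUSTER_SIZES = (522, 94, 32)  #: phenotype cluster sizes, largest first
N_ANALYSIS = sum(CLUSTER_SIZES)  #: patients in the final analysis (648)
N_ENROLLED = 715  #: patients enrolled before follow-up exclusions
N_FOLLOWUP_REACHED = 366  #: patients reached by telephone follow-up
FEMALE_COUNTS = (295, 241, 46, 8)  #: overall, cluster 1, 2, 3
SURGERY_COUNTS = {
    "repair": (324, 279, 35, 10),
    "shunts": (204, 150, 38, 16),
    "repair_plus_shunts": (120, 93, 21, 6),
}


def _data_path(name: str) -> Path:
    return Path(resources.files("phenoclust") / "data" / name)


def load_reference_counts() -> pd.DataFrame:
    """Per-cluster term carrier counts, indexed by term id."""
    df = pd.read_csv(_data_path("reference_term_counts.tsv"), sep="\t")
    return df.set_index("term_id")


def fixture_ontology_path() -> Path:
    return _data_path("toy_cardio.obo")


def load_fixture_ontology() -> OntologyDAG:
    """The packaged toy cardiovascular ontology (60 terms, depth 4)."""
    return parse_obo(fixture_ontology_path())
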