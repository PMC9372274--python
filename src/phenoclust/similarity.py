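"""Resnik term similarity, best-match-average patient similarity, and the
similarity -> distance transform.

The similarity of two ontology terms is the information content of their
most informative common ancestor (MICA):

    sim(s, t) = max_{v in anc(s) ∩ anc(t)} IC(v)

and the similarity of two patients' term sets ``D_a``, ``D_b`` is the
symmetric best-match average

    sim(D_a, D_b) = 1/(2|D_a|) Σ_{s in D_a} max_{t in D_b} sim(s, t)
                  + 1/(2|D_b|) Σ_{s in D_b} max_{t in D_a} sim(s, t).

Clustering consumes the dissimilarity ``max(sim_mat) − sim_mat`` where the
max runs over the full matrix (diagonal included); the diagonal of the
result is then forced to exactly zero so it is a valid dissimilarity.

Accumulation order is fixed (term ids sorted) so matrices are
bit-reproducible run to run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import Cohort, ICTable
from .ontology import OntologyDAG

__all__ = [
    "term_similarity",
    "set_similarity",
    "similarity_matrix",
    "to_distance",
    "PatientSimilarityMatrix",
    "PatientDistanceMatrix",
]


def term_similarity(s: str, t: str, ic: ICTable, dag: OntologyDAG) -> float:
    """Resnik similarity: max IC over the common ancestors of ``s`` and ``t``.

    Common ancestors never observed in the cohort carry no IC and
    contribute 0; if the two terms share no ancestor at all (multi-rooted
    ontology) the similarity is 0.
    """
    common = dag.common_ancestors(s, t)
    if not common:
        return 0.0
    return max((ic.get_ic(v) for v in sorted(common)), default=0.0)


def set_similarity(
    Da: Iterable[str], Db: Iterable[str], ic: ICTable, dag: OntologyDAG
) -> float:
    """Symmetric best-match-average similarity of two phenotype term sets."""
    Da, Db = sorted(set(Da)), sorted(set(Db))
    if not Da or not Db:
        raise ValueError("set similarity requires two non-empty term sets")
    forward = sum(max(term_similarity(s, t, ic, dag) for t in Db) for s in Da)
    backward = sum(max(term_similarity(s, t, ic, dag) for t in Da) for s in Db)
    return forward / (2 * len(Da)) + backward / (2 * len(Db))


@dataclass
class PatientSimilarityMatrix:
    patient_ids: list[str]
    sim: np.ndarray  # (n, n) symmetric, entries >= 0

    @property
    def max_sim(self) -> float:
        """Global maximum of the matrix, diagonal included."""
        return float(self.sim.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sim, index=self.patient_ids, columns=self.patient_ids)


@dataclass
class PatientDistanceMatrix:
    patient_ids: list[str]
    dist: np.ndarray
    max_sim: float  # derivation record: the max subtracted from

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist, index=self.patient_ids, columns=self.patient_ids)


def similarity_matrix(
    cohort: Cohort, ic: ICTable, dag: OntologyDAG | None = None
) -> PatientSimilarityMatrix:
    """All pairwise best-match-average similarities of a cohort.

    Vectorised in two passes: first a term x term Resnik matrix over the
    cohort vocabulary, then per-patient best-match rows, so the n x n
    matrix costs O(n·T + n²) rather than n² set_similarity calls.
    """
    dag = dag or cohort.dag
    vocab = sorted({t for p in cohort for t in p.terms})
    index = {t: i for i, t in enumerate(vocab)}
    T = len(vocab)
    tsim = np.zeros((T, T))
    anc = {t: dag.ancestors(t) for t in vocab}
    ic_of = {t: ic.get_ic(t) for v in anc.values() for t in v}
    for i, s in enumerate(vocab):
        for j in range(i, T):
            t = vocab[j]
            common = anc[s] & anc[t]
            val = max((ic_of[v] for v in common), default=0.0) if common else 0.0
            tsim[i, j] = tsim[j, i] = val

    n = len(cohort)
    term_idx = [
        np.array(sorted(index[t] for t in p.terms), dtype=int) for p in cohort
    ]
    sizes = np.array([len(ix) for ix in term_idx], dtype=float)
    # best[b, s] = max over t in D_b of sim(s, t)
    best = np.empty((n, T))
    for b, ix in enumerate(term_idx):
        best[b] = tsim[:, ix].max(axis=1)
    # membership matrix (n, T): mean over s in D_a of best[b, s]
    member = np.zeros((n, T))
    for a, ix in enumerate(term_idx):
        member[a, ix] = 1.0
    directed = (member @ best.T) / sizes[:, None]  # directed[a, b]
    sim = 0.5 * (directed + directed.T)
    return PatientSimilarityMatrix(patient_ids=cohort.patient_ids, sim=sim)


def to_distance(
    simmat: PatientSimilarityMatrix, zero_diagonal: bool = True
) -> PatientDistanceMatrix:
    """Dissimilarity ``max(sim) − sim`` with the diagonal forced to zero.

    The max is searched over the full matrix including the diagonal (self
    similarity — the mean IC of a patient's terms — is usually the
    largest entry).  Without zero-forcing, the diagonal would be a
    positive, patient-dependent quantity and the matrix would not be a
    valid dissimilarity; ``zero_diagonal=False`` preserves the raw
    subtraction for inspection.
    """
    m = simmat.max_sim
    dist = m - simmat.sim
    if zero_diagonal:
        np.fill_diagonal(dist, 0.0)
    return PatientDistanceMatrix(
        patient_ids=list(simmat.patient_ids), dist=dist, max_sim=m
    )


def save_matrix(
    mat: PatientSimilarityMatrix | PatientDistanceMatrix,
    path: str | Path,
    meta: dict | None = None,
) -> None:
    """Write a matrix as TSV with a JSON sidecar recording its provenance."""
    path = Path(path)
    mat.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    sidecar = dict(meta or {})
    if isinstance(mat, PatientDistanceMatrix):
        sidecar["max_sim"] = mat.max_sim
        sidecar["kind"] = "distance"
    else:
        sidecar["max_sim"] = mat.max_sim
        sidecar["kind"] = "similarity"
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def load_matrix(path: str | Path) -> tuple[list[str], np.ndarray, dict]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return [str(c) for c in df.index], df.to_numpy(dtype=float), meta
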