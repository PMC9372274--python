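"""Complete-linkage clustering of patients and per-cluster characterisation.

Patients are clustered agglomeratively on the phenotype dissimilarity
matrix; the inter-cluster distance is the maximum pairwise distance between
members (complete linkage), which is monotone, so cutting the dendrogram at
the height that leaves ``k`` groups is well defined.  Cluster labels are
renumbered 1..k by descending size, so cluster 1 is always the largest.

Characterisation mirrors the usual clinical "Table 1": for every term a
present/absent x cluster contingency table tested by Pearson chi-square —
switching to Fisher's exact test when any observed cell is small — and for
every continuous covariate a one-way ANOVA or Kruskal–Wallis rank test
depending on a per-group Shapiro–Wilk normality gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from .cohort import Cohort
from .similarity import PatientDistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "complete_linkage",
    "cut_tree",
    "cluster_term_table",
    "cluster_covariate_table",
    "fisher_exact_2xk",
]


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage form.

    ``linkage`` is the (n-1, 4) scipy matrix: members merged, merge
    height, cluster size.  ``patient_ids`` fixes the leaf <-> patient
    correspondence.
    """

    patient_ids: list[str]
    linkage: np.ndarray
    method: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.patient_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )


@dataclass
class ClusterAssignment:
    k: int
    labels: dict[str, int]  # patient_id -> 1..k, cluster 1 largest
    sizes: list[int]

    def labels_for(self, patient_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[p] for p in patient_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.labels), "cluster": list(self.labels.values())}
        )


def complete_linkage(
    dist: PatientDistanceMatrix, method: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    Complete linkage is the default; other scipy linkage methods pass
    through for exploration.  Requires a symmetric matrix with a zero
    diagonal and at least two patients.
    """
    d = np.asarray(dist.dist, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two patients")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal is not zero")
    condensed = squareform((d + d.T) / 2.0, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(
        patient_ids=list(dist.patient_ids), linkage=Z, method=method
    )


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into exactly ``k`` clusters, labelled by size.

    Labels are renumbered so cluster 1 is the largest; ties in size break
    by the smallest original leaf index, keeping relabelling stable.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    if len(np.unique(raw)) != k:
        heights = np.unique(dend.heights)
        raise ValueError(
            f"cannot cut into exactly {k} clusters: tied merge heights "
            f"{heights.tolist()}"
        )
    # order clusters by (descending size, first leaf index)
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int(np.sum(raw == c)), int(np.argmax(raw == c))),
    )
    rank = {c: i + 1 for i, c in enumerate(order)}
    labels = {
        pid: rank[c] for pid, c in zip(dend.patient_ids, raw, strict=True)
    }
    sizes = [int(np.sum(raw == c)) for c in order]
    return ClusterAssignment(k=k, labels=labels, sizes=sizes)


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher's exact test for a 2 x k contingency table.

    Full enumeration over tables with the observed margins; the p-value is
    the total probability of tables no more probable than the observed one
    (the standard two-sided convention, identical to scipy's 2x2 case).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()

    log_const = (
        gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
    )

    def log_prob(top: np.ndarray) -> float:
        bottom = col - top
        return log_const - gammaln(top + 1).sum() - gammaln(bottom + 1).sum()

    observed_lp = log_prob(table[0])
    k = table.shape[1]

    total = 0.0
    tol = 1e-9  # "no more probable" with float slack

    def recurse(j: int, remaining: int, top: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if remaining <= col[j]:
                lp = log_prob(np.array(top + [remaining]))
                if lp <= observed_lp + tol:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, top + [a])

    recurse(0, int(row[0]), [])
    return min(total, 1.0)


def _term_test(table: np.ndarray, fisher_threshold: int) -> tuple[str, float, float]:
    """Choose and run the categorical test for one 2 x k table."""
    if (table < fisher_threshold).any():
        return "fisher", float("nan"), fisher_exact_2xk(table)
    if table.shape == (2, 2):
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2", float(stat), float(p)


def cluster_term_table(
    cohort: Cohort,
    assignment: ClusterAssignment,
    fisher_threshold: int = 10,
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """Per-term counts/percentages per cluster with a between-cluster test.

    Each explicit annotation term yields a 2 x k (present/absent x cluster)
    table tested by Pearson chi-square without continuity correction, or by
    Fisher's exact test when any observed cell is below
    ``fisher_threshold`` (default 10, the usual small-count rule).
    Percentages are count / cluster size, rounded to two decimals in the
    exported table.
    """
    labels = assignment.labels_for(cohort.patient_ids)
    k = assignment.k
    cluster_sizes = np.array(
        [int(np.sum(labels == c)) for c in range(1, k + 1)]
    )
    vocab = terms or sorted({t for p in cohort for t in p.terms})

    rows = []
    for term in vocab:
        has = np.array([term in p.terms for p in cohort], dtype=bool)
        if not has.any():
            logger.warning("term %s absent from all patients; skipped", term)
            continue
        present = np.array(
            [int(np.sum(has & (labels == c))) for c in range(1, k + 1)]
        )
        table = np.vstack([present, cluster_sizes - present])
        test, stat, p = _term_test(table, fisher_threshold)
        row = {
            "term_id": term,
            "name": cohort.dag.terms[term].name if term in cohort.dag else "",
            "n_all": int(has.sum()),
            "pct_all": round(100.0 * has.sum() / len(cohort), 2),
        }
        for c in range(1, k + 1):
            row[f"n_cluster{c}"] = int(present[c - 1])
            row[f"pct_cluster{c}"] = round(
                100.0 * present[c - 1] / cluster_sizes[c - 1], 2
            )
        row.update({"test": test, "statistic": stat, "p_value": p})
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_covariate_table(
    cohort: Cohort,
    assignment: ClusterAssignment,
    covariates: tuple[str, ...] = ("age_at_surgery", "bmi"),
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Continuous covariates compared across clusters.

    Each covariate is tested by one-way ANOVA when every cluster passes a
    Shapiro–Wilk normality check at ``normality_alpha``, otherwise by the
    Kruskal–Wallis rank test (the k-group generalisation of the Wilcoxon
    rank-sum).  Summaries are mean ± SD under ANOVA, median (IQR) under the
    rank test.
    """
    labels = assignment.labels_for(cohort.patient_ids)
    k = assignment.k
    rows = []
    for cov in covariates:
        values = np.array(
            [getattr(p, cov) if getattr(p, cov) is not None else np.nan for p in cohort],
            dtype=float,
        )
        groups = [
            values[(labels == c) & ~np.isnan(values)] for c in range(1, k + 1)
        ]
        if any(len(g) < 2 for g in groups):
            logger.warning(
                "covariate %s has a cluster with <2 observations; skipped", cov
            )
            continue
        normal = all(
            len(g) < 3 or stats.shapiro(g).pvalue >= normality_alpha
            for g in groups
        )
        row: dict = {"covariate": cov}
        if normal:
            stat, p = stats.f_oneway(*groups)
            row["test"] = "anova"
            for c, g in enumerate(groups, start=1):
                row[f"cluster{c}"] = f"{g.mean():.2f} ± {g.std(ddof=1):.2f}"
        else:
            stat, p = stats.kruskal(*groups)
            row["test"] = "kruskal"
            for c, g in enumerate(groups, start=1):
                q1, med, q3 = np.percentile(g, [25, 50, 75])
                row[f"cluster{c}"] = f"{med:.2f} ({q1:.2f}–{q3:.2f})"
        row["statistic"] = float(stat)
        row["p_value"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
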