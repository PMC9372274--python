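"""Independent brute-force oracles used by the test suite.

Everything here is implemented from the defining formulas, deliberately
ignoring the package's own code paths, so agreement is evidence rather
than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# -- ontology ---------------------------------------------------------------


def bfs_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Reflexive ancestor closure by literal breadth-first traversal."""
    seen = {term}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in parents.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return seen


# -- similarity -------------------------------------------------------------


def literal_term_sim(
    parents: dict[str, set[str]], ic: dict[str, float], s: str, t: str
) -> float:
    common = bfs_ancestors(parents, s) & bfs_ancestors(parents, t)
    return max((ic.get(v, 0.0) for v in common), default=0.0)


def literal_set_sim(parents, ic, Da, Db) -> float:
    """The displayed best-match-average double sum, term by term."""
    Da, Db = sorted(Da), sorted(Db)
    left = sum(max(literal_term_sim(parents, ic, s, t) for t in Db) for s in Da)
    right = sum(max(literal_term_sim(parents, ic, s, t) for t in Da) for s in Db)
    return left / (2 * len(Da)) + right / (2 * len(Db))


# -- clustering -------------------------------------------------------------


def naive_complete_linkage(d: np.ndarray) -> list[float]:
    """O(n^3) agglomeration rescanning every cluster pair each step.

    Returns the sequence of merge heights.
    """
    clusters: list[list[int]] = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


def chi2_statistic(table: np.ndarray) -> float:
    """Textbook sum of (O-E)^2/E."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def fisher_2x2_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d

    def log_p(x):
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(n - r1 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    observed = log_p(a)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        lp = log_p(x)
        if lp <= observed + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def fisher_2x3_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p for a 2x3 table by a literal triple loop."""
    table = np.asarray(table, dtype=int)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()

    def log_prob(t0, t1, t2):
        tops = (t0, t1, t2)
        lp = (
            sum(math.lgamma(r + 1) for r in row)
            + sum(math.lgamma(c + 1) for c in col)
            - math.lgamma(n + 1)
        )
        for c, t in zip(col, tops):
            lp -= math.lgamma(t + 1) + math.lgamma(c - t + 1)
        return lp

    observed = log_prob(*table[0])
    total = 0.0
    for t0 in range(min(row[0], col[0]) + 1):
        for t1 in range(min(row[0] - t0, col[1]) + 1):
            t2 = row[0] - t0 - t1
            if 0 <= t2 <= col[2]:
                lp = log_prob(t0, t1, t2)
                if lp <= observed + 1e-9:
                    total += math.exp(lp)
    return min(total, 1.0)


def kruskal_two_group(x: np.ndarray, y: np.ndarray) -> float:
    """Two-group Kruskal-Wallis H by direct rank arithmetic (tie-corrected)."""
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    # mid-ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n, n1 = len(pooled), len(x)
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / (n - n1)) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


# -- survival ---------------------------------------------------------------


def product_limit(times, events) -> list[tuple[float, float]]:
    """Literal Kaplan-Meier product over distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    surv = 1.0
    out = []
    for t in sorted(set(times[events == 1])):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        out.append((t, surv))
    return out


def two_group_logrank_oe(times, events, groups) -> tuple[float, float, float]:
    """Observed-minus-expected score and hypergeometric variance for group 0.

    Returns (O, E, V); the chi-square statistic is (O - E)^2 / V.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    O = E = V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d0 = ((times == t) & (events == 1) & (groups == g0)).sum()
        O += d0
        E += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return float(O), float(E), float(V)


def cox_partial_loglik_no_ties(beta: float, x, times, events) -> float:
    """Literal partial likelihood for one covariate, distinct event times."""
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ll = 0.0
    for i in np.nonzero(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll


# -- partitions -------------------------------------------------------------


def pair_count_ari(a, b) -> float:
    """Adjusted Rand index from the closed-form pair-counting formula."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    labels_a, labels_b = np.unique(a), np.unique(b)
    contingency = np.array(
        [[np.sum((a == la) & (b == lb)) for lb in labels_b] for la in labels_a]
    )

    def comb2(v):
        return v * (v - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(np.array(n))
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# -- random structures ------------------------------------------------------


def random_dag(rng: np.random.Generator, n_terms: int) -> dict[str, set[str]]:
    """Random single-rooted DAG as a parent mapping (child -> parents)."""
    names = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {names[0]: set()}
    for i in range(1, n_terms):
        k = min(i, 1 + rng.integers(0, 2))
        parents[names[i]] = set(
            rng.choice(names[:i], size=k, replace=False).tolist()
        )
    return parents
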