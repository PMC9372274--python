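"""End-to-end pipeline orchestration with file-based stage contracts.

Every stage consumes and produces plain TSV/JSON artifacts, so stages are
independently runnable and a whole run is reproducible from its serialized
config alone.  ``run_pipeline`` sequences: information content ->
similarity matrix -> distance -> complete-linkage clustering -> cluster
summary tables -> Kaplan–Meier / log-rank / Cox, and writes a manifest with
a config hash stamped on the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import similarity as sim
from .clustering import (
    cluster_covariate_table,
    cluster_term_table,
    complete_linkage,
    cut_tree,
)
from .cohort import Cohort, cohort_information_content, load_cohort, terms_per_patient
from .ontology import parse_obo
from .survival import (
    build_survival_frame,
    km_estimate,
    logrank_test,
    multivariate_cox,
    select_variables,
    univariate_cox_screen,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashable and serialisable."""

    ontology_path: str
    cohort_path: str
    output_dir: str
    log_base: str = "e"
    closure_mode: str = "propagated"
    k: int = 3
    linkage: str = "complete"
    zero_diagonal: bool = True
    ties: str = "efron"
    low_prevalence: float = 0.05
    high_prevalence: float = 0.25
    alpha: float = 0.05
    fisher_threshold: int = 10
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")  # where outputs land does not change results
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Artifacts: ``ic_table.tsv``, ``similarity.tsv(+json)``,
    ``distance.tsv(+json)``, ``dendrogram.tsv``, ``assignment.tsv``,
    ``cluster_terms.tsv``, ``cluster_covariates.tsv``, ``km_curves.tsv``,
    ``survival_tests.json``, ``cox_univariate.tsv``,
    ``cox_multivariate.tsv`` and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json() + "\n")
    manifest: dict = {"config_hash": config.config_hash, "stages": {}}

    def stage(name):
        def wrap(fn):
            t0 = _time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(
                    json.dumps(manifest, indent=2) + "\n"
                )
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            elapsed = _time.perf_counter() - t0
            manifest["stages"][name] = {"status": "ok", "seconds": round(elapsed, 3)}
            logger.info("stage=%s elapsed=%.3fs", name, elapsed)
            return result

        return wrap

    dag = stage("ontology")(lambda: parse_obo(config.ontology_path))
    cohort: Cohort = stage("cohort")(lambda: load_cohort(config.cohort_path, dag))

    def _ic():
        table = cohort_information_content(
            cohort, closure_mode=config.closure_mode, log_base=config.log_base
        )
        _write_tsv(table.to_frame(dag), out / "ic_table.tsv")
        hist, median = terms_per_patient(cohort)
        manifest["terms_per_patient_median"] = median
        return table

    ic = stage("ic")(_ic)

    def _simmat():
        simmat = sim.similarity_matrix(cohort, ic, dag)
        meta = {
            "closure_mode": config.closure_mode,
            "log_base": config.log_base,
            "config_hash": config.config_hash,
        }
        sim.save_matrix(simmat, out / "similarity.tsv", meta)
        dist = sim.to_distance(simmat, zero_diagonal=config.zero_diagonal)
        sim.save_matrix(dist, out / "distance.tsv", meta)
        return simmat, dist

    simmat, dist = stage("simmat")(_simmat)

    def _cluster():
        dend = complete_linkage(dist, method=config.linkage)
        _write_tsv(dend.to_frame(), out / "dendrogram.tsv")
        assignment = cut_tree(dend, config.k)
        _write_tsv(assignment.to_frame(), out / "assignment.tsv")
        manifest["cluster_sizes"] = assignment.sizes
        return dend, assignment

    dend, assignment = stage("cluster")(_cluster)

    def _summarize():
        terms_tbl = cluster_term_table(
            cohort, assignment, fisher_threshold=config.fisher_threshold
        )
        _write_tsv(terms_tbl, out / "cluster_terms.tsv")
        cov_tbl = cluster_covariate_table(cohort, assignment)
        _write_tsv(cov_tbl, out / "cluster_covariates.tsv")
        return terms_tbl

    stage("summarize")(_summarize)

    def _survive():
        df = build_survival_frame(cohort, assignment)
        curves = []
        for c in range(1, config.k + 1):
            sub = df[df["cluster"] == c]
            curve = km_estimate(sub["time"], sub["event"], label=f"cluster{c}")
            frame = curve.to_frame()
            frame.insert(0, "group", f"cluster{c}")
            curves.append(frame)
        _write_tsv(pd.concat(curves, ignore_index=True), out / "km_curves.tsv")
        chi2, dof, p = logrank_test(df["time"], df["event"], df["cluster"])
        (out / "survival_tests.json").write_text(
            json.dumps(
                {"logrank_chi2": chi2, "df": dof, "p_value": p,
                 "config_hash": config.config_hash},
                indent=2,
            )
            + "\n"
        )
        uni_vars = select_variables(
            cohort, assignment, "univariate",
            low_prevalence=config.low_prevalence, alpha=config.alpha,
        )
        uni = univariate_cox_screen(df, uni_vars, ties=config.ties)
        _write_tsv(uni, out / "cox_univariate.tsv", index=True)
        multi_vars = select_variables(
            cohort, assignment, "multivariate", univariate_results=uni,
            high_prevalence=config.high_prevalence, alpha=config.alpha,
        )
        multi = multivariate_cox(df, multi_vars, ties=config.ties)
        _write_tsv(multi.table, out / "cox_multivariate.tsv", index=True)
        return uni, multi

    stage("survive")(_survive)

    manifest["n_patients"] = len(cohort)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
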