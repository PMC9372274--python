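# phenoclust

Ontology-based deep phenotyping for patient cohorts: semantic-similarity
clustering of phenotype profiles and survival comparison of the resulting
clusters.

Heterogeneous diseases — the motivating case is pulmonary atresia, a complex
congenital heart defect — resist simple clinical dichotomies. When each
patient's record is annotated with terms from a phenotype ontology (such as
the Human Phenotype Ontology), patients can be compared by the *information
content* of the phenotypes they share, stratified into data-driven clusters,
and those clusters compared for survival. `phenoclust` implements that whole
pipeline for epidemiologists and clinical researchers, together with a
synthetic-cohort generator so every stage is testable without access to
protected clinical data.

## The method

Given a cohort of `n` patients, each with a term set `D` from an is-a DAG of
phenotype terms:

1. **Information content.** For each term `t`, `p_t` is the fraction of
   patients carrying `t` (optionally after closing each patient's terms
   under ontology ancestors), and `IC(t) = −log p_t`. Rare phenotypes are
   informative; universal ones carry none.
2. **Term similarity** (Resnik): `sim(s, t) = max{ IC(v) : v ∈ anc(s) ∩ anc(t) }`
   — the IC of the most informative common ancestor.
3. **Patient similarity** (symmetric best-match average):

       sim(Dₐ, D_b) = 1/(2|Dₐ|) Σ_{s∈Dₐ} max_{t∈D_b} sim(s, t)
                    + 1/(2|D_b|) Σ_{s∈D_b} max_{t∈Dₐ} sim(s, t)

4. **Clustering.** The dissimilarity `max(sim_mat) − sim_mat` (diagonal
   forced to zero) is clustered by complete-linkage agglomeration and the
   dendrogram is cut into `k` clusters (default `k = 3`), labelled 1..k by
   descending size.
5. **Characterisation.** Per-term 2×k contingency tables (Pearson χ², or
   Fisher's exact test when any cell is below 10) and continuous-covariate
   comparisons (ANOVA or Kruskal–Wallis after a Shapiro–Wilk normality gate).
6. **Survival.** Kaplan–Meier curves per cluster, the k-sample log-rank
   test, and univariate/multivariate Cox proportional-hazards models with a
   prevalence-based variable screen (terms above 5% prevalence enter the
   univariate screen; the multivariate model adds univariate-significant
   variables, cluster dummies, demographics, surgery type, and terms above
   25% prevalence).

## Worked example

A synthetic cohort shaped like a published pulmonary-atresia cohort (648
patients in three planted clusters of 522/94/32, ~47 distinct cardiovascular
terms, median six terms per patient, cluster-dependent hazards):

```python
from phenoclust import *
from phenoclust import reference
from phenoclust.simulate import SimulationSpec, generate_cohort

dag = reference.load_fixture_ontology()
result = generate_cohort(SimulationSpec(seed=1))
cohort = result.cohort(dag)

ic = cohort_information_content(cohort, closure_mode="propagated")
simmat = similarity_matrix(cohort, ic)
assignment = cut_tree(complete_linkage(to_distance(simmat)), k=3)
ari, _ = evaluate_recovery(assignment.labels, result.ground_truth)

df = build_survival_frame(cohort, assignment)
chi2, dof, p = logrank_test(df["time"], df["event"], df["cluster"])
uni = univariate_cox_screen(df, select_variables(cohort, assignment, "univariate"))
multi = multivariate_cox(
    df, select_variables(cohort, assignment, "multivariate", univariate_results=uni)
)
```

prints (via the obvious `print` calls):

```
patients: 648, distinct terms: 44
median terms per patient: 6
max(sim_mat) = 3.7966
cluster sizes: [522, 94, 32], ARI vs planted clusters: 1.000
log-rank: chi2 = 20.17 (df = 2), p = 4.18e-05
cluster 1 vs 3: HR = 1.70 (0.27-10.61), p = 0.57
LSVC analog: HR = 2.24 (1.55-3.23), p = 1.5e-05
```

Reading the numbers: the three planted clusters are recovered exactly
(adjusted Rand index 1.0, sizes 522/94/32); survival differs between
clusters (log-rank p ≈ 4e-5, clusters 2–3 were simulated at twice the
cluster-1 hazard); the persistent-left-superior-vena-cava analog's true
hazard ratio of 2.3 is estimated at 2.24 with a covering confidence
interval; and the cluster dummies lose significance in the multivariate
model because the high-prevalence signature terms absorb the cluster effect
— the same behaviour the motivating study reports.

The same pipeline runs from the shell:

```sh
phenoclust simulate --seed 1 -o run/
phenoclust run -O run/ontology.obo -c run/cohort.tsv -o run/out --k 3
phenoclust report -r run/out
```

or stage by stage (`ic`, `simmat`, `cluster`, `summarize`, `survive`), each
stage exchanging plain TSV/JSON files.

## Layout

- `src/phenoclust/ontology.py` — OBO parsing (via obonet), ancestor closure,
  term remapping
- `src/phenoclust/cohort.py` — cohort TSV loading, term frequencies, IC
- `src/phenoclust/similarity.py` — Resnik / best-match-average similarity,
  distance transform
- `src/phenoclust/clustering.py` — complete linkage, tree cutting, cluster
  characterisation tables
- `src/phenoclust/survival.py` — Kaplan–Meier, log-rank, Cox partial
  likelihood (Efron/Breslow), variable selection
- `src/phenoclust/simulate.py` — synthetic ontologies and cohorts with
  planted clusters and proportional-hazards survival
- `src/phenoclust/pipeline.py`, `cli.py` — file-based orchestration and the
  `phenoclust` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
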