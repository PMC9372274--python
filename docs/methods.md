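# Methods

## Scope and data model

`phenoclust` stratifies a patient cohort by phenotype-ontology annotations
and compares the resulting strata for survival. A cohort is a list of
patients, each carrying a non-empty set of term ids from an is-a DAG, plus
demographics (age at surgery, sex, BMI, family history), a 3-level surgery
factor, and a right-censored survival outcome with time measured in years
from definitive surgery. Patient-level exclusion rules (age limits, missing
records) are assumed to have been applied upstream; the loader enforces only
structural validity (known non-obsolete terms, at least one term per
patient, unique ids, non-negative times, an event indicator wherever a time
is present).

## Ontology semantics

Only `is_a` edges define the graph; other OBO relationship types are
ignored. Ancestor closure is **reflexive** — a term is its own ancestor —
which is the standard Resnik convention and gives `sim(s, s) = IC(s)`.
Obsolete terms are excluded from the DAG (and hence from annotation) but
their ids are remembered so error messages can distinguish "obsolete" from
"never existed". `alt_id` accessions resolve to their primary term at load
time. Multi-rooted ontologies are accepted without inserting a virtual
super-root; two terms in different rooted components then have no common
ancestor and their similarity is defined as 0. Terms annotated outside a
supported vocabulary can be remapped to their nearest supported ancestor
(minimum edge distance, ties broken to the lexicographically smallest id) or
dropped, at the caller's choice — both behaviours exist because source
pipelines differ in how they handle terms their similarity index lacks.

## Information content

`IC(t) = −log p_t` with `p_t` the fraction of patients carrying `t`.
Two counting modes:

- **explicit** — a patient carries exactly the recorded terms. Used for
  descriptive frequency tables, which is how clinical characterisation
  tables are conventionally reported.
- **propagated** (default for similarity) — each patient's set is closed
  under ancestors, so an ancestor is never rarer than a descendant and IC is
  monotone non-decreasing from root to leaf. This guarantees the Resnik
  bound `sim(s, t) ≤ min(IC(s), IC(t))`.

The log is natural by default (base 2 and 10 available); the choice only
rescales similarities and distances and cannot change cluster assignments.
Terms never observed in the cohort have no IC and contribute 0 as common
ancestors — the analysis vocabulary is the observed cohort vocabulary plus
its ancestors.

## Patient similarity and distance

Term similarity is the IC of the most informative common ancestor; set
similarity is the symmetric best-match average (each term matched to its
best counterpart, averaged within each direction, directions averaged).
The full matrix is computed in vectorised form (term×term Resnik matrix,
then per-patient best-match rows); accumulation order is fixed by sorted
term id so repeated runs are bit-identical.

The clustering input is `max(sim_mat) − sim_mat`, with the max taken over
the **full** matrix including the diagonal. Self-similarity is the mean IC
of a patient's terms and is patient-dependent, so after the subtraction the
diagonal would be positive; it is forced to exactly 0 (configurable) so the
result is a valid dissimilarity. The most self-similar patient therefore
anchors the distance scale; this is an offset that complete linkage is
insensitive to.

## Clustering and characterisation

Agglomerative clustering uses complete linkage (inter-cluster distance =
maximum member pair distance), which is monotone, so the cut producing
exactly `k` clusters is well defined; `k = 3` by default, matching the
three-way stratification the pipeline was designed around. Tie handling in
the agglomeration follows scipy's deterministic nearest-neighbor-chain
implementation; with continuous similarity data, exact ties have measure
zero. Cluster labels are renumbered 1..k by descending size (ties broken by
first leaf index) so "cluster 1" is always the largest.

Per-term characterisation builds a present/absent × cluster table per term,
tested by Pearson χ² without continuity correction, switching to Fisher's
exact test when **any observed cell is < 10** (the conventional small-count
rule; threshold configurable). Fisher's test for 2×k tables with k > 2 is
computed by full enumeration over tables with the observed margins, with
p = total probability of tables no more probable than the observed one —
the same two-sided convention as the 2×2 case. At cohort scale (n ≈ 650,
k = 3) enumeration is at most a few hundred thousand tables and runs in
milliseconds. Continuous covariates are tested by one-way ANOVA when every
cluster passes Shapiro–Wilk at α = 0.05, otherwise by Kruskal–Wallis (the
k-group rank-sum test); summaries switch between mean ± SD and median (IQR)
accordingly.

## Survival analysis

Kaplan–Meier estimation and the k-sample log-rank test are delegated to
`lifelines` behind thin package interfaces; censorings tied with deaths are
handled events-first. The Cox proportional-hazards fit is implemented in
the package: Newton–Raphson maximisation of the partial likelihood with
Efron's tie correction (default) or Breslow's, step-halving to keep the
likelihood monotone, standard errors from the inverse observed information,
Wald p-values, and 95% intervals `exp(β̂ ± 1.96·SE)`. Convergence is
declared when the gradient max-norm falls below 1e-8 or the Newton increment
falls below 1e-8 in β (the gradient's float64 noise floor grows with n, and
an increment that small is orders of magnitude below the standard errors).
Non-convergence within 100 iterations raises with the last gradient norm;
coefficient magnitudes above 20 trigger a complete-separation warning and
the estimate is flagged. The implementation is cross-checked in the test
suite against `lifelines` (coefficients and SEs to < 1e-5) and against
literal risk-set enumeration oracles.

Variable selection follows the two-stage rule the pipeline models:
univariate screen = cluster (ordinal), age, sex, BMI, family history,
surgery type, and every term above 5% prevalence; multivariate model =
cluster dummies (smallest cluster as reference), demographics, surgery
type, terms above 25% prevalence, and all univariate-significant variables
(two-sided p < 0.05 throughout). Surgery enters as a single ordinal column
in both stages. Rarer terms can reach the multivariate model only via the
significance route if the caller screens them explicitly; the source
analyses this mirrors were not fully derivable from their stated rules, so
the roster functions accept explicit overrides.

## The synthetic cohort generator

No patient-level data are distributed with the motivating study, so the
generator emulates its *shape*: three clusters of 522/94/32 patients, ~47
distinct cardiovascular terms from the packaged 60-term toy ontology, 1–12
terms per patient with median ≈ 6, and exponential proportional-hazards
survival with right censoring. Cluster archetypes assign each term a
Bernoulli inclusion probability per cluster, following the qualitative
direction of the published characterisation (cluster 1: VSD / tetralogy of
Fallot / right-ventricular hypertrophy / collateral arteries; cluster 2:
hypoplastic right heart / ASD / tricuspid disease; cluster 3: single
ventricle / dextrocardia / common atrium).

Defaults are deliberately **well-separated**, which required three design
rules discovered while analysing complete-linkage failure modes:

1. *The shared common term is near-universal.* A term common to all
   clusters at moderate frequency keeps the between-cluster similarity
   floor high; at ≈ 90% prevalence its IC (≈ 0.1) makes it neutral glue.
2. *Members express all but at most one core lesion.* Each cluster's core
   terms (inclusion probability ≥ 0.85 within the cluster, < 0.5
   elsewhere) are guaranteed by rejection-resampling, so by pigeonhole any
   two members share informative terms. Without this, single "orphan"
   patients or orphan pairs below the cross-cluster similarity floor can
   hijack a k = 3 cut (complete linkage judges a cluster by its worst
   pair).
3. *Rare terms are cluster-exclusive and branch-aligned.* A rare term whose
   mid-IC category ancestor blankets another cluster glues its carriers to
   that cluster; rare terms therefore live in ontology branches their own
   cluster dominates, and the atrioventricular-connection analog is
   parented directly at the root.

Consequences worth knowing: unlike the published table, PDA is common in
all three simulated clusters and PFO is rare in cluster 1. Passing the
recovery tests on this generator shows the pipeline recovers structure of
this planted, well-separated kind; it does **not** show that three clusters
exist in any real cohort, nor that real phenotype data are this clean.

Survival: hazard = `baseline × cluster multiplier × exp(Σ β_t x_t)` with
baseline 0.024 events/patient-year (five-year survival ≈ 88.7% in the
low-risk cluster, the published cluster-1 figure), multipliers (1, 2, 2)
mirroring the published direction of cluster separation, and two term-level
effects at the published multivariate hazard ratios (≈ 3.7 for the
abnormal-atrioventricular-connection analog, ≈ 2.3 for the persistent-left-
superior-vena-cava analog). Censoring is an administrative horizon of 13
years (the span from earliest surgery to analysis in the emulated study)
plus a 10% uniform early-dropout fraction (the study lost only ~9% of
enrolled patients entirely; the rest contributed at least revisit records).
Overall simulated mortality is ≈ 16–33% depending on effects enabled —
higher than the published 12.8%, a deliberate trade for adequately powered
survival tests at desk scale. Covariates: log-normal age with
cluster-specific medians (2 / 0.7 / 5.5 years; cluster 3 oldest), female
fractions (0.46 / 0.49 / 0.25), normal BMI (15.8 ± 3.5, clipped to a
plausible pediatric range), 2% positive family history.

All randomness flows from one integer seed through fixed named streams
(terms / covariates / survival / censoring), so adding a stream never
perturbs another and a seed reproduces byte-identical TSV output.

## Reference counts

`data/reference_term_counts.tsv` transcribes per-cluster carrier counts of
47 terms from the published cohort characterisation (overall n = 648;
clusters 522/94/32). It is used to verify explicit-frequency arithmetic
against the printed percentages and to orient the archetypes. One
inconsistency is preserved as printed: the PAS row's cluster counts sum to
48 against a printed overall count of 49 (each printed percentage checks
out individually).

## Numerical and degenerate-input choices

- Natural log for IC; base is a config option.
- Similarity accumulation in sorted-term order; matrices bit-reproducible.
- `to_distance` zeroes the diagonal by default (flag to disable).
- `cut_tree` raises if tied merge heights make exactly-k unattainable,
  naming the heights.
- Fisher enumeration uses a 1e-9 log-probability slack for the "no more
  probable" comparison to absorb rounding.
- Cox rejects constant covariates, warns when events < covariates, and
  flags suspected complete separation rather than failing.
- Empty term sets, zero-frequency ICs, zero-event log-rank inputs and
  single-patient clustering all raise with specific messages rather than
  propagating NaNs.

## Limitations

- Resnik/best-match-average only; no Lin, Jiang–Conrath or simGIC variants,
  and no asymmetric best-match option.
- No automatic choice of k, no bootstrap cluster-stability assessment.
- Cox: no time-varying covariates, competing risks, stratification or
  proportionality diagnostics.
- The generator draws terms independently within a cluster given the
  archetype; real comorbidity correlation structure (beyond cluster
  membership) is not modelled, and neither is inter-centre heterogeneity.
- The toy ontology is a 60-term stand-in with the branch structure the
  pipeline needs, not a subset of any real ontology release.
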