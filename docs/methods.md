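# Methods

## Scope and units of analysis

The pipeline estimates the comorbidity burden of an inpatient cancer
cohort. The raw unit is the hospital admission (one primary plus up to 18
secondary ICD-10 diagnoses); the analysis unit is the patient, formed by
deduplicating diagnosis codes across all of a patient's admissions,
summing cost over admissions, and taking demographics from the first
qualifying admission (conflicts are logged, first admission wins). All
pattern and outcome analyses are stratified by cancer type (lung, colon,
rectal, breast, gastric).

## Eligibility rules

Patients are filtered in a fixed order — cancer type, diagnosis-date
window, histology, too-few-admissions — so that each exclusion is counted
exactly once and the filter report's stage counts sum to the input patient
count. The defaults:

* cancer type in the five-type set;
* diagnosis date (operationalized as the earliest admission date, the
  only date the record stream guarantees) inside the half-open window
  [2017-01-01, 2019-11-01);
* histology not in the excluded lists (breast: in-situ disease, mucinous
  adenocarcinoma, medullary carcinoma, adenoid cystic carcinoma, Paget's
  disease; colon/rectal: lymphoma, sarcoma, squamous cell carcinoma;
  lung: small cell carcinoma), and male breast cancer excluded alongside
  them;
* at least `min_admissions = 2` admissions. A single observed admission
  cannot anchor a treatment trajectory, hence the default removal of
  once-seen patients. A stricter mode (`require_pair_within_days`)
  additionally demands two admissions within a configurable number of
  days (90 by convention) of each other; it is off by default because the
  plain admission-count rule is what the flow-chart semantics require and
  the windowed variant changes only sparse multi-admission edge cases.

Filtering is idempotent and order-independent in the input rows; both
properties are tested.

## Comorbidity scoring

Conditions follow the cancer-adapted (NCI) Charlson roster: the Charlson
conditions minus solid tumours, leukaemias and lymphomas, consolidated to
14 conditions, plus hypertension as a 15th because of its high prevalence
in hospital cancer cohorts. Connective tissue disease ships as an optional
16th condition, off by default. ICD-10 membership uses the published Quan
code lists, stored as dot-free uppercase prefixes in a versioned YAML data
file; matching is case- and dot-insensitive prefix matching, and
syntactically invalid codes are skipped with a per-patient warning. One
deliberate restriction: the hypertension condition keeps only essential
and secondary hypertension (I10, I15), because the hypertensive heart and
renal codes (I11.0, I12.0, I13.x) already belong to the heart-failure and
renal-disease lists and no prefix may map to two conditions outside the
declared hierarchies.

Two severity hierarchies are enforced at scoring time: moderate/severe
liver disease masks mild liver disease, and diabetes with complications
masks uncomplicated diabetes — a patient coded for both counts once, at
the severe level.

The Charlson score is the weight sum over positive conditions, integer
weights 1–6 from the original one-year-mortality calibration (AIDS 6,
moderate/severe liver 3, renal/paralysis/complicated diabetes 2, the rest
1). Hypertension carries weight 0: it contributes to the comorbidity count
and the pattern analysis but not to the score, since it sits outside the
Charlson index. Severity bands default to the common convention mild 1–2,
moderate 3–4, severe ≥ 5, configurable; score 0 is graded "none" even when
weight-0 conditions are present. No age adjustment is applied.

Prevalence tables report, per condition, the total count and the share of
that condition's carriers per cancer type (row percentages); per stratum,
the comorbidity rate (patients with ≥ 1 condition over all patients); the
distribution of comorbidity counts (1, 2, 3, > 3) among burdened patients;
and severity shares. Group comparisons use Student's t test for continuous
variables (one-way ANOVA when more than two groups) and Pearson's
chi-square without continuity correction for categorical ones;
zero-variance cells are reported as undefined rather than raised.

## Pattern discovery

The clustered entities are **conditions**, not patients: each condition is
a binary column over patients, and the discovered patterns are groups of
conditions that co-occur. Patient-level clustering would answer a
different question; condition-level clustering is what the reported
cluster structure (pairs such as hypertension–diabetes) describes.

Steps and conventions:

* columns with fewer than `min_count = 3` positive patients in the
  stratum are dropped first (their correlations are numerically fragile
  and clinically unstable);
* columns are z-scored and the Pearson correlation r computed; the
  distance is d = 1 − r (range [0, 2]; the z-scoring is a mathematical
  no-op for r and is retained only to make the standardize-then-correlate
  convention explicit). d = sqrt(2(1 − r)) is available; neither is a
  metric and no triangle inequality is assumed;
* agglomeration is written from first principles: start from singletons,
  repeatedly merge the pair with minimum linkage distance, update
  distances by the Lance–Williams recurrences (unweighted average,
  complete, single). Ties are broken by the lexicographically smallest
  pair of cluster labels, a cluster's label being its alphabetically
  first member — this makes the merge sequence fully deterministic. The
  implementation is cross-checked in the tests against a brute-force
  agglomerator that recomputes every inter-group distance from the
  original matrix, and against scipy's heights;
* default linkage is average (unspecified in the source convention;
  recorded in every output);
* the tree is cut either into a fixed number of groups or at a height
  threshold (merges with height ≤ h are applied). The pipeline default is
  a height cut at 0.8, i.e. conditions stay grouped only while their
  merge correlation exceeds 0.2; on the default synthetic cohort this
  recovers exactly the four planted pairs in every stratum without a
  per-stratum group-count choice. Groups with ≥ 2 conditions are promoted
  to clusters; singletons are reported but not promoted;
* a patient belongs to a cluster iff **all** its conditions are positive.
  By default membership is exclusive: a patient matching several clusters
  is assigned to the one with most matched conditions, ties to the
  earlier cluster, and the reassignment count is logged. Non-exclusive
  membership is available.

Dendrograms are exported as Newick (branch lengths from merge heights)
and as a flat merge table.

## Association models

Treatment is recoded to two binary outcomes: conventional treatment
(any of surgery, chemotherapy, radiotherapy) and targeted therapy (its own
flag) — both may be 1. Missing total cost is mean-imputed (imputation
flags carried; the post-imputation mean equals the observed mean by
construction, which is asserted, and an observed-only mode exists because
it is not documented whether the source models used imputed or observed
cost).

Each (stratum, cluster, outcome) is fitted on the subset {cluster members
∪ reference}, with the cluster indicator as exposure. The default
reference is patients with **no identified cluster** in the stratum; a
stricter no-comorbidity-at-all reference is available (the source
convention is ambiguous between the two). Binary outcomes use
maximum-likelihood logistic regression, cost uses ordinary least squares
on the raw RMB scale (a log-cost variant is a one-line change via the
outcomes argument). Covariates are configurable with two presets:
`table` (age, sex, education, insurance, marriage, cancer stage — the
default, matching the reported-model footnote convention) and `body`
(age, sex, education, residency, marriage). Continuous age enters
linearly; categoricals are dummy-coded with first-level reference.

Reported per fit: the exposure coefficient (log-odds for binary outcomes
— the convention in which reported "OR" values can be negative — or the
RMB difference), its Wald 95% CI, the p-value, and for binary outcomes
also exp(coefficient). Defensive behaviour is flag-not-raise: constant
outcomes, clusters below `min_cluster_size = 10`, rank-deficient designs
(the collinear column is named) and (quasi-)separation (detected by a
failed fit or an absurd coefficient/standard-error magnitude) produce
not-estimable results rendered as `\` in the formatted table. An
unadjusted fit on a 2×2 table reproduces the closed-form cross-product
odds ratio to 1e-6, which is tested on 1000 random tables.

## Synthetic cohort generator

The generator emulates the marginal structure of a Chinese
tertiary-hospital cancer cohort of 4,666 inpatients: cancer-type mix
(37.0 / 12.2 / 12.5 / 17.1 / 21.2% for lung/colon/rectal/breast/gastric),
age normal 62.42 ± 11.62 truncated to [18, 100], 94.68% insured, 87.74%
married, 64.96% urban, the five-level stage distribution, per-condition
prevalences (hypertension 32.04% down to paralysis 0.04%; AIDS 0), and
total cost log-normal with log-mean 10.915 and log-SD 0.762, matched by
moments to mean 73,552 / SD 65,288 RMB. Education (35/45/20%
primary/secondary/tertiary) and per-type sex mixes (breast all female,
other types male-dominated) are plausible fills where the emulated cohort
reports no values. Admissions per patient follow a configurable
distribution over {1,…,5} (mean ≈ 2.9); per-admission dates fall in the
2017-01 to 2019-10 window with 14–75-day gaps and 3–14-day stays, and a
patient's cost is split across admissions by a Dirichlet draw. Five
percent of patient costs are set missing by default. Each active
condition emits one exemplar ICD-10 code into the admission's secondary
diagnosis list (configurable); a small rate of excluded histologies
(e.g. 5% small cell among lung) exercises the eligibility filter.

**Planted co-occurrence.** Four condition pairs known to cluster in such
cohorts — hypertension–diabetes, cerebrovascular–peripheral vascular,
mild liver–renal, heart failure–COPD — share, per pair, a latent
Bernoulli factor F ~ Bern(q). A block condition with prevalence p is
drawn as X = M·F + (1 − M)·Y with M ~ Bern(λ), Y ~ Bern(r),
λ = sqrt(ρ p(1−p) / (q(1−q))) and r solved so that E[X] = p exactly;
every within-block pair then has correlation exactly ρ in expectation
while the marginals are preserved. q is placed mid-way inside the
feasibility interval implied by λ ≤ 1 and 0 ≤ r ≤ 1; a ρ beyond what the
two Bernoulli margins admit (e.g. > ≈ 0.45 for the heart-failure–COPD
margins) is rejected at validation time with the offending margins named.
The default ρ = 0.4 is a clearly super-null association feasible for all
four default pairs. Severity hierarchies are enforced after the draw (the
severe member clears the mild one), which shaves the mild member's
marginal by p_mild · p_severe — under 0.005 absolute at the default
prevalences and well inside the tested 3-standard-error reproduction
band; this was preferred over conditional draws to keep the block
correlations exact.

**Planted effects.** Treatment flags are drawn from per-flag logistic
models (default intercepts put conventional coverage high and targeted
therapy near 17%); a pattern → log-odds-shift map plants treatment
effects and a pattern → RMB map plants cost shifts for patients carrying
all of a pattern's conditions. These are the ground truth for the
parameter-recovery tests (targeted shift −1.0 and cost shift +17,000 RMB
on hypertension–diabetes, recovered within the estimated 95% CIs in
≥ 90% of replicates at n = 3000).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: conditions are drawn independently of
demographics, stage and cancer type, so the pronounced between-type
differences in comorbidity rates seen in real cohorts (e.g. far lower
burden in breast cancer) are absent; no longitudinal disease progression,
clinical narrative or lab values; coding noise is limited to exemplar
codes (one code per condition) rather than realistic code diversity;
costs are independent of conditions except through the planted shifts.
The generator validates the machinery (marginal reproduction, planted
correlation and effect recovery, determinism), not clinical conclusions.

## Determinism, problem sizes, degenerate inputs

All randomness flows from a single integer seed through numpy
Generators; identical spec + seed yields byte-identical CSV output, and a
full pipeline rerun with the same configuration and seed reproduces every
artifact byte for byte (the provenance manifest stores the seed, a
canonical configuration hash excluding the output location, the package
version and per-artifact checksums; no output embeds a timestamp).

The test suite sizes simulations to keep the default run fast while
leaving comfortable statistical margins: marginal reproduction at
n = 10,000 (3 binomial SEs), planted-pair recovery at n = 5,000 × 100
replicates (threshold 95%), effect-recovery CI coverage at n = 3,000 ×
100 replicates (threshold 90%), null CI coverage at n = 2,000 × 200
replicates, oracle equivalence of the agglomerator exhaustively up to 6
leaves across all three linkages, and scoring monotonicity over the full
hierarchy-valid profile lattice (2^15 masks).

Degenerate inputs are handled explicitly: empty cohorts are legal filter
output but an error for prevalence tables; zero-variance condition
columns are an error in the distance computation (they belong to the rare
filter); all-missing cost is an error for imputation; a dendrogram cut at
height 0 leaves every leaf alone (merges are applied at height ≤ cut);
two-leaf trees merge at the pair distance under every linkage.
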