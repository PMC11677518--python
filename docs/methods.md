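# Methods

## Counting model

The unit of analysis is the individual case safety report (ICSR).  A report
may mention several suspected drugs and several reaction preferred terms
(PTs); both are stored as sets, so a substance or a PT contributes at most
once per report, and a report contributes once per system organ class (SOC)
in SOC-level analyses.  Reports are attributed to a drug only when the drug
is *suspected*; concomitant medication feeds the risk-factor covariates
only.  De-duplication keeps the first occurrence of each case key; exact
key matching is used, since duplicate transmissions share the worldwide
case identifier, and probabilistic record linkage is out of scope.

Seriousness is a single mutually exclusive category per report (death >
life-threatening > disabling > hospitalization > congenital anomaly >
other medically important > unspecified); "serious" aggregates the first
four.  "Vulnerable age" means an age band strictly below 18 years or above
65 years (the 65–85 and >85 bands both count; unspecified ages do not).

## Disproportionality

Every drug–event pair is compared against the **full-dataset comparator**:
all reports in the ingested database, the index drug's reports included in
the margins.  This choice reproduces published reference values exactly on
reconstructed tables and reduces the impact of reporting biases relative to
restricted comparators, at the cost of confounding by indication.

- PRR and ROR as defined in the README; both undefined-cell situations are
  handled explicitly: a zero comparator event count yields an infinite PRR
  with a warning, and a zero `b` or `c` cell triggers the Haldane–Anscombe
  correction (0.5 added to all four cells) with the result flagged.  Pairs
  with `a = 0` report ROR 0 and are never signals.
- The χ² statistic used by the signal rule carries the Yates continuity
  correction, consistent with the 2006 EMA definition of a signal of
  disproportionate reporting; the uncorrected statistic is reported
  alongside, and the seriousness module's independence test is uncorrected
  (it is an R×C test, not a screening rule).
- The p-value printed next to the ROR is the two-sided normal test of
  ln ROR = 0 with the Wald standard error, the conventional companion of
  the Wald interval.
- SDR thresholds (3 cases, χ² ≥ 4, PRR ≥ 2) are inclusive and
  configurable; pairs below three cases are listed but can never be
  flagged.

A useful identity checked by the property tests: on any 2×2 table the
relative gap between ROR and PRR is bounded by max(a/b, c/(c+d)), because
ROR/PRR − 1 = (ad − bc)/(b(c+d)).  The two statistics therefore agree
closely only when the event is rare *within the exposed reports* (small
a/b), not merely when the drug margin is small; strongly disproportionate
pairs (e.g. ROR 726 vs PRR 563 above) show the expected ~a/b ≈ 29% gap.

## Seriousness comparison

Drug × category counts are tested with Pearson's χ² ((R−1)(C−1) df,
all-zero rows/columns dropped with a warning).  Post hoc cellwise
comparisons use adjusted standardized residuals with two-sided normal
p-values, Bonferroni-corrected over all R·C tested cells — the total count
is used because the comparison sweeps every compound and outcome, and a
full-matrix residual is the standard post hoc when the pairwise
construction is not otherwise specified.  A non-reference compound is
"different from the reference" in a category when its cell residual is
significant; the residual's sign gives the direction.  On a 2×2 matrix each
squared adjusted residual equals the uncorrected χ², which the tests assert.

## Logistic risk model

The hypercalcemia outcome (the canonical `Hypercalcaemia` PT after synonym
normalization, which folds in `Blood calcium increased`) is regressed on
boolean covariates extracted per report:

| covariate | source | default lexicon |
|---|---|---|
| overdose | reaction PTs | "overdose", "toxicity to various agents" |
| calcium_supplements | concomitant drugs | substring "calcium" |
| lithium | concomitant drugs | substring "lithium" |
| thiazide | concomitant drugs | "thiazide", chlorthalidone, indapamide, metolazone |
| dehydration | reaction PTs | "dehydration", "hypovolaemia" |
| cancer | reactions + indications | "neoplasm", "carcinoma", ... |
| polypharmacy | concomitant count ≥ 5 | — |
| age_vulnerable / sex_female | demographics | — |
| multi_vdr | ≥ 2 VDR agonists among suspect + concomitant | — |

Matching is case-insensitive substring containment; the lexicons are YAML
configuration with the defaults above, since the categories, not the term
lists, are what is specified upstream.  Polypharmacy counts concomitant
drugs only (configurable by supplying a different lexicon/extraction).

Fitting is Newton maximum likelihood (statsmodels `Logit`), gradient
tolerance 1e-8, at most 100 iterations — stricter than any reported
precision.  Standard errors come from the inverse observed information;
perfect separation is reported as non-convergence with a warning rather
than an exception; a rank-deficient design raises an error naming the
columns.  The shipped model suite is: model 1 = the six hypercalcemic
conditions; model 2 adds age and sex; model 3 adds polypharmacy; model 4
adds the age×calcium, age×dehydration and age×polypharmacy interactions
(12 covariates).  The exact composition of the smaller published models is
not itemized anywhere, so models 1–3 are this package's nested convention
and the suite is configuration-driven.  Models are ranked by AIC with ties
broken by parameter count.  Sex is coded female = 1, so a negative sex
coefficient is a protective female effect, matching the reported direction.

## Synthetic databases

`vigisignal.synth` generates line listings with known ground truth.  Per
report: independent Bernoulli drug exposures; independent Bernoulli PTs
with logit(p) = logit(background) + Σ planted log-ROR effects of suspected
drugs (so the population ROR of a planted pair against the full-database
comparator is exp(effect)); demographics and a single seriousness category
from configured probability vectors (defaults: the study cohort's
distributions); optional exact duplicate rows sharing the case key.  When a
logistic risk structure is configured, the hypercalcemia PT is drawn from
logit(p) = intercept + β'x (+ planted drug effects), with sampled covariate
prevalences, and every active covariate leaves a recoverable footprint in
the report (an `Overdose` PT, a `calcium carbonate` concomitant, at least
five concomitants for polypharmacy, ...), so that extraction followed by
fitting recovers β.

Two study-shaped configurations are provided, mirroring the two analysis
populations: `study_config` emulates the full database (drug exposure
probabilities equal to the published report fractions of the 5,369,581
reports; hypercalcemia background equal to its rate outside the study
drugs; planted log-RORs reconstructed from the published joint counts), and
`risk_cohort_config` emulates the drug cohort on which the risk model is
estimated (every report in-cohort, outcome driven by the published
12-covariate coefficient vector, intercept −2.6774 giving a ~6–9% outcome
rate as observed in that cohort).  Default covariate prevalences (overdose
6%, calcium salts 15%, cancer 4%, thiazide 5%, lithium 1%, dehydration
1.5%, polypharmacy 25%) are plausible for an osteoporosis-heavy reporting
population and give every coefficient a usable effective sample size at
n = 50,000.

What the generator does **not** emulate: dependence between co-reported
PTs (each PT is conditionally independent given exposure — adequate for
marginal 2×2 analyses, silent about PT co-occurrence structure), reporting
trends over time, free-text narratives, near-duplicate records, and drug
ontologies.  Passing tests therefore demonstrate correctness of the
statistics and recovery under the stated sampling model, not robustness to
real-world coding noise.

Determinism: one seed drives a fixed sequence of vectorized draws, so an
identical configuration yields a byte-identical database.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their error bounds sharp
while keeping the suite quick: brute-force contingency equivalence at
1,000 reports; planted-signal recovery over 100 replicates of 8,000
reports (expected joint count ≈ 53, comfortably above the ≥ 20 validity
floor for the Wald bound); logistic recovery over 20 replicates of 50,000
reports, asserting mean absolute bias below three mean standard errors per
coefficient; model-selection consistency over 50 replicates of 6,000
reports; a type-I-error check of the uncorrected χ² over 1,000 independent
null pairs at 20,000 reports (rate ≤ 7%, the binomial upper bound at the
nominal 5%).  Confidence levels are parametrized through the normal
quantile; display rounding (ROR 1 dp, PRR 2 dp, percentages 2 dp) is a
formatting concern and never enters computation.

## Known limitations

- Published confidence intervals for reconstructed tables agree to ~1% but
  not always to the last printed digit; the original cell values or CI
  variant may differ slightly, so interval checks use a 1% tolerance while
  point estimates are exact.
- The sex distribution of the study cohort is taken at face value from the
  published counts (26% female, 70% male), although it sits oddly with the
  osteoporosis-dominated indications; the generator simply reproduces the
  stated margins.
- The full-dataset comparator confounds by indication; restricted or
  Bayesian comparators (BCPNN, MGPS) are out of scope.
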