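# vigisignal

Signal detection and risk-factor modelling for spontaneous adverse-event
report databases, built around the safety profile of vitamin D receptor
(VDR) agonists (cholecalciferol, calcitriol, alfacalcidol, paricalcitol,
ergocalciferol, calcifediol and the rarer analogues).

Pharmacovigilance databases such as EudraVigilance collect individual case
safety reports (ICSRs): one spontaneous report of one or more suspected
adverse drug reactions, coded as MedDRA preferred terms (PTs).  `vigisignal`
implements the standard case-level analysis pipeline for such line listings,
for pharmacoepidemiologists and drug-safety scientists who want the whole
chain — ingestion, de-duplication, disproportionality statistics,
seriousness profiling and logistic risk-factor modelling — as a reproducible,
tested package rather than a spreadsheet, together with a synthetic report
generator so every stage can be validated against known ground truth.

## What it computes

For each drug–event pair, reports are counted into a 2×2 table against the
full-database comparator (`a` = reports with drug and event, `b` = drug
only, `c` = event only, `d` = neither; a PT counts at most once per report):

- **PRR** = [a/(a+b)] / [c/(c+d)] — proportional reporting ratio;
- **ROR** = (a·d)/(b·c) — reporting odds ratio, with the Wald interval
  exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d));
- Pearson χ² on 1 df (Yates-corrected for signal evaluation); and
- the EMA **SDR** rule: a signal of disproportionate reporting is flagged
  when a ≥ 3, χ² ≥ 4 and PRR ≥ 2 (all inclusive).

Seriousness and age profiles are compared across compounds with a χ² test
of independence followed by post hoc adjusted standardized residuals
r = (O − E)/√(E(1 − n_row/N)(1 − n_col/N)) and Bonferroni-corrected flags.
Hypercalcemia risk factors (overdose, calcium salts, lithium, thiazides,
dehydration, cancer, polypharmacy, vulnerable age, sex, combined VDR
agonist use) are extracted from each report via configurable lexicons and
fitted with maximum-likelihood logistic regression; candidate models are
ranked by AIC and judged by McFadden pseudo-R² and the likelihood-ratio
test, with odds ratios exp(β) and Wald intervals.

## Worked example

Rebuilding the hypercalcemia–calcitriol table from its published counts
(304 joint reports, 1,355 calcitriol reports, 2,442 hypercalcemia reports,
5,369,581 reports in the database):

```python
import vigisignal as vs

table = vs.ContingencyTable.from_margins(a=304, drug_margin=1355,
                                         event_margin=2442, n=5_369_581)
print(f"ROR = {vs.compute_ror(table):.1f}")
print(f"PRR = {vs.compute_prr(table):.2f}")
lo, hi = vs.ror_confidence_interval(table)
print(f"95% CI = ({lo:.1f}, {hi:.1f})")
chi2, p = vs.chi_square(table, continuity_correction=True)
print("SDR:", vs.evaluate_sdr(table.a, chi2, vs.compute_prr(table)))
```

prints

```
ROR = 726.0
PRR = 563.32
95% CI = (634.6, 830.5)
SDR: True
```

i.e. hypercalcemia is reported 726 times more often (on the odds scale)
with calcitriol than expected from the rest of the database, with a
confidence interval far above 1, so the pair is flagged as a signal.

The same analysis end-to-end on a synthetic database, from the shell:

```
vigisignal run --outdir demo_run --n 5000 --seed 1
```

simulates 5,250 reports (5,000 cases plus 5% duplicate transmissions),
de-duplicates, scans all drug–event pairs in both the full and the
serious-only stratum, tabulates seriousness with adjusted residuals, and
fits four nested logistic risk models.  `demo_run/signals.tsv` contains the
flagged planted signals, e.g.

```
drug        event           a   b    c    d     prr   ror   ci_low  ci_high  chi2    p         is_sdr  stratum
calcitriol  Hypercalcaemia  83  58   436  4423  6.56  14.5  10.2    20.6     361.31  7.31e-51  True    all
alfacalcidol Hypercalcaemia 73  69   446  4412  5.60  10.5  7.4     14.8     259.95  5.28e-41  True    all
```

and `demo_run/risk_report.tsv` shows the correctly specified 12-covariate
model winning the AIC comparison (`model4`, AIC 3209.69, vs 3218.15 for the
next candidate).  Each subcommand (`simulate`, `ingest`, `signals`,
`seriousness`, `risk`) is also available on its own; see `vigisignal --help`.

## Layout

- `vigisignal.synth` — synthetic database generator (`SynthConfig`,
  `generate_database`, study-scale and demo configurations)
- `vigisignal.ingest` — line-listing I/O, de-duplication, PT normalization,
  PT→SOC mapping, subsetting
- `vigisignal.dispro` — contingency tables, PRR/ROR/χ²/SDR, signal scans,
  descriptive frequency tables
- `vigisignal.seriousness` — category matrices, independence test, adjusted
  residuals, Bonferroni flags
- `vigisignal.riskmodel` — risk-flag extraction, `HypercalcemiaRiskModel`
  / `HypercalcemiaRiskResults`, model comparison
- `vigisignal.pipeline`, `vigisignal.cli` — orchestration and the
  `vigisignal` command

See `docs/methods.md` for the modelling assumptions and numerical choices.
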