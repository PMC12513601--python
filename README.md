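# pvsignal

Disproportionality signal screening for spontaneous adverse-event
reporting systems (SRS).

## The problem

Passive pharmacovigilance databases — FAERS, VigiAccess and their kin —
collect voluntarily submitted adverse drug event (ADE) reports. Safety
signal detection asks whether a given (drug, event) pair is reported
*disproportionately* often relative to the background of all other drugs
and events in the database. `pvsignal` implements the standard
threshold-based workflow for one drug of interest:

1. **Ingestion** of a report table (one row per report, with
   demographics and a set of MedDRA-style preferred terms, PTs) and a
   PT → system organ class (SOC) dictionary.
2. **Descriptives**: demographic breakdowns (reports as the unit), SOC
   distributions and top-N PT rankings (event occurrences as the unit),
   and the Venn partition of two databases' top-N lists.
3. **Screening**: per-PT 2×2 contingency tables and the classical
   statistics

   | statistic | formula | positive when |
   |---|---|---|
   | ROR | ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | a ≥ 3 and CI lower bound > 1 |
   | PRR | a(c+d) / (c(a+b)) | a ≥ 3, PRR ≥ 2 and χ² ≥ 4 |
   | χ² | (ad−bc)²(a+b+c+d) / ((a+b)(c+d)(a+c)(b+d)) | (with PRR) |

   where a = reports of the drug with the event, b = other-drug reports
   with the event, c = drug reports without it, d = the remainder. A
   PT meeting **both** criteria is a positive signal. χ² is the plain
   Pearson statistic without Yates correction; zero cells produce
   flagged non-finite values, never exceptions, and are never positive.
4. **Subgroups**: the same screen within each level of a demographic
   stratifier (sex, age group, region, year), partitioned before
   contingency construction.
5. **Synthetic SRS generation** with exact ground truth (per-PT
   reporting-rate ratios), so the whole pipeline is testable without a
   database download.

Signals are statistical associations, not causal findings, and no
multiple-testing adjustment is applied — both standard caveats of
threshold-based SRS screening.

## Worked example

```python
import pvsignal as pv
from pvsignal.simulate import default_config, simulate, catalog_dictionary

cfg = default_config(n_reports=20_000, seed=3)     # 6 planted signals
reports, truth = simulate(cfg)
dictionary = catalog_dictionary(cfg.pt_catalog)

model = pv.DisproportionalityModel(reports, dictionary, drug="DRUG-X")
res = model.fit()
print(res.summary())
```

prints

```
Disproportionality screen: DRUG-X in synthetic
universe 20000 reports (2051 drug-of-interest); 40 PTs screened, 5 positive signals
criteria: a>=3, ROR CI low>1.0, PRR>=2.0, chi2>=4.0

PT                                       a        ROR                 95% CI      PRR      chi2
Blood potassium abnormal               134      9.155        [7.179, 11.676]    5.108   461.056
Blood potassium increased              287      7.522         [6.404, 8.835]    4.716   805.297
Blood sodium increased                  59      5.451         [3.931, 7.559]    3.768   129.811
Hypernatraemia                          38      4.753         [3.197, 7.067]    3.445    72.108
Oedema                                 238      3.365         [2.880, 3.931]    2.748   260.562
```

Five of the six planted rate-ratio elevations are recovered as combined
ROR/PRR positives (the sixth, a rate ratio of 2.5 on a 0.8% baseline,
sits near the detection threshold at this sample size); every a-count,
ROR and CI is computed from the drawn 2×2 tables.
`res.to_frame()` gives the full per-PT statistics,
`res.forest_frame()` a forest-plot-ready table, and
`model.fit(stratify_by="sex")` the sex-stratified screen with its
cross-stratum comparison matrix.

The same workflow is available from the shell:

```bash
pvsignal simulate --n-reports 20000 --seed 3 --out-reports r.csv
pvsignal screen --reports r.csv --drug DRUG-X --out screen.csv
pvsignal run --config examples/demo_config.yaml   # full two-source bundle
```

## Replaying published aggregates

`pvsignal.replay` ships the published aggregate tables of one worked
study — adverse-event extracts for the potassium binder sodium zirconium
cyclosilicate from FAERS (1384 reports, 2246 event occurrences) and
VigiAccess (1518 reports, 2555 occurrences) — and rebuilds the
descriptive layer from counts alone: demographic percentages, SOC
distributions, top-30 PT tables and the 28-PT overlap between the two
databases' top-30 lists. Report-level replay sets pad the published
top-30 with a clearly-labelled synthetic tail so event totals are exact.

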