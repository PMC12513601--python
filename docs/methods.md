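# Methods

## Counting conventions

Spontaneous-reporting-system (SRS) summaries mix two units, and the
package fixes them explicitly:

* **Reports** are the unit of demographic tables and of every 2×2
  contingency cell. A report contributes to exactly one cell per PT,
  and contains a PT at most once (PT sets, not lists).
* **Event occurrences** — (report, PT) pairs for the drug of interest
  as primary suspect — are the unit of SOC and top-PT tables, and their
  percentage denominators. A report with three PTs contributes three
  occurrences.

The drug-of-interest arm of every contingency table is "named as
primary suspect"; reports naming the drug in any other role fall in the
comparator arm together with all other drugs' reports. Whether a PT
repeated inside one source record should count once or twice is not
observable in aggregate exports; set semantics (once) is assumed.

"Unknown" is a first-class level of every demographic category, never a
missing value: unknown rows stay in demographic denominators, and in
stratified screening unknown forms its own stratum (so strata always
partition the universe) rather than being merged into a named level.

PT and SOC strings are matched after trimming, collapsing internal
whitespace and case-folding; display forms keep the dictionary's
casing. This absorbs the case variants different databases print for
the same term.

## Screening statistics

For a table (a, b, c, d) with N = a+b+c+d:

* ROR = ad/bc, with Wald 95% CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
  z = 1.96.
* PRR = a(c+d)/(c(a+b)) — the ratio of the drug's share among event
  reports to its share among non-event reports.
* χ² = (ad−bc)²·N / ((a+b)(c+d)(a+c)(b+d)), the uncorrected Pearson
  statistic; deliberately **not** Yates-corrected, matching the form
  conventional in SRS screening.

Positivity: ROR-positive iff a ≥ 3 and CI lower bound > 1; PRR-positive
iff a ≥ 3, PRR ≥ 2 and χ² ≥ 4; a positive signal requires both. All
thresholds are parameters (`ScreeningCriteria`) with those defaults.

Degenerate tables: b·c = 0 makes the ROR infinite (or NaN when the
numerator also vanishes); a zero anywhere leaves the CI undefined; zero
PRR/χ² denominators give NaN. Non-finite statistics carry through as
flags and can never be positive. A Haldane–Anscombe continuity constant
(`continuity=0.5` adds it to all cells of zero-cell tables) is
available but off by default, since the screening formulas above are
conventionally applied uncorrected. Ranking ("signal strength") is by
the ROR point estimate; display rounding of ROR/CI is three decimals,
percentages two decimals, rounding half-up as printed tables do.

No multiple-testing adjustment is applied; with hundreds of PTs
screened at fixed thresholds, the family-wise false-positive count is
material, and the per-PT null calibration below is the honest
description of what the thresholds control.

## Synthetic reporting-system generator

`simulate(SimConfig)` draws: a suspect drug per report (categorical
over the drug of interest and `n_background_drugs` background drugs);
independent Bernoulli inclusion of each catalog PT with baseline
probability `p` (background drugs) or `min(1, ρ·p)` (drug of interest,
per-PT rate ratio ρ); independent demographics with explicit unknown
mass. Reports drawing fewer than `min_pts_per_report` (default 1) PTs
are redrawn, since an event-less spontaneous report does not exist.
Identical configs (including seed) are bit-identical.

Independence makes the null and alternative exact. The redraw step
conditions each report's PT vector on K ≥ m, so the *conditional*
marginal of PT i is p_i·P(K₋ᵢ ≥ m−1)/P(K ≥ m), computed exactly by a
Poisson-binomial recursion; the true report-level odds ratio used by
the coverage checks is the odds ratio of these conditional
probabilities between arms (`GroundTruth.true_report_odds_ratio`). For
the default m = 1 this reduces to q_i = p_i/(1−∏(1−p_j)).

Default study conditions: 5 000 reports, drug-of-interest weight 0.10,
40 background drugs, a 40-PT catalog with baselines from 0.2% to 8%
spanning the organ classes a potassium-binder extract touches, six
planted rate ratios (2.5–10) on potassium/sodium laboratory terms and
oedema-related terms, and demographic masses mirroring a real
hyperkalemia-drug extract (male-dominated, large unknown-age mass,
mostly Americas, counts rising by year). What the generator does *not*
emulate: within-report PT correlation, reporting delays and duplicate
submissions, concomitant drugs, dose, and drug-dependent demographics.
Passing calibration tests therefore show the statistics and thresholds
behave correctly under independent reporting — not that real FAERS
extracts satisfy independence.

## Replay of published aggregates

The bundled fixtures encode the published aggregate tables of one
study (a FAERS and a VigiAccess extract for sodium zirconium
cyclosilicate): demographic counts, SOC counts (event totals 2246 and
2555), and top-30 PT counts. Replay constructors rebuild each table
from counts with the published denominators. For event-level
operations a report-level stand-in is generated: the published top-30
counts exactly, plus a deterministic synthetic tail (labelled
`Synthetic background term NNN`) spreading the remaining event mass
over the remaining published distinct-PT count, with tail counts kept
strictly below the published rank-30 count so the top-30 is unchanged.
The published tables carry a few internal inconsistencies (year and
age rows that do not sum to the report totals, and isolated cells
whose printed percentage differs from count/total by 0.01); counts are
replayed verbatim and the affected cells are simply not used as
checks. The bundled PT→SOC dictionary is a small synthetic stand-in
with plausible primary-SOC assignments, not a licensed terminology.

## Sizes and numerical choices

Monte-Carlo checks use: power — 100 systems of 20 000 reports with a
planted ρ = 6 on a 2% baseline; null calibration — 300 all-null systems
of 3 000 reports, monitoring PTs with expected drug-arm count ≥ 5 and
testing each PT's ROR-positive rate against 5% with a one-sided
binomial check (Monte-Carlo error makes a raw ≤ 5% comparison of 300
Bernoulli draws miscalibrated); CI coverage — 500 systems of 5 000
reports at ρ = 3, requiring 93–97% coverage of the exact generative
odds ratio. These sizes give binomial standard errors comfortably
inside the asserted bands while keeping a full run under a minute.

Ties in rankings break alphabetically (ascending PT, or SOC, name);
screening output orders combined positives first by descending ROR.
All pipeline CSVs use fixed orderings and rounding so reruns are
byte-identical; the run manifest records versions, a config hash,
row-count accounting and timing.

## Known limitations

* Threshold screening inherits all SRS biases (under-reporting,
  duplicates, confounding by indication); outputs are hypotheses.
* The Wald CI is anti-conservative for very small a; the a ≥ 3 gate
  bounds but does not remove this.
* The comparator arm is "everything else in the extract", so absolute
  RORs depend strongly on the background; values are only comparable
  within a universe.
* Stratified screens restrict the comparator to the same stratum; with
  small strata the zero-cell flags appear often and stratum-specific
  labels should be read as descriptive, not as interaction tests.
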