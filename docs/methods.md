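# Methods

## Data model and cohort construction

A spontaneous report is one DEMO row joined with its DRUG/REAC/OUTC/THER/
INDI children, keyed by `primaryid` (one per report version) and `caseid`
(shared across versions of the same case). Child rows referencing a
`primaryid` absent from DEMO are counted as orphans and never fabricated.
Dates are parsed as `YYYYMMDD`; partial dates (`YYYYMM`, `YYYY`) map to the
first day of their period and are flagged imprecise rather than dropped,
since onset arithmetic must state its convention. Age unit codes are
converted to years (DEC ×10, YR ×1, MON ÷12, DY ÷365.25).

Deduplication is two-pass. Pass 1 keeps, per `caseid`, the report with the
latest FDA tracking date, ties resolved to the higher report number. Pass 2
collapses residual duplicates that agree on the full matching tuple (age,
sex, country, event date, sorted reaction PTs, sorted ingredients, sorted
indication PTs), keeping the most recent. A missing field never matches
anything — two reports both missing age are *not* considered equal on age.
This is the conservative reading of a matching rule stated only as
"fields such as ..."; the alternative (missing matches missing) would
collapse unrelated sparse reports. Deduplication is idempotent and the
per-pass removal counts are carried into the run manifest
(`reports_in = reports_out + removed_pass1 + removed_pass2`).

Exposure requires the primary-suspect (PS) role; SS/C/I never confer it. An
event is neurological iff at least one reaction PT has Nervous system
disorders as its *primary* SOC — multiaxial secondary links do not qualify.
Outcome classes: serious ⇔ outcomes ∩ {death, life-threatening,
hospitalization} ≠ ∅ ("near death" is the FAERS life-threatening code LT);
nonserious ⇔ other outcomes only; missing ⇔ no outcome row. Age bins are
{<45, [45,65), ≥65}, weight bins {<50, [50,100), ≥100} kg — half-open at the
upper boundary so no report is counted twice. Monotherapy vs polypharmacy is
operationalised as exactly one distinct ingredient on the report vs more
than one (the dichotomy is otherwise undefined in the source tables).

## Disproportionality statistics

For a 2×2 table (a, b, c, d) with N = a+b+c+d:

- ROR = ad/bc, CI = exp(ln ROR ± 1.96·s) with s = √(1/a+1/b+1/c+1/d);
- PRR = [a/(a+b)]/[c/(c+d)]; its default SE is the conventional
  √(1/a − 1/(a+b) + 1/c − 1/(c+d)); an option (`se_style="ror"`) reproduces
  the ROR-style SE that some published equation blocks print;
- IC = log₂(aN/((a+b)(a+c))), the frequentist information component
  (observed over expected joint reporting probability, base 2 by
  pharmacovigilance convention).

The IC interval deserves a note. Published equation blocks sometimes print
IC ± 1.96·s with s the *natural-log* SE above. That interval is too narrow
by a factor ln 2 ≈ 0.693: by the delta method the standard error of a
base-2 log statistic is s/ln 2. Null-calibration simulation confirms the
narrow form inflates the one-sided false-positive rate of the IC condition
several-fold. The package therefore defaults to the log2-scaled SE
(`se_scale="log2"`) and keeps the additive printed form available
(`se_scale="printed"`) for comparison with published tables.

Zero cells: the default policy is `strict` (statistics undefined, verdict
false with reason "undefined"); `haldane` adds 0.5 to every cell and flags
the result corrected. The per-PT signal rule (a ≥ 3) makes zero-a tables
irrelevant for signal verdicts either way. No multiple-testing adjustment
is applied across PTs; the screen records this in its output metadata.

IC is *not* globally monotone in a with b, c, d fixed, because N grows with
a and the observed/expected ratio saturates: (1,1,1,5)→(2,1,1,5) leaves IC
unchanged and (99,1,1,1)→(100,1,1,1) decreases it. Strict monotonicity
holds in the rare-event regime a ≤ min(b, c), which is where signal
detection operates; the property test is scoped accordingly.

## Risk-factor models and E-values

Risk factors for the neurological outcome are estimated by maximum-
likelihood logistic regression with Wald intervals, complete-case
throughout (missingness in these data is strongly nonrandom — related to
reporter type and region — so imputation assumptions would not hold).
Model 1 adjusts for reporter type (professional vs nonprofessional), region
(US vs other) and monotherapy vs polypharmacy; Model 2 adds age
(continuous, untransformed), sex and body weight (continuous). Dropped-row
accounting is explicit: n_input = n_complete + n_dropped per fit. Fits with
fewer than 50 complete rows (configurable) are flagged non-estimable, as is
separation (a zero cell of exposure × outcome); there is no silent
fallback. For a binary factor the univariate logistic OR equals the 2×2
cross-product ratio, which the tests enforce as an algebraic
cross-check against the disproportionality code path.

E-values quantify robustness to unmeasured confounding: for RR > 1,
E = RR + √(RR·(RR−1)); protective estimates are inverted first; RR = 1
gives E = 1. Reporting odds ratios are treated as risk-ratio approximations
under the rare-outcome assumption (nAE share < 10%). The CI E-value is
computed at the confidence bound closer to the null and set to 1 when the
interval crosses 1.

## Onset, severity and trend

Time to onset is the event date minus the *earliest* PS therapy start, in
whole days. (The subtraction is stated in this order deliberately: it is
the only order producing the non-negative onsets the summaries describe.)
Negative differences are data inconsistencies — excluded with reason
"negative", never clipped; every summary reports its excluded counts.
Quantiles use linear interpolation between order statistics; "within two
months" means onset ≤ 60 days.

Group comparisons of onset report both a log-rank test and the rank test
(Mann–Whitney U for two groups, Kruskal–Wallis for more). Spontaneous
reports carry no censoring information, so the log-rank treats every onset
as an observed event — a documented approximation that makes it close to a
rank test here. Generic continuous comparisons pass a normality gate
(Shapiro–Wilk for n ≤ 50, Kolmogorov–Smirnov against a moment-fitted normal
above) selecting t-test/ANOVA vs the rank-based alternative; all tests are
two-sided. Severity comparisons use Pearson chi-square without continuity
correction (a flag enables Yates); expected cells below 1 raise a warning
but the statistic is still computed.

The quarterly trend is OLS of nAE counts on the quarter index 0, 1, 2, ...,
slope in cases per quarter, CI from the t distribution with n−2 df, R² as
the explained-variance fraction (0 by convention when the counts are
constant).

## Synthetic data generator

The generator exists so that every downstream stage can be validated
against planted truth. Each report draws one exposure drug (catalog shares,
respecting marketing-start quarters) and a set of reaction PTs; PT
inclusion is Bernoulli with logit(p) = logit(baseline · multiplier(drug,PT))
+ xᵀβ on neurological PTs, with centred covariates (age, sex, weight). For
rare events the marginal 2×2 odds ratio then approaches the planted
multiplier, which is what the recovery tests exploit. Reports that draw no
reaction receive one background PT (FAERS reports always carry at least one
reaction); the fill pool is non-neurological so planted odds ratios are not
distorted. Event dates are uniform within their quarter; therapy start
precedes the event by a per-drug lognormal onset draw, making onset
distributions recoverable. Duplicates are near-copies sharing all matching
fields and the case identifier, with a strictly higher report number and an
equal-or-later tracking date, so both deduplication passes are exercised.
Random streams are split per field (fixed stream keys under a single seed),
so adding a field leaves the other draws unchanged and fixtures stay
stable; identical configs give identical bundles.

Default study conditions: 39 calendar quarters (2014Q4–2024Q2) with
linearly growing volume; three target PD-1 ingredients (shares 17%, 14%,
1%, cemiplimab entering 2018Q4) among eight catalog drugs; 16 neurological
PTs with baseline per-report rates 10⁻⁴–6·10⁻³ and 12 common background
PTs (rates 1.5–7%); covariates centred on age 64 ± 14 y, weight 72 ± 21 kg,
42% female, 70% professional reporters, a US share of 33%; missingness
70% (weight), 25% (age), ~61% (onset information, via therapy-start and
event-date gaps), 7.6% (sex and outcome); 2% duplicate submissions; onset
medians 39/26/52 days for the three target drugs with lognormal σ = 1.6.
These mirror the reporting profile the analysis is designed for. What the
generator does **not** model: reporting-propensity waves and media effects,
country-specific regulatory lag, free-text narratives, within-report
correlation beyond the shared covariate term, and drug-specific
*confounding* (covariates are independent of the exposure drug). Passing
tests therefore demonstrate correctness of the statistical machinery under
a known mechanism, not robustness to the biases of real spontaneous data.

## Numerical and design choices

- Field separator `$` per the public FAERS ASCII convention (configurable).
- Wald CIs and p-values for logistic coefficients; z₀.₉₇₅ carried at full
  precision (1.959963984540054).
- Percentages in descriptive tables round half-up (decimal arithmetic, not
  banker's rounding) to 1–2 decimals.
- Pass-2 dedup matches the full sorted reaction/ingredient/indication
  tuples; empty reaction or drug lists make a report unmatchable.
- The class-level screen treats "any" as exposure to at least one target
  ingredient in the PS role.
- Problem sizes in the test suite: the large recovery bundle is 200k
  reports (planted multipliers 5 and 3); CI coverage uses 10k simulated
  tables; logistic recovery 200 replicates of n = 3,000; trend coverage
  1,000 replicates of 39 quarters; null calibration 200 bundles of 1,500
  reports. These sizes put Monte-Carlo error well inside the asserted
  bands while keeping the default run in the tens of seconds.

## Known limitations

- The log-rank comparison without censoring is equivalent in spirit to a
  rank test; it is retained for comparability with common practice, not
  because censoring exists in the data.
- The frequentist IC is not the shrinkage-based BCPNN credibility interval;
  very small cells are handled by the zero-cell policy and the a ≥ 3 rule
  rather than by Bayesian shrinkage.
- Drug-name normalisation is exact-match after case/punctuation folding; no
  fuzzy matching or spelling correction is attempted, and unmapped names
  are reported as unmapped, never guessed.
- The synthetic hierarchy is a structural stand-in (five levels, one
  primary SOC per PT, multiaxial links), not licensed dictionary content.
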