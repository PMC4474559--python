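# Methods

## Setting and data model

The package operates on country-period panels of life expectancy at birth
(LE, years) with population sizes, the form in which UN World Population
Prospects (WPP) publishes country-level demographic summaries. A record is
one country × period × sex observation; periods are half-open calendar
intervals, canonically 5-year spans such as 1965–1970 (the shorthand
"1965–70" is normalised on input). Sex takes the values `female`, `male`,
`both`. Validity requires 0 < LE < 130 and population ≥ 0; these are checked
by the report-only validator rather than at construction, so dirty inputs
can be loaded and audited. Country identifiers are opaque strings matched
exactly after trimming — name harmonisation is a data-preparation concern
outside this package.

## Regional aggregation

A region is a named membership list. Its LE for a period and sex is the
population-weighted mean over members, Σ popᵢ·LEᵢ / Σ popᵢ. Members without
a record for a slice are skipped and logged (no imputation); a slice with no
members at all, or zero total population, is an error. When a `both` row is
absent for a country, the both-sex LE is derived as the sex-population-
weighted mean of the female and male rows.

Two comparison series are supported: the **gap** (region minus a caller-
supplied world average, signed) and the **shortfall** (maximum of a caller-
supplied comparator LE set minus the region). The comparator set is always
caller-supplied — typically the weighted LE of each configured region, or
the 22 UN world sub-regions when that external series is available — so the
package hard-codes no world geography. A region contained in its own
comparator set has shortfall exactly 0 when it is the best performer.

Gender summaries report F − M (years), 100·(F − M)/F and F/M. The percent
difference uses the **female** LE as denominator; this convention was fixed
by checking it against two independent published cells (5.16/74.42 → 6.93
and 5.31/77.91 → 6.82), which male- or midpoint-denominator variants fail.

## Disparity metrics

For a slice of n countries with LE values LEᵢ, populations popᵢ, shares
pᵢ = popᵢ/Σpop and weighted mean μ = Σ pᵢLEᵢ:

| metric | definition | units | family |
|---|---|---|---|
| LED | max − min | years | absolute, simple |
| LER | max / min | — | relative, simple |
| MD | (1/n)·Σᵢ (LE_best − LEᵢ) | years | absolute, complex |
| ID | 100·MD / LE_best | % | relative, complex |
| BGV | Σᵢ pᵢ(LEᵢ − μ)² | years² | absolute, complex |
| STI | scale·(T + MLD)/2 | — | relative, complex |

with T = Σᵢ pᵢ(LEᵢ/μ)ln(LEᵢ/μ) and MLD = Σᵢ pᵢ ln(μ/LEᵢ). LED, LER, MD and
ID ignore populations; BGV and STI are population-share weighted with the
same μ as the aggregation step, and are invariant to uniform population
rescaling. Presenting the suite together follows standard practice in
health-disparity monitoring: consensus across absolute and relative measures
is the evidence for a disparity trend, since no single measure captures both
facets.

Design choices that were genuinely open:

* **MD/ID denominator.** The default divides by all n countries (the best
  performer contributes a zero term); an `include_reference=False` /
  `md_denominator="n-1"` mode divides by n − 1, a variant that exists in the
  disparity literature. Both are exposed because published descriptions are
  often ambiguous on this point.
* **STI reporting scale.** Entropy indices on LE data are of order 10⁻³;
  the unscaled T and MLD are always retained, and the reported STI is
  multiplied by a configurable constant (default 1000; 1 and 10000 are the
  other common conventions). Percent changes are scale-invariant, so trend
  statements do not depend on this choice.
* **Reference-country tie-break.** At equal maximal LE the reference is the
  lexicographically first country id; deterministic and recorded in the
  suite.
* **Combined-sex suites.** By default computed on both-sex LE slices
  (derived when necessary); an `average-of-suites` mode instead averages
  the female and male suites metric-wise. Published combined-sex rows are
  approximately but not exactly the mean of sex-specific rows, so both
  interpretations are available.

Percent change is 100·(v_to − v_from)/v_from and is undefined for a zero
baseline (`percent_change` raises). Inside pipelines, a metric that is
exactly zero in both periods is reported as 0% change and a zero-baseline-
only cell as NaN with a warning, so equality fixtures and degenerate slices
flow through without aborting a run. The averaged **absolute** reduction is
the arithmetic mean of the LED, MD and BGV percent changes; the **relative**
reduction averages LER, ID and STI. Display rounding is applied only at
rendering: values and percent changes at 2 dp, headline averages as
whole-percent magnitudes ("14%"). Because published inputs are themselves
printed at 2 dp, a derived cell recomputed from them can differ from its
printed counterpart by one unit in the last digit; the bundled reference
tables document this.

## Leave-one-out sensitivity

For each member country the region is recomputed without it: weighted LE in
a base and end period, the deviation from the full-region aggregate, the LE
change between periods (years and percent), and the percent change of
selected disparity metrics (MD and ID by default; any suite metric can be
selected). Removing a member with LE below the full-region weighted mean
necessarily raises the aggregate, and conversely. The exact reconstruction
identity le_full·P = le_without·(P − pop_r) + LE_r·pop_r holds for every row
and is tested to 1e−9 relative. A member missing from a period is flagged on
its row, never silently dropped. The summary reports min/max reduced-region
LE per period and min/max metric-trend change, with the responsible removal
(ties broken by country id).

## Synthetic data generator

The generator emulates the *structure* of WPP-like regional input at desk
scale — it makes no demographic claims. Per country: a both-sex baseline LE
~ Normal(baseline_mean, baseline_sd) in the first period, a constant annual
gain ~ Normal(annual_gain_mean, annual_gain_sd), period-level Gaussian noise
(noise_sd), and a gender gap ~ Normal(gender_gap_mean, gender_gap_sd) split
± half around the both-sex value (clipped to keep LE in (1, 129) years).
Populations are log-normal and constant across periods unless a growth rate
is set (default 0, isolating weighting effects). Defaults: 21 countries,
nine 5-year periods 1965–70 … 2005–10, baseline 60 ± 5 years, gain 0.3 ±
0.1 years/year (global LE rose roughly a third of a year per calendar year
over this era), gender gap 5 ± 1 years, log-normal populations with
log-mean 13.1 (median ≈ 4.9·10⁵ persons) and log-sd 1.5, echoing the
heavy-tailed spread from ~10⁵ to ~10⁷ inhabitants across Caribbean
territories. The `outlier` scenario adds a Haiti-like member: 15 years
subtracted from its drawn baseline and its population set to exactly 22% of
the regional total; removing it from the region therefore lifts the
weighted LE by ≈ 0.22 × 15 = 3.3 years in expectation, a closed form used
as a recovery check. LE dynamics are deliberately linear-with-noise, not
logistic convergence; the generator supports metric, trend and sensitivity
testing, and passing tests on it say nothing about mortality schedules,
migration or cohort effects in real data.

## Numerical and testing notes

All arithmetic is double precision with no internal rounding. Metric
implementations are vectorised (numpy); the test suite checks them against
independently coded plain-Python direct-summation oracles to 1e−10 on
random slices, plus an unweighted-expansion oracle for BGV (replicating
each country pop times). Consistency between the variance and entropy
families is checked through the small-dispersion limit BGV ≈ 2μ²·STI
(unscaled), with relative error under 1% once the LE spread is ≤ 0.5% of
the mean. Stochastic recovery checks (outlier shift over 200 seeds, annual
gain over 100 seeds) use a 3-standard-error band. Problem sizes in the test
and acceptance runs — 21-country panels, 9 periods, hundreds of seeds —
match the scale of the regional analyses the package targets while keeping
the default suite fast.

## Limitations

* Life tables are not constructed: LE is an input, never estimated from
  mortality rates, and 5-year periods are not interpolated to annual series.
* No sampling variance or confidence intervals for the metrics; the suite
  quantifies disparity, not estimation uncertainty.
* Rank-based measures for ordered groups (slope/concentration indices) are
  out of scope; the implemented suite assumes unordered groups.
* The bundled Caribbean membership list reconstructs a published 21-territory
  grouping by its stated inclusion rule; it carries names only, no data.
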