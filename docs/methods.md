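# Methods

## Scope and procedure

`aquarisk` implements the deterministic, conservative residential
drinking-water risk assessment of the EPA Superfund guidance for a fixed set
of persistent organic pollutants: thirteen PCB congeners (assessed jointly as
a mixture) and four chloroorganic pesticides (gamma-HCH, DDE, DDD, DDT). The
pipeline is a pure function of its inputs — no fitting, no sampling beyond
the synthetic-campaign generator — in five stages:

1. **Aggregation.** Per-sample concentrations (ng/dm³) are averaged per site,
   then the exposure-point concentration c̄ per analyte is the *unweighted
   arithmetic mean of the per-site means over the supply wells*. This is
   deliberate: the bundled study tabulates its cross-well averages as the
   mean of the three well columns, not as a pooled mean over all samples.
   Surface-water reference sites (the river) are summarised but excluded
   from c̄, since only well water is drunk.
2. **Screening.** c̄ and the class totals are converted to mg/dm³ (×10⁻⁶) and
   compared with the US EPA PCB maximum contaminant level (0.0005 mg/dm³)
   and the EU limits for single (0.0001 mg/dm³) and total (0.0005 mg/dm³)
   pesticides. Equality with a limit is compliant: the limit is the maximum
   permitted level. Screening is monotone in concentration by construction.
3. **Exposure.** LADD and ADD per (analyte, group) from the dose equation in
   the README. PCB congeners enter as one class-total row under the key
   `SUM-PCB`; pesticides enter individually.
4. **Risk.** One-hit ELCR per cell, additive per-group totals, expected extra
   cancer cases ECC = ELCR × N, and the acceptability classification.
5. **Hazard.** HQ = ADD/RfD per cell against chronic RfDs and per-group
   HI = ΣHQ, flagged when HI > 1.

## Parameters and defaults

| parameter | children 0–6 | children 7–17 | adults | units |
|---|---|---|---|---|
| population N | 934 | 2,046 | 8,140 | persons |
| body weight BW | 15 | 46 | 70 | kg |
| intake rate IR | 0.3 | 1.0 | 1.4 | dm³/day |
| exposure duration ED | 6 | 11 | 30 | years |
| AT (cancer) | 25,550 | 25,550 | 25,550 | days |
| AT (noncancer) | 2,190 | 4,015 | 10,950 | days |

Scenario-wide: fraction ingested FI = 0.65 (≈65% of consumed water is tap
water, the remainder bottled), exposure frequency EF = 365 days/year,
absorption coefficient 1 (conservative). The adult exposure duration is the
EPA upper-bound 30 years at one residence, not the 70-year lifetime; `ED` is
an ordinary parameter, so the 70-year variant is one argument away.

Toxicity constants (oral slope factor SF₀ in (mg/(kg·day))⁻¹, chronic RfD in
mg/(kg·day)): PCB mixture 2.0 / 2·10⁻⁵ (NOAEL 0.007, Aroclor 1016, class B2);
gamma-HCH 1.10 / 3·10⁻⁴ (NOAEL 0.33; not EPA-classified, but a slope factor
is available and used); DDE 0.34 / 3·10⁻³; DDD 0.24 / 9·10⁻³; DDT 0.34 /
5·10⁻⁴ (NOAEL 0.05). All B2 except gamma-HCH.

## Slope-factor configurations

The study whose tables this package reproduces applied the PCB-mixture slope
factor of 2.0 to *all five* assessment rows — in its published risk matrix
every ELCR equals twice the corresponding LADD, including for the pesticides
whose own slope factors are 1.10/0.34/0.24/0.34. Whether that was intended
is not decidable from the published record, so neither option is silent:

* `as_published` — uniform SF 2.0; reproduces the published ELCR/ECC tables.
* `per_analyte` — each analyte's registry slope factor; the default, since it is
  the toxicologically standard choice. It lowers the whole-population burden
  from ≈0.0535 to ≈0.0494 expected cases.

## Averaging-time conventions

`epa_lifetime` (default) averages carcinogenic doses over 25,550 days for
every group, per Superfund guidance. `duration_matched` sets the carcinogenic
AT equal to the exposure duration for a designated set of groups — the
appropriate convention when concentrations are roughly constant over the
assessment horizon, and always the more conservative one for short-duration
groups. The packaged scenario designates the two children groups and leaves
adults at lifetime averaging; that specific split is the only reconstruction
under which the study's alternative whole-population figure (≈0.091 cases,
vs 0.053 under lifetime averaging) is recovered, and it is flagged here as a
reconstruction rather than a documented protocol.

## Censored values

Below-LOQ determinations (LOQ 1 ng/dm³, DDE 5 ng/dm³) are *retained as
reported* by default — the campaign reported sub-LOQ values to show that
compounds were detected at very low levels, and they barely move the risk.
`zero` and `half_loq` substitution policies are provided for sensitivity
runs; for fixed records, mean(zero) ≤ mean(half_loq), and the two differ by
exactly (n_censored/n)·LOQ/2.

## Synthetic campaigns

The generator draws one determination per (site, analyte, date) from a
log-normal parameterized by its arithmetic mean and coefficient of variation
(σ² = ln(1+cv²), μ = ln m − σ²/2), so the sample mean converges to the
target. Log-normal because concentrations are non-negative and right-skewed;
the campaign reports no distributional information, so cv is a free parameter
with default 0.3. cv = 0 degenerates to constants at the per-well study
means, which is how the full pipeline is verified end to end. Defaults: 10
dates at 14-day cadence (the campaign's sampling protocol is ambiguous
between weekly and two-weekly; both are parameters). Draws below the LOQ are
flagged with the value retained. Zero-mean cells are fixed at 0 without a
draw (a cv is unattainable there).

What the generator does *not* emulate: temporal autocorrelation, seasonal
trends (none were observed in the campaign), inter-analyte correlation, and
spatial transport. Passing tests therefore demonstrate correctness of the
deterministic pipeline and the generator's marginal distributions, not
robustness to structured real-world variability.

## Numerical choices

* Concentrations are converted ng→mg exactly once (×10⁻⁶); no intermediate
  rounding anywhere. Published intermediates are 4-significant-figure
  roundings, hence the 0.1–0.5% comparison tolerances in the tests.
* Site and cross-site means use compensated summation (`math.fsum`), making
  `summarize` exactly permutation-invariant.
* The linear risk form is capped at 1; `auto` model switches from linear to
  one-hit at dose·SF = 0.01. Cumulative risks warn (not error) above 1.
* Classification bins are half-open with inclusive lower bounds
  ([10⁻⁶, 10⁻⁴) is the acceptable range, etc.).
* ECC is a real-valued expectation; it is never rounded to whole cases.
* An empty monitoring file yields an empty (zero-dose) report, not an error;
  analytes missing an RfD (or slope factor) are dropped from HI (or ELCR)
  with a logged warning rather than failing the run.
* Problem sizes: the bundled study is desk-scale (17 analytes × 4 sites;
  the verification campaign uses 20 dates, 1,360 records), and the
  Monte-Carlo checks of the generator use 4,000–10,000 draws, which bounds
  the binomial/LLN error at well under the asserted tolerances.

## Known limitations

Ingestion pathway only (no inhalation/dermal); chronic RfDs are used for all
exposure durations because no subchronic values are registered; no
quantitative uncertainty propagation (the parameterization is conservative
by design); congener-specific toxic-equivalency weighting is out of scope —
the mixture slope factor carries all PCB carcinogenicity.
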