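# Methods

This note documents the statistical model behind `codewatch`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real EHR data.

## The measurement model

The unit of observation is the count `n[p, c, t]` of occurrences of clinical
code `c` recorded at practice `p` in calendar month `t`. Counts are
occurrences, not unique patients: repeat recordings on one patient all
count, and no deduplication is attempted (repeat coding is part of the
activity signal being monitored).

Rates are per 1000 registered patients,

    r[p, c, t] = 1000 * n[p, c, t] / L[p],

with `L[p]` the practice's list size at a fixed **index date** (the study
end). Using a fixed denominator means events of patients who died or
deregistered before the index date are missing, so observed activity
undercounts true activity by an amount that is largest at the start of the
window and vanishes at the index month. This is a deliberate fidelity choice
— the design being mirrored counts exactly this way — and the generator
emulates it (see below). A monthly-denominator mode is not provided; the
fixed denominator *is* the method.

The rate table is **dense**: every registry practice contributes an explicit
rate (possibly 0.0) for every measured subject and month. Zero-filling
matters: medians of 0.0 for heavily disrupted activities are only obtainable
if zero-activity practices are in the decile vector.

For each subject (code or group) and month, the cross-practice distribution
is summarised by deciles d10…d90 with median = d50. The quantile rule is
linear interpolation between order statistics (numpy's `"linear"` method) by
default; the rule is configurable, is recorded in the run manifest, and the
oracle tests pin the implementation to an independent sort-and-interpolate
formulation to 1e-12 relative error. Note that under this rule deciles are
not *exactly* invariant to duplicating the practice set — the interpolation
position shifts by less than one order statistic — so the corresponding
property test bounds the movement by the largest adjacent-order-statistic
gap rather than asserting equality.

Year-on-year change is computed on the median series,

    delta[t] = 100 * (m[t] - m[t-12]) / m[t-12],

which cancels any purely seasonal multiplicative structure. A zero baseline
makes the change **undefined** — it is carried as a flag, never emitted as 0
or infinity — whereas a positive baseline with a current median of zero is a
well-defined −100.0%. Changes are computed at full precision and rounded
only at the reporting boundary (1 decimal place, ties away from zero, ASCII
signs, explicit `+` for increases, e.g. `19.8 (-86.9%)`, `6.5 (+12.0%)`);
cells without a defined change render the median with a trailing `*`.

## Disruption/recovery taxonomy

The qualitative vocabulary of service disruption is operationalised with two
statistics per subject: the **nadir** (most negative defined change in the
disruption window) and the **terminal** change (at the final study month).
Default cut points, all configurable:

| category         | condition                              |
|------------------|----------------------------------------|
| maintained       | nadir > −20%                           |
| increase         | terminal > +10%                        |
| recovered        | terminal in (−10%, +10%]               |
| partial_recovery | terminal in (−30%, −10%]               |
| sustained_drop   | terminal ≤ −30%                        |

The cut points were fixed a priori to reproduce the qualitative reading of
published key-month patterns (a deep April drop with terminal −0.6% must be
"recovered"; a −56%/−42% pattern must be "sustained drop"); they are
reported alongside every classification. The classifier is monotone in the
terminal change for a fixed nadir.

## Terminology and grouping

CTV3-style codes are 5-character, case-sensitive strings arranged in an
acyclic parent–child forest (multiple top-level concepts allowed);
SNOMED-style codes are long numeric identifiers, inferred from the code
string (6+ digits). Three group definitions are supported and deliberately
kept distinct: **prefix** groups match on the literal code string (code
strings encode the hierarchy by prefix only approximately, and published
group definitions are stated as leading characters), **subtree** groups use
tree position, and **explicit** groups are curated lists. Group membership
is fully resolved at construction; overlap between groups is reported, never
silently resolved. Keyword search is case-insensitive substring match on
descriptions; code matching is always case-sensitive.

Frequency-based discovery keeps codes whose total occurrences across all
practices in the threshold year reach the threshold (default 1000; a total
of exactly 1000 is retained — the exclusion rule is "fewer than 1000").
Totals are over the threshold year only, not the whole window.
Medication/vaccination-style exclusions are expressed as code-prefix lists,
since record-type flags from source systems are not part of a generic event
table.

## The synthetic-data generator

The generator is the package's test bed and defines the study conditions:

* **Window and scale.** 24 months (Jan 2019 – Dec 2020), index date
  31 Dec 2020; default 2500 practices (the scale of a 40%-of-England
  deployment); list sizes log-normal with median 8000 patients
  (sdlog 0.5), a typical English practice list.
* **Code volumes.** Per-code baseline rates log-normal with median
  2 events/1000 patients/month and sdlog 1.5, giving the heavy-tailed
  volume distribution in which a few codes dominate — the regime the
  frequency filter is designed for.
* **Practice heterogeneity.** A multiplicative log-normal practice effect
  (sd 0.35 on the log scale), constant over time — the simplest mechanism
  producing a persistent between-practice decile spread. The true
  between-practice distribution in real data is not characterised; the
  log-normal is a modelling convenience.
* **Seasonality.** A single cosine with amplitude 0.10 peaking in January;
  richer seasonal shapes are out of scope because the year-on-year measure
  cancels them anyway.
* **Count noise.** Gamma–Poisson (NB2): var = μ + αμ² with dispersion
  α = 0.15 by default; α = 0 gives exact Poisson for tight tests. Monthly
  per-practice EHR counts are overdispersed; α is per-cell.
* **Disruption.** A multiplicative trajectory m(t): 1 before the disruption
  month, 1 − drop_fraction at it, then moving to a terminal level reached
  exactly `recovery_months` later (shapes: none / linear / exponential with
  time constant recovery_months/3, clamped / linear-plus-half-sine
  overshoot). The terminal level expresses sustained drops (< 1), full
  recovery (1) or increases (> 1). Newly introduced codes (expectation zero
  before an introduction month) are handled separately, since m(t) = 1
  pre-disruption by definition.
* **Attrition.** Binomial thinning with retention 1 − a(t), a(t) declining
  linearly from `attrition_fraction_start` (default 0.07) at the first
  study month to 0 at the index month. Only the aggregate early-period
  undercount is emulated, not its patient-level mechanism.

All stages draw from independent seeded streams; one config seed fixes the
entire dataset byte-for-byte.

**What passing tests show and do not show.** Parameter recovery on this
generator demonstrates that the measurement chain (counting → rates →
zero-filled deciles → year-on-year change → classification) is unbiased and
well-calibrated under multiplicative practice effects, NB2 noise and the
stated disruption family. It does not validate behaviour under features the
generator omits: secular trends, coding-behaviour changes, practice mergers
and closures, correlated noise across codes, demographic shifts, or
non-multiplicative disruption. Conclusions about real data rest on the
measurement conventions, not on these simulations.

## Parameter-recovery experiment

The decisive end-to-end check crosses drop fractions {0.30, 0.60, 0.87} with
terminal levels {0.6, 1.0, 1.2}, assigns the nine combinations round-robin
to 60 codes across 200 practices, and measures each combination's mean
(over its ~7 codes) drop-month and terminal year-on-year change per
replicate. The drop estimate is read **at the disruption month**, where the
injected drop is defined (for recovering trajectories this is also the
minimum; for terminal levels below the post-drop level the trajectory's true
minimum is the terminal value, so min-over-window would measure the terminal
level, not the drop). Success means both estimates within ±5 percentage
points of truth and the classifier returning the category implied by the
injected parameters; the acceptance suite requires ≥95% success per
combination over 100 replicates. Experiment conditions (base-rate median
30/1000/month so medians are well resolved, practice-effect sd 0.30,
dispersion 0.10, attrition off so the injected truth is not biased by the
undercount) were fixed when the experiment was designed. The problem size —
200 × 60 × 24 cells per replicate, 100 replicates — was chosen as the
smallest design that resolves a 5-point tolerance with comfortable margin.

## Numerical and engineering choices

* Months are calendar months (`YYYY-MM`); event dates are ISO-8601,
  truncated to month. Malformed dates and negative counts fail loudly with
  the row number; rows outside the study window are dropped with a logged
  tally.
* Practices appearing in counts but missing from the registry are an error
  (never silently dropped); list sizes below 1 are rejected — closed
  practices must be removed from the registry explicitly.
* Pipeline outputs are staged in a `.partial` directory and renamed into
  place on success; a failing stage quarantines the partial tree under
  `.failed-<stage>` and raises an error naming the stage.
* Charts are SVG with a fixed hash salt and no embedded date, so reruns are
  byte-identical; rendering is a pure view over the already-written CSVs.
* Small-number suppression is not applied anywhere; all cells are reported
  as computed.

## Known limitations

* Topic rules and group definitions are user configuration; the package
  ships the mechanism (prefix/keyword/explicit rules, overlap reporting),
  not curated clinical code lists, which are licensing-restricted and
  context-specific.
* The classifier summarises a series by two numbers; double-dip or
  late-collapse trajectories can be mislabelled and should be read together
  with the decile charts.
* No interrupted-time-series regression, seasonal decomposition or
  significance testing is provided — the measures are deliberately
  descriptive.
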