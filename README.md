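# codewatch

Practice-level surveillance of coded clinical activity in primary-care
electronic health records.

When routine general-practice services are disrupted — as they were at the
onset of the COVID-19 pandemic — the disruption and the subsequent recovery
are visible in the volume of clinical codes recorded in the EHR: blood
pressure checks, HbA1c tests, cervical smears, medication reviews, and so on.
`codewatch` implements the observatory-style analysis of such data as a
reusable, tested pipeline:

1. **Counting.** Occurrences of every clinical code per general practice per
   calendar month are tallied from a long-format event table (repeat
   recordings count as occurrences, not unique patients), and converted to a
   monthly rate per 1000 registered patients using each practice's list size
   at a fixed index date.
2. **Discovery.** High-volume codes are selected data-driven: any code with
   fewer than a threshold number of total occurrences in a reference year
   (default 1000) is excluded; survivors are organised into broad clinical
   topics by prefix, description-keyword and explicit-list rules.
3. **Grouping.** Related codes are rolled together using the coding
   dictionary: CTV3-style 5-character codes form a parent–child forest, and
   groups can be defined by code-string prefix (e.g. all codes beginning
   `61`), by subtree, or by explicit list.
4. **Measures.** For each code/group and month, the median and deciles
   (d10…d90) of the rate across practices; the year-on-year change of the
   median series, Δ<sub>t</sub> = 100·(m<sub>t</sub> − m<sub>t−12</sub>)/m<sub>t−12</sub>,
   which cancels seasonality by construction; key-month summary tables
   rendered as `median (±change%)`; and a disruption/recovery taxonomy
   (maintained / recovered / partial recovery / sustained drop / increase)
   driven by the nadir and terminal changes.
5. **Reporting.** Decile charts (median solid, other deciles dashed),
   total-count series for newly introduced codes, and a CLI pipeline with a
   run manifest; all CSV and SVG outputs are byte-reproducible from one
   config and seed.

Because patient-level EHR event tables cannot be redistributed, the package
ships a first-class synthetic-data generator with known ground truth
(heterogeneous practice list sizes, heavy-tailed code volumes, persistent
practice effects, seasonality, overdispersed counts, an injectable
April-2020-style disruption with configurable recovery, and the early-month
undercount caused by fixing the denominator population at the study end
date). Every downstream stage is validated by parameter recovery against
this generator.

## Worked example

Inject an 87% April-2020 drop with linear recovery to baseline by December,
then read it back through the measures:

```python
from codewatch import (
    SyntheticConfig, DisruptionProfile, generate_dataset,
    count_events, compute_rates, median_series, pct_change_yoy,
    classify_recovery, format_cell,
)

cfg = SyntheticConfig(n_practices=200, n_codes=12, seed=1)
profile = DisruptionProfile(disruption_month="2020-04", drop_fraction=0.87,
                            recovery_shape="linear", recovery_months=8,
                            terminal_level=1.0)
ds = generate_dataset(cfg, profile)

counts = count_events(ds.counts, ("2019-01", "2020-12"))
rates = compute_rates(counts, ds.practices)          # per 1000 patients
code = ds.base_rates.idxmax()                        # busiest synthetic code
series = median_series(rates, code)                  # median across practices
changes = pct_change_yoy(series, code)
for month in ("2020-02", "2020-04", "2020-12"):
    cp = next(c for c in changes if str(c.month) == month)
    print(month, format_cell(cp.median_rate, cp.pct_change))
print(classify_recovery(changes, disruption_start="2020-04").category)
```

prints

```
2020-02 44.2 (+5.4%)
2020-04 5.2 (-86.6%)
2020-12 44.5 (+3.2%)
recovered
```

The April cell reads "median rate 5.2 per 1000 patients, down 86.6% on April
2019" — the injected 87% drop recovered from the data — and by December the
median is back at baseline, so the classifier reports `recovered`. The small
positive drift in the other months is real, not noise: the default generator
emulates the undercount produced by a fixed index-date denominator (2019
months are thinned by up to 7%), which slightly inflates year-on-year
changes, exactly as it does in the real data this design mirrors.

The full pipeline runs from a YAML config:

```bash
codewatch run --config examples/demo.yaml --out results/demo
```

writing `selection.csv`, `measures.csv` (deciles per subject-month),
`changes.csv`, `key_months.csv`, `recovery.csv`, decile/total charts and a
`manifest.json` tying the outputs to the config hash and seed.

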