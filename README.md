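# sleepagree

Agreement analysis between morning sleep-diary responses (chatbot-style,
5-minute button grid) and wearable per-night sleep records, built as a
reusable, tested pipeline:

- **core_time** — wrap-aware clock arithmetic: parsing 24-h / 12-h / button
  dialects, elapsed time across midnight, and anchored (circular) means of
  times of day using a noon-to-noon window.
- **records_io** — CSV/JSON readers and writers for device sleep records,
  diary entries, sleep-quality survey records and participant profiles, with
  per-row reject lists (nothing is silently dropped).
- **synthetic_cohort** — a seeded generator that renders per-night ground
  truth as device + diary + survey files, with configurable self-report
  biases, :00/:30 heaping, AM/PM and ordering input errors, missing days,
  and a truth ledger for recovery testing.
- **qc_match** — per-(participant, date) matching of main sleeps to diary
  entries, order and >9 h clock-difference exclusions, a first-14-days cap,
  a ≥7-valid-nights inclusion rule, and wear/latency compliance buckets.
- **derive_agreement** — per-night variables (TST, AST, span − awake time),
  participant means, Bland–Altman statistics (mean ± 1.96 SD limits of
  agreement, paired t), and stratified agreement by survey group, gender,
  age decade, BMI class and nightly sleep quality.
- **descriptives** — minute-of-hour heaping histograms and
  within-±threshold coverage statistics under none / global-mean /
  per-quality-stratum bias corrections.
- **cli_report** — config-driven orchestration producing a report bundle of
  delimited-text tables plus a JSON manifest.

## CLI

```sh
# generate a synthetic cohort (CSV files + truth ledger)
sleepagree simulate --out data/ --seed 1 --n-participants 50 --nights 14

# run the full pipeline from a YAML config
sleepagree run --config config.yaml

# re-render agreement/coverage tables from a saved derived store
sleepagree report --derived out/nights.csv --out rerender/
```

A minimal config for a simulated run:

```yaml
output_dir: out
seed: 1
simulate:
  n_participants: 50
  nights_per_participant: 14
min_days: 7          # inclusion rule
cap_days: 14         # first-N-device-days cap
max_clock_diff_hours: 9
coverage_thresholds: [30, 60]
```

To run on real files instead, replace `simulate:` with `fitbit_path`,
`chat_path`, `psqi_path` and `profiles_path`. The cohort-calibrated
generator defaults ship in `src/sleepagree/configs/paper_calibrated.yaml`
and can be passed to `simulate --params`.

The report bundle contains `exclusions.csv`, `compliance_days.csv`,
`compliance_latency.csv`, `demographics.csv`, `rounding.csv`,
`minute_histogram_*.csv`, `agreement_overall.csv`, `agreement_strata.csv`,
`coverage.csv`, `nights.csv`, `bland_altman_*.csv` and `manifest.json`
(config echo, seed, per-stage counts).

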