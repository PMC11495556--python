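# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports.

`faersig` implements a complete post-marketing safety screen for one target
drug: ingestion of the quarterly `$`-delimited ASCII tables
(DEMO/DRUG/REAC/THER/OUTC), case deduplication, primary-suspect drug
filtering, PT/SOC standardization against a user-supplied PT→SOC map,
descriptive clinical characteristics, four-algorithm disproportionality
screening (ROR with Wald CI, PRR with Pearson χ², simplified BCPNN
information component with a moment-approximation credibility bound, and
the simplified EBGM observed/expected ratio), unexpected-signal flagging
against a label PT list, and time-to-onset analysis. A vectorized synthetic
generator with planted reporting-rate ratios, duplicates, missingness and a
log-normal onset model makes the whole chain testable offline.

## Command-line usage

The pipeline is driven by one YAML config naming either the five input
tables or a synthetic-generation block:

```yaml
target_names: [RELUGOLIX, ORGOVYX]
synthetic:            # or: inputs: {demo: ..., drug: ..., reac: ..., ther: ..., outc: ...}
  n_reports: 50000    #     plus meddra_map: path/to/pt_soc.csv
  planted: {PT0170: 10.0}
level: both           # pt | soc | both
unit: drug_event_pair # or report
zero_cell: undefined  # or haldane
seed: 1
```

```sh
faersig all --config config.yaml --out results/run1
faersig generate --config gen.yaml --seed 3 --out synth/
```

Flags `--drug-name` (repeatable), `--level`, `--unit`, `--zero-cell`,
`--label-pts FILE`, `--exclude FILE` and `--seed` override the config.
Outputs are CSVs (characteristics, SOC/PT signal tables, unexpected
signals, time-to-onset summary and per-case audit) plus `manifest.json`
recording input checksums, per-stage counts and the config snapshot.
Exit codes: 0 success, 2 config error, 3 data error.

## Library sketch

```python
from faersig import SyntheticConfig, generate_dataset, screen_signals, Level
from faersig.preprocess import assemble_case_table

cfg = SyntheticConfig(n_reports=100_000, planted={"PT0170": 10.0}, seed=7)
bundle, truth = generate_dataset(cfg)
cases, flow = assemble_case_table(bundle, cfg.target_names, truth.meddra_map())
signals = screen_signals(cases, level=Level.PT)
print(signals[signals.significant].head())
```

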