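# Deposited field data (not distributed here)

This directory is the expected location for the field study's deposited
data files, which are **not redistributed** with this package.  To
reproduce the published network and summary tables, export the deposited
spreadsheets to CSV and place them here as:

- `network_low.csv`, `network_intermediate.csv`, `network_high.csv` —
  one tortoise-by-oxyurid count matrix per habitat-loss level, first
  column = species names, header row = tortoise ids (use
  `transposed=True` in the loader if the export has hosts as rows);
- `traits.csv` — the tortoise trait table with columns
  `host_id, habitat, stage, sex, age_years, weight_g, carapace_mm`
  plus optional `count:<species>` infestation columns.

The tests and analyses that require these files fail with a clear
message when they are absent; everything else in the package runs on
synthetic data generated at test time.
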