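# mircircuit

Tools for designing and evaluating miRNA-input cell-state classifier
circuits:

- **expression_data** — read, merge (by mature sequence, hairpins removed),
  replicate-average, and binarize multi-source miRNA expression matrices.
- **circuit_model** — closed-form steady state of the four-step bow-tie
  cascade (miRNA ⊣ Act1 → FF4 ⊣ Act2 → Out), On/Off ratios, single-parameter
  and combinatorial (Act1MAX × Act2MAX) screens, miSFIT output attenuation.
- **classifier_search** — exhaustive enumeration of circuit topologies
  (miR_high OR-gate + miR_low sensors) under input-count constraints,
  scored by classification margin (cMargin, log10 scale), ROC AUC and truth
  calls, with optional bootstrap pruning of non-contributing inputs.
- **cytometry** — 99.9th-percentile gating against negative controls,
  reporter signal in relative (rel.U.) and absolute units, viability.
- **colony_metrics** — annular radial intensity profiles of micropatterned
  colonies, peak normalization, baseline-subtracted area under the profile,
  marker-positive composition fractions.
- **synthetic_data** — seeded generators for all inputs (expression
  matrices with planted markers, cytometry event tables, colony point
  clouds) with ground-truth manifests.

## CLI

```
mircircuit merge --matrix wide.csv --sequences seqs.csv --samples sheet.csv --out merged
mircircuit binarize --matrix merged.csv --t 0.01 --out ratios.csv
mircircuit simulate --mir-high 3000
mircircuit screen --param FF4MAX --grid 30,300,3000,30000 --out screen.csv
mircircuit combiscreen --act1 30000,10000,3333 --act2 30000,10000,3333 --out combi.csv
mircircuit search --matrix merged.csv --max-inputs 3 --max-per-gate 2 --out results
mircircuit cytometry --sample events.csv --control reporter=ctrl.csv \
    --control marker=ctrl.csv --reporter reporter --marker marker --out metrics.csv
mircircuit colony --cells cells.csv --colonies colonies.csv \
    --markers Sox2,Sox17,TBXT --bins 20 --out colony
mircircuit fixtures expression|cytometry|colony --seed 1 --out dir/
```

Input formats: the merge step takes a wide matrix CSV (rows = miRNAs,
columns = samples), a sequence table CSV (`name,sequence,is_hairpin`) and a
sample sheet CSV (`sample,label,cell_state,replicate_group,dataset`).
Model parameters default to the optimized published set and can be
overridden with a JSON/YAML file (`--params`).

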