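# nmregen

Lineage tracing, clonal analysis and machine-learning fate prediction for
regenerating zebrafish neuromasts.

Neuromasts — the mechanosensory organs of the fish lateral line — are
circular epithelia of ~60–70 cells in three classes: central postmitotic
hair cells (H), tri-potent sustentacular supporting cells (S) around and
between them, and mantle cells (M) forming the outer rim.  After severe
laser ablation, as few as 4–10 surviving founder cells rebuild the whole
organ.  Long-term videomicroscopy (one volume every 15 min for 65–100 h,
starting 4 h post injury) with manual single-cell tracking yields *track
tables*: one row per cell per frame, with heap-encoded lineage identities
(the daughters of cell *n* are 2*n* and 2*n*+1).

`nmregen` turns such track tables into quantitative regeneration
analyses, for researchers studying organ regeneration and collective
cell-fate control:

- **track_io** — a documented CSV dialect for tracks plus per-experiment
  manifests (YAML/JSON), with validation of lineage, timing and
  cell-class-transition invariants (hair cells are terminal).
- **lineage** — heap-encoded lineage forests: divisions, generations,
  cycle lengths, Newick export.
- **clone_analysis** — clone typing (S/SM/SH/SHM/M), division
  categorization by daughter fates (SS/HH/MM/SM), cell-count timecourses.
- **spatial** — organ-centered coordinates, compass quadrants, progeny
  laterality, division-location maps.
- **kinetics** — division-wave detection and continuous two-segment
  (broken-stick) change-point regression of cycle length against time or
  organ size, by exhaustive deterministic search.
- **features** — the 32 spatial/movement/neighborhood predictors of a
  cell at a timepoint.
- **fate_prediction** — bagged random forests with round-robin
  leave-one-experiment-out validation, entity-level majority vote,
  Matthews correlation (MCC) with a 15×15 experiment-level bootstrap, and
  permutation feature importance.
- **synthetic_data** — an agent-based simulator of neuromast regeneration
  calibrated to the tracked statistics (founder divisions ~19 ± 6 hpi,
  cycles ~11 ± 3 h lengthening past 47 hpi, fate marginals
  SS/HH/MM/SM = 78/16/3/3% with central hair and peripheral mantle
  production), emitting valid track tables plus ground truth.

The central statistic is the Matthews correlation coefficient of a binary
fate choice,

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)) ∈ [−1, 1],

scored on held-out experiments so that imbalanced fate frequencies (78%
of divisions are self-renewing) cannot inflate the apparent accuracy.

## Worked example

Simulate a small cohort, reconstruct lineages, and ask whether the choice
between hair-producing (HH) and mantle-producing (SM/MM) divisions is
predictable from a cell's spatial context:

```python
from nmregen import synthetic_data as sd
from nmregen.lineage import build_forest
from nmregen.spatial import center_tracks
from nmregen.clone_analysis import division_summary
from nmregen.features import build_feature_table
from nmregen.fate_prediction import TASKS, ForestConfig, round_robin_evaluate

cohort = sd.generate_cohort(sd.SimulationConfig(seed=1))        # 15 recordings
forests = [build_forest(center_tracks(e.table)) for e in cohort]

print(division_summary(forests).to_string(index=False))

table = build_feature_table(forests, "division")
report = round_robin_evaluate(table, TASKS["HH-vs-SMMM"], ForestConfig(seed=0))
print(f"HH vs SM/MM: MCC = {report.mcc_boot_mean:.2f} ± {report.mcc_boot_sd:.2f}, "
      f"{report.n_correct}/{report.n_entities} divisions correct")
print("top features:", list(report.importances.index[:3]))
```

Output (seed 1):

```
parent_class category  count  fraction
           M       MM     26  1.000000
           S       HH     78  0.152941
           S       MM     15  0.029412
           S       SM     11  0.021569
           S       SS    406  0.796078
HH vs SM/MM: MCC = 0.95 ± 0.03, 102/104 divisions correct
top features: ['absolute_time_hpi', 'number_of_m_cells', 'normalized_distance_to_center']
```

All 26 mantle-cell divisions are self-renewing, ~80% of sustentacular
divisions self-renew, ~15% make hair-cell pairs; and the hair-versus-
mantle fate of a dividing sustentacular cell is almost perfectly
predictable (MCC ≈ 0.95) from when and where it divides — hair fates
central and late, mantle fates peripheral — while the same features
separate self-renewing from differentiating divisions far less well.

The same analyses are scriptable from the shell:

```sh
nmregen simulate --seed 1 -o cohort/
nmregen validate cohort/s1e01_tracks.csv --manifest cohort/s1e01_manifest.yaml
nmregen clones   cohort/*_tracks.csv --manifest cohort/s1e01_manifest.yaml ... 
nmregen kinetics cohort/*_tracks.csv --manifest ... --changepoint time
nmregen features cohort/*_tracks.csv --manifest ... --task divisions -o feat.csv
nmregen predict  feat.csv --task HH-vs-SMMM --seed 7 -o report.json
```

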