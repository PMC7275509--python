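# End-to-end winter pipeline on simulated tracks:
#   movestates simulate  --config examples/winter_pipeline.yaml
#   movestates preprocess --config examples/winter_pipeline.yaml
#   movestates fit        --config examples/winter_pipeline.yaml   (or: select)
#   movestates decode     --config examples/winter_pipeline.yaml
#   movestates summarise  --config examples/winter_pipeline.yaml
seed: 1
paths:
  tracks: out/tracks.csv
  out_dir: out
preprocessing:
  max_gap_hours: 10
  min_weeks: 1          # simulated example tracks are short; field data: 4
  snow_threshold: 0.0
covariates:
  hour: {kind: cyclic, period: 24}
  snow_depth: {kind: continuous}
model:
  n_states: 3
  n_starts: 10
simulation:
  season: winter
  n_animals: 2
  n_hours: 1200
  gap_start_prob: 0.005
  gap_mean_length: 3
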