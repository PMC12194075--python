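# 83-cell detached endodermal plate; switch mode/interval for the
# center-first and edge-first time series.
scene:
  builder: detached_plate
  n_cells: 83
  subdivision_level: 3
params:
  seed: 1
events:
  - {type: constrict, mode: simultaneous, region: [0, 50], f_c: 0.1, start: 50, ramp: 50}
end_time: 800
output: {record_every: 100, snapshot_every: 2000, snapshot_format: obj}
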