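# Detached endodermal plate, simultaneous apical constriction.
scene:
  builder: detached_plate
  n_cells: 19
params:
  seed: 1
events:
  - type: constrict
    mode: simultaneous
    region: [0, 50]
    f_c: 0.1
    start: 20
    ramp: 50
end_time: 150
output:
  record_every: 200
  snapshot_every: 1000
  snapshot_format: obj
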