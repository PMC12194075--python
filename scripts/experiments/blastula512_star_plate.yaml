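# 512-cell blastula with a five-lobed star endodermal plate.
scene:
  builder: blastula
  n_cells: 512
  subdivision_level: 3
  plate: {kind: star, size: 1.1}
params:
  seed: 1
events:
  - {type: constrict, mode: simultaneous, region: [0, 50], f_c: 0.1, start: 50, ramp: 50}
end_time: 600
output: {record_every: 100, snapshot_every: 2000, snapshot_format: vtk}
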