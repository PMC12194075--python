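# 256-cell blastula, three stiffness zones, f_c = 0.05.
scene:
  builder: blastula
  n_cells: 256
  subdivision_level: 3
  plate: {kind: cap, size: 0.96}
params:
  seed: 1
events:
  - {type: stiffness, cells: endoderm, region: [0, 30],  k: 1.0, start: 0, ramp: 0}
  - {type: stiffness, cells: endoderm, region: [70, 100], k: 0.1, start: 0, ramp: 0}
  - {type: stiffness, cells: ectoderm, region: [0, 30],  k: 1.0, start: 0, ramp: 0}
  - {type: stiffness, cells: ectoderm, region: [70, 100], k: 0.1, start: 0, ramp: 0}
  - {type: constrict, mode: simultaneous, region: [0, 50], f_c: 0.05, start: 50, ramp: 50}
end_time: 600
output: {record_every: 100, snapshot_every: 2000, snapshot_format: vtk}
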