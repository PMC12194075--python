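# blastosim

A 3D deformable-cell vertex model of epithelial sheet bending, built to
simulate gastrulation by invagination in early (diploblastic) embryos —
the stage where a hollow blastula folds part of its wall (the
endodermal plate) into the interior to form a two-layered gastrula.

Each cell is an individually deformable closed triangle mesh: vertices
are point masses, edges are strain-stiffening springs
(F = −(k/l0)x² − kx, x = l − l0), and the enclosed volume V is
conserved by a pressure-like force of magnitude k_v·|V − V0|/V0.
Cortical strain keeps the surface taut (l0 = f_et·l_rest); apical
constriction shrinks the rest lengths of a surface band by a factor
f_c on a linear ramp.  Cells interact through stochastic constant-force
adhesion bonds between adhesive surface bands and through
vertex–triangle collision handling (restoring forces proportional to
penetration depth on the intruding vertex and the violated face's
corners).  Positions advance by damped Verlet,
x_{n+1} = (2−c)x_n − (1−c)x_{n−1} + aΔt², and an AABB broad phase
keeps the pairwise work linear in cell count.

Scene builders assemble the standard experiments: a single free cell, a
detached endodermal plate (hex disc), a planar ring of 3D cells between
two plates (a blastula cross-section), and hollow blastulas of 32–1024
typed cells with selectable plate shapes (cap, rectangle, triangle, T,
star) and constriction modes (simultaneous, center-first, edge-first
ring schedules).  See `docs/methods.md` for the model details and
defaults.

## Worked example

Constrict the apical hemispheres of all cells of a small detached
plate and watch the plate curl:

```python
import blastosim as bs
from blastosim import scenes, measure

scene = scenes.build_detached_plate(n_cells=19, seed=1)
scene.events.extend(scenes.constriction_schedule(
    scene.meta["rings"], scenes.ConstrictionMode("simultaneous"),
    f_c=0.1, start=20.0))
rec = measure.MeasurementRecorder()
scene.run(150.0, recorder=rec, record_every=200)
df = rec.frame()
print(df[["t", "bonds", "max_volume_err", "invagination_depth"]].round(4))
```

prints (seed 1):

```
        t  bonds  max_volume_err  invagination_depth
0    10.0    500          0.0057              0.0001
1    20.0    536          0.0060             -0.0012
...
6    70.0    320          0.0148              0.0033
...
12  130.0    236          0.0163              0.0121
13  140.0    236          0.0163              0.0211
14  150.0    236          0.0164              0.0315
```

`bonds` is the number of adhesion links holding the plate together —
it saturates during equilibration, then drops as constriction shrinks
the apical bands and over-stretched bonds release.  `max_volume_err`
is the worst relative volume deviation over all 19 cells (volume stays
conserved to ~1.5% while the apical surfaces shrink), and
`invagination_depth` is the inward displacement of the plate-center
cell in the scene frame — it starts growing once constriction
(start = 20, ramp 50) bends the plate.

The same experiment as a script, via the CLI:

```sh
blastosim validate examples/plate19.yaml
blastosim run examples/plate19.yaml --out runs/plate19 --seed 1
blastosim measure runs/plate19 --out runs/plate19/metrics.csv
```

which writes a measurement CSV, OBJ/VTK snapshots with per-vertex cell
type and region scalars, bond CSVs, restart state JSONs and a manifest
echoing every resolved parameter.  Full-size experiment scripts
(256–1024-cell blastulas, plate-shape and stiffness variants) live in
`scripts/experiments/`.

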