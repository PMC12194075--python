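# Full-size experiment scripts

These scripts reproduce the full-scale invagination experiments with
level-3 (642-vertex) cells and 256–512-cell blastulas.  They are
provided for exploration — each takes hours on one core — and are not
asserted by the test suite.  Expected qualitative outcomes, from the
desk-scale behaviour of the same schedules:

* `blastula256_simultaneous.yaml` — all endodermal cells constrict at
  once: the plate edge moves inward first while the plate center
  bulges outward, then the plate flattens and invaginates; the final
  gastrula is bowl-like with a wide blastoporal opening.
* `blastula256_center_first.yaml` — ring constriction from the plate
  center (interval 100): an early dip at the plate center that widens
  into a concave plate from the start of invagination.
* `blastula256_edge_first.yaml` — ring constriction from the plate
  edge: a pronounced outward bulge of the plate center before the
  plate finally folds in.
* `blastula256_nonuniform_stiffness.yaml` — apical 0–30% k = 1,
  lateral 30–70% k = 0.5, basal 70–100% k = 0.1 with f_c = 0.05:
  longer, bottle-like endodermal cells and a flatter outer surface.
* `blastula512_star_plate.yaml` — a five-lobed star-shaped endodermal
  plate: the plate still invaginates; the star arms fold naturally and
  reduce the blastoporal opening.
* `plate83_modes.yaml` — the 83-cell detached plate (simultaneous
  mode; switch `mode:` to `center_first` / `edge_first` and
  `interval:` to 100 or 500 to reproduce the other time series): edge
  curling, center dips or center bulges depending on the mode, ending
  in a closed oval shape.

Run with:

```sh
blastosim run scripts/experiments/blastula256_simultaneous.yaml \
    --out runs/b256_sim --seed 1
```
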