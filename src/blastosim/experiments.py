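"""Canonical desk-scale experiments.

Standard study conditions used by the test-suite and the result
reproduction script: a single constricting cell, free-cell relaxation,
detached-plate elongation, constriction-mode plate signatures, and the
planar-ring invagination.  Each function builds its scene from scratch,
runs it, and returns plain measured quantities.  All randomness derives
from the ``seed`` argument.

Sizes and run lengths are the package's desk-scale choices: level-2
cells for multi-cell scenes (level 3 for the single-cell volume run),
19-cell plates for elongation, 37-cell plates for mode signatures, a
32-cell planar ring, and runs of a few hundred time units — long
enough for the overdamped dynamics to reach effectively static shapes.
"""

from __future__ import annotations

import numpy as np

from . import measure
from . import scenes
from .mechanics import ConstrictionEvent
from .mesh import RegionSpec, sphericity

__all__ = [
    "single_cell_volume_run",
    "free_cell_sphericity",
    "single_cell_elongation",
    "plate_center_elongation",
    "mode_signature_run",
    "planar_invagination_run",
]

# the single-cell demonstration constricts the whole apical hemisphere;
# plate experiments constrict the apical cap proper (0-30%), which keeps
# cells packed side by side instead of folding their upper half away
APICAL_BAND = RegionSpec(0.0, 50.0)
PLATE_BAND = RegionSpec(0.0, 30.0)
# plate packing: tight spacing and firm contacts so neighbours confine
# each other laterally, plus a bond force that keeps the sheet cohesive
PLATE_SPACING = 1.95
PLATE_K_COL = 10.0
PLATE_ADHESION_PULL = 0.5
RING_ADHESION_PULL = 2.0


def single_cell_volume_run(seed: int, f_c: float = 0.1, level: int = 3,
                           end_time: float = 150.0):
    """Constrict a free cell's apical hemisphere; track volume deviation.

    Returns ``(max_rel_volume_err, n_records)`` over every recorded
    step of the run (records every 20 steps).
    """
    ev = ConstrictionEvent(cells=(0,), region=APICAL_BAND, f_c=f_c,
                           start=20.0, ramp=50.0)
    scene = scenes.build_single_cell(subdivision_level=level, events=[ev],
                                    seed=seed)
    errs = []

    def recorder(s):
        errs.append(abs(s.volumes()[0] / s.V0[0] - 1.0))
        return {}

    scene.run(end_time, recorder=recorder, record_every=20)
    return float(max(errs)), len(errs)


def free_cell_sphericity(seed: int, steps: int = 10_000, level: int = 2):
    """Relax a free cell with uniform strain and stiffness; return its
    sphericity (1 for a perfect sphere)."""
    scene = scenes.build_single_cell(subdivision_level=level, seed=seed)
    scene.run(steps * scene.integrator.dt)
    return float(sphericity(scene.cells[0]))


def single_cell_elongation(seed: int, f_c: float = 0.1,
                           end_time: float = 400.0) -> float:
    """Steady-state elongation of a detached constricting cell."""
    ev = ConstrictionEvent(cells=(0,), region=PLATE_BAND, f_c=f_c,
                           start=20.0, ramp=50.0)
    scene = scenes.build_single_cell(events=[ev], seed=seed)
    scene.run(end_time)
    return measure.cell_elongation(scene.cells[0])


def _plate_scene(n_cells: int, seed: int, f_c: float, mode: str = "simultaneous",
                 interval: float = 100.0, start: float = 20.0,
                 band: RegionSpec = PLATE_BAND):
    scene = scenes.build_detached_plate(n_cells, seed=seed,
                                        spacing_factor=PLATE_SPACING,
                                        k_col=PLATE_K_COL)
    for p in scene.adhesion_params:
        p.k_adh = PLATE_ADHESION_PULL
    scene.events.extend(scenes.constriction_schedule(
        scene.meta["rings"], scenes.ConstrictionMode(mode, interval),
        f_c, start=start, region=band))
    return scene


def plate_center_elongation(seed: int, f_c: float = 0.1, n_cells: int = 19,
                            end_time: float = 400.0) -> float:
    """Steady-state elongation of the center cell of a constricting
    hex plate (all cells constrict simultaneously)."""
    scene = _plate_scene(n_cells, seed, f_c)
    scene.run(end_time)
    center = scene.meta["rings"][0][0]
    return measure.cell_elongation(scene.cells[center])


def mode_signature_run(mode: str, seed: int, n_cells: int = 37,
                       interval: float = 100.0, start: float = 20.0,
                       end_time: float = 220.0, record_every: int = 40):
    """Run a plate under one constriction mode; return ring displacement
    curves.

    Returns ``(times, inward)`` where ``inward[r][k]`` is ring r's mean
    displacement against the apical axis (positive = away from the
    apical side, i.e. a dip) at record k, measured in the scene frame.
    """
    scene = _plate_scene(n_cells, seed, 0.1, mode=mode, interval=interval,
                         start=start)
    rings = scene.meta["rings"]
    axis = np.asarray(scene.meta["oral_axis"], float)
    times, curves = [], [[] for _ in rings]

    def recorder(s):
        disp = np.stack([s.center_displacement(i) for i in range(len(s.cells))])
        disp = disp - disp.mean(axis=0)
        times.append(s.t)
        for r, ring in enumerate(rings):
            idx = [s.id_to_index[c] for c in ring]
            curves[r].append(float(-(disp[idx] @ axis).mean()))
        return {}

    scene.run(end_time, recorder=recorder, record_every=record_every)
    return np.array(times), [np.array(c) for c in curves]


def planar_invagination_run(seed: int, n_cells: int = 32, n_endoderm: int = 8,
                            start: float = 50.0, end_time: float = 800.0):
    """Planar-ring invagination: constrict the endodermal arc's apical
    band and measure how deep it folds inward.

    Returns a dict with the invagination depth (model length units,
    positive = inward), the cell radius, and the distance between the
    two ends of the endodermal arc at the start and the end of the run
    (the "mouth" of the fold).
    """
    scene = scenes.build_planar_scene(n_cells=n_cells, n_endoderm=n_endoderm,
                                      seed=seed, spacing_factor=PLATE_SPACING,
                                      k_col=PLATE_K_COL)
    # in the single-cell-thick ring the apical contraction is carried by
    # just two lateral neighbours per cell, so the bond pull is set
    # stronger than in the sheet experiments
    for p in scene.adhesion_params:
        p.k_adh = RING_ADHESION_PULL
    endo = scene.meta["plate_cells"]
    scene.events.append(ConstrictionEvent(
        cells=tuple(endo), region=APICAL_BAND, f_c=0.1, start=start, ramp=50.0))

    # the two arc-end cells (extreme azimuth within the contiguous arc)
    centers = scene.cell_centers()
    ang = np.arctan2(centers[endo, 1], centers[endo, 0])
    ends = [endo[int(np.argmin(ang))], endo[int(np.argmax(ang))]]
    mouth0 = float(np.linalg.norm(
        centers[scene.id_to_index[ends[0]]] - centers[scene.id_to_index[ends[1]]]))

    scene.run(end_time)
    depth = measure.invagination_depth(scene)
    centers = scene.cell_centers()
    mouth1 = float(np.linalg.norm(
        centers[scene.id_to_index[ends[0]]] - centers[scene.id_to_index[ends[1]]]))
    return {
        "depth": float(depth),
        "cell_radius": float(scene.meta["cell_radius"]),
        "mouth_start": mouth0,
        "mouth_end": mouth1,
    }
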