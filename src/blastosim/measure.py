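"""Shape metrics and measurement streams.

All metrics are purely geometric functions of the current vertex
positions, invariant under rigid motions of the scene (scene-level
metrics are evaluated in the scene frame, i.e. relative to the mean
cell center).  Lengths are model length units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mesh import CellMesh, RegionSpec, surface_area
from .dynamics import Scene

__all__ = [
    "cell_elongation",
    "cell_height_width",
    "apical_extents",
    "rim_diameter",
    "opening_diameter",
    "invagination_depth",
    "MeasurementRecorder",
]


def cell_height_width(cell: CellMesh):
    """Apico-basal extent and maximal lateral extent of one cell.

    Height is the vertex-position range projected on the apical axis;
    width is twice the largest distance from the axis through the
    centroid.
    """
    axis = cell.apical_axis
    rel = cell.positions - cell.center()
    proj = rel @ axis
    perp = rel - proj[:, None] * axis
    height = float(proj.max() - proj.min())
    width = float(2.0 * np.linalg.norm(perp, axis=1).max())
    return height, width


def cell_elongation(cell: CellMesh) -> float:
    """Height / width ratio; 1 for an undeformed sphere, > 1 when columnar."""
    h, w = cell_height_width(cell)
    return h / w


def apical_extents(
    cell: CellMesh,
    vertical,
    horizontal,
    band: RegionSpec = RegionSpec(0.0, 20.0),
):
    """Extent of the apical-band vertex set along two tangent directions.

    ``vertical`` and ``horizontal`` are the plate-frame tangent unit
    vectors at the cell.  Returns ``(vertical_length,
    horizontal_length)``; an empty apical band is rejected.
    """
    mask = (cell.band >= band.band_start_pct) & (cell.band <= band.band_end_pct)
    if not np.any(mask):
        raise ValueError("apical band selects no vertices")
    pts = cell.positions[mask]
    v = np.asarray(vertical, float)
    h = np.asarray(horizontal, float)
    pv = pts @ (v / np.linalg.norm(v))
    ph = pts @ (h / np.linalg.norm(h))
    return float(pv.max() - pv.min()), float(ph.max() - ph.min())


def rim_diameter(positions: np.ndarray, axis, centroid=None, n_bins: int = 24):
    """Diameter of the opening rim of a cup-like point set.

    Operational rim rule: work in the frame of ``centroid`` (default:
    the mean position); in each of ``n_bins`` azimuth bins around
    ``axis`` the rim candidate is the point with the greatest height
    along the axis, and the rim radius is the mean distance of those
    candidates from the axis.  If the surface covers the pole on the
    axis side (some point lies close to the axis at near-maximal
    height) the shape is closed and the opening is reported as 0.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    pos = np.asarray(positions, float)
    if centroid is None:
        centroid = pos.mean(axis=0)
    rel = pos - centroid
    h = rel @ axis
    perp = rel - h[:, None] * axis
    rho = np.linalg.norm(perp, axis=1)
    h_max = h.max()
    rho_scale = rho.max()
    # closed-pole check: points sitting on the axis near the top
    near_axis = rho < 0.15 * rho_scale
    if np.any(near_axis & (h > 0.75 * h_max)):
        return 0.0
    phi = np.arctan2(perp @ _tangent(axis, 1), perp @ _tangent(axis, 0))
    bins = np.floor((phi + np.pi) / (2 * np.pi) * n_bins).astype(int).clip(0, n_bins - 1)
    radii = []
    for b in range(n_bins):
        sel = bins == b
        if not np.any(sel):
            continue
        top = np.argmax(h[sel])
        radii.append(rho[sel][top])
    return float(2.0 * np.mean(radii))


def _tangent(axis: np.ndarray, which: int) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1 if which == 0 else e2


def opening_diameter(scene: Scene, oral_axis=None) -> float:
    """Blastoporal opening diameter of an invaginating blastula scene.

    Applies :func:`rim_diameter` to all vertex positions in the frame
    of the mean cell center, along the oral axis (taken from
    ``scene.meta`` when not given).  A scene whose surface still covers
    the oral pole (no invagination yet) reports 0.
    """
    if oral_axis is None:
        oral_axis = scene.meta["oral_axis"]
    centroid = scene.cell_centers().mean(axis=0)
    return rim_diameter(scene.X, oral_axis, centroid=centroid)


def invagination_depth(scene: Scene, oral_axis=None) -> float:
    """Inward displacement of the plate-center cell since t = 0.

    Positive values mean the plate center has moved into the embryo
    (against the outward oral axis).  Computed in the scene frame —
    the mean displacement of all cells is subtracted — so rigid
    translations of the whole scene do not register.
    """
    if oral_axis is None:
        oral_axis = scene.meta["oral_axis"]
    axis = np.asarray(oral_axis, float)
    axis = axis / np.linalg.norm(axis)
    rings = scene.meta.get("rings")
    if rings:
        center_cell = scene.id_to_index[rings[0][0]]
    else:
        center_cell = scene.id_to_index[scene.meta["plate_cells"][0]]
    disp = scene.center_displacement(center_cell)
    mean_disp = np.mean(
        [scene.center_displacement(i) for i in range(len(scene.cells))], axis=0
    )
    return float(-(disp - mean_disp) @ axis)


class MeasurementRecorder:
    """Collects one record per output step into a tidy table.

    Records per-cell volume, surface area, height, width and elongation
    plus scene-level invagination depth, opening diameter and bond
    count.  Use as the ``recorder`` argument of :meth:`Scene.run` and
    read ``.frame()`` afterwards.
    """

    def __init__(self, scene_metrics: bool = True, per_cell: bool = True):
        self.scene_metrics = scene_metrics
        self.per_cell = per_cell
        self.rows: list[dict] = []

    def __call__(self, scene: Scene) -> dict:
        rec: dict = {"t": scene.t, "bonds": scene.bond_count(),
                     "kinetic": scene.kinetic_proxy()}
        vols = scene.volumes()
        rec["max_volume_err"] = float(np.abs(vols / scene.V0 - 1.0).max())
        if self.scene_metrics and getattr(scene, "meta", None) and (
            scene.meta.get("plate_cells")
        ):
            rec["invagination_depth"] = invagination_depth(scene)
            if scene.meta.get("kind") == "blastula":
                rec["opening_diameter"] = opening_diameter(scene)
        if self.per_cell:
            for i, c in enumerate(scene.cells):
                h, w = cell_height_width(c)
                rec[f"volume_{c.cell_id}"] = float(vols[i])
                rec[f"area_{c.cell_id}"] = surface_area(c)
                rec[f"height_{c.cell_id}"] = h
                rec[f"width_{c.cell_id}"] = w
                rec[f"elongation_{c.cell_id}"] = h / w
        self.rows.append(rec)
        return rec

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)
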