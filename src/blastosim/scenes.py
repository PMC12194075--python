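"""Scene builders for the invagination experiments.

Assembles the standard configurations: a single free cell, a detached
endodermal plate (hexagonal disc of adhered cells), a planar ring of
cells between two confinement plates (a blastula cross-section), and a
hollow blastula of 32-1024 typed cells with a selectable endodermal
plate shape.  Also provides the ring decomposition of a plate and the
constriction-mode schedules (simultaneous / edge-first / center-first).

All construction is deterministic given the specification; cell
placement uses a generalized Fibonacci spiral on the sphere, which is
quasi-uniform for any cell count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .dynamics import Scene
from .interactions import AdhesionParams, ConfinementPlane
from .mechanics import ConstrictionEvent, CortexParams, StiffnessEvent
from .mesh import RegionSpec, build_icosphere

__all__ = [
    "PlateShape",
    "ConstrictionMode",
    "BlastulaSpec",
    "place_cells_on_sphere",
    "select_plate",
    "ring_decomposition",
    "constriction_schedule",
    "build_single_cell",
    "build_blastula",
    "build_detached_plate",
    "build_planar_scene",
    "purse_string_setup",
]

# default region bands (percent of polar arc from the apical pole)
ENDODERM_ADHESION = RegionSpec(20.0, 65.0)
ECTODERM_ADHESION = RegionSpec(20.0, 100.0)
CONSTRICTION_BAND = RegionSpec(0.0, 50.0)


@dataclass(frozen=True)
class PlateShape:
    """Endodermal plate mask drawn around the oral pole.

    kind: ``cap`` (polar-angle threshold), ``rectangle``, ``triangle``,
    ``t_shape`` or ``star``; ``size`` is the controlling angular extent
    in radians (cap half-angle, rectangle half-width, triangle
    circumradius, star outer radius).  ``aspect`` scales the second
    dimension where meaningful.
    """

    kind: str = "cap"
    size: float = 0.6
    aspect: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("cap", "rectangle", "triangle", "t_shape", "star"):
            raise ValueError(f"unknown plate shape kind '{self.kind}'")
        if self.size <= 0:
            raise ValueError("plate shape size must be > 0")


@dataclass(frozen=True)
class ConstrictionMode:
    """How constriction sweeps over the plate rings.

    mode: ``simultaneous``, ``edge_first`` or ``center_first``;
    interval: time units between successive rings.
    """

    mode: str = "simultaneous"
    interval: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("simultaneous", "edge_first", "center_first"):
            raise ValueError(f"unknown constriction mode '{self.mode}'")
        if self.interval < 0:
            raise ValueError("ring interval must be >= 0")


@dataclass
class BlastulaSpec:
    """Specification of a hollow blastula scene."""

    n_cells: int = 64
    cell_radius: float = 1.0
    subdivision_level: int = 2
    plate: PlateShape = field(default_factory=PlateShape)
    endoderm_adhesion: RegionSpec = ENDODERM_ADHESION
    ectoderm_adhesion: RegionSpec = ECTODERM_ADHESION
    spacing_factor: float = 2.05  # center spacing in cell radii

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("a blastula needs at least 2 cells")


# ---------------------------------------------------------------------------
# placement and plate selection
# ---------------------------------------------------------------------------


def place_cells_on_sphere(n: int, radius: float):
    """Quasi-uniform deterministic point set on a sphere (Fibonacci lattice).

    Returns ``(centers (n, 3), apical_axes (n, 3))`` with apical axes
    pointing radially outward.
    """
    if n < 2:
        raise ValueError("need n >= 2 cells")
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.arccos(np.clip(z, -1, 1))
    phi = 2.0 * np.pi * i / golden
    axes = np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )
    return radius * axes, axes


def _pole_chart(centers: np.ndarray, oral_axis: np.ndarray):
    """Azimuthal-equidistant chart around the oral pole.

    Returns (u, v) in radians: the polar angle from the oral axis,
    resolved along two fixed tangent directions.
    """
    axis = np.asarray(oral_axis, float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    unit = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    theta = np.arccos(np.clip(unit @ axis, -1, 1))
    phi = np.arctan2(unit @ e2, unit @ e1)
    return theta * np.cos(phi), theta * np.sin(phi), theta, phi


def select_plate(centers: np.ndarray, shape: PlateShape, oral_axis=(0.0, 0.0, 1.0)):
    """Indices of the cells forming the endodermal plate.

    The shape mask is drawn around the oral pole in an
    azimuthal-equidistant chart; all remaining cells are ectoderm.
    """
    u, v, theta, phi = _pole_chart(centers, np.asarray(oral_axis, float))
    s = shape.size
    if shape.kind == "cap":
        mask = theta <= s
    elif shape.kind == "rectangle":
        mask = (np.abs(u) <= s) & (np.abs(v) <= s * shape.aspect)
    elif shape.kind == "triangle":
        # equilateral triangle of circumradius s, one vertex on +u
        corners = np.array(
            [[np.cos(a), np.sin(a)] for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
        ) * s
        pts = np.stack([u, v], axis=1)
        mask = np.ones(len(u), dtype=bool)
        for i in range(3):
            a, b = corners[i], corners[(i + 1) % 3]
            edge = b - a
            normal = np.array([-edge[1], edge[0]])  # inward for CCW corners
            mask &= (pts - a) @ normal >= 0
    elif shape.kind == "t_shape":
        bar = (np.abs(v) <= s) & (u >= s * 0.4) & (u <= s)
        stem = (np.abs(v) <= s * 0.35) & (u >= -s) & (u <= s * 0.4)
        mask = bar | stem
    elif shape.kind == "star":
        # five-lobed star: polar-angle threshold modulated in azimuth
        inner = 0.35
        lobe = 0.5 * (1.0 + np.cos(5.0 * phi))
        mask = theta <= s * (inner + (1.0 - inner) * lobe)
    else:  # pragma: no cover - guarded by PlateShape validation
        raise ValueError(shape.kind)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValueError(f"plate shape {shape} selects no cells")
    return idx


def _adjacency(centers: np.ndarray, factor: float = 1.3):
    """Cell adjacency by center proximity: distance < factor × mean NN distance."""
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    cutoff = factor * nn.mean()
    return d < cutoff


def ring_decomposition(centers: np.ndarray, plate_idx: np.ndarray, oral_axis=(0, 0, 1.0)):
    """Partition the plate into concentric rings by graph distance.

    Ring 0 is the plate-center cell (the one whose center maximizes the
    dot product with the oral axis, ties to the lowest id); ring i holds
    the plate cells at breadth-first distance i over the adjacency
    graph.  A disconnected plate is rejected.
    """
    plate_idx = np.asarray(plate_idx)
    axis = np.asarray(oral_axis, float)
    axis = axis / np.linalg.norm(axis)
    sub = centers[plate_idx]
    adj = _adjacency(centers)[np.ix_(plate_idx, plate_idx)]
    n_comp, _ = connected_components(coo_matrix(adj), directed=False)
    if n_comp != 1:
        raise ValueError("endodermal plate is not edge-connected")
    score = sub @ axis
    center_local = int(np.lexsort((plate_idx, -score))[0])
    dist = np.full(len(plate_idx), -1, dtype=int)
    dist[center_local] = 0
    frontier = [center_local]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for i in frontier:
            for j in np.nonzero(adj[i])[0]:
                if dist[j] < 0:
                    dist[j] = d
                    nxt.append(j)
        frontier = nxt
    rings = [plate_idx[dist == i] for i in range(dist.max() + 1)]
    return rings


def constriction_schedule(
    rings,
    mode: ConstrictionMode,
    f_c: float,
    start: float,
    region: RegionSpec = CONSTRICTION_BAND,
    ramp: float = 50.0,
):
    """Constriction events for a ring decomposition under a given mode.

    simultaneous: every ring starts at ``start``; center_first: ring i
    starts at start + i·interval; edge_first: the outermost ring starts
    first and the wave runs inward.
    """
    events = []
    n = len(rings)
    for i, ring in enumerate(rings):
        if mode.mode == "simultaneous":
            t0 = start
        elif mode.mode == "center_first":
            t0 = start + i * mode.interval
        else:  # edge_first
            t0 = start + (n - 1 - i) * mode.interval
        events.append(
            ConstrictionEvent(
                cells=tuple(int(c) for c in ring),
                region=region,
                f_c=f_c,
                start=t0,
                ramp=ramp,
            )
        )
    return events


# ---------------------------------------------------------------------------
# scene builders
# ---------------------------------------------------------------------------

_DEFAULT_ADHESION = dict(connect_length=0.3, k_adh=0.5, lin_length=0.05,
                         adhesion_chance=100.0, break_chance=0.0)


def default_adhesion(region: RegionSpec, **over) -> AdhesionParams:
    kw = {**_DEFAULT_ADHESION, **over}
    return AdhesionParams(region=region, **kw)


def build_single_cell(
    subdivision_level: int = 2,
    radius: float = 1.0,
    cortex: CortexParams | None = None,
    events=(),
    seed: int = 0,
    **scene_kw,
) -> Scene:
    """A single free-floating cell."""
    cell = build_icosphere(subdivision_level, radius=radius, cell_id=0)
    sc = Scene([cell], cortex=cortex, events=list(events), seed=seed, **scene_kw)
    sc.meta = {"kind": "single_cell"}
    return sc


def _make_cells(centers, axes, radius, level, types, spacing_factor):
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    min_d = d.min()
    r = radius
    if min_d < 1.9 * r:
        r_new = min_d / spacing_factor
        warnings.warn(
            f"cells overlap beyond tolerance (min spacing {min_d:.3f}); "
            f"reducing cell radius {r:.3f} -> {r_new:.3f}"
        )
        r = r_new
    return [
        build_icosphere(level, radius=r, center=centers[i], apical_axis=axes[i],
                        cell_id=i, cell_type=types[i])
        for i in range(len(centers))
    ], r


def build_blastula(
    spec: BlastulaSpec,
    oral_axis=(0.0, 0.0, 1.0),
    seed: int = 0,
    cortex: CortexParams | None = None,
    adhesion_overrides: dict | None = None,
    **scene_kw,
) -> Scene:
    """A hollow blastula of adhered cells with endoderm/ectoderm typing.

    Cells sit on a sphere whose radius is chosen so that nearest
    neighbours are ``spacing_factor`` cell radii apart; the endodermal
    plate is cut by the plate-shape mask around the oral pole.  The
    returned scene carries ``meta`` with the plate cell ids, their ring
    decomposition and the oral axis.  Run an equilibration phase
    (events scheduled after t≈50) so neighbours bond before constriction
    starts.
    """
    # sphere radius so that the Fibonacci lattice spacing matches the cells
    unit_centers, _ = place_cells_on_sphere(spec.n_cells, 1.0)
    d = np.linalg.norm(unit_centers[:, None] - unit_centers[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    mean_nn_unit = d.min(axis=1).mean()
    R = spec.spacing_factor * spec.cell_radius / mean_nn_unit
    centers, axes = place_cells_on_sphere(spec.n_cells, R)

    plate = select_plate(centers, spec.plate, oral_axis)
    types = ["ectoderm"] * spec.n_cells
    for i in plate:
        types[i] = "endoderm"
    cells, r_used = _make_cells(
        centers, axes, spec.cell_radius, spec.subdivision_level, types,
        spec.spacing_factor,
    )
    adhesion = {
        "endoderm": default_adhesion(spec.endoderm_adhesion),
        "ectoderm": default_adhesion(spec.ectoderm_adhesion),
    }
    if adhesion_overrides:
        adhesion.update(adhesion_overrides)
    scene_kw.setdefault("collision_stride", 4)
    scene_kw.setdefault("adhesion_stride", 5)
    sc = Scene(cells, cortex=cortex, adhesion=adhesion, seed=seed, **scene_kw)
    sc.meta = {
        "kind": "blastula",
        "plate_cells": [int(i) for i in plate],
        "rings": [list(map(int, r)) for r in ring_decomposition(centers, plate, oral_axis)],
        "oral_axis": list(np.asarray(oral_axis, float) / np.linalg.norm(oral_axis)),
        "blastula_radius": float(R),
        "cell_radius": float(r_used),
    }
    return sc


def _hex_disc_centers(n_cells: int, spacing: float):
    """Centers of a hexagonal-packing disc with ``n_cells`` cells.

    Full discs have 1 + 3r(r+1) cells (1, 7, 19, 37, 61, 91, ...); for
    other counts the outermost ring is trimmed by removing cells at
    evenly spaced angular positions (a deterministic, documented rule —
    the resulting plate stays edge-connected).
    """
    if n_cells < 7:
        raise ValueError("a plate needs at least 7 cells")
    r = 0
    while 1 + 3 * r * (r + 1) < n_cells:
        r += 1
    # axial hex coordinates within radius r
    pts = []
    ring_of = []
    for q in range(-r, r + 1):
        for s in range(max(-r, -q - r), min(r, -q + r) + 1):
            x = spacing * (q + s / 2.0)
            y = spacing * (np.sqrt(3) / 2.0) * s
            pts.append((x, y, 0.0))
            ring_of.append(max(abs(q), abs(s), abs(-q - s)))
    pts = np.array(pts)
    ring_of = np.array(ring_of)
    excess = len(pts) - n_cells
    if excess > 0:
        outer = np.nonzero(ring_of == r)[0]
        ang = np.arctan2(pts[outer, 1], pts[outer, 0])
        order = outer[np.argsort(ang, kind="stable")]
        drop = order[np.round(np.linspace(0, len(order), excess, endpoint=False)).astype(int)]
        keep = np.setdiff1d(np.arange(len(pts)), drop)
        pts = pts[keep]
    return pts


def build_detached_plate(
    n_cells: int = 83,
    cell_radius: float = 1.0,
    subdivision_level: int = 2,
    adhesion_region: RegionSpec = ENDODERM_ADHESION,
    spacing_factor: float = 2.05,
    seed: int = 0,
    cortex: CortexParams | None = None,
    **scene_kw,
) -> Scene:
    """A detached endodermal plate: a flat hexagonal disc of adhered cells.

    The plate floats freely (no confinement); apical axes point along
    +z.  ``meta`` carries the ring decomposition for constriction
    schedules.
    """
    centers = _hex_disc_centers(n_cells, spacing_factor * cell_radius)
    axes = np.tile(np.array([0.0, 0.0, 1.0]), (len(centers), 1))
    types = ["endoderm"] * len(centers)
    cells, _ = _make_cells(centers, axes, cell_radius, subdivision_level, types,
                           spacing_factor)
    adhesion = {"endoderm": default_adhesion(adhesion_region)}
    scene_kw.setdefault("collision_stride", 4)
    scene_kw.setdefault("adhesion_stride", 5)
    sc = Scene(cells, cortex=cortex, adhesion=adhesion, seed=seed, **scene_kw)
    # ring decomposition: reuse the BFS machinery with the plate normal as axis;
    # the center cell is the one nearest the centroid.
    d_cent = np.linalg.norm(centers - centers.mean(axis=0), axis=1)
    adj = _adjacency(centers)
    order = np.argsort(d_cent, kind="stable")
    center = int(order[0])
    dist = np.full(len(centers), -1, int)
    dist[center] = 0
    frontier = [center]
    dd = 0
    while frontier:
        dd += 1
        nxt = []
        for i in frontier:
            for j in np.nonzero(adj[i])[0]:
                if dist[j] < 0:
                    dist[j] = dd
                    nxt.append(j)
        frontier = nxt
    rings = [list(map(int, np.nonzero(dist == i)[0])) for i in range(dist.max() + 1)]
    sc.meta = {
        "kind": "detached_plate",
        "plate_cells": list(range(len(centers))),
        "rings": rings,
        "oral_axis": [0.0, 0.0, 1.0],
        "cell_radius": float(cell_radius),
    }
    return sc


def build_planar_scene(
    n_cells: int = 64,
    n_endoderm: int = 16,
    gap: float = 1.9,
    cell_radius: float = 1.0,
    subdivision_level: int = 2,
    spacing_factor: float = 2.05,
    seed: int = 0,
    cortex: CortexParams | None = None,
    plane_stiffness: float = 20.0,
    **scene_kw,
) -> Scene:
    """3D cells on a circle between two confinement plates.

    A cross-section through a blastula: the cells sit on a circle in
    the x-y plane, squeezed between two immovable plates a distance
    ``gap`` apart; apical axes point radially outward.  The endodermal
    arc (``n_endoderm`` contiguous cells) is centred on +x.
    """
    if n_cells < 3:
        raise ValueError("planar ring needs at least 3 cells")
    if gap <= 0:
        raise ValueError("plate gap must be > 0")
    spacing = spacing_factor * cell_radius
    R = spacing / (2.0 * np.sin(np.pi / n_cells))
    ang = 2.0 * np.pi * np.arange(n_cells) / n_cells
    centers = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros(n_cells)], axis=1)
    axes = np.stack([np.cos(ang), np.sin(ang), np.zeros(n_cells)], axis=1)
    # endodermal arc centred on +x
    half = n_endoderm // 2
    endo = set((np.arange(-half, -half + n_endoderm) % n_cells).tolist())
    types = ["endoderm" if i in endo else "ectoderm" for i in range(n_cells)]
    cells, _ = _make_cells(centers, axes, cell_radius, subdivision_level, types,
                           spacing_factor)
    adhesion = {
        "endoderm": default_adhesion(ENDODERM_ADHESION),
        "ectoderm": default_adhesion(ECTODERM_ADHESION),
    }
    planes = [
        ConfinementPlane(point=(0, 0, -gap / 2), normal=(0, 0, 1), stiffness=plane_stiffness),
        ConfinementPlane(point=(0, 0, gap / 2), normal=(0, 0, -1), stiffness=plane_stiffness),
    ]
    scene_kw.setdefault("collision_stride", 4)
    scene_kw.setdefault("adhesion_stride", 5)
    sc = Scene(cells, cortex=cortex, adhesion=adhesion, planes=planes, seed=seed, **scene_kw)
    sorted_endo = sorted(endo, key=lambda i: ((ang[i] + np.pi) % (2 * np.pi)))
    sc.meta = {
        "kind": "planar",
        "plate_cells": sorted(endo),
        "oral_axis": [1.0, 0.0, 0.0],
        "ring_radius": float(R),
        "gap": float(gap),
        "cell_radius": float(cell_radius),
    }
    return sc


def purse_string_setup(
    cells,
    band: RegionSpec = RegionSpec(20.0, 40.0),
    f_c: float = 0.1,
    start: float = 50.0,
    ramp: float = 50.0,
    cap_k: tuple = (0.9, 1.8),
    collar_k: tuple = (0.5, 1.4),
):
    """Events for purse-string constriction of a sub-apical ring.

    The constriction band must sit strictly below the apical pole so
    the apex keeps a convex cap; apical-cap stiffening events
    (0-20%: cap_k[0] → cap_k[1]; 20-60%: collar_k[0] → collar_k[1])
    counteract the outward volume bulge of the free apex.
    """
    if band.band_start_pct <= 0:
        raise ValueError("purse-string band must exclude the apical pole")
    cells = tuple(int(c) for c in cells)
    return [
        # base stiffness pattern, set before constriction begins
        StiffnessEvent(cells=cells, region=RegionSpec(0.0, 20.0),
                       k_target=cap_k[0], start=0.0, ramp=0.0),
        StiffnessEvent(cells=cells, region=RegionSpec(20.0, 60.0),
                       k_target=collar_k[0], start=0.0, ramp=0.0),
        ConstrictionEvent(cells=cells, region=band, f_c=f_c, start=start, ramp=ramp),
        StiffnessEvent(cells=cells, region=RegionSpec(0.0, 20.0),
                       k_target=cap_k[1], start=start, ramp=ramp),
        StiffnessEvent(cells=cells, region=RegionSpec(20.0, 60.0),
                       k_target=collar_k[1], start=start, ramp=ramp),
    ]
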