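"""Intracellular forces and scheduled property changes.

The cell cortex is a network of nonlinear springs whose stiffness grows
with extension (strain stiffening): F = −(k/l0)·x² − k·x with
x = l − l0, so stretching is resisted more strongly than compression.
Cortical strain keeps the network under permanent tension by setting
every rest length to a fixed fraction f_et of its reference length
(l0 = f_et·l_rest); the conserved cell volume then keeps the edges
stretched and the surface taut.  Active constriction multiplies the
rest lengths of a surface band by a further factor f_c, ramped linearly
in time.  Volume conservation acts as a pressure-like restoring force
of magnitude k_v·|V − V0|/V0 on every vertex along its outward normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import CellMesh, RegionSpec, vertex_normals

__all__ = [
    "CortexParams",
    "ConstrictionEvent",
    "StiffnessEvent",
    "AdhesionEvent",
    "elastic_force",
    "elastic_edge_forces",
    "apply_cortical_strain",
    "ramp_fraction",
    "volume_force",
]


@dataclass
class CortexParams:
    """Global cortex parameters.

    f_et : cortical strain factor in (0, 1]; every edge rest length is
        f_et times its reference length, keeping the cortex taut.
    k_v : volume stiffness (force per vertex per unit relative volume
        deviation).
    """

    f_et: float = 0.5
    k_v: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_et <= 1.0):
            raise ValueError(f"f_et must be in (0, 1], got {self.f_et}")
        if self.k_v < 0:
            raise ValueError("k_v must be >= 0")


# ---------------------------------------------------------------------------
# elastic elements
# ---------------------------------------------------------------------------


def elastic_force(k, l, l0):
    """Signed spring force along the edge direction.

    F = −(k/l0)·x² − k·x with x = l − l0.  Negative pulls the endpoints
    together, positive pushes them apart.  The quadratic term makes the
    response strain-stiffening in extension; in compression the force
    crosses zero again at x = −l0, beyond which it would become
    anti-restorative, so it is clamped to 0 for l < 0 (which cannot
    occur for a physical length) and evaluated as-is otherwise.
    """
    k = np.asarray(k, dtype=float)
    l = np.asarray(l, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    if np.any(l0 <= 0):
        raise ValueError("rest length l0 must be positive")
    x = l - l0
    return -(k / l0) * x * x - k * x


def elastic_edge_forces(positions, edges, k, l0):
    """Per-vertex forces from all cortical springs.

    Returns an (V, 3) array.  For each edge the scalar law of
    :func:`elastic_force` is applied along the edge direction, with
    equal and opposite vectors on the two endpoints (their sum is zero
    edge by edge).
    """
    d = positions[edges[:, 1]] - positions[edges[:, 0]]
    l = np.linalg.norm(d, axis=1)
    safe = np.maximum(l, 1e-12)
    u = d / safe[:, None]
    f = elastic_force(k, l, l0)
    # F < 0 (stretched): endpoint 0 is pulled toward endpoint 1 (+u)
    vec = (-f)[:, None] * u
    n = len(positions)
    out = np.empty_like(positions)
    for c in range(3):
        out[:, c] = np.bincount(edges[:, 0], weights=vec[:, c], minlength=n)
        out[:, c] -= np.bincount(edges[:, 1], weights=vec[:, c], minlength=n)
    return out


def apply_cortical_strain(cell: CellMesh, f_et: float) -> None:
    """Set l0 = f_et·l_rest on every edge of the cell (in place)."""
    if not (0.0 < f_et <= 1.0):
        raise ValueError(f"f_et must be in (0, 1], got {f_et}")
    cell.l0 = f_et * cell.l_rest


# ---------------------------------------------------------------------------
# scheduled events
# ---------------------------------------------------------------------------


def ramp_fraction(t: float, start: float, ramp: float) -> float:
    """Linear ramp: 0 before ``start``, 1 after ``start + ramp``."""
    if t <= start:
        return 0.0
    if ramp <= 0 or t >= start + ramp:
        return 1.0
    return (t - start) / ramp


@dataclass
class ConstrictionEvent:
    """Gradually shorten the rest lengths of a surface band.

    The per-edge rest-length multiplier goes linearly from 1 at
    ``start`` to ``f_c`` at ``start + ramp``; it composes
    multiplicatively with the cortical strain factor
    (l0 = f_c·f_et·l_rest), so releasing the constriction restores the
    strained baseline.
    """

    cells: tuple[int, ...]
    region: RegionSpec
    f_c: float
    start: float
    ramp: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_c <= 1.0):
            raise ValueError(f"f_c must be in (0, 1], got {self.f_c}")
        if self.ramp < 0:
            raise ValueError("ramp duration must be >= 0")
        self.cells = tuple(self.cells)

    def multiplier(self, t: float) -> float:
        s = ramp_fraction(t, self.start, self.ramp)
        return 1.0 + s * (self.f_c - 1.0)


@dataclass
class StiffnessEvent:
    """Linearly ramp the stiffness of a surface band to a target value.

    The starting stiffness is whatever each edge carries when the event
    fires; it is captured at the first step at or after ``start``.
    """

    cells: tuple[int, ...]
    region: RegionSpec
    k_target: float
    start: float
    ramp: float = 50.0
    _k_from: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.k_target < 0:
            raise ValueError("target stiffness must be >= 0")
        if self.ramp < 0:
            raise ValueError("ramp duration must be >= 0")
        self.cells = tuple(self.cells)

    def value(self, k_from: np.ndarray, t: float) -> np.ndarray:
        s = ramp_fraction(t, self.start, self.ramp)
        return k_from + s * (self.k_target - k_from)


@dataclass
class AdhesionEvent:
    """Switch a cell set's adhesion parameters at a given time."""

    cells: tuple[int, ...]
    start: float
    params: object = None  # AdhesionParams; typed loosely to avoid a cycle

    def __post_init__(self) -> None:
        self.cells = tuple(self.cells)


# ---------------------------------------------------------------------------
# volume conservation
# ---------------------------------------------------------------------------


def area_weighted_normals(positions: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unnormalised outward vertex normals: the sum of adjacent face
    area vectors.  Over a closed mesh these sum to exactly zero."""
    p0 = positions[faces[:, 0]]
    cross = np.cross(positions[faces[:, 1]] - p0, positions[faces[:, 2]] - p0)
    acc = np.zeros_like(positions)
    for c in range(3):
        np.add.at(acc, faces[:, c], cross)
    return acc


def volume_force(cell: CellMesh, k_v: float, weighting: str = "area"):
    """Pressure-like volume restoring forces, one vector per vertex.

    The per-vertex magnitude is k_v·|V − V0|/V0, directed along the
    outward vertex normal when the cell is compressed (V < V0) and
    inward when inflated.  With the default ``area`` weighting each
    vertex's magnitude is additionally scaled by its share of the
    surface area (normalised to mean 1), which makes the force field a
    true uniform pressure: the vector sum over the closed cortex is
    exactly zero, so a deformed cell cannot propel itself through the
    volume term.  ``weighting="uniform"`` applies the bare magnitude to
    every vertex; on an asymmetric cell this leaves a small net thrust.
    An inverted mesh (V ≤ 0) aborts.
    """
    V = cell.volume()
    if V <= 0:
        raise FloatingPointError(
            f"cell {cell.cell_id}: mesh inverted (signed volume {V:.3g} <= 0)"
        )
    scale = -k_v * (V - cell.V0) / cell.V0
    if weighting == "uniform":
        return scale * vertex_normals(cell)
    if weighting != "area":
        raise ValueError(f"unknown volume-force weighting {weighting!r}")
    acc = area_weighted_normals(cell.positions, cell.faces)
    mean_norm = np.linalg.norm(acc, axis=1).mean()
    return scale / mean_norm * acc
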