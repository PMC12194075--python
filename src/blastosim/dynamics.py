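"""Force accumulation and time stepping.

The scene is advanced with a position-Verlet scheme with linear viscous
damping:

    x_{n+1} = (2 − c)·x_n − (1 − c)·x_{n−1} + a·Δt²

with a = F_total/m and damping factor c in [0, 1].  Per step the loop
applies due schedule events, refreshes bounding boxes and adhesion
bonds, detects collisions, accumulates all forces (elastic + volume +
adhesion + collision + confinement), integrates, and optionally records
measurements.  Runs are fully reproducible given the seed.

Internally all cells share flat position/edge/face arrays (each
:class:`~blastosim.mesh.CellMesh` holds numpy views into them) so the
per-step force work is a handful of vectorised operations regardless of
cell count; the pairwise interaction work is pruned by the AABB broad
phase, keeping the cost linear in the number of cells for
blastula-like packings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import interactions as inter
from . import mechanics as mech
from .mesh import CellMesh

__all__ = ["IntegratorParams", "Scene", "SimulationError", "verlet_step"]


class SimulationError(RuntimeError):
    """Numerical abort: inverted mesh or non-finite state."""


@dataclass
class IntegratorParams:
    """Time-stepping parameters.

    dt : time step in model time units (the simulation clock advances
        by dt per step, so T time units = T/dt steps).
    c : viscous damping factor in [0, 1]; c = 0 is undamped Verlet,
        c = 1 kills all velocity each step.
    mass : point mass per vertex.
    """

    dt: float = 0.05
    c: float = 0.2
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("damping factor c must be in [0, 1]")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")

    @property
    def steps_per_time_unit(self) -> float:
        return 1.0 / self.dt


def verlet_step(x, x_prev, accel, dt, c):
    """One damped-Verlet update; returns x_{n+1}."""
    return (2.0 - c) * x - (1.0 - c) * x_prev + accel * dt * dt


class Scene:
    """A set of cells plus confinement planes, integrator state and RNG.

    Parameters
    ----------
    cells : sequence of CellMesh
        Cell meshes; copied into shared flat arrays (the originals are
        not modified, the stored cells are views).
    adhesion : dict or None
        Maps cell type (or cell id for per-cell overrides) to
        :class:`~blastosim.interactions.AdhesionParams`; cells with no
        entry do not adhere.
    events : sequence
        Constriction / stiffness / adhesion events applied on schedule.
    """

    def __init__(
        self,
        cells,
        cortex: mech.CortexParams | None = None,
        adhesion: dict | None = None,
        planes=(),
        integrator: IntegratorParams | None = None,
        events=(),
        k_col: float = 5.0,
        aabb_margin: float | None = None,
        narrow_pad: float = 0.05,
        collision_stride: int = 1,
        adhesion_stride: int = 1,
        seed: int = 0,
    ):
        self.cortex = cortex or mech.CortexParams()
        self.integrator = integrator or IntegratorParams()
        self.planes = list(planes)
        self.events = list(events)
        self.k_col = float(k_col)
        self.narrow_pad = float(narrow_pad)
        self.collision_stride = int(collision_stride)
        self.adhesion_stride = int(adhesion_stride)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.t = 0.0
        self.step_count = 0

        self._build_flat(cells)

        # per-cell adhesion parameters (None = non-adhesive)
        adhesion = adhesion or {}
        self.adhesion_params = []
        for c in self.cells:
            p = adhesion.get(c.cell_id, adhesion.get(c.cell_type))
            self.adhesion_params.append(p)
        if aabb_margin is None:
            connect = [p.connect_length for p in self.adhesion_params if p is not None]
            aabb_margin = max(connect) if connect else 0.1
        self.aabb_margin = float(aabb_margin)

        # adhesion bonds: list of AdhesionBond + per-cell bonded masks
        self.bonds: list[inter.AdhesionBond] = []
        self.bonded = [np.zeros(len(c.positions), dtype=bool) for c in self.cells]

        # cached collision contacts (global index arrays)
        self._contact_v = np.empty(0, dtype=np.int64)
        self._contact_f = np.empty((0, 3), dtype=np.int64)

        self._stiffness_applied: dict[int, dict] = {}
        self._adhesion_applied: set[int] = set()
        self._adhesive_cache: dict[int, np.ndarray] = {}
        self._bond_arrays = None
        self.event_log: list[dict] = []
        self.last_forces: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------

    def _build_flat(self, cells) -> None:
        nv = [len(c.positions) for c in cells]
        ne = [len(c.edges) for c in cells]
        nf = [len(c.faces) for c in cells]
        self.voff = np.concatenate([[0], np.cumsum(nv)])
        self.eoff = np.concatenate([[0], np.cumsum(ne)])
        self.foff = np.concatenate([[0], np.cumsum(nf)])

        self.X = np.concatenate([c.positions for c in cells]).astype(float)
        self.X_prev = self.X.copy()
        self.E = np.concatenate(
            [c.edges + self.voff[i] for i, c in enumerate(cells)]
        )
        self.F = np.concatenate(
            [c.faces + self.voff[i] for i, c in enumerate(cells)]
        )
        self.l_rest = np.concatenate([c.l_rest for c in cells]).astype(float)
        self.k = np.concatenate([c.k for c in cells]).astype(float)
        self.c_mult = np.ones_like(self.l_rest)
        self.l0 = self.cortex.f_et * self.l_rest
        self.band = np.concatenate([c.band for c in cells]).astype(float)
        self.V0 = np.array([c.V0 for c in cells], dtype=float)
        self.vertex_cell = np.repeat(np.arange(len(cells)), nv)

        # re-view the cells into the flat arrays
        self.cells: list[CellMesh] = []
        for i, c in enumerate(cells):
            vs, ve = self.voff[i], self.voff[i + 1]
            es, ee = self.eoff[i], self.eoff[i + 1]
            view = CellMesh(
                positions=self.X[vs:ve],
                edges=c.edges.copy(),
                faces=c.faces.copy(),
                l_rest=self.l_rest[es:ee],
                l0=self.l0[es:ee],
                k=self.k[es:ee],
                band=self.band[vs:ve],
                apical_axis=np.array(c.apical_axis, dtype=float),
                V0=c.V0,
                cell_id=c.cell_id,
                cell_type=c.cell_type,
            )
            self.cells.append(view)
        self.id_to_index = {c.cell_id: i for i, c in enumerate(self.cells)}
        self._initial_centers = np.stack([c.center() for c in self.cells])
        self._edge_region_cache: dict = {}

    # ------------------------------------------------------------------
    # bulk geometry
    # ------------------------------------------------------------------

    def volumes(self) -> np.ndarray:
        """Current signed volume of every cell."""
        p0 = self.X[self.F[:, 0]]
        cross = np.cross(self.X[self.F[:, 1]] - p0, self.X[self.F[:, 2]] - p0)
        contrib = np.einsum("ij,ij->i", p0, cross) / 6.0
        return np.add.reduceat(contrib, self.foff[:-1])

    def _normal_acc(self) -> np.ndarray:
        """Per-vertex sum of adjacent face area vectors (unnormalised)."""
        p0 = self.X[self.F[:, 0]]
        cross = np.cross(self.X[self.F[:, 1]] - p0, self.X[self.F[:, 2]] - p0)
        n = len(self.X)
        acc = np.empty_like(self.X)
        for c in range(3):
            acc[:, c] = (
                np.bincount(self.F[:, 0], weights=cross[:, c], minlength=n)
                + np.bincount(self.F[:, 1], weights=cross[:, c], minlength=n)
                + np.bincount(self.F[:, 2], weights=cross[:, c], minlength=n)
            )
        return acc

    def vertex_normals(self) -> np.ndarray:
        """Outward area-weighted unit normals for every vertex in the scene."""
        acc = self._normal_acc()
        norms = np.maximum(np.linalg.norm(acc, axis=1, keepdims=True), 1e-300)
        return acc / norms

    def kinetic_proxy(self) -> float:
        """Σ|x_n − x_{n−1}|² over all vertices (squared step displacement)."""
        return float(((self.X - self.X_prev) ** 2).sum())

    def bond_count(self) -> int:
        return len(self.bonds)

    # ------------------------------------------------------------------
    # schedule
    # ------------------------------------------------------------------

    def _adhesive_vertices(self, i: int) -> np.ndarray:
        """Cached adhesive-band vertex indices of cell i (band membership
        is fixed; the cache is cleared when adhesion parameters change)."""
        if i not in self._adhesive_cache:
            params = self.adhesion_params[i]
            v, _ = inter.select_region(self.cells[i], params.region)
            self._adhesive_cache[i] = v
        return self._adhesive_cache[i]

    def _event_edges(self, ev_idx: int, ev) -> np.ndarray:
        key = ev_idx
        if key not in self._edge_region_cache:
            parts = []
            for cid in ev.cells:
                i = self.id_to_index[cid]
                _, eidx = inter.select_region(self.cells[i], ev.region)
                parts.append(eidx + self.eoff[i])
            self._edge_region_cache[key] = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
            )
        return self._edge_region_cache[key]

    def apply_schedule(self, t: float) -> None:
        """Apply all events due at simulation time ``t``.

        Constriction multipliers are recomputed from scratch each call
        (later events in the list win on overlapping edges), then
        l0 = c_mult · f_et · l_rest everywhere.  Stiffness events
        capture their per-edge starting stiffness on first activation
        and ramp linearly to the target.
        """
        self.c_mult[:] = 1.0
        for idx, ev in enumerate(self.events):
            if isinstance(ev, mech.ConstrictionEvent):
                m = ev.multiplier(t)
                if m != 1.0:
                    edges = self._event_edges(idx, ev)
                    if np.any(self.c_mult[edges] != 1.0):
                        self.event_log.append(
                            {"t": t, "event": idx, "note": "overlapping constriction; latest wins"}
                        )
                    self.c_mult[edges] = m
            elif isinstance(ev, mech.StiffnessEvent):
                if t >= ev.start:
                    edges = self._event_edges(idx, ev)
                    if idx not in self._stiffness_applied:
                        self._stiffness_applied[idx] = self.k[edges].copy()
                        self.event_log.append({"t": t, "event": idx, "note": "stiffness ramp start"})
                    k_from = self._stiffness_applied[idx]
                    self.k[edges] = ev.value(k_from, t)
            elif isinstance(ev, mech.AdhesionEvent):
                if t >= ev.start and idx not in self._adhesion_applied:
                    for cid in ev.cells:
                        self.adhesion_params[self.id_to_index[cid]] = ev.params
                    self._adhesion_applied.add(idx)
                    self._adhesive_cache.clear()
                    self._bond_arrays = None
                    self.event_log.append({"t": t, "event": idx, "note": "adhesion change"})
        np.multiply(self.c_mult, self.cortex.f_et * self.l_rest, out=self.l0)

    # ------------------------------------------------------------------
    # interactions
    # ------------------------------------------------------------------

    def update_interactions(self) -> None:
        """Refresh AABBs, adhesion bonds and the collision contact cache.

        The broad phase runs twice with different inflation margins: the
        adhesion margin must cover the connect length, while collision
        candidates only need a thin shell around the actual geometric
        overlap — a much smaller vertex/face set to test.
        """
        do_adh = self.step_count % self.adhesion_stride == 0
        do_col = self.step_count % self.collision_stride == 0

        if do_adh and self.bonds:
            # break pass: each existing bond releases with break_chance/100
            kept = []
            for b in self.bonds:
                ia, ib = self.id_to_index[b.cell_a], self.id_to_index[b.cell_b]
                pa, pb = self.adhesion_params[ia], self.adhesion_params[ib]
                p_break = max(
                    pa.break_chance if pa else 0.0, pb.break_chance if pb else 0.0
                ) / 100.0
                if (pa and pa.chance_per_time) or (pb and pb.chance_per_time):
                    p_break = min(1.0, p_break * self.integrator.dt
                                  * self.adhesion_stride)
                sep = np.linalg.norm(
                    self.cells[ib].positions[b.vertex_b]
                    - self.cells[ia].positions[b.vertex_a]
                )
                connect = min(
                    pa.connect_length if pa else np.inf,
                    pb.connect_length if pb else np.inf,
                )
                drop = sep > 2.0 * connect  # over-stretched tether releases
                if not drop and p_break > 0.0:
                    drop = self.rng.random() < p_break
                if drop:
                    self.bonded[ia][b.vertex_a] = False
                    self.bonded[ib][b.vertex_b] = False
                    self._bond_arrays = None
                else:
                    kept.append(b)
            self.bonds = kept

        if do_adh:
            pairs, overlaps = inter.broad_phase(self.cells, self.aabb_margin)
            for (i, j), box in zip(pairs, overlaps):
                pa, pb = self.adhesion_params[i], self.adhesion_params[j]
                if pa is not None and pb is not None:
                    new = inter.update_bonds(
                        self.cells[i], self.cells[j], pa, pb,
                        self.bonded[i], self.bonded[j],
                        self.rng, overlap_box=box, t=self.t,
                        adhesive_a=self._adhesive_vertices(i),
                        adhesive_b=self._adhesive_vertices(j),
                        chance_scale=(
                            self.integrator.dt * self.adhesion_stride
                            if pa.chance_per_time or pb.chance_per_time
                            else 1.0
                        ),
                    )
                    self.bonds.extend(new)
                    if new:
                        self._bond_arrays = None

        if do_col:
            pairs, overlaps = inter.broad_phase(self.cells, self.narrow_pad)
            self._contact_v, self._contact_f = self._detect_contacts(pairs, overlaps)

    def _detect_contacts(self, pairs, overlaps):
        """Vertex-through-face contacts for all candidate pairs at once.

        Semantically identical to running
        :func:`blastosim.interactions.narrow_phase` per pair (the test
        suite asserts this), but all point-triangle distance work is
        fused into one vectorised call, which is what keeps many-cell
        scenes fast.  Returns global (vertex, face-corner) index arrays.
        """
        pad = self.narrow_pad
        blocks = []  # (vidx_global, face_rows_global (m, 3))
        for (i, j), box in zip(pairs, overlaps):
            for a, b in ((i, j), (j, i)):
                ca, cb = self.cells[a], self.cells[b]
                vmask = inter._in_box(ca.positions, box, pad)
                if not vmask.any():
                    continue
                fmask = inter._in_box(cb.positions, box, pad)[cb.faces].any(axis=1)
                if not fmask.any():
                    continue
                vidx = np.nonzero(vmask)[0] + self.voff[a]
                frows = cb.faces[fmask] + self.voff[b]
                blocks.append((vidx, frows))
        if not blocks:
            return np.empty(0, np.int64), np.empty((0, 3), np.int64)

        # cheap cull before the exact point-triangle distances: the true
        # nearest face's centroid lies within (min centroid distance +
        # max face circumradius) of the vertex, because distance-to-face
        # <= distance-to-centroid and centroid-distance <= face-distance
        # + circumradius
        culled = []  # per block: keep mask (n, m)
        kept_v, kept_f = [], []
        for vidx, frows in blocks:
            tri = self.X[frows]
            cent = tri.mean(axis=1)
            r_max = np.sqrt(((tri - cent[:, None, :]) ** 2).sum(axis=2)).max()
            diff = self.X[vidx][:, None, :] - cent[None, :, :]
            dc = np.sqrt((diff * diff).sum(axis=2))
            keep = dc <= (dc.min(axis=1, keepdims=True) + r_max) * (1 + 1e-12)
            culled.append(keep)
            kn = np.nonzero(keep)
            kept_v.append(vidx[kn[0]])
            kept_f.append(frows[kn[1]])
        pv = np.concatenate(kept_v)
        pf = np.concatenate(kept_f)
        pts = self.X[pv]
        closest, _ = inter.closest_point_triangle(
            pts, self.X[pf[:, 0]], self.X[pf[:, 1]], self.X[pf[:, 2]]
        )
        d2_kept = ((pts - closest) ** 2).sum(axis=1)

        out_v, out_f = [], []
        pos = 0
        for (vidx, frows), keep in zip(blocks, culled):
            n, m = len(vidx), len(frows)
            kcount = int(keep.sum())
            d2 = np.full((n, m), np.inf)
            d2[keep] = d2_kept[pos:pos + kcount]
            pos += kcount
            nearest = np.argmin(d2, axis=1)
            tri = self.X[frows]
            crosses = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            areas2 = np.linalg.norm(crosses, axis=1)
            ok = areas2[nearest] > 1e-300  # skip degenerate faces
            normals = crosses[nearest[ok]] / areas2[nearest[ok], None]
            signed = np.einsum(
                "ij,ij->i",
                self.X[vidx[ok]] - tri[nearest[ok], 0],
                normals,
            )
            inside = signed < 0
            out_v.append(vidx[ok][inside])
            out_f.append(frows[nearest[ok][inside]])
        return (
            np.concatenate(out_v).astype(np.int64),
            np.concatenate(out_f).astype(np.int64).reshape(-1, 3),
        )

    # ------------------------------------------------------------------
    # forces
    # ------------------------------------------------------------------

    def accumulate_forces(self) -> np.ndarray:
        """Total per-vertex force; component fields kept in ``last_forces``."""
        X = self.X
        total = np.zeros_like(X)
        comp: dict[str, np.ndarray] = {}

        # elastic cortex springs
        f_el = mech.elastic_edge_forces(X, self.E, self.k, self.l0)
        comp["elastic"] = f_el
        total += f_el

        # volume conservation
        V = self.volumes()
        if np.any(V <= 0):
            bad = int(np.argmax(V <= 0))
            raise SimulationError(
                f"cell {self.cells[bad].cell_id}: mesh inverted (V={V[bad]:.4g})"
            )
        # area-weighted pressure field: per-cell mean magnitude follows
        # k_v|V-V0|/V0 and the per-cell vector sum is exactly zero
        acc = self._normal_acc()
        norms = np.linalg.norm(acc, axis=1)
        mean_norm = np.add.reduceat(norms, self.voff[:-1]) / np.diff(self.voff)
        scale = -self.cortex.k_v * (V - self.V0) / (self.V0 * mean_norm)
        f_vol = np.repeat(scale, np.diff(self.voff))[:, None] * acc
        comp["volume"] = f_vol
        total += f_vol

        # adhesion bonds (index/parameter arrays cached until the bond
        # list or the adhesion parameters change)
        if self.bonds:
            if self._bond_arrays is None:
                ga = np.array(
                    [self.voff[self.id_to_index[b.cell_a]] + b.vertex_a
                     for b in self.bonds]
                )
                gb = np.array(
                    [self.voff[self.id_to_index[b.cell_b]] + b.vertex_b
                     for b in self.bonds]
                )
                k_adh = np.empty(len(self.bonds))
                lin = np.empty(len(self.bonds))
                for n, b in enumerate(self.bonds):
                    pa = self.adhesion_params[self.id_to_index[b.cell_a]]
                    pb = self.adhesion_params[self.id_to_index[b.cell_b]]
                    k_adh[n] = min(pa.k_adh if pa else 0.0, pb.k_adh if pb else 0.0)
                    lin[n] = min(
                        pa.lin_length if pa else np.inf,
                        pb.lin_length if pb else np.inf,
                    )
                self._bond_arrays = (ga, gb, k_adh, lin)
            ga, gb, k_adh, lin = self._bond_arrays
            d = X[gb] - X[ga]
            l = np.linalg.norm(d, axis=1)
            mag = np.where(l > lin, k_adh, k_adh * l / np.maximum(lin, 1e-300))
            u = d / np.maximum(l, 1e-12)[:, None]
            vec = mag[:, None] * u
            f_adh = np.zeros_like(X)
            np.add.at(f_adh, ga, vec)
            np.add.at(f_adh, gb, -vec)
            comp["adhesion"] = f_adh
            total += f_adh

        # collision contacts (cached pairs re-evaluated at current positions)
        if len(self._contact_v):
            tri_a = X[self._contact_f[:, 0]]
            cr = np.cross(X[self._contact_f[:, 1]] - tri_a, X[self._contact_f[:, 2]] - tri_a)
            nrm = np.maximum(np.linalg.norm(cr, axis=1), 1e-300)
            normal = cr / nrm[:, None]
            pts = X[self._contact_v]
            depth = -np.einsum("ij,ij->i", pts - tri_a, normal)
            active = depth > 0
            if np.any(active):
                av = self._contact_v[active]
                af = self._contact_f[active]
                an = normal[active]
                _, bary = inter.closest_point_triangle(
                    pts[active], X[af[:, 0]], X[af[:, 1]], X[af[:, 2]]
                )
                fmag = (self.k_col * depth[active])[:, None] * an
                f_col = np.zeros_like(X)
                np.add.at(f_col, av, fmag)
                for cidx in range(3):
                    np.add.at(f_col, af[:, cidx], -bary[:, cidx, None] * fmag)
                comp["collision"] = f_col
                total += f_col

        # confinement planes
        if self.planes:
            f_pl = np.zeros_like(X)
            for plane in self.planes:
                f_pl += inter.plane_confinement(X, plane)
            comp["confinement"] = f_pl
            total += f_pl

        for name, f in comp.items():
            if not np.all(np.isfinite(f)):
                raise SimulationError(f"non-finite force from module '{name}'")
        self.last_forces = comp
        return total

    # ------------------------------------------------------------------
    # stepping
    # ------------------------------------------------------------------

    def step(self) -> None:
        """Advance the scene by one time step Δt."""
        self.apply_schedule(self.t)
        self.update_interactions()
        F = self.accumulate_forces()
        a = F / self.integrator.mass
        x_new = verlet_step(self.X, self.X_prev, a, self.integrator.dt, self.integrator.c)
        if not np.all(np.isfinite(x_new)):
            raise SimulationError("non-finite vertex position after integration")
        self.X_prev[:] = self.X
        self.X[:] = x_new
        self.step_count += 1
        self.t = self.step_count * self.integrator.dt

    def run(
        self,
        end_time: float,
        recorder=None,
        record_every: int = 20,
        snapshot_cb=None,
        snapshot_every: int | None = None,
    ):
        """Run until the simulation clock reaches ``end_time``.

        ``recorder(scene)`` is called every ``record_every`` steps (and
        at the final step) and must return a dict; the collected rows
        are returned as a list.  ``snapshot_cb(scene, step)`` is called
        every ``snapshot_every`` steps when given.
        """
        rows = []
        n_steps = int(round((end_time - self.t) / self.integrator.dt))
        for s in range(n_steps):
            self.step()
            last = s == n_steps - 1
            if recorder is not None and (self.step_count % record_every == 0 or last):
                rows.append(recorder(self))
            if snapshot_cb is not None and snapshot_every and (
                self.step_count % snapshot_every == 0 or last
            ):
                snapshot_cb(self, self.step_count)
        return rows

    # ------------------------------------------------------------------
    # displacement helpers
    # ------------------------------------------------------------------

    def cell_centers(self) -> np.ndarray:
        return np.stack([c.center() for c in self.cells])

    def center_displacement(self, cell_index: int) -> np.ndarray:
        """Displacement of one cell's centroid since scene construction."""
        return self.cells[cell_index].center() - self._initial_centers[cell_index]
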