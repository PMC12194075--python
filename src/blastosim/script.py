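"""Declarative experiment scripts.

An experiment is described by a small YAML document: a scene
declaration (which builder plus its parameters), global physical and
integrator parameters, a list of timed events, and output cadence.
The format is strict — unknown keys are rejected by name so a typo
cannot silently change an experiment — and everything, defaults
included, is echoed into the run manifest.

Example::

    scene:
      builder: detached_plate
      n_cells: 19
    params:
      seed: 1
      f_c: 0.1
    events:
      - type: constrict
        mode: simultaneous
        start: 50
    end_time: 150
    output:
      record_every: 20

Constriction events may either list explicit ``cells`` or give a
``mode`` (simultaneous / edge_first / center_first), in which case the
builder's ring decomposition expands them into per-ring events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from . import scenes
from .dynamics import IntegratorParams, Scene
from .interactions import AdhesionParams
from .mechanics import AdhesionEvent, ConstrictionEvent, CortexParams, StiffnessEvent
from .mesh import RegionSpec

__all__ = ["ScriptError", "ExperimentScript", "parse_script"]


class ScriptError(ValueError):
    """Raised for any malformed experiment script; names the offending field."""


_BUILDERS = {
    "single_cell": scenes.build_single_cell,
    "blastula": scenes.build_blastula,
    "detached_plate": scenes.build_detached_plate,
    "planar": scenes.build_planar_scene,
}

_PARAM_KEYS = {
    "dt": 0.05, "damping": 0.2, "mass": 1.0, "f_et": 0.5, "k_v": 50.0,
    "k_col": 5.0, "seed": 0, "collision_stride": None, "adhesion_stride": None,
}

_SCENE_KEYS = {
    "single_cell": {"subdivision_level", "radius"},
    "blastula": {"n_cells", "cell_radius", "subdivision_level", "plate",
                 "endoderm_adhesion", "ectoderm_adhesion", "spacing_factor"},
    "detached_plate": {"n_cells", "cell_radius", "subdivision_level",
                       "adhesion_region", "spacing_factor"},
    "planar": {"n_cells", "n_endoderm", "gap", "cell_radius",
               "subdivision_level", "spacing_factor", "plane_stiffness"},
}

_EVENT_KEYS = {
    "constrict": {"cells", "mode", "interval", "region", "f_c", "start", "ramp"},
    "stiffness": {"cells", "region", "k", "start", "ramp"},
    "adhesion": {"cells", "start", "region", "connect_length", "k_adh",
                 "lin_length", "adhesion_chance", "break_chance"},
}


def _require(cond: bool, where: str, msg: str) -> None:
    if not cond:
        raise ScriptError(f"{where}: {msg}")


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    _require(not unknown, where, f"unknown key(s) {sorted(unknown)}")


def _region(value, where: str) -> RegionSpec:
    _require(
        isinstance(value, (list, tuple)) and len(value) == 2,
        where, f"region must be a [start, end] pair, got {value!r}",
    )
    try:
        return RegionSpec(float(value[0]), float(value[1]))
    except ValueError as e:
        raise ScriptError(f"{where}: {e}") from None


@dataclass
class ExperimentScript:
    """A validated experiment declaration."""

    builder: str
    scene_args: dict
    params: dict
    events: list = field(default_factory=list)  # raw event dicts
    end_time: float = 100.0
    record_every: int = 20
    snapshot_every: int = 0
    snapshot_format: str = "obj"

    def build(self) -> Scene:
        """Construct the scene and attach the resolved event list."""
        kw = dict(self.scene_args)
        if self.builder == "blastula":
            plate = kw.pop("plate", {})
            spec = scenes.BlastulaSpec(
                plate=scenes.PlateShape(**plate) if isinstance(plate, dict) else plate,
                **{k: v for k, v in kw.items()
                   if k in ("n_cells", "cell_radius", "subdivision_level",
                            "spacing_factor")},
            )
            for name in ("endoderm_adhesion", "ectoderm_adhesion"):
                if name in kw:
                    setattr(spec, name, _region(kw[name], f"scene.{name}"))
            builder_kw = {"spec": spec}
        else:
            if "adhesion_region" in kw:
                kw["adhesion_region"] = _region(kw["adhesion_region"],
                                                "scene.adhesion_region")
            builder_kw = kw
        p = self.params
        integ = IntegratorParams(dt=p["dt"], c=p["damping"], mass=p["mass"])
        cortex = CortexParams(f_et=p["f_et"], k_v=p["k_v"])
        extra = {"k_col": p["k_col"], "integrator": integ}
        for name in ("collision_stride", "adhesion_stride"):
            if p[name] is not None:
                extra[name] = int(p[name])
        scene = _BUILDERS[self.builder](
            seed=int(p["seed"]), cortex=cortex, **builder_kw, **extra
        )
        scene.events.extend(self._resolve_events(scene))
        return scene

    def _resolve_events(self, scene: Scene) -> list:
        out = []
        for n, ev in enumerate(self.events):
            where = f"events[{n}]"
            kind = ev["type"]
            region = _region(ev.get("region", [0, 50]), f"{where}.region")
            start = float(ev.get("start", 50.0))
            ramp = float(ev.get("ramp", 50.0))
            cells = ev.get("cells")
            if isinstance(cells, str):
                ids = [c.cell_id for c in scene.cells if c.cell_type == cells]
                _require(ids, where, f"no cells of type '{cells}'")
                cells = ids
            if kind == "constrict":
                f_c = float(ev.get("f_c", 0.1))
                if "mode" in ev:
                    mode = scenes.ConstrictionMode(
                        ev["mode"], float(ev.get("interval", 100.0))
                    )
                    rings = scene.meta.get("rings")
                    _require(rings is not None, where,
                             "mode-based constriction needs a scene with a plate")
                    out.extend(scenes.constriction_schedule(
                        rings, mode, f_c, start, region=region, ramp=ramp))
                else:
                    _require(cells is not None, where,
                             "constrict event needs 'cells' or 'mode'")
                    out.append(ConstrictionEvent(
                        cells=tuple(cells), region=region, f_c=f_c,
                        start=start, ramp=ramp))
            elif kind == "stiffness":
                _require(cells is not None, where, "stiffness event needs 'cells'")
                out.append(StiffnessEvent(
                    cells=tuple(cells), region=region,
                    k_target=float(ev["k"]), start=start, ramp=ramp))
            elif kind == "adhesion":
                _require(cells is not None, where, "adhesion event needs 'cells'")
                params = AdhesionParams(
                    region=region,
                    connect_length=float(ev.get("connect_length", 0.3)),
                    k_adh=float(ev.get("k_adh", 0.05)),
                    lin_length=float(ev.get("lin_length", 0.05)),
                    adhesion_chance=float(ev.get("adhesion_chance", 100.0)),
                    break_chance=float(ev.get("break_chance", 0.0)),
                )
                out.append(AdhesionEvent(cells=tuple(cells), start=start,
                                         params=params))
        return out

    def to_config(self) -> dict:
        return {
            "scene": {"builder": self.builder, **self.scene_args},
            "params": dict(self.params),
            "events": list(self.events),
            "end_time": self.end_time,
            "output": {
                "record_every": self.record_every,
                "snapshot_every": self.snapshot_every,
                "snapshot_format": self.snapshot_format,
            },
        }


def parse_script(text: str) -> ExperimentScript:
    """Parse and validate an experiment script.

    Every validation error names the offending section and field;
    YAML syntax errors carry the line number from the YAML parser.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ScriptError(f"YAML syntax error: {e}") from None
    _require(isinstance(doc, dict), "document", "script must be a mapping")
    _check_keys(doc, {"scene", "params", "events", "end_time", "output"}, "document")

    scene_decl = doc.get("scene")
    _require(isinstance(scene_decl, dict), "scene", "missing or not a mapping")
    builder = scene_decl.get("builder")
    _require(builder in _BUILDERS, "scene.builder",
             f"unknown builder {builder!r}; expected one of {sorted(_BUILDERS)}")
    scene_args = {k: v for k, v in scene_decl.items() if k != "builder"}
    _check_keys(scene_args, _SCENE_KEYS[builder], "scene")
    if "plate" in scene_args and isinstance(scene_args["plate"], dict):
        _check_keys(scene_args["plate"], {"kind", "size", "aspect"}, "scene.plate")
        try:
            scenes.PlateShape(**scene_args["plate"])
        except ValueError as e:
            raise ScriptError(f"scene.plate: {e}") from None

    raw_params = doc.get("params") or {}
    _check_keys(raw_params, set(_PARAM_KEYS), "params")
    params = {**_PARAM_KEYS, **raw_params}

    events = doc.get("events") or []
    _require(isinstance(events, list), "events", "must be a list")
    for n, ev in enumerate(events):
        where = f"events[{n}]"
        _require(isinstance(ev, dict), where, "must be a mapping")
        kind = ev.get("type")
        _require(kind in _EVENT_KEYS, f"{where}.type",
                 f"unknown event type {kind!r}; expected one of {sorted(_EVENT_KEYS)}")
        _check_keys({k: v for k, v in ev.items() if k != "type"},
                    _EVENT_KEYS[kind], where)
        if "mode" in ev:
            _require(ev["mode"] in ("simultaneous", "edge_first", "center_first"),
                     f"{where}.mode", f"unknown constriction mode {ev['mode']!r}")
        if float(ev.get("start", 50.0)) < 0:
            raise ScriptError(f"{where}.start: events before t = 0 are rejected")

    output = doc.get("output") or {}
    _check_keys(output, {"record_every", "snapshot_every", "snapshot_format"},
                "output")
    fmt = output.get("snapshot_format", "obj")
    _require(fmt in ("obj", "vtk"), "output.snapshot_format",
             f"expected 'obj' or 'vtk', got {fmt!r}")

    end_time = float(doc.get("end_time", 100.0))
    _require(end_time > 0, "end_time", "must be > 0")

    return ExperimentScript(
        builder=builder,
        scene_args=scene_args,
        params=params,
        events=events,
        end_time=end_time,
        record_every=int(output.get("record_every", 20)),
        snapshot_every=int(output.get("snapshot_every", 0)),
        snapshot_format=fmt,
    )
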