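"""Read/write musculoskeletal models as a structured YAML document.

Schema (version ``capgap-model/1``): top-level keys ``name``, ``label``,
``lineage``, ``curves``, ``segments``, ``coordinates``, ``muscles`` and
optionally ``patella`` and ``provenance`` (surgery plans are recorded there
verbatim by the surgery module). Angles are stored in degrees and lengths in
meters at the file boundary; everything is radians internally. Round trips
are lossless to well below 1e-12.
"""

from __future__ import annotations

import math

import numpy as np
import yaml

from .errors import FormatError
from .model import (
    JointCoordinate,
    MuscleCurveSet,
    MusculoskeletalModel,
    MuscleTendonActuator,
    PatellaConstruct,
    PathPoint,
    Segment,
)

__all__ = ["model_to_dict", "model_from_dict", "write_model", "read_model"]

FORMAT_TAG = "capgap-model/1"


def _listify(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def model_to_dict(model: MusculoskeletalModel) -> dict:
    d: dict = {
        "format": FORMAT_TAG,
        "name": model.name,
        "label": model.label,
        "lineage": model.lineage,
        "curves": {
            "active_width": model.curves.active_width,
            "passive_k": model.curves.passive_k,
            "passive_eps": model.curves.passive_eps,
        },
        "segments": [],
        "coordinates": [],
        "muscles": [],
    }
    for s in model.segments:
        sd: dict = {
            "name": s.name,
            "parent": s.parent,
            "joint_axis": _listify(s.joint_axis),
            "joint_center": _listify(s.joint_center),
        }
        if s.joint_offset is not None:
            sd["joint_offset"] = [_listify(row) for row in s.joint_offset]
        if s.landmarks:
            sd["landmarks"] = {k: _listify(v) for k, v in s.landmarks.items()}
        if s.mesh_vertices is not None:
            sd["mesh"] = {
                "vertices": [_listify(v) for v in s.mesh_vertices],
                "faces": [list(map(int, f)) for f in s.mesh_faces],
            }
        d["segments"].append(sd)
    for c in model.coordinates:
        d["coordinates"].append(
            {
                "name": c.name,
                "segment": c.segment,
                "range_deg": [math.degrees(c.range[0]), math.degrees(c.range[1])],
            }
        )
    for m in model.muscles:
        d["muscles"].append(
            {
                "name": m.name,
                "F_max": m.F_max,
                "l_mo": m.l_mo,
                "l_ts": m.l_ts,
                "alpha_deg": math.degrees(m.alpha),
                "subset": m.subset,
                "path": [
                    {"segment": p.segment, "location": _listify(p.location), "role": p.role}
                    for p in m.path
                ],
            }
        )
    if model.patella is not None:
        p = model.patella
        d["patella"] = {
            "femur_segment": p.femur_segment,
            "tibia_segment": p.tibia_segment,
            "knee_coordinate": p.knee_coordinate,
            "prox_point": _listify(p.prox_point),
            "dist_point": _listify(p.dist_point),
            "ligament_point": _listify(p.ligament_point),
            "ligament_length": p.ligament_length,
            "tibial_insertion": _listify(p.tibial_insertion),
            "femoral_profile": [_listify(v) for v in p.femoral_profile],
        }
        if p.path is not None:
            d["patella"]["path"] = [_listify(v) for v in p.path]
    if model.provenance:
        d["provenance"] = model.provenance
    return d


def model_from_dict(d: dict) -> MusculoskeletalModel:
    if d.get("format") != FORMAT_TAG:
        raise FormatError(f"unsupported model format {d.get('format')!r}")
    try:
        segments = []
        for sd in d["segments"]:
            mesh = sd.get("mesh")
            segments.append(
                Segment(
                    name=sd["name"],
                    parent=sd["parent"],
                    joint_axis=sd["joint_axis"],
                    joint_center=sd["joint_center"],
                    landmarks=sd.get("landmarks", {}),
                    mesh_vertices=np.asarray(mesh["vertices"], float) if mesh else None,
                    mesh_faces=np.asarray(mesh["faces"], int) if mesh else None,
                    joint_offset=(np.asarray(sd["joint_offset"], float)
                                  if "joint_offset" in sd else None),
                )
            )
        coordinates = [
            JointCoordinate(
                name=cd["name"],
                segment=cd["segment"],
                range=(math.radians(cd["range_deg"][0]), math.radians(cd["range_deg"][1])),
            )
            for cd in d["coordinates"]
        ]
        muscles = [
            MuscleTendonActuator(
                name=md["name"],
                path=[
                    PathPoint(segment=p["segment"], location=p["location"], role=p["role"])
                    for p in md["path"]
                ],
                F_max=md["F_max"],
                l_mo=md["l_mo"],
                l_ts=md["l_ts"],
                alpha=math.radians(md["alpha_deg"]),
                subset=md["subset"],
            )
            for md in d["muscles"]
        ]
        curves = MuscleCurveSet(**d.get("curves", {}))
        patella = None
        if "patella" in d:
            pd = dict(d["patella"])
            path = pd.pop("path", None)
            patella = PatellaConstruct(
                **pd, path=np.asarray(path, float) if path is not None else None
            )
    except KeyError as e:
        raise FormatError(f"missing model field {e.args[0]!r}") from None
    return MusculoskeletalModel(
        segments=segments,
        coordinates=coordinates,
        muscles=muscles,
        curves=curves,
        lineage=d.get("lineage"),
        label=d.get("label", "pre-operative"),
        name=d.get("name", "model"),
        patella=patella,
        provenance=list(d.get("provenance", [])),
    )


def write_model(model: MusculoskeletalModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False, default_flow_style=None)


def read_model(path) -> MusculoskeletalModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: not a model document")
    return model_from_dict(d)
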