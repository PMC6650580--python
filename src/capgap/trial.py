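"""Trial data bundles and the typically-developing (TD) reference motion.

A :class:`TrialBundle` carries everything the optimizations consume for one
gait recording: joint angles, inverse-dynamics joint moments, musculotendon
lengths, moment arms, and EMG envelopes on a common uniform time grid.
Bundles are stored as tab-separated text tables (one per quantity) with a
``time`` first column; an importer for the storage dialect with a
``nRows``/``nColumns``/``endheader`` preamble is included.

The module also computes range-of-motion musculotendon lengths from clinical
test postures, and builds the "desired motion" bundle by scaling a reference
gait template to the patient (moments by mass) — optionally retargeting the
reference kinematics by tracking virtual marker trajectories instead of
imposing joint angles, which keeps distal segments pointing forward when the
patient model carries torsional bone deformities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares

from .errors import ConfigurationError, FormatError
from .model import MusculoskeletalModel, forward_kinematics, musculotendon_geometry

__all__ = [
    "TrialBundle",
    "ROMAssessment",
    "ReferenceGaitTemplate",
    "read_trial_bundle",
    "write_trial_bundle",
    "derive_trial_geometry",
    "rom_musculotendon_lengths",
    "make_reference_trial",
    "resample_bundle",
    "emg_envelope",
    "read_rom_assessment",
    "write_rom_assessment",
    "read_template",
    "write_template",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class TrialBundle:
    """Time-indexed inputs for one gait trial.

    Shapes: time (F,); q and tau_ID (F, J); l_mt (F, M); r (F, M, J);
    emg (F, C). ``channel_map`` maps each EMG channel name to the model
    muscles it informs (the subset of EMG-mapped muscles).
    """

    time: np.ndarray
    coordinate_names: list[str]
    muscle_names: list[str]
    q: np.ndarray
    tau_ID: np.ndarray | None = None
    l_mt: np.ndarray | None = None
    r: np.ndarray | None = None
    emg: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)
    channel_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.q = np.asarray(self.q, float)
        F = len(self.time)
        for name in ("tau_ID", "l_mt", "r", "emg"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                setattr(self, name, v)
                if v.shape[0] != F:
                    raise FormatError(f"{name} has {v.shape[0]} frames, expected {F}")
        if np.any(np.diff(self.time) <= 0):
            raise FormatError("time must be strictly increasing")
        if self.emg is not None:
            if self.emg.shape[1] != len(self.channel_names):
                raise FormatError("emg column count does not match channel names")
            if self.emg.size and (np.nanmin(self.emg) < -1e-12
                                  or np.nanmax(self.emg) > 1 + 1e-12):
                raise FormatError("EMG envelopes must be normalized to [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def validate_against(self, model: MusculoskeletalModel) -> None:
        if self.coordinate_names != model.coordinate_names:
            raise ConfigurationError("trial coordinates do not match model coordinates")
        if self.muscle_names and self.muscle_names != model.muscle_names:
            raise ConfigurationError("trial muscles do not match model muscles")
        known = set(model.muscle_names)
        for ch, muscles in self.channel_map.items():
            for m in muscles:
                if m not in known:
                    raise ConfigurationError(
                        f"EMG channel {ch!r} maps to unknown muscle {m!r}"
                    )

    def mapped_muscles(self) -> list[str]:
        """Muscles informed by at least one EMG channel, in model order."""
        mapped = {m for ms in self.channel_map.values() for m in ms}
        return [m for m in self.muscle_names if m in mapped]

    def emg_for_muscle(self, muscle: str) -> np.ndarray:
        """Envelope of the channel mapped to ``muscle`` (channels may share)."""
        for ci, ch in enumerate(self.channel_names):
            if muscle in self.channel_map.get(ch, []):
                return self.emg[:, ci]
        raise ConfigurationError(f"no EMG channel maps to muscle {muscle!r}")


@dataclass
class ROMAssessment:
    """Clinical range-of-motion exam: named test postures and the muscles
    whose stretch each test measures."""

    tests: list[tuple[str, dict[str, float], list[str]]]  # (name, q rad by coord, muscles)

    def muscles(self) -> list[str]:
        out: list[str] = []
        for _, _, ms in self.tests:
            for m in ms:
                if m not in out:
                    out.append(m)
        return out


@dataclass
class ReferenceGaitTemplate:
    """Normalized average gait cycle used as the desired TD motion."""

    percent: np.ndarray  # 0..100, >= 100 points recommended
    coordinate_names: list[str]
    q: np.ndarray  # (P, J) rad
    moments_per_kg: np.ndarray  # (P, J) N*m/kg
    markers: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (P, 3) m
    reference_height: float = 1.5  # m

    def __post_init__(self):
        self.percent = np.asarray(self.percent, float)
        self.q = np.asarray(self.q, float)
        self.moments_per_kg = np.asarray(self.moments_per_kg, float)
        if len(self.percent) < 2:
            raise FormatError("template needs at least 2 samples")
        if not (
            np.allclose(self.q[0], self.q[-1], atol=1e-6)
            and np.allclose(self.moments_per_kg[0], self.moments_per_kg[-1], atol=1e-6)
        ):
            raise FormatError("template must be periodic (first ~ last sample)")


# ---------------------------------------------------------------------------
# Delimited-table reading/writing (plain and storage-dialect headers)
# ---------------------------------------------------------------------------

def _read_table(path) -> tuple[list[str], np.ndarray, dict]:
    """Read a tab/whitespace-delimited table with a header row.

    Accepts either a bare header line or a storage-dialect preamble of
    ``key=value`` lines ending in ``endheader`` (keys like ``nRows``,
    ``nColumns``, ``inDegrees`` are honored).
    """
    meta: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    # optional storage preamble
    probe = 0
    has_preamble = False
    while probe < len(lines):
        s = lines[probe].strip()
        if s.lower() == "endheader":
            has_preamble = True
            break
        if "=" in s or (probe == 0 and "\t" not in lines[probe] and " " not in s and s):
            probe += 1
            continue
        break
    if has_preamble:
        for i in range(probe):
            s = lines[i].strip()
            if "=" in s:
                k, v = s.split("=", 1)
                meta[k.strip()] = v.strip()
        i = probe + 1
    else:
        i = 0
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines):
        raise FormatError("empty table", line=i + 1)
    names = lines[i].split()
    if names[0] != "time":
        raise FormatError(f"first column must be 'time', got {names[0]!r}", line=i + 1)
    rows = []
    for ln in range(i + 1, len(lines)):
        s = lines[ln].strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != len(names):
            raise FormatError(
                f"expected {len(names)} columns, found {len(parts)}", line=ln + 1
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as e:
            raise FormatError(str(e), line=ln + 1) from None
    data = np.asarray(rows, float)
    if "nRows" in meta and int(meta["nRows"]) != len(rows):
        raise FormatError(f"nRows={meta['nRows']} but table has {len(rows)} rows")
    if "nColumns" in meta and int(meta["nColumns"]) != len(names):
        raise FormatError(f"nColumns={meta['nColumns']} but table has {len(names)} columns")
    if np.any(np.diff(data[:, 0]) <= 0):
        raise FormatError("time column must be strictly increasing")
    return names[1:], data, meta


def _write_table(path, names: list[str], time: np.ndarray, values: np.ndarray,
                 in_degrees: bool = False) -> None:
    values = np.asarray(values, float)
    with open(path, "w") as fh:
        fh.write(f"nRows={len(time)}\n")
        fh.write(f"nColumns={len(names) + 1}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(names) + "\n")
        out = np.degrees(values) if in_degrees else values
        for t, row in zip(time, out):
            fh.write(f"{float(t)!r}\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_trial_bundle(bundle: TrialBundle, stem) -> None:
    """Write a bundle as ``<stem>.angles/.moments/.lmt/.momentarms.<joint>/.emg``
    plus a ``<stem>.channels`` YAML channel map."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _write_table(stem.with_suffix(".angles"), bundle.coordinate_names, bundle.time,
                 bundle.q, in_degrees=True)
    if bundle.tau_ID is not None:
        _write_table(stem.with_suffix(".moments"), bundle.coordinate_names, bundle.time,
                     bundle.tau_ID)
    if bundle.l_mt is not None:
        _write_table(stem.with_suffix(".lmt"), bundle.muscle_names, bundle.time, bundle.l_mt)
    if bundle.r is not None:
        for j, joint in enumerate(bundle.coordinate_names):
            _write_table(stem.with_suffix(f".momentarms.{joint}"), bundle.muscle_names,
                         bundle.time, bundle.r[:, :, j])
    if bundle.emg is not None:
        _write_table(stem.with_suffix(".emg"), bundle.channel_names, bundle.time, bundle.emg)
    with open(stem.with_suffix(".channels"), "w") as fh:
        yaml.safe_dump(
            {"channel_map": bundle.channel_map, "muscles": bundle.muscle_names},
            fh, sort_keys=False,
        )


def read_trial_bundle(stem) -> TrialBundle:
    stem = Path(stem)
    names, data, meta = _read_table(stem.with_suffix(".angles"))
    time = data[:, 0]
    q = data[:, 1:]
    if meta.get("inDegrees", "no").lower() == "yes":
        q = np.radians(q)
    coordinate_names = names

    tau = l_mt = r = emg = None
    muscle_names: list[str] = []
    channel_names: list[str] = []
    channel_map: dict[str, list[str]] = {}

    p = stem.with_suffix(".moments")
    if p.exists():
        mnames, mdata, _ = _read_table(p)
        if mnames != coordinate_names:
            raise FormatError(f"{p}: moment columns do not match angle columns")
        tau = mdata[:, 1:]
    p = stem.with_suffix(".lmt")
    if p.exists():
        muscle_names, ldata, _ = _read_table(p)
        l_mt = ldata[:, 1:]
    if muscle_names:
        arms = []
        for joint in coordinate_names:
            pj = stem.with_suffix(f".momentarms.{joint}")
            if not pj.exists():
                arms = []
                break
            anames, adata, _ = _read_table(pj)
            if anames != muscle_names:
                raise FormatError(f"{pj}: moment-arm columns do not match muscles")
            arms.append(adata[:, 1:])
        if arms:
            r = np.stack(arms, axis=2)
    p = stem.with_suffix(".emg")
    if p.exists():
        channel_names, edata, _ = _read_table(p)
        emg = edata[:, 1:]
    p = stem.with_suffix(".channels")
    if p.exists():
        with open(p) as fh:
            d = yaml.safe_load(fh) or {}
        channel_map = {k: list(v) for k, v in (d.get("channel_map") or {}).items()}
        muscle_names = list(d.get("muscles", muscle_names))
    for ch in channel_map:
        if channel_names and ch not in channel_names:
            raise FormatError(f"channel map references unknown EMG channel {ch!r}")

    return TrialBundle(
        time=time, coordinate_names=coordinate_names, muscle_names=muscle_names,
        q=q, tau_ID=tau, l_mt=l_mt, r=r, emg=emg,
        channel_names=channel_names, channel_map=channel_map,
    )


# ---------------------------------------------------------------------------
# Geometry over trials
# ---------------------------------------------------------------------------

def derive_trial_geometry(model: MusculoskeletalModel, bundle: TrialBundle) -> TrialBundle:
    """Fill ``l_mt`` and ``r`` from the model at every frame of ``bundle.q``."""
    F = bundle.n_frames
    M = len(model.muscles)
    J = len(model.coordinates)
    l_mt = np.empty((F, M))
    r = np.empty((F, M, J))
    for i in range(F):
        l_mt[i], r[i] = musculotendon_geometry(model, bundle.q[i])
    return replace(bundle, l_mt=l_mt, r=r, muscle_names=model.muscle_names)


def rom_musculotendon_lengths(
    model: MusculoskeletalModel, rom: ROMAssessment
) -> dict[str, float]:
    """Per-muscle maximum musculotendon length over the clinical tests that
    measure it (a muscle stretched by two tests gets the longer of the two)."""
    out: dict[str, float] = {}
    for name, posture, muscles in rom.tests:
        q = np.zeros(len(model.coordinates))
        for cn, val in posture.items():
            q[model.coordinate_names.index(cn)] = val
        l_mt, _ = musculotendon_geometry(model, q)
        for m in muscles:
            idx = model.muscle_names.index(m) if m in model.muscle_names else None
            if idx is None:
                raise ConfigurationError(f"ROM test {name!r}: unknown muscle {m!r}")
            out[m] = max(out.get(m, -np.inf), float(l_mt[idx]))
    return out


def read_rom_assessment(path) -> ROMAssessment:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    tests = []
    for t in d["tests"]:
        posture = {k: math.radians(v) for k, v in t["posture_deg"].items()}
        tests.append((t["name"], posture, list(t["muscles"])))
    return ROMAssessment(tests=tests)


def write_rom_assessment(rom: ROMAssessment, path) -> None:
    d = {
        "tests": [
            {
                "name": name,
                "posture_deg": {k: math.degrees(v) for k, v in posture.items()},
                "muscles": list(muscles),
            }
            for name, posture, muscles in rom.tests
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reference (desired) motion
# ---------------------------------------------------------------------------

def _model_marker_positions(model: MusculoskeletalModel, q: np.ndarray,
                            marker_names: list[str]) -> np.ndarray:
    poses = forward_kinematics(model, q)
    out = np.empty((len(marker_names), 3))
    lookup = {}
    for s in model.segments:
        for lname, loc in s.landmarks.items():
            lookup[lname] = (s.name, loc)
    for k, name in enumerate(marker_names):
        if name not in lookup:
            raise ConfigurationError(f"model has no landmark named {name!r} for retargeting")
        seg, loc = lookup[name]
        R, t = poses[seg]
        out[k] = R @ loc + t
    return out


def make_reference_trial(
    template: ReferenceGaitTemplate,
    model: MusculoskeletalModel,
    mass: float,
    height: float | None = None,
    retarget: bool = False,
    grid: int = 51,
) -> TrialBundle:
    """Build the desired-motion bundle: TD kinematics and moments scaled to
    the patient, with musculotendon geometry evaluated on ``model``.

    Moments scale linearly with body mass (the template stores N*m/kg). With
    ``retarget=True`` the joint angles are re-solved per frame by nonlinear
    least squares so the model's virtual markers track the template marker
    trajectories (scaled by the height ratio); otherwise template angles are
    imposed directly.
    """
    pct = np.linspace(0.0, 100.0, grid)
    q = np.column_stack(
        [np.interp(pct, template.percent, template.q[:, j])
         for j in range(template.q.shape[1])]
    )
    tau = mass * np.column_stack(
        [np.interp(pct, template.percent, template.moments_per_kg[:, j])
         for j in range(template.q.shape[1])]
    )
    time = pct / 100.0  # one cycle normalized to 1 s

    if retarget:
        if not template.markers:
            raise ConfigurationError("retargeting requested but template has no markers")
        marker_names = sorted(template.markers)
        scale = 1.0 if height is None else height / template.reference_height
        targets = np.stack(
            [np.column_stack(
                [np.interp(pct, template.percent, template.markers[m][:, d])
                 for d in range(3)])
             for m in marker_names], axis=1,
        ) * scale  # (grid, n_markers, 3)
        # validates marker correspondence up front
        _model_marker_positions(model, q[0], marker_names)
        lo = np.array([c.range[0] for c in model.coordinates])
        hi = np.array([c.range[1] for c in model.coordinates])
        sol = np.empty_like(q)
        x0 = np.clip(q[0], lo, hi)
        for i in range(grid):
            ti = targets[i]

            def resid(x, ti=ti):
                return (_model_marker_positions(model, x, marker_names) - ti).ravel()

            res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
            sol[i] = res.x
            x0 = res.x
        q = sol

    bundle = TrialBundle(
        time=time,
        coordinate_names=template.coordinate_names,
        muscle_names=model.muscle_names,
        q=q,
        tau_ID=tau,
    )
    return derive_trial_geometry(model, bundle)


def write_template(template: ReferenceGaitTemplate, path) -> None:
    """Reference template as a JSON document (lists, full float precision)."""
    import json

    d = {
        "percent": template.percent.tolist(),
        "coordinate_names": template.coordinate_names,
        "q": template.q.tolist(),
        "moments_per_kg": template.moments_per_kg.tolist(),
        "markers": {k: v.tolist() for k, v in template.markers.items()},
        "reference_height": template.reference_height,
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def read_template(path) -> ReferenceGaitTemplate:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return ReferenceGaitTemplate(
        percent=np.asarray(d["percent"], float),
        coordinate_names=list(d["coordinate_names"]),
        q=np.asarray(d["q"], float),
        moments_per_kg=np.asarray(d["moments_per_kg"], float),
        markers={k: np.asarray(v, float) for k, v in d.get("markers", {}).items()},
        reference_height=float(d.get("reference_height", 1.5)),
    )


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

def resample_bundle(bundle: TrialBundle, n_points: int) -> TrialBundle:
    """Linear resampling of every time series onto a uniform grid."""
    t_new = np.linspace(bundle.time[0], bundle.time[-1], n_points)

    def interp(arr):
        if arr is None:
            return None
        flat = arr.reshape(arr.shape[0], -1)
        out = np.column_stack(
            [np.interp(t_new, bundle.time, flat[:, k]) for k in range(flat.shape[1])]
        )
        return out.reshape((n_points,) + arr.shape[1:])

    return replace(
        bundle, time=t_new, q=interp(bundle.q), tau_ID=interp(bundle.tau_ID),
        l_mt=interp(bundle.l_mt), r=interp(bundle.r), emg=interp(bundle.emg),
    )


def emg_envelope(raw: np.ndarray, fs: float, highpass: float = 20.0,
                 lowpass: float = 6.0) -> np.ndarray:
    """Standard EMG envelope: high-pass, rectify, low-pass, peak-normalize.

    Provided as plumbing for users starting from raw EMG; bundles normally
    carry envelopes already.
    """
    from scipy.signal import butter, filtfilt

    raw = np.atleast_2d(np.asarray(raw, float).T).T  # (F, C)
    b, a = butter(4, highpass / (fs / 2.0), "highpass")
    x = filtfilt(b, a, raw, axis=0)
    x = np.abs(x)
    b, a = butter(4, lowpass / (fs / 2.0), "lowpass")
    x = filtfilt(b, a, x, axis=0)
    x = np.clip(x, 0.0, None)
    peaks = x.max(axis=0)
    peaks[peaks == 0] = 1.0
    return x / peaks
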