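"""Domain types and bundle I/O for high-density surface EMG recordings.

A *recording* is one contraction trial: a channels x samples monopolar EMG
matrix acquired from one or more 2-D electrode grids, a synchronized torque
trace in %MVC, and trial metadata (task, target effort level, protocol phase).
Recordings are persisted as a JSON sidecar plus raw little-endian float32
matrices (no standard HD-EMG container exists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, IntegrityError, ParameterError

TASKS = ("flexion", "extension", "supination", "pronation")
LEVELS = (0.10, 0.30, 0.50)
PHASES = ("submaximal", "time_effect_source", "endurance")

#: canonical order of the five monitored muscles (feature vectors follow it)
MUSCLE_ORDER = (
    "biceps_brachii",
    "triceps_brachii",
    "anconeus",
    "brachioradialis",
    "pronator_teres",
)


@dataclass(frozen=True)
class ArrayGeometry:
    """A rectangular electrode grid and its muscle-region column ranges.

    Grid coordinates are 1-based (row, col); flat channel indices are
    0-based row-major. ``muscle_regions`` maps muscle labels to inclusive
    1-based column ranges; ranges must be disjoint.
    """

    name: str
    rows: int
    cols: int
    pitch_mm: float = 10.0
    muscle_regions: tuple[tuple[str, tuple[int, int]], ...] = ()

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ParameterError("grid must be at least 2x2")
        if self.pitch_mm <= 0:
            raise ParameterError("electrode pitch must be positive")
        covered: set[int] = set()
        for muscle, (lo, hi) in self.muscle_regions:
            if not (1 <= lo <= hi <= self.cols):
                raise ParameterError(
                    f"column range {lo}..{hi} of {muscle!r} outside [1, {self.cols}]"
                )
            cols = set(range(lo, hi + 1))
            if covered & cols:
                raise ParameterError(f"muscle region {muscle!r} overlaps another region")
            covered |= cols

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_index(self, row: int, col: int) -> int:
        """Flat 0-based channel index of 1-based grid cell (row, col)."""
        if not (1 <= row <= self.rows and 1 <= col <= self.cols):
            raise ParameterError(
                f"(row, col) = ({row}, {col}) outside {self.rows}x{self.cols} grid"
            )
        return (row - 1) * self.cols + (col - 1)

    def grid_position(self, index: int) -> tuple[int, int]:
        """Inverse of :meth:`channel_index`."""
        if not (0 <= index < self.n_channels):
            raise ParameterError(f"flat index {index} outside grid")
        return index // self.cols + 1, index % self.cols + 1

    def region_shape(self, muscle: str) -> tuple[int, int]:
        lo, hi = dict(self.muscle_regions)[muscle]
        return self.rows, hi - lo + 1

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rows": self.rows,
            "cols": self.cols,
            "pitch_mm": self.pitch_mm,
            "muscle_regions": [[m, list(rng)] for m, rng in self.muscle_regions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayGeometry":
        return cls(
            name=d["name"],
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            pitch_mm=float(d.get("pitch_mm", 10.0)),
            muscle_regions=tuple(
                (m, (int(lo), int(hi))) for m, (lo, hi) in d.get("muscle_regions", [])
            ),
        )


def default_geometries() -> tuple[ArrayGeometry, ...]:
    """The three-array layout: A1 over the forearm (three muscles on one
    6x16 grid, default column split 1-5 / 6-11 / 12-16, configurable), A2
    (6x12) over biceps brachii, A3 (6x12) over triceps brachii. 240
    channels in total."""
    a1 = ArrayGeometry(
        "A1", 6, 16,
        muscle_regions=(
            ("anconeus", (1, 5)),
            ("brachioradialis", (6, 11)),
            ("pronator_teres", (12, 16)),
        ),
    )
    a2 = ArrayGeometry("A2", 6, 12, muscle_regions=(("biceps_brachii", (1, 12)),))
    a3 = ArrayGeometry("A3", 6, 12, muscle_regions=(("triceps_brachii", (1, 12)),))
    return (a1, a2, a3)


def channel_index(geometry: ArrayGeometry, row: int, col: int) -> int:
    return geometry.channel_index(row, col)


@dataclass
class Recording:
    """One trial: monopolar EMG, synchronized torque, and metadata.

    ``signals`` is channels x samples in mV; ``torque`` is per-sample in
    %MVC on the same time base; ``target_level`` is a fraction of MVC
    (0.10 / 0.30 / 0.50) or None for rest / endurance trials without a
    nominal submaximal target.
    """

    signals: np.ndarray
    fs: float
    geometries: tuple[ArrayGeometry, ...]
    torque: np.ndarray
    task: str
    target_level: float | None = None
    phase: str = "submaximal"
    mvc: dict[str, float] = field(default_factory=dict)
    rec_id: str = ""

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.torque = np.asarray(self.torque, dtype=np.float64)
        self.geometries = tuple(self.geometries)
        self.validate()

    def validate(self) -> None:
        if self.signals.ndim != 2:
            raise IntegrityError("signals must be a 2-D channels x samples matrix")
        n_expected = sum(g.n_channels for g in self.geometries)
        if self.signals.shape[0] != n_expected:
            raise IntegrityError(
                f"{self.signals.shape[0]} signal rows but geometries declare {n_expected}"
            )
        if self.torque.shape != (self.signals.shape[1],):
            raise IntegrityError("torque and signals must share one time base")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.task not in TASKS + ("rest",):
            raise ParameterError(f"unknown task {self.task!r}")
        if self.target_level is not None and not any(
            abs(self.target_level - lv) < 1e-9 for lv in LEVELS
        ):
            raise ParameterError(f"target_level must be one of {LEVELS} or None")
        if self.phase not in PHASES:
            raise ParameterError(f"unknown phase {self.phase!r}")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def muscles(self) -> tuple[str, ...]:
        found = [m for g in self.geometries for m, _ in g.muscle_regions]
        return tuple(m for m in MUSCLE_ORDER if m in found) + tuple(
            m for m in found if m not in MUSCLE_ORDER
        )

    def muscle_channel_grid(self, muscle: str) -> np.ndarray:
        """Rows x region-cols array of flat channel indices for ``muscle``."""
        offset = 0
        for geom in self.geometries:
            regions = dict(geom.muscle_regions)
            if muscle in regions:
                lo, hi = regions[muscle]
                idx = np.empty((geom.rows, hi - lo + 1), dtype=np.intp)
                for r in range(1, geom.rows + 1):
                    for c in range(lo, hi + 1):
                        idx[r - 1, c - lo] = offset + geom.channel_index(r, c)
                return idx
            offset += geom.n_channels
        raise ParameterError(f"muscle {muscle!r} not found in any geometry")

    def with_signals(self, signals: np.ndarray) -> "Recording":
        return replace(self, signals=signals)


def save_bundle(recording: Recording, path: str | Path) -> Path:
    """Write a recording bundle: ``<path>.json`` sidecar + ``<path>.f32``
    raw float32 channel-major matrix + ``<path>.torque.f32``."""
    if recording.n_samples == 0:
        raise FormatError("refusing to save an empty recording")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": recording.fs,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "geometries": [g.to_dict() for g in recording.geometries],
        "task": recording.task,
        "target_level": recording.target_level,
        "phase": recording.phase,
        "mvc": recording.mvc,
        "rec_id": recording.rec_id or path.name,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    recording.signals.astype("<f4").tofile(path.with_suffix(".f32"))
    recording.torque.astype("<f4").tofile(path.with_suffix(".torque.f32"))
    return path


def load_bundle(path: str | Path) -> Recording:
    """Load a bundle written by :func:`save_bundle`, validating integrity."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    raw = np.fromfile(path.with_suffix(".f32"), dtype="<f4")
    if raw.size != n_ch * n_s:
        raise IntegrityError(
            f"matrix holds {raw.size} values, metadata declares {n_ch}x{n_s}"
        )
    torque = np.fromfile(path.with_suffix(".torque.f32"), dtype="<f4")
    if torque.size != n_s:
        raise IntegrityError("torque length does not match metadata")
    return Recording(
        signals=raw.reshape(n_ch, n_s),
        fs=float(meta["fs"]),
        geometries=tuple(ArrayGeometry.from_dict(g) for g in meta["geometries"]),
        torque=torque,
        task=meta["task"],
        target_level=meta["target_level"],
        phase=meta["phase"],
        mvc={k: float(v) for k, v in meta.get("mvc", {}).items()},
        rec_id=meta.get("rec_id", path.name),
    )


@dataclass
class SessionDataset:
    """All recordings of one subject's session, with set membership tags."""

    recordings: list[Recording]
    subject_id: str = "synthetic"

    @property
    def set_tags(self) -> list[str]:
        return [
            "endurance" if r.phase == "endurance" else "submaximal"
            for r in self.recordings
        ]

    @property
    def submaximal(self) -> list[Recording]:
        return [r for r in self.recordings if r.phase == "submaximal"]

    @property
    def endurance(self) -> list[Recording]:
        return [r for r in self.recordings if r.phase == "endurance"]

    def get(self, rec_id: str) -> Recording:
        for r in self.recordings:
            if r.rec_id == rec_id:
                return r
        raise KeyError(rec_id)


def save_session(session: SessionDataset, directory: str | Path) -> Path:
    """Write every recording bundle plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(session.recordings):
        name = rec.rec_id or f"rec{i:02d}"
        save_bundle(rec, directory / name)
        entries.append({"bundle": name, "set": session.set_tags[i]})
    manifest = directory / "manifest.json"
    manifest.write_text(
        json.dumps({"subject_id": session.subject_id, "recordings": entries}, indent=1)
    )
    return manifest


def load_session(manifest_path: str | Path) -> SessionDataset:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    recs = [
        load_bundle(manifest_path.parent / e["bundle"]) for e in meta["recordings"]
    ]
    return SessionDataset(recordings=recs, subject_id=meta.get("subject_id", ""))
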