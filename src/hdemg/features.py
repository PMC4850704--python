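"""Feature extraction from activation maps and raw channel windows.

Three feature sets feed the classifier, each concatenated over the five
monitored muscles in canonical order:

* ``I``     — log10 mean map intensity, one value per muscle (5 features).
  The logarithm linearises the non-linear EMG-amplitude/force relationship.
* ``I+CG``  — intensity plus the intensity-weighted centroid (row, col) of
  the map in 1-based electrode-pitch units (15 features).
* ``Diff``  — log10 RMS of a single differential channel: the difference of
  two adjacent channels along the fiber direction, the conventional bipolar
  gold standard (5 features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedFeatureError
from .mapping import ActivationMap, compute_maps, window_span
from .recording import MUSCLE_ORDER, Recording

FEATURE_SETS = ("I", "I+CG", "Diff")
#: floor for logarithms of near-silent windows, in mV
LOG_EPS = 1e-6


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    feature_set: str
    muscle_order: tuple[str, ...]
    class_label: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature values must be finite")
        expected = {"I": 1, "I+CG": 3, "Diff": 1}[self.feature_set] * len(
            self.muscle_order
        )
        if self.values.shape != (expected,):
            raise ParameterError(
                f"{self.feature_set} over {len(self.muscle_order)} muscles "
                f"needs {expected} values, got {self.values.shape}"
            )


def intensity(amap: ActivationMap, eps: float = LOG_EPS) -> float:
    """I = log10 of the mean map intensity, clamped at ``eps`` mV."""
    if np.any(amap.values < 0):
        raise ParameterError("map intensities must be non-negative")
    mean = float(np.mean(amap.values))
    return float(np.log10(max(mean, eps)))


def center_of_gravity(amap: ActivationMap) -> tuple[float, float]:
    """Intensity-weighted mean (row, col) in 1-based electrode-index units."""
    total = float(np.sum(amap.values))
    if total <= 0:
        raise UndefinedFeatureError("center of gravity undefined for an all-zero map")
    rows, cols = amap.values.shape
    i = np.arange(1, rows + 1)[:, None]
    j = np.arange(1, cols + 1)[None, :]
    return (
        float(np.sum(amap.values * i) / total),
        float(np.sum(amap.values * j) / total),
    )


def default_diff_site(grid_shape: tuple[int, int]) -> tuple[int, int]:
    """Middle row, central column of the muscle region (1-based); the pair
    is (site, site + one row along the fiber direction)."""
    rows, cols = grid_shape
    return max(1, rows // 2), (cols + 1) // 2


def single_differential(
    recording: Recording,
    muscle: str,
    span: tuple[int, int],
    site: tuple[int, int] | None = None,
    eps: float = LOG_EPS,
) -> float:
    """Diff = log10 RMS of the difference of channels (i, j) and (i+1, j)
    of the muscle region over the given sample span."""
    grid = recording.muscle_channel_grid(muscle)
    rows, cols = grid.shape
    r, c = site if site is not None else default_diff_site((rows, cols))
    if not (1 <= r < rows and 1 <= c <= cols):
        raise ParameterError(
            f"differential site ({r}, {c}) has no fiber-direction neighbour "
            f"in a {rows}x{cols} region"
        )
    a, b = span
    d = (
        recording.signals[grid[r - 1, c - 1], a:b]
        - recording.signals[grid[r, c - 1], a:b]
    )
    rms = float(np.sqrt(np.mean(d**2)))
    return float(np.log10(max(rms, eps)))


def build_vector(
    maps: dict[str, ActivationMap],
    feature_set: str,
    recording: Recording | None = None,
    diff_sites: dict[str, tuple[int, int]] | None = None,
    class_label: str = "",
    eps: float = LOG_EPS,
) -> FeatureVector:
    """Concatenate per-muscle features in canonical muscle order.

    ``maps`` holds one map per muscle for a common window. Diff requires the
    raw recording since it acts on the unaveraged channel pair over the same
    window span as the maps.
    """
    if feature_set not in FEATURE_SETS:
        raise ParameterError(f"unknown feature set {feature_set!r}")
    expected = recording.muscles if recording is not None else tuple(maps)
    missing = [m for m in expected if m not in maps]
    if missing:
        raise ParameterError(f"missing maps for muscles {missing}")
    order = tuple(m for m in MUSCLE_ORDER if m in maps) + tuple(
        sorted(m for m in maps if m not in MUSCLE_ORDER)
    )
    vals: list[float] = []
    for muscle in order:
        amap = maps[muscle]
        if feature_set == "I":
            vals.append(intensity(amap, eps))
        elif feature_set == "I+CG":
            try:
                cg = center_of_gravity(amap)
            except UndefinedFeatureError:
                # near-silent window: fall back to the grid centroid
                rows, cols = amap.values.shape
                cg = ((rows + 1) / 2, (cols + 1) / 2)
            vals.extend((intensity(amap, eps), cg[0], cg[1]))
        else:  # Diff
            if recording is None:
                raise ParameterError("Diff features need the raw recording")
            site = (diff_sites or {}).get(muscle)
            vals.append(
                single_differential(recording, muscle, amap.window_span, site, eps)
            )
    return FeatureVector(np.array(vals), feature_set, order, class_label)


def feature_table(
    recording: Recording,
    window_indices: list[int],
    feature_set: str,
    labels: list[str] | None = None,
    window_s: float = 0.250,
    diff_sites: dict[str, tuple[int, int]] | None = None,
    maps: dict[str, list[ActivationMap]] | None = None,
) -> pd.DataFrame:
    """One row per epoch: metadata columns then the feature columns.

    ``maps`` may be passed to reuse precomputed activation maps; otherwise
    they are computed here on the standard window grid.
    """
    maps = maps if maps is not None else compute_maps(recording, window_s)
    labels = labels or [recording.task] * len(window_indices)
    rows = []
    for w, lab in zip(window_indices, labels):
        per_muscle = {m: seq[w] for m, seq in maps.items()}
        fv = build_vector(per_muscle, feature_set, recording, diff_sites, lab)
        a, b = window_span(w, recording.fs, window_s)
        rows.append(
            {
                "rec_id": recording.rec_id,
                "task": recording.task,
                "target_level": recording.target_level,
                "phase": recording.phase,
                "window_index": w,
                "span_start": a,
                "span_end": b,
                "label": lab,
                **{f"f{k}": v for k, v in enumerate(fv.values)},
            }
        )
    return pd.DataFrame(rows)
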