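"""HD-EMG activation maps: per-muscle grids of windowed RMS intensity.

Each map cell HM(i, j) is the RMS of channel (i, j) over one non-overlapping
analysis window (default 250 ms). Artifact channels are repaired on the map
(intensity domain) by triangle-based cubic interpolation over good cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator

from .errors import InsufficientDataError, InterpolationError, ParameterError
from .recording import Recording

DEFAULT_WINDOW_S = 0.250


@dataclass(frozen=True)
class ActivationMap:
    """One muscle's intensity image over one analysis window."""

    values: np.ndarray          # rows x region-cols, mV RMS, >= 0
    muscle: str
    window_index: int
    window_span: tuple[int, int]  # half-open sample indices

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ParameterError("map values must be a 2-D grid")
        if np.any(self.values < 0):
            raise ParameterError("map intensities must be non-negative")


def window_count(n_samples: int, fs: float, window_s: float = DEFAULT_WINDOW_S) -> int:
    return n_samples // window_length(fs, window_s)


def window_length(fs: float, window_s: float = DEFAULT_WINDOW_S) -> int:
    if window_s <= 0:
        raise ParameterError("window length must be positive")
    return int(round(window_s * fs))


def window_span(index: int, fs: float, window_s: float = DEFAULT_WINDOW_S) -> tuple[int, int]:
    w = window_length(fs, window_s)
    return index * w, (index + 1) * w


def compute_maps(
    recording: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    muscles: tuple[str, ...] | None = None,
) -> dict[str, list[ActivationMap]]:
    """RMS activation maps on non-overlapping windows aligned to sample 0.

    Returns one map sequence per muscle; a trailing partial window is
    discarded. Windows are indexed from 0 so epoch selection and feature
    extraction address identical spans.
    """
    w = window_length(recording.fs, window_s)
    if w > recording.n_samples:
        raise InsufficientDataError(
            f"window of {w} samples exceeds recording of {recording.n_samples}"
        )
    n_win = recording.n_samples // w
    muscles = muscles or recording.muscles
    out: dict[str, list[ActivationMap]] = {}
    for muscle in muscles:
        idx = recording.muscle_channel_grid(muscle)
        rows, cols = idx.shape
        x = recording.signals[idx.ravel(), : n_win * w]
        rms = np.sqrt(
            np.mean(x.reshape(rows * cols, n_win, w) ** 2, axis=2)
        ).reshape(rows, cols, n_win)
        out[muscle] = [
            ActivationMap(rms[:, :, k], muscle, k, (k * w, (k + 1) * w))
            for k in range(n_win)
        ]
    return out


def interpolate_bad(amap: ActivationMap, bad: set[tuple[int, int]]) -> ActivationMap:
    """Replace bad cells by Delaunay-triangle cubic interpolation.

    ``bad`` holds 1-based (row, col) grid cells. Cells outside the convex
    hull of the good cells fall back to nearest-neighbour. Good cells are
    never altered.
    """
    if not bad:
        return amap
    rows, cols = amap.values.shape
    bad0 = {(r - 1, c - 1) for r, c in bad}
    for r, c in bad0:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ParameterError(f"bad cell {(r + 1, c + 1)} outside grid")
    mask = np.zeros((rows, cols), dtype=bool)
    for r, c in bad0:
        mask[r, c] = True
    good_pts = np.argwhere(~mask)
    if good_pts.shape[0] == 0:
        raise InterpolationError("all cells flagged bad; nothing to interpolate from")
    good_vals = amap.values[~mask]
    bad_pts = np.argwhere(mask)

    filled = np.full(bad_pts.shape[0], np.nan)
    if good_pts.shape[0] >= 4 and np.linalg.matrix_rank(good_pts - good_pts[0]) == 2:
        ct = CloughTocher2DInterpolator(good_pts.astype(float), good_vals)
        filled = ct(bad_pts.astype(float))
    nn_needed = np.isnan(filled)
    if np.any(nn_needed):
        nn = NearestNDInterpolator(good_pts.astype(float), good_vals)
        filled[nn_needed] = nn(bad_pts[nn_needed].astype(float))

    values = amap.values.copy()
    values[mask] = np.maximum(filled, 0.0)  # RMS intensities stay non-negative
    return replace(amap, values=values)
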