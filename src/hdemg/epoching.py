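"""Torque-guided epoch selection and endurance segmentation.

Analysis epochs are the 250 ms map windows. For submaximal contractions the
torque trace gates the candidates: a window qualifies if its mean torque
stays within +-5 %MVC of a 10 %MVC target, or +-10 %MVC of a 30 or 50 %MVC
target; the 20 candidates closest to the target are kept. Rest (no-activity)
epochs come from the 3 s rest prefix of each recording. Endurance
contractions are segmented into quintiles of the total duration of
contraction (TDC) for the fatigue analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientEpochsError, ParameterError, SegmentationError
from .mapping import DEFAULT_WINDOW_S, window_length
from .recording import Recording

logger = logging.getLogger(__name__)

REST_PREFIX_S = 3.0
#: half-width of the admissible torque band per target level, in %MVC
TORQUE_BANDS = {0.10: 5.0, 0.30: 10.0, 0.50: 10.0}
NOACT_LABEL = "NoAct"


@dataclass(frozen=True)
class Epoch:
    rec_id: str
    window_index: int
    label: str


@dataclass
class EpochSet:
    epochs: list[Epoch]
    scheme: str = "task5"
    balanced: bool = False

    def __len__(self) -> int:
        return len(self.epochs)

    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]

    def by_recording(self) -> dict[str, list[Epoch]]:
        out: dict[str, list[Epoch]] = {}
        for e in self.epochs:
            out.setdefault(e.rec_id, []).append(e)
        return out


def _window_means(x: np.ndarray, w: int) -> np.ndarray:
    n_win = x.size // w
    return x[: n_win * w].reshape(n_win, w).mean(axis=1)


def select_submax_epochs(
    recording: Recording,
    n: int = 20,
    window_s: float = DEFAULT_WINDOW_S,
) -> EpochSet:
    """The ``n`` non-overlapping windows whose mean torque is closest to the
    target level, among windows inside the admissible band.

    Distance is |window-mean torque - target| in %MVC; ties break toward the
    earlier window. Raises InsufficientEpochsError (with the shortfall) if
    fewer than ``n`` windows qualify.
    """
    if recording.target_level is None:
        raise ParameterError("recording has no submaximal target level")
    band = TORQUE_BANDS[round(recording.target_level, 2)]
    target = 100.0 * recording.target_level
    w = window_length(recording.fs, window_s)
    means = _window_means(recording.torque, w)
    dist = np.abs(means - target)
    candidates = np.flatnonzero(dist <= band)
    if candidates.size < n:
        raise InsufficientEpochsError(n, int(candidates.size))
    # stable sort on distance => ties broken by earlier start time
    chosen = candidates[np.argsort(dist[candidates], kind="stable")][:n]
    label = f"{recording.task}@{int(round(100 * recording.target_level))}"
    return EpochSet(
        [Epoch(recording.rec_id, int(k), label) for k in sorted(chosen)],
        scheme="task_level13",
    )


def select_rest_epochs(
    recordings: list[Recording],
    n_total: int = 60,
    window_s: float = DEFAULT_WINDOW_S,
    mode: str = "lowest",
    seed: int | None = None,
    rest_s: float = REST_PREFIX_S,
) -> EpochSet:
    """``n_total`` no-activity epochs from the rest prefixes of a set of
    recordings.

    Candidates are windows lying entirely within the first ``rest_s`` seconds
    of each recording. ``mode='lowest'`` (default) ranks them by mean
    absolute torque ascending, ties broken by recording order then time;
    ``mode='random'`` draws uniformly with the given seed.
    """
    candidates: list[tuple[float, int, int, Epoch]] = []
    for r_idx, rec in enumerate(recordings):
        w = window_length(rec.fs, window_s)
        n_rest = min(int(rest_s * rec.fs), rec.torque.size) // w
        if n_rest == 0:
            warnings.warn(
                f"recording {rec.rec_id!r} has no rest prefix; excluded", stacklevel=2
            )
            continue
        means = np.abs(_window_means(rec.torque[: n_rest * w], w))
        for k in range(n_rest):
            candidates.append(
                (float(means[k]), r_idx, k, Epoch(rec.rec_id, k, NOACT_LABEL))
            )
    if len(candidates) < n_total:
        raise InsufficientEpochsError(n_total, len(candidates))
    if mode == "random":
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(candidates), size=n_total, replace=False)
        chosen = [candidates[i] for i in sorted(picks)]
    elif mode == "lowest":
        chosen = sorted(candidates, key=lambda c: (c[0], c[1], c[2]))[:n_total]
    else:
        raise ParameterError(f"unknown rest-selection mode {mode!r}")
    return EpochSet([c[3] for c in chosen], scheme="task5")


def contraction_windows(
    recording: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    rest_s: float = REST_PREFIX_S,
) -> list[int]:
    """Indices of complete windows starting at or after the rest prefix."""
    w = window_length(recording.fs, window_s)
    n_win = recording.n_samples // w
    first = int(np.ceil(rest_s * recording.fs / w))
    return list(range(first, n_win))


def tdc_segments(
    recording: Recording,
    k: int = 5,
    window_s: float = DEFAULT_WINDOW_S,
    rest_s: float = REST_PREFIX_S,
) -> list[list[int]]:
    """Split the contraction windows into ``k`` contiguous equal-count
    segments of the total duration of contraction; remainder windows go to
    the last segment. Segment 0 covers 0-20 % TDC for k=5."""
    wins = contraction_windows(recording, window_s, rest_s)
    if len(wins) < k:
        raise SegmentationError(
            f"{len(wins)} contraction windows cannot form {k} segments"
        )
    per = len(wins) // k
    segments = [wins[i * per : (i + 1) * per] for i in range(k - 1)]
    segments.append(wins[(k - 1) * per :])
    return segments


def time_effect_subset(
    recording: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    rest_s: float = REST_PREFIX_S,
) -> EpochSet:
    """Epochs of the first TDC quintile (0-20 %), labeled with the task."""
    seg = tdc_segments(recording, 5, window_s, rest_s)[0]
    return EpochSet(
        [Epoch(recording.rec_id, w, recording.task) for w in seg], scheme="task5"
    )
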