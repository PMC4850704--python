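"""Channel-quality screening, band-pass filtering and power-line suppression.

Processing order: screening on the raw monopolar signals, zero-phase
Butterworth band-pass (15-350 Hz, 4th order design applied forward-backward),
then adaptive least-mean-squares cancellation of the power-line fundamental
and its harmonics using sine/cosine reference pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import AdaptationError, InsufficientDataError, ParameterError
from .recording import Recording

DEFAULT_BAND = (15.0, 350.0)
DEFAULT_ORDER = 4
DEFAULT_LINE_FREQ = 50.0
#: harmonics suppressed by the canceller (the screening stage inspects only
#: the fundamental plus four harmonics; the two stages intentionally differ)
DEFAULT_N_HARMONICS = 6
DEFAULT_LMS_STEP = 1e-3


@dataclass(frozen=True)
class QualityThresholds:
    """Screening thresholds. Relative powers are fractions of total power;
    the RMS-derived power bounds are in mV^2. Defaults are calibration
    knobs — the original expert-system thresholds are not published."""

    max_lowfreq_rel_power: float = 0.25
    max_powerline_rel_power: float = 0.50
    rms_power_bounds: tuple[float, float] = (1e-4, 25.0)

    def __post_init__(self):
        lo, hi = self.rms_power_bounds
        if min(self.max_lowfreq_rel_power, self.max_powerline_rel_power, lo, hi) <= 0:
            raise ParameterError("all thresholds must be positive")
        if lo >= hi:
            raise ParameterError("rms_power_bounds must satisfy low < high")


@dataclass
class ChannelQualityReport:
    good: np.ndarray              # bool per channel
    lowfreq_rel_power: np.ndarray
    powerline_rel_power: np.ndarray
    rms_power: np.ndarray
    thresholds: QualityThresholds

    @property
    def artifact_channels(self) -> np.ndarray:
        return np.flatnonzero(~self.good)


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (freqs >= lo) & (freqs <= hi)
    return psd[:, mask].sum(axis=1)


def screen_channels(
    recording: Recording | np.ndarray,
    thresholds: QualityThresholds | None = None,
    fs: float | None = None,
    line_freq: float = DEFAULT_LINE_FREQ,
) -> ChannelQualityReport:
    """Flag artifact channels from three spectral features.

    A channel is an artifact iff its relative power below 12 Hz exceeds the
    threshold, its relative power within +-1 Hz of the line fundamental and
    first four harmonics exceeds the threshold, or its mean-square power
    falls outside the admissible bounds.
    """
    thresholds = thresholds or QualityThresholds()
    if isinstance(recording, Recording):
        x, fs = recording.signals, recording.fs
    else:
        x = np.atleast_2d(np.asarray(recording, dtype=float))
        if fs is None:
            raise ParameterError("fs required when passing a raw matrix")
    if x.shape[1] < fs:
        raise InsufficientDataError("screening needs at least 1 s of signal")

    nper = int(min(x.shape[1], 4 * fs))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nper, detrend=False)
    total = psd.sum(axis=1)
    total = np.where(total > 0, total, np.finfo(float).tiny)

    low_rel = _band_power(freqs, psd, 0.0, 12.0) / total
    line = np.zeros(x.shape[0])
    for k in range(1, 6):  # fundamental + first four harmonics
        f0 = k * line_freq
        if f0 >= fs / 2:
            break
        line += _band_power(freqs, psd, f0 - 1.0, f0 + 1.0)
    line_rel = line / total
    rms_power = np.mean(x**2, axis=1)

    lo, hi = thresholds.rms_power_bounds
    good = (
        (low_rel <= thresholds.max_lowfreq_rel_power)
        & (line_rel <= thresholds.max_powerline_rel_power)
        & (rms_power >= lo)
        & (rms_power <= hi)
    )
    return ChannelQualityReport(good, low_rel, line_rel, rms_power, thresholds)


def bandpass(
    signals: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied forward-backward per channel."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ParameterError(f"band {band} must satisfy 0 < low < high < fs/2")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signals, dtype=float), axis=-1)


def suppress_powerline(
    signals: np.ndarray,
    fs: float,
    line_freq: float = DEFAULT_LINE_FREQ,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    step: float = DEFAULT_LMS_STEP,
) -> np.ndarray:
    """Adaptive transversal cancellation of power-line harmonics.

    Each channel is modelled as EMG plus a sum of sinusoids at k*line_freq.
    Unit-variance sine/cosine reference pairs at each harmonic are combined
    with per-channel weights updated by least mean squares; the estimated
    interference is subtracted. Raises AdaptationError on divergence
    (running output power exceeding 10x the input power).
    """
    if step <= 0:
        raise AdaptationError("LMS step must be positive")
    if n_harmonics * line_freq >= fs / 2:
        raise ParameterError("highest harmonic must lie below Nyquist")
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_s = x.shape
    t = np.arange(n_s) / fs
    # unit-variance references: sqrt(2) * sin/cos
    refs = np.empty((2 * n_harmonics, n_s))
    for k in range(n_harmonics):
        w0 = 2 * np.pi * (k + 1) * line_freq
        refs[2 * k] = np.sqrt(2.0) * np.sin(w0 * t)
        refs[2 * k + 1] = np.sqrt(2.0) * np.cos(w0 * t)

    weights = np.zeros((n_ch, 2 * n_harmonics))
    out = np.empty_like(x)
    in_power = np.mean(x**2) + np.finfo(float).tiny
    acc = 0.0
    check_every = max(1, int(fs))
    with np.errstate(over="ignore", invalid="ignore"):
        for n in range(n_s):
            r = refs[:, n]
            y = weights @ r
            e = x[:, n] - y
            out[:, n] = e
            weights += step * np.outer(e, r)
            acc += float(np.mean(e**2))
            if (n + 1) % check_every == 0:
                m = acc / (n + 1)
                if not np.isfinite(m) or m > 10.0 * in_power:
                    raise AdaptationError("LMS canceller diverged; reduce the step")
        total = np.mean(out**2)
    if not np.isfinite(total) or total > 10.0 * in_power:
        raise AdaptationError("LMS canceller diverged; reduce the step")
    return out if signals.ndim == 2 else out[0]


def preprocess_recording(
    recording: Recording,
    thresholds: QualityThresholds | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
    line_freq: float = DEFAULT_LINE_FREQ,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    lms_step: float = DEFAULT_LMS_STEP,
    line_suppression: bool = True,
) -> tuple[Recording, ChannelQualityReport]:
    """Screen, band-pass, and (optionally) line-cancel a recording.

    Returns the filtered recording and the channel-quality report; artifact
    channels are carried in the report and interpolated later at the map
    stage.
    """
    report = screen_channels(recording, thresholds, line_freq=line_freq)
    filtered = bandpass(recording.signals, recording.fs, band, order)
    if line_suppression:
        filtered = suppress_powerline(
            filtered, recording.fs, line_freq, n_harmonics, lms_step
        )
    return recording.with_signals(filtered), report
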