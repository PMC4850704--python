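"""Synthetic HD-EMG session generator.

The generative model: each muscle carries one band-limited (15-350 Hz)
Gaussian source process shared by all channels of its grid region, weighted
by a 2-D Gaussian spatial profile whose center and gain depend on the
(muscle, task) pair; the gain scales with effort level by a power law
(exponent 0.7, encoding the non-linear EMG-amplitude/force relationship).
Channels add independent instrumentation noise and optional power-line
harmonics. Each trial is 3 s of rest (sources silent) followed by the
contraction; endurance trials add myoelectric-fatigue drift (amplitude
growth plus compression of the source spectrum toward low frequencies as
the contraction progresses) and optional gel-drying drift (slowly varying
per-channel multiplicative gain). Torque is the target %MVC plus smooth
noise small enough to stay inside the epoching bands.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .recording import (
    LEVELS,
    TASKS,
    ArrayGeometry,
    Recording,
    SessionDataset,
    default_geometries,
)

#: physiologically motivated base gains (mV source RMS at 100 % MVC) of each
#: muscle in each task: elbow flexion drives biceps + brachioradialis,
#: extension drives triceps + anconeus, supination mainly biceps,
#: pronation mainly pronator teres. Non-prime movers keep a substantial
#: co-activation floor — task-specific *co-activation patterns*, not
#: isolated recruitment, are what distinguishes the classes in impaired
#: motor control.
DEFAULT_GAINS: dict[tuple[str, str], float] = {}
for _task, _g in {
    "flexion": dict(biceps_brachii=0.60, brachioradialis=0.50, anconeus=0.18,
                    triceps_brachii=0.15, pronator_teres=0.25),
    "extension": dict(biceps_brachii=0.15, brachioradialis=0.20, anconeus=0.45,
                      triceps_brachii=0.60, pronator_teres=0.18),
    "supination": dict(biceps_brachii=0.45, brachioradialis=0.30, anconeus=0.20,
                       triceps_brachii=0.15, pronator_teres=0.22),
    "pronation": dict(biceps_brachii=0.20, brachioradialis=0.35, anconeus=0.18,
                      triceps_brachii=0.16, pronator_teres=0.50),
}.items():
    for _m, _v in _g.items():
        DEFAULT_GAINS[(_m, _task)] = _v

#: per-task offsets (rows, cols) of the source center from the region
#: centroid, in electrode pitches — tasks recruit different muscle territory
TASK_CENTER_OFFSETS = {
    "flexion": (-1.0, -1.0),
    "extension": (-1.0, 1.0),
    "supination": (1.0, -1.0),
    "pronation": (1.0, 1.0),
}


def default_source_centers(
    geometries: tuple[ArrayGeometry, ...],
    tasks: tuple[str, ...] = TASKS,
    scale: float = 1.0,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Task-specific source centers: region centroid plus a symmetric
    per-task offset, clamped one pitch inside the region edges."""
    centers = {}
    for geom in geometries:
        for muscle, (lo, hi) in geom.muscle_regions:
            rows, cols = geom.rows, hi - lo + 1
            cr, cc = (rows + 1) / 2, (cols + 1) / 2
            for task in tasks:
                dr, dc = TASK_CENTER_OFFSETS.get(task, (0.0, 0.0))
                r = float(np.clip(cr + scale * dr, 2.0, rows - 1.0))
                c = float(np.clip(cc + scale * dc, 2.0, cols - 1.0))
                centers[(muscle, task)] = (r, c)
    return centers


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of a synthetic session."""

    seed: int = 0
    fs: float = 2048.0
    geometries: tuple[ArrayGeometry, ...] = field(default_factory=default_geometries)
    tasks: tuple[str, ...] = TASKS
    levels: tuple[float, ...] = LEVELS
    rest_s: float = 3.0
    submax_s: float = 10.0
    endurance_s: float = 60.0
    endurance_level: float = 0.50
    band: tuple[float, float] = (15.0, 350.0)
    source_centers: dict[tuple[str, str], tuple[float, float]] | None = None
    source_gains: dict[tuple[str, str], float] | None = None
    level_exponent: float = 0.7
    rest_gain: float = 0.0
    sigma: float = 1.5            # spatial spread in electrode pitches
    noise_mv: float = 0.02        # per-channel noise RMS
    line_freq: float = 50.0
    line_amps: tuple[float, ...] = ()   # mV per harmonic; empty = clean mains
    torque_noise_pct: float = 1.0       # smooth torque noise SD, %MVC
    rest_torque_noise_pct: float = 0.3
    effort_fluctuation: float = 0.12    # CV of slow per-muscle amplitude wander
    fatigue_gain_slope: float = 0.0     # fractional gain growth over full TDC
    fatigue_compression: float = 0.0    # fractional upper-cutoff shrink over TDC
    fatigue_spread_growth: float = 0.0  # fractional widening of sigma over TDC
    gel_sigma: float = 0.0              # per-channel log-gain SD, part 2 only
    gel_walk_sigma: float = 0.0         # log-gain random-walk step SD (4 Hz nodes)
    artifacts: tuple[tuple[int, str], ...] = ()  # (flat channel, kind)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("spatial spread sigma must be positive")
        if self.level_exponent <= 0:
            raise ParameterError("level->gain law must be strictly increasing")
        if any(g < 0 for g in (self.source_gains or {}).values()):
            raise ParameterError("source gains must be non-negative")

    def centers(self) -> dict[tuple[str, str], tuple[float, float]]:
        return self.source_centers or default_source_centers(
            self.geometries, self.tasks
        )

    def gains(self) -> dict[tuple[str, str], float]:
        return self.source_gains or dict(DEFAULT_GAINS)

    def level_gain(self, level: float) -> float:
        return float(level**self.level_exponent)


@dataclass
class GroundTruth:
    rec_id: str
    task: str
    level: float | None
    phase: str
    centers: dict[str, tuple[float, float]]
    gains: dict[str, float]
    artifacts: tuple[tuple[int, str], ...] = ()
    fatigue: dict | None = None
    gel_drift: bool = False


def _smooth_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass (2 Hz) Gaussian noise with the requested SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    w = rng.standard_normal(n + int(fs))
    sos = sps.butter(2, min(2.0, 0.4 * fs / 2), btype="low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, w)[int(fs) // 2 : int(fs) // 2 + n]
    s = x.std()
    return x / s * sd if s > 0 else np.zeros(n)


def _source_process(
    n: int,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
    compression_u: np.ndarray | None = None,
    compression: float = 0.0,
) -> np.ndarray:
    """Unit-RMS band-limited source; optional per-sample spectral compression.

    Compression narrows the upper band edge to ``hi * (1 - compression * u)``
    as the drift coordinate u goes 0 -> 1, by blending block-wise between a
    bank of progressively narrower filters. RMS is normalised against the
    *uncompressed* process, so compression also lowers amplitude (as fatigue
    narrows the EMG spectrum the differential RMS drops too).
    """
    white = rng.standard_normal(n)
    lo, hi = band
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    base = sps.sosfiltfilt(sos, white)
    scale = base.std()
    if scale == 0:
        return base
    base = base / scale
    if compression_u is None or compression <= 0:
        return base
    n_levels = 8
    bank = [base]
    for j in range(1, n_levels):
        hi_j = hi * (1 - compression * j / (n_levels - 1))
        hi_j = max(hi_j, lo * 1.5)
        sos_j = sps.butter(4, (lo, hi_j), btype="bandpass", fs=fs, output="sos")
        bank.append(sps.sosfiltfilt(sos_j, white) / scale)
    bank = np.stack(bank)  # n_levels x n
    idx = np.clip(
        np.round(compression_u * (n_levels - 1)).astype(int), 0, n_levels - 1
    )
    return bank[idx, np.arange(n)]


def _spatial_profile(
    shape: tuple[int, int], center: tuple[float, float], sigma: float
) -> np.ndarray:
    rows, cols = shape
    i = np.arange(1, rows + 1)[:, None]
    j = np.arange(1, cols + 1)[None, :]
    r0, c0 = center
    return np.exp(-((i - r0) ** 2 + (j - c0) ** 2) / (2 * sigma**2))


def simulate_recording(
    cfg: SimConfig,
    task: str,
    level: float | None,
    phase: str = "submaximal",
    seed_key: tuple[int, ...] = (0,),
    rec_id: str = "",
) -> tuple[Recording, GroundTruth]:
    """Generate one trial. ``seed_key`` disambiguates trials under one config
    seed; the RNG stream is ``SeedSequence([cfg.seed, *seed_key])``."""
    centers, gains = cfg.centers(), cfg.gains()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, *seed_key]))
    dur = cfg.endurance_s if phase == "endurance" else cfg.submax_s
    eff_level = cfg.endurance_level if phase == "endurance" else level
    n_rest = int(round(cfg.rest_s * cfg.fs))
    n_con = int(round(dur * cfg.fs))
    n = n_rest + n_con

    # drift coordinate: 0 during rest, 0 -> 1 across the contraction (TDC)
    u = np.zeros(n)
    u[n_rest:] = np.arange(n_con) / max(n_con - 1, 1)
    fatigue_active = phase == "endurance" and (
        cfg.fatigue_gain_slope > 0
        or cfg.fatigue_compression > 0
        or cfg.fatigue_spread_growth > 0
    )

    n_channels = sum(g.n_channels for g in cfg.geometries)
    signals = rng.standard_normal((n_channels, n)) * cfg.noise_mv

    # fatigue develops in the muscles doing the work: the amplitude slope of
    # each muscle scales with its relative load in this task
    task_gains = [gains[(m, task)] for g in cfg.geometries for m, _ in g.muscle_regions]
    max_gain = max(task_gains) if task_gains else 1.0

    offset = 0
    true_centers: dict[str, tuple[float, float]] = {}
    true_gains: dict[str, float] = {}
    for geom in cfg.geometries:
        for muscle, (lo_col, hi_col) in geom.muscle_regions:
            center = centers[(muscle, task)]
            rows, cols = geom.rows, hi_col - lo_col + 1
            if not (1 <= center[0] <= rows and 1 <= center[1] <= cols):
                raise ParameterError(
                    f"source center {center} outside {rows}x{cols} region of {muscle}"
                )
            g = gains[(muscle, task)] * cfg.level_gain(eff_level or 0.0)
            true_centers[muscle], true_gains[muscle] = center, g
            src = _source_process(
                n, cfg.fs, cfg.band, rng,
                compression_u=u if fatigue_active else None,
                compression=cfg.fatigue_compression if fatigue_active else 0.0,
            )
            envelope = np.full(n, cfg.rest_gain)
            envelope[n_rest:] = g
            if fatigue_active and cfg.fatigue_gain_slope > 0:
                rel_load = gains[(muscle, task)] / max_gain if max_gain > 0 else 0.0
                envelope = envelope * (1.0 + cfg.fatigue_gain_slope * rel_load * u)
            if cfg.effort_fluctuation > 0:
                # slow log-normal wander of the drive to each muscle; real
                # force-matched contractions are not amplitude-stationary
                envelope = envelope * np.exp(
                    _smooth_noise(n, cfg.fs, cfg.effort_fluctuation, rng)
                )
            drive = envelope * src
            if fatigue_active and cfg.fatigue_spread_growth > 0:
                # fatigue widens and smooths the spatial distribution: slower,
                # longer motor-unit potentials spread over more electrodes,
                # which is what erodes adjacent-channel differentials
                n_levels = 8
                lvl = np.clip(np.round(u * (n_levels - 1)).astype(int), 0, n_levels - 1)
                block = np.empty((rows * cols, n))
                for j in range(n_levels):
                    mask = lvl == j
                    if not np.any(mask):
                        continue
                    sig_j = cfg.sigma * (
                        1.0 + cfg.fatigue_spread_growth * j / (n_levels - 1)
                    )
                    w_j = _spatial_profile((rows, cols), center, sig_j)
                    block[:, mask] = w_j.reshape(-1, 1) * drive[mask][None, :]
            else:
                w = _spatial_profile((rows, cols), center, cfg.sigma)
                block = w.reshape(-1, 1) * drive[None, :]
            for r in range(rows):
                for c in range(cols):
                    ch = offset + geom.channel_index(r + 1, lo_col + c)
                    signals[ch] += block[r * cols + c]
        offset += geom.n_channels

    # power-line coupling: common phase jitter per channel, per-harmonic amps
    if cfg.line_amps:
        t = np.arange(n) / cfg.fs
        for k, amp in enumerate(cfg.line_amps, start=1):
            if amp <= 0 or k * cfg.line_freq >= cfg.fs / 2:
                continue
            phases = rng.uniform(0, 2 * np.pi, n_channels)
            scales = amp * rng.uniform(0.5, 1.5, n_channels)
            signals += scales[:, None] * np.sin(
                2 * np.pi * k * cfg.line_freq * t[None, :] + phases[:, None]
            )

    # gel-drying drift: per-channel multiplicative gain, part 2 only
    gel = phase == "endurance" and (cfg.gel_sigma > 0 or cfg.gel_walk_sigma > 0)
    if gel:
        log_gain = rng.normal(0.0, cfg.gel_sigma, n_channels)[:, None]
        if cfg.gel_walk_sigma > 0:
            n_nodes = max(2, int(dur * 4))
            walk = np.cumsum(
                rng.normal(0.0, cfg.gel_walk_sigma, (n_channels, n_nodes)), axis=1
            )
            node_t = np.linspace(0, n - 1, n_nodes)
            walk_full = np.vstack(
                [np.interp(np.arange(n), node_t, walk[ch]) for ch in range(n_channels)]
            )
            log_gain = log_gain + walk_full
        signals *= np.exp(log_gain)

    # injected artifact channels
    t = np.arange(n) / cfg.fs
    for ch, kind in cfg.artifacts:
        if kind == "dead":
            signals[ch] = 0.0
        elif kind == "lowfreq":
            signals[ch] += 1.0 * np.sin(2 * np.pi * 5.0 * t)
        elif kind == "powerline":
            signals[ch] += 1.0 * np.sin(2 * np.pi * cfg.line_freq * t)
        elif kind == "loud":
            signals[ch] += 8.0 * rng.standard_normal(n)
        else:
            raise ParameterError(f"unknown artifact kind {kind!r}")

    torque = np.empty(n)
    torque[:n_rest] = _smooth_noise(n_rest, cfg.fs, cfg.rest_torque_noise_pct, rng)
    torque[n_rest:] = 100.0 * (eff_level or 0.0) + _smooth_noise(
        n_con, cfg.fs, cfg.torque_noise_pct, rng
    )

    rec = Recording(
        signals=signals,
        fs=cfg.fs,
        geometries=cfg.geometries,
        torque=torque,
        task=task,
        target_level=level,
        phase=phase,
        mvc={tk: 100.0 for tk in cfg.tasks},
        rec_id=rec_id or f"{phase}_{task}_{level}",
    )
    gt = GroundTruth(
        rec_id=rec.rec_id,
        task=task,
        level=level,
        phase=phase,
        centers=true_centers,
        gains=true_gains,
        artifacts=cfg.artifacts,
        fatigue=(
            {"gain_slope": cfg.fatigue_gain_slope,
             "compression": cfg.fatigue_compression,
             "spread_growth": cfg.fatigue_spread_growth}
            if fatigue_active else None
        ),
        gel_drift=gel,
    )
    return rec, gt


def simulate_session(cfg: SimConfig) -> tuple[SessionDataset, list[GroundTruth]]:
    """A full two-part session: part 1 — every task at every level in seeded
    random order; part 2 — one endurance contraction per task at 50 % MVC."""
    order_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_000]))
    part1 = [(t, lv) for t in cfg.tasks for lv in cfg.levels]
    order_rng.shuffle(part1)
    part2 = list(cfg.tasks)
    order_rng.shuffle(part2)

    recordings, truths = [], []
    for t, lv in part1:
        ti, li = cfg.tasks.index(t), cfg.levels.index(lv)
        rec, gt = simulate_recording(
            cfg, t, lv, "submaximal", seed_key=(1, ti, li),
            rec_id=f"sub_{t}_{int(round(100 * lv))}",
        )
        recordings.append(rec)
        truths.append(gt)
    for t in part2:
        ti = cfg.tasks.index(t)
        rec, gt = simulate_recording(
            cfg, t, None, "endurance", seed_key=(2, ti), rec_id=f"end_{t}"
        )
        recordings.append(rec)
        truths.append(gt)
    return SessionDataset(recordings=recordings), truths


# ---------------------------------------------------------------------------
# fixture presets: reduced scale for fast, deterministic tests
# ---------------------------------------------------------------------------

FIXTURE_PRESETS = (
    "separable",
    "spatial_only",
    "chance",
    "fatigue_drift",
    "gel_drift",
    "artifact_channels",
)


def _fixture_geometries() -> tuple[ArrayGeometry, ...]:
    """Five small single-muscle 5x5 grids (125 channels)."""
    from .recording import MUSCLE_ORDER

    return tuple(
        ArrayGeometry(f"G{i+1}", 5, 5, muscle_regions=((m, (1, 5)),))
        for i, m in enumerate(MUSCLE_ORDER)
    )


def _symmetric_centers(tasks) -> dict[tuple[str, str], tuple[float, float]]:
    """Centers at the four symmetric interior positions of a 5x5 grid, so the
    truncated spatial profile has identical total mass for every task."""
    from .recording import MUSCLE_ORDER

    pos = {"flexion": (2.0, 2.0), "extension": (2.0, 4.0),
           "supination": (4.0, 2.0), "pronation": (4.0, 4.0)}
    return {(m, t): pos[t] for m in MUSCLE_ORDER for t in tasks}


def fixture_config(preset: str, seed: int = 0) -> SimConfig:
    """The SimConfig behind :func:`make_fixture` (exposed for inspection)."""
    if preset not in FIXTURE_PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    from .recording import MUSCLE_ORDER

    base = dict(
        seed=seed,
        fs=1024.0,
        geometries=_fixture_geometries(),
        endurance_s=60.0,
        sigma=0.8,
        band=(15.0, 350.0),
        source_centers=_symmetric_centers(TASKS),
    )
    if preset == "spatial_only":
        base["source_gains"] = {(m, t): 0.40 for m in MUSCLE_ORDER for t in TASKS}
    elif preset == "chance":
        base["source_gains"] = {(m, t): 0.40 for m in MUSCLE_ORDER for t in TASKS}
        base["source_centers"] = {(m, t): (3.0, 3.0) for m in MUSCLE_ORDER for t in TASKS}
    elif preset == "fatigue_drift":
        base["fatigue_gain_slope"] = 0.8
        base["fatigue_compression"] = 0.5
        base["fatigue_spread_growth"] = 0.5
    elif preset == "gel_drift":
        base["gel_sigma"] = 0.25
        base["gel_walk_sigma"] = 0.02
    elif preset == "artifact_channels":
        base["artifacts"] = ((3, "dead"), (30, "lowfreq"), (60, "powerline"), (100, "loud"))
    return SimConfig(**base)


def make_fixture(preset: str, seed: int = 0) -> tuple[SessionDataset, list[GroundTruth]]:
    """Small deterministic session presets for tests and property checks."""
    return simulate_session(fixture_config(preset, seed))
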