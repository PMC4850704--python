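"""The three experiment drivers: short-term, time-effect, and fatigue.

Each driver composes epoch selection, feature extraction and the iterated
balanced LDA evaluation on a session dataset, returning per-condition
confusion summaries. Recordings are assumed preprocessed (see
``preprocess.preprocess_recording``); synthetic sessions are generated
band-limited and interference-free, so tests feed them in directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import (
    INDEX_NAMES,
    ConfusionSummary,
    ShrinkageLDA,
    evaluate_iterated,
    performance_indices,
)
from .epoching import (
    NOACT_LABEL,
    Epoch,
    select_rest_epochs,
    select_submax_epochs,
    tdc_segments,
    time_effect_subset,
)
from .errors import CompletenessError, ParameterError
from .features import build_vector
from .mapping import compute_maps
from .recording import LEVELS, TASKS, Recording, SessionDataset

DEFAULT_WINDOW_S = 0.250


@dataclass
class ProtocolResult:
    protocol: str
    feature_set: str
    scheme: str | None
    conditions: dict[str, ConfusionSummary]
    seed: int | None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "feature_set": self.feature_set,
            "scheme": self.scheme,
            "seed": self.seed,
            "conditions": {k: v.to_dict() for k, v in self.conditions.items()},
            "meta": self.meta,
        }


class _FeatureCache:
    """Per-recording activation maps and feature vectors, computed lazily."""

    def __init__(self, session: SessionDataset, feature_set: str, window_s: float):
        self.session = session
        self.feature_set = feature_set
        self.window_s = window_s
        self._maps: dict[str, dict] = {}

    def _rec_maps(self, rec: Recording):
        if rec.rec_id not in self._maps:
            self._maps[rec.rec_id] = compute_maps(rec, self.window_s)
        return self._maps[rec.rec_id]

    def matrix(self, epochs: list[Epoch]) -> np.ndarray:
        rows = []
        for ep in epochs:
            rec = self.session.get(ep.rec_id)
            maps = self._rec_maps(rec)
            per_muscle = {m: seq[ep.window_index] for m, seq in maps.items()}
            fv = build_vector(per_muscle, self.feature_set, rec, class_label=ep.label)
            rows.append(fv.values)
        return np.asarray(rows)


def _submax_by_cell(session: SessionDataset) -> dict[tuple[str, float], Recording]:
    cells = {}
    for rec in session.submaximal:
        if rec.target_level is not None:
            cells[(rec.task, round(rec.target_level, 2))] = rec
    missing = [
        (t, lv) for t in TASKS for lv in LEVELS if (t, round(lv, 2)) not in cells
    ]
    if missing:
        raise CompletenessError(f"submaximal set incomplete; missing {missing}")
    return cells


def run_short_term(
    session: SessionDataset,
    feature_set: str = "I+CG",
    scheme: str = "task5",
    n_iter: int = 1000,
    seed: int | None = 0,
    window_s: float = DEFAULT_WINDOW_S,
    n_per_cell: int = 20,
    n_noact: int = 60,
    include_noact: bool = True,
) -> ProtocolResult:
    """Short-term identification on the submaximal set.

    ``scheme='task5'`` labels epochs by task (all effort levels mixed) plus
    the no-activity class; per-effort-level sensitivity/precision of the
    mixed-level classifier is tallied as a by-product. ``'task_level13'``
    labels by task x level plus no-activity (balanced to the per-cell epoch
    count). ``include_noact=False`` restricts to the active task classes.
    """
    if scheme not in ("task5", "task_level13"):
        raise ParameterError(f"unknown scheme {scheme!r}")
    cells = _submax_by_cell(session)
    cache = _FeatureCache(session, feature_set, window_s)

    epochs: list[Epoch] = []
    labels: list[str] = []
    groups: list[str] = []
    for (task, lv), rec in sorted(cells.items()):
        es = select_submax_epochs(rec, n_per_cell, window_s)
        for ep in es.epochs:
            epochs.append(ep)
            labels.append(task if scheme == "task5" else ep.label)
            groups.append(f"{int(round(100 * lv))}%")
    if include_noact:
        n_rest = n_noact if scheme == "task5" else n_per_cell
        # canonical recording order so results don't depend on manifest order
        rest = select_rest_epochs([cells[k] for k in sorted(cells)], n_rest, window_s)
        for ep in rest.epochs:
            epochs.append(ep)
            labels.append(NOACT_LABEL)
            groups.append("rest")

    X = cache.matrix(epochs)
    summary = evaluate_iterated(
        X, np.array(labels), n_iter=n_iter, seed=seed,
        groups=np.array(groups) if scheme == "task5" else None,
        track_train=True,
    )
    return ProtocolResult(
        protocol="short_term",
        feature_set=feature_set,
        scheme=scheme,
        conditions={"overall": summary},
        seed=seed,
        meta={"n_epochs": len(epochs), "classes": summary.classes.tolist()},
    )


def _confusion(k: int, y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    m = np.zeros((k, k), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return m


def _summarize(classes, confusions, seed, meta=None) -> ConfusionSummary:
    n_iter = confusions.shape[0]
    indices = {name: np.empty((n_iter, len(classes))) for name in INDEX_NAMES}
    for it in range(n_iter):
        perf = performance_indices(confusions[it])
        for name in INDEX_NAMES:
            indices[name][it] = perf[name].to_numpy()
    return ConfusionSummary(
        classes=np.asarray(classes), confusions=confusions, indices=indices,
        seed=seed, meta=meta or {},
    )


def run_time_effect(
    session: SessionDataset,
    feature_set: str = "I+CG",
    n_iter: int = 1000,
    seed: int | None = 0,
    window_s: float = DEFAULT_WINDOW_S,
    n_per_cell: int = 20,
    reg: float = 1e-6,
) -> ProtocolResult:
    """Time-progress robustness: train on part 1, validate within part 1
    (condition A, 50 %MVC hold-outs) and on the 0-20 % TDC slice of part 2
    (condition B).

    Per iteration, half the epochs of every task x level cell train the
    classifier together with half of the part-1 rest epochs; condition A
    validates on the held-out 50 %MVC epochs plus held-out part-1 rest,
    condition B on the time-effect epochs plus part-2 rest. Training and
    validation are disjoint by construction.
    """
    cells = _submax_by_cell(session)
    endurance = {r.task: r for r in session.endurance}
    missing = [t for t in TASKS if t not in endurance]
    if missing:
        raise CompletenessError(f"endurance set incomplete; missing {missing}")
    cache = _FeatureCache(session, feature_set, window_s)

    # epoch pools (features computed once, indexed per iteration)
    cell_epochs = {
        key: select_submax_epochs(rec, n_per_cell, window_s).epochs
        for key, rec in sorted(cells.items())
    }
    rest1 = select_rest_epochs(
        [cells[k] for k in sorted(cells)], 60, window_s
    ).epochs
    te_epochs = {t: time_effect_subset(endurance[t], window_s).epochs for t in TASKS}
    rest2 = select_rest_epochs(
        [endurance[t] for t in TASKS],
        min(48, sum(1 for _ in TASKS) * 12),
        window_s,
    ).epochs

    pools: dict[str, list[Epoch]] = {"rest1": rest1, "rest2": rest2}
    for key, eps in cell_epochs.items():
        pools[f"cell_{key}"] = eps
    for t in TASKS:
        pools[f"te_{t}"] = te_epochs[t]
    feats = {name: cache.matrix(eps) for name, eps in pools.items()}

    classes = np.array(sorted(set(TASKS) | {NOACT_LABEL}))
    cls_idx = {c: i for i, c in enumerate(classes)}
    k = classes.size
    n_half = n_per_cell // 2
    n_val = n_half  # per class per condition

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_iter)
    conf_a = np.zeros((n_iter, k, k), dtype=np.int64)
    conf_b = np.zeros((n_iter, k, k), dtype=np.int64)
    for it in range(n_iter):
        rng = np.random.default_rng(child[it])
        Xtr, ytr = [], []
        Xa, ya = [], []
        for (task, lv) in sorted(cells):
            n_cell = len(cell_epochs[(task, lv)])
            perm = rng.permutation(n_cell)
            tr_rows = perm[:n_half]
            Xtr.append(feats[f"cell_{(task, lv)}"][tr_rows])
            ytr.extend([cls_idx[task]] * n_half)
            if round(lv, 2) == 0.50:
                va_rows = perm[n_half : n_half + n_val]
                Xa.append(feats[f"cell_{(task, lv)}"][va_rows])
                ya.extend([cls_idx[task]] * len(va_rows))
        perm_r1 = rng.permutation(len(rest1))
        n_tr_noact = n_half * len(LEVELS)  # match per-task training count
        Xtr.append(feats["rest1"][perm_r1[:n_tr_noact]])
        ytr.extend([cls_idx[NOACT_LABEL]] * n_tr_noact)
        Xa.append(feats["rest1"][perm_r1[n_tr_noact : n_tr_noact + n_val]])
        ya.extend([cls_idx[NOACT_LABEL]] * n_val)

        Xb, yb = [], []
        for t in TASKS:
            rows = rng.choice(len(te_epochs[t]), size=n_val, replace=False)
            Xb.append(feats[f"te_{t}"][rows])
            yb.extend([cls_idx[t]] * n_val)
        rows2 = rng.choice(len(rest2), size=n_val, replace=False)
        Xb.append(feats["rest2"][rows2])
        yb.extend([cls_idx[NOACT_LABEL]] * n_val)

        model = ShrinkageLDA(reg=reg).fit(np.vstack(Xtr), np.array(ytr))
        conf_a[it] = _confusion(k, np.array(ya), model.predict(np.vstack(Xa)))
        conf_b[it] = _confusion(k, np.array(yb), model.predict(np.vstack(Xb)))
    # disjointness is structural: training rows and condition-A rows come from
    # disjoint slices of one permutation; condition B uses other recordings.
    summary_a = _summarize(classes, conf_a, seed, {"condition": "submaximal hold-out"})
    summary_b = _summarize(classes, conf_b, seed, {"condition": "time-effect (part 2)"})
    return ProtocolResult(
        protocol="time_effect",
        feature_set=feature_set,
        scheme="task5",
        conditions={"A_submaximal": summary_a, "B_time_effect": summary_b},
        seed=seed,
        meta={"n_val_per_class": n_val, "classes": classes.tolist()},
    )


def run_fatigue(
    session: SessionDataset,
    feature_set: str = "I+CG",
    n_iter: int = 1000,
    seed: int | None = 0,
    window_s: float = DEFAULT_WINDOW_S,
    k_segments: int = 5,
    reg: float = 1e-6,
) -> ProtocolResult:
    """Fatigue robustness on the endurance set.

    Each endurance contraction is split into TDC quintiles; the classifier
    trains on half of the first-quintile epochs (plus no-activity epochs from
    the endurance rest prefixes) and is validated on every quintile with
    equal per-class counts: the held-out half for quintile 1, equally sized
    random subsamples for the later quintiles.
    """
    endurance = {r.task: r for r in session.endurance}
    missing = [t for t in TASKS if t not in endurance]
    if missing:
        raise CompletenessError(f"endurance set incomplete; missing {missing}")
    cache = _FeatureCache(session, feature_set, window_s)

    segments = {
        t: tdc_segments(endurance[t], k_segments, window_s) for t in TASKS
    }
    m = min(len(seg) for segs in segments.values() for seg in segs)
    rest = select_rest_epochs([endurance[t] for t in TASKS], 4 * 12, window_s).epochs
    m = min(m, len(rest) // 2 * 2)
    if m < 2:
        raise ParameterError("quintiles too short for a balanced split")
    n_half = m // 2

    seg_feats = {
        (t, q): cache.matrix(
            [Epoch(endurance[t].rec_id, w, t) for w in segments[t][q]]
        )
        for t in TASKS
        for q in range(k_segments)
    }
    rest_feats = cache.matrix(rest)

    classes = np.array(sorted(set(TASKS) | {NOACT_LABEL}))
    cls_idx = {c: i for i, c in enumerate(classes)}
    k = classes.size

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_iter)
    confs = {q: np.zeros((n_iter, k, k), dtype=np.int64) for q in range(k_segments)}
    for it in range(n_iter):
        rng = np.random.default_rng(child[it])
        Xtr, ytr = [], []
        holdout = {}
        for t in TASKS:
            n_q1 = seg_feats[(t, 0)].shape[0]
            perm = rng.permutation(n_q1)
            Xtr.append(seg_feats[(t, 0)][perm[:n_half]])
            ytr.extend([cls_idx[t]] * n_half)
            holdout[t] = perm[n_half : n_half + n_half]
        perm_r = rng.permutation(len(rest))
        Xtr.append(rest_feats[perm_r[:n_half]])
        ytr.extend([cls_idx[NOACT_LABEL]] * n_half)
        rest_val = perm_r[n_half : 2 * n_half]

        model = ShrinkageLDA(reg=reg).fit(np.vstack(Xtr), np.array(ytr))
        for q in range(k_segments):
            Xv, yv = [], []
            for t in TASKS:
                if q == 0:
                    rows = holdout[t]
                else:
                    rows = rng.choice(
                        seg_feats[(t, q)].shape[0], size=n_half, replace=False
                    )
                Xv.append(seg_feats[(t, q)][rows])
                yv.extend([cls_idx[t]] * len(rows))
            Xv.append(rest_feats[rest_val])
            yv.extend([cls_idx[NOACT_LABEL]] * n_half)
            confs[q][it] = _confusion(k, np.array(yv), model.predict(np.vstack(Xv)))

    conditions = {
        f"q{q + 1}": _summarize(
            classes, confs[q], seed,
            {"tdc_range": f"{20 * q}-{20 * (q + 1)} % TDC"},
        )
        for q in range(k_segments)
    }
    return ProtocolResult(
        protocol="fatigue",
        feature_set=feature_set,
        scheme="task5",
        conditions=conditions,
        seed=seed,
        meta={"n_per_class_train": n_half, "classes": classes.tolist()},
    )
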