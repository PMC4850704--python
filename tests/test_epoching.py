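"""Torque-guided epoch selection and TDC segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import tiny_recording
from hdemg.epoching import (
    select_rest_epochs,
    select_submax_epochs,
    tdc_segments,
    time_effect_subset,
)
from hdemg.errors import InsufficientEpochsError, SegmentationError

FS = 512.0
W = 128  # 250 ms at 512 Hz


def _torque(rest_s, contraction, fs=FS):
    return np.concatenate([np.zeros(int(rest_s * fs)), contraction])


class TestSelectSubmaxEpochs:
    def test_flat_on_target_selects_earliest_20_of_28(self):
        # 3 s rest + 7 s contraction -> 40 windows total, 28 post-rest
        torque = _torque(3.0, np.full(int(7 * FS), 10.0))
        es = select_submax_epochs(tiny_recording(torque))
        idx = [e.window_index for e in es.epochs]
        assert idx == list(range(12, 32))  # ties broken by earlier start
        assert all(e.label == "flexion@10" for e in es.epochs)

    def test_band_is_plus_minus_5_for_10pct_target(self):
        # alternate windows at 14 %MVC (inside) and 16 %MVC (outside)
        n_win = 28
        vals = np.repeat([14.0, 16.0], W)[: 2 * W]
        contraction = np.tile(vals, n_win // 2)
        torque = _torque(3.0, contraction)
        es = select_submax_epochs(tiny_recording(torque), n=14)
        means = [torque[e.window_index * W : (e.window_index + 1) * W].mean()
                 for e in es.epochs]
        assert all(abs(m - 14.0) < 1e-9 for m in means)

    def test_band_is_plus_minus_10_for_30pct_target(self):
        torque = _torque(3.0, np.full(int(7 * FS), 39.0))  # |39-30| = 9 < 10
        es = select_submax_epochs(tiny_recording(torque, target_level=0.30))
        assert len(es) == 20
        torque_out = _torque(3.0, np.full(int(7 * FS), 41.0))
        with pytest.raises(InsufficientEpochsError):
            select_submax_epochs(tiny_recording(torque_out, target_level=0.30))

    def test_closest_windows_win(self):
        # distances from 10 %: window k at 10 + 0.1*k -> the smallest-k windows win
        n_win = 28
        means = 10.0 + 0.1 * np.arange(n_win)
        contraction = np.repeat(means, W)
        torque = _torque(3.0, contraction)
        es = select_submax_epochs(tiny_recording(torque))
        assert [e.window_index for e in es.epochs] == list(range(12, 32))

    def test_never_in_band_raises_with_shortfall(self):
        torque = _torque(3.0, np.full(int(7 * FS), 50.0))  # far from 10 %
        with pytest.raises(InsufficientEpochsError) as exc:
            select_submax_epochs(tiny_recording(torque))
        assert exc.value.requested == 20
        assert exc.value.available == 0

    def test_exactly_n_qualifying_all_returned(self):
        contraction = np.full(int(7 * FS), 50.0)
        contraction[: 20 * W] = 10.0  # only the first 20 windows qualify
        torque = _torque(3.0, contraction)
        es = select_submax_epochs(tiny_recording(torque))
        assert sorted(e.window_index for e in es.epochs) == list(range(12, 32))

    def test_epochs_disjoint_and_in_band(self):
        rng = np.random.default_rng(0)
        torque = _torque(3.0, 10.0 + rng.normal(0, 2.0, int(7 * FS)))
        es = select_submax_epochs(tiny_recording(torque))
        idx = [e.window_index for e in es.epochs]
        assert len(set(idx)) == 20
        for k in idx:
            assert abs(torque[k * W : (k + 1) * W].mean() - 10.0) <= 5.0


class TestSelectRestEpochs:
    def _recordings(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            torque = _torque(3.0, np.full(int(7 * FS), 10.0))
            torque[: int(3 * FS)] = np.abs(rng.normal(0, 0.2, int(3 * FS)))
            recs.append(tiny_recording(torque, rec_id=f"r{i}"))
        return recs

    def test_60_of_144_candidates(self):
        es = select_rest_epochs(self._recordings())
        assert len(es) == 60
        assert all(e.label == "NoAct" for e in es.epochs)
        # every epoch lies entirely within the 3 s rest prefix (12 windows)
        assert all(e.window_index < 12 for e in es.epochs)

    def test_lowest_torque_windows_preferred(self):
        recs = self._recordings(n=2)
        es = select_rest_epochs(recs, n_total=12)
        chosen = {(e.rec_id, e.window_index) for e in es.epochs}
        means = {}
        for rec in recs:
            for k in range(12):
                means[(rec.rec_id, k)] = np.abs(rec.torque[k * 128 : (k + 1) * 128]).mean()
        worst_chosen = max(means[c] for c in chosen)
        best_skipped = min(v for c, v in means.items() if c not in chosen)
        assert worst_chosen <= best_skipped

    def test_short_recording_excluded_with_warning(self):
        recs = self._recordings(n=6)
        stub = tiny_recording(np.zeros(64), rec_id="short")  # 0.125 s only
        with pytest.warns(UserWarning, match="no rest prefix"):
            es = select_rest_epochs(recs + [stub], n_total=60)
        assert all(e.rec_id != "short" for e in es.epochs)

    def test_all_zero_torque_takes_earliest(self):
        recs = [tiny_recording(np.zeros(int(10 * FS)), rec_id=f"z{i}") for i in range(6)]
        es = select_rest_epochs(recs, n_total=12)
        assert [(e.rec_id, e.window_index) for e in es.epochs] == [
            (f"z{i}", k) for i in range(1) for k in range(12)
        ]

    def test_insufficient_candidates_raise(self):
        with pytest.raises(InsufficientEpochsError):
            select_rest_epochs(self._recordings(n=2), n_total=60)

    def test_random_mode_is_seeded(self):
        recs = self._recordings()
        a = select_rest_epochs(recs, mode="random", seed=7)
        b = select_rest_epochs(recs, mode="random", seed=7)
        assert [(e.rec_id, e.window_index) for e in a.epochs] == [
            (e.rec_id, e.window_index) for e in b.epochs
        ]


def _endurance(n_windows, fs=FS):
    torque = _torque(3.0, np.full(n_windows * W, 50.0))
    return tiny_recording(torque, target_level=None, phase="endurance", task="flexion")


class TestTdcSegments:
    def test_100_windows_five_ranges_of_20(self):
        segs = tdc_segments(_endurance(100))
        assert [len(s) for s in segs] == [20] * 5
        assert segs[0][0] == 12  # contraction starts after the 3 s rest

    def test_remainder_goes_to_last_segment(self):
        segs = tdc_segments(_endurance(103))
        assert [len(s) for s in segs] == [20, 20, 20, 20, 23]

    @given(st.integers(5, 200))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, n_windows):
        segs = tdc_segments(_endurance(n_windows))
        flat = [w for seg in segs for w in seg]
        assert flat == sorted(flat)
        assert len(set(flat)) == len(flat)
        assert flat == list(range(12, 12 + n_windows))

    def test_too_few_windows_raise(self):
        with pytest.raises(SegmentationError):
            tdc_segments(_endurance(3))


class TestTimeEffectSubset:
    def test_first_quintile_returned(self):
        rec = _endurance(100)
        es = time_effect_subset(rec)
        assert [e.window_index for e in es.epochs] == tdc_segments(rec)[0]
        assert all(e.label == "flexion" for e in es.epochs)

    def test_ten_windows_give_two(self):
        assert len(time_effect_subset(_endurance(10))) == 2
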