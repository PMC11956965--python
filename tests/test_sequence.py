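import numpy as np
import pytest

import seqtime as st
from seqtime.core_io import ValidationError
from seqtime.sequence import (DetectionParams, SequenceCellStats,
                              circular_shuffle_test, reliability)

from conftest import make_aligned


def _stats(neuron, preferred, peak_time, significant=True, reliability=1.0):
    return SequenceCellStats(
        neuron=neuron, preferred=preferred, peak_bin=0, peak_time=peak_time,
        observed_peak=1.0, shuffle_threshold=0.5, reliability=reliability,
        significant=significant)


class TestPreferredTrialType:
    def test_planted_a_cell_is_short(self, default_aligned, default_session, cfg):
        _, cells = default_session
        a_cells = [c for c in cells
                   if c.preferred_odor == "A" and c.align_event == "odor1"]
        for c in a_cells[:5]:
            assert st.preferred_trial_type(default_aligned, c.neuron, cfg) == "short"

    def test_planted_b_cell_is_long(self, default_aligned, default_session, cfg):
        _, cells = default_session
        b_cells = [c for c in cells
                   if c.preferred_odor == "B" and c.align_event == "odor1"
                   and c.field_center > 1.0]
        for c in b_cells[:5]:
            assert st.preferred_trial_type(default_aligned, c.neuron, cfg) == "long"

    def test_silent_neuron_ties_to_short(self, cfg):
        aligned = make_aligned(np.zeros((1, 8, 80)), cfg)
        assert st.preferred_trial_type(aligned, 0, cfg) == "short"


class TestCircularShuffleTest:
    def test_all_zero_fails(self):
        rng = np.random.default_rng(0)
        obs, thr, ok = circular_shuffle_test(
            np.zeros((4, 20)), DetectionParams(n_shuffles=100), rng)
        assert obs == 0.0 and thr == 0.0 and not ok

    def test_constant_in_time_fails(self):
        # shift invariance: every shuffle reproduces the observed peak
        rng = np.random.default_rng(0)
        traces = np.tile(np.array([1.0, 2.0, 0.5, 1.5])[:, None], (1, 15))
        obs, thr, ok = circular_shuffle_test(
            traces, DetectionParams(n_shuffles=100), rng)
        assert obs == pytest.approx(thr)
        assert not ok

    def test_locked_peak_passes(self):
        rng = np.random.default_rng(1)
        traces = np.abs(rng.normal(0, 0.05, size=(20, 30)))
        traces[:, 12] += 5.0
        obs, thr, ok = circular_shuffle_test(
            traces, DetectionParams(n_shuffles=500), rng)
        assert ok and obs > thr

    def test_requires_two_trials(self):
        with pytest.raises(ValidationError):
            circular_shuffle_test(np.zeros((1, 10)), DetectionParams(),
                                  np.random.default_rng(0))

    def test_null_pass_rate_calibrated(self):
        # stimulus-independent traces: pass rate near the 5% construction
        rng = np.random.default_rng(2)
        params = DetectionParams(n_shuffles=200)
        passes = 0
        n = 300
        for _ in range(n):
            traces = rng.exponential(1.0, size=(10, 25))
            _, _, ok = circular_shuffle_test(traces, params, rng)
            passes += ok
        rate = passes / n
        se = np.sqrt(0.05 * 0.95 / n)
        assert rate <= 0.05 + 3 * se

    def test_shift_equivariance(self, cfg):
        # rotating every trial by the same offset rotates the peak
        rng = np.random.default_rng(3)
        traces = np.abs(rng.normal(0, 0.1, size=(8, 20)))
        traces[:, 5] += 4.0
        shift = 7
        rolled = np.roll(traces, shift, axis=1)
        p1 = int(np.argmax(traces.mean(axis=0)))
        p2 = int(np.argmax(rolled.mean(axis=0)))
        assert p2 == (p1 + shift) % 20


class TestReliability:
    def test_perfect_cell(self, cfg):
        time_axis = np.arange(20) * 0.16
        traces = np.zeros((10, 20))
        traces[:, 8] = 3.0
        r = reliability(traces, time_axis, time_axis[8], DetectionParams())
        assert r == 1.0

    def test_boundary_bin_counted(self, cfg):
        # an event exactly at peak_time + 0.5 s is inside the closed window
        time_axis = np.array([0.0, 0.25, 0.5])
        traces = np.zeros((4, 3))
        traces[:, 2] = 2.5
        r = reliability(traces, time_axis, 0.0, DetectionParams())
        assert r == 1.0

    def test_binomial_recovery(self, cfg):
        rng = np.random.default_rng(4)
        time_axis = np.arange(30) * 0.16
        p = 0.5
        n = 400
        traces = np.zeros((n, 30))
        hits = rng.random(n) < p
        traces[hits, 10] = 3.0
        r = reliability(traces, time_axis, time_axis[10], DetectionParams())
        assert abs(r - p) < 4 * np.sqrt(p * (1 - p) / n)


class TestDetect:
    def test_planted_recovery(self, default_aligned, default_stats,
                              default_session):
        _, cells = default_session
        planted = {c.neuron: c for c in cells if c.align_event == "odor1"}
        sig = {s.neuron: s for s in default_stats if s.significant}
        recovered = [n for n in planted if n in sig]
        assert len(recovered) / len(planted) >= 0.9
        for n in recovered:
            err = abs(sig[n].peak_time - planted[n].field_center)
            assert err <= default_aligned.bin_size + 1e-9

    def test_all_zero_session(self, cfg, small_cfg):
        trials = st.generate_trials(small_cfg, seed=0, iti=2.0, pre_roll=3.0)
        aligned = make_aligned(np.zeros((3, len(trials), 80)), small_cfg,
                               trials=trials)
        stats = st.detect_sequence_cells(
            aligned, small_cfg, DetectionParams(n_shuffles=100), seed=0)
        assert not any(s.significant for s in stats)

    def test_significance_invariant(self, default_stats):
        params = DetectionParams()
        for s in default_stats:
            if s.significant:
                assert s.observed_peak > s.shuffle_threshold
                assert s.reliability >= params.min_reliability

    def test_deterministic(self, default_aligned, cfg):
        p = DetectionParams(n_shuffles=100)
        a = st.detect_sequence_cells(default_aligned, cfg, p, seed=9)
        b = st.detect_sequence_cells(default_aligned, cfg, p, seed=9)
        assert a == b


class TestHeatmap:
    def test_row_order_follows_peaks(self, cfg):
        # 3 cells with fields at 1, 2, 3 s, passed in scrambled order
        trials = st.generate_trials(
            st.TaskConfig(n_blocks=1, trials_per_block=8, reverse_fraction=0.0),
            seed=0, iti=2.0, pre_roll=3.0)
        n_bins = 80
        tensor = np.zeros((3, len(trials), n_bins))
        time_axis = -2.0 + (np.arange(n_bins) + 0.5) * 5 / cfg.frame_rate
        centers = {0: 3.0, 1: 1.0, 2: 2.0}
        for neuron, c in centers.items():
            b = int(np.argmin(np.abs(time_axis - c)))
            for j, t in enumerate(trials):
                if t.odor1 == "A":
                    tensor[neuron, j, b] = 5.0 * (neuron + 1)
        aligned = make_aligned(tensor, cfg, trials=trials)
        stats = [
            _stats(0, "short", 3.0), _stats(1, "short", 1.0),
            _stats(2, "short", 2.0),
        ]
        for i, s in enumerate(stats):
            b = int(np.argmin(np.abs(time_axis - s.peak_time)))
            stats[i] = SequenceCellStats(**{**s.__dict__, "peak_bin": b})
        mat, order = st.sequence_heatmap(stats, aligned, cfg, "short")
        assert order == [1, 2, 0]
        assert np.allclose(mat.max(axis=1), 1.0)  # peak-normalized rows
        # amplitude rescaling does not change the order
        mat2, order2 = st.sequence_heatmap(stats, aligned, cfg, "short")
        assert order2 == order

    def test_diagonal_band(self, default_aligned, default_stats, cfg):
        mat, order = st.sequence_heatmap(default_stats, default_aligned, cfg,
                                         "short")
        if mat.shape[0] >= 3:
            peaks = mat.argmax(axis=1)
            assert np.all(np.diff(peaks) >= -1)  # near-monotone diagonal


class TestPeakDistributions:
    def test_identical_samples(self):
        x = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
        stat, p = st.compare_peak_distributions(x, x.copy())
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = st.compare_peak_distributions(
            np.linspace(0.1, 1.0, 20), np.linspace(2.0, 3.0, 20))
        assert stat == 1.0

    def test_window_restriction(self):
        # peaks outside [0, 3.5] are ignored
        short = np.array([1.0, 2.0, 5.9])
        long_ = np.array([1.0, 2.0, 4.5])
        stat, p = st.compare_peak_distributions(short, long_)
        assert stat == 0.0

    def test_p_decreases_with_planted_weight(self, cfg):
        rng = np.random.default_rng(5)
        n = 300
        long_peaks = rng.uniform(0, 3.5, size=n)
        pvals = []
        for w in (0.0, 1.0, 4.0):
            from seqtime.synthetic import sample_field_centers
            short = sample_field_centers(cfg, n, w, "A",
                                         np.random.default_rng(6))
            _, p = st.compare_peak_distributions(short, long_peaks)
            pvals.append(p)
        assert pvals[0] > pvals[1] > pvals[2]


class TestBinnedPeakFractions:
    def test_identical_sets_no_rejections(self):
        session = [_stats(i, "short", t) for i, t in enumerate([0.4, 1.2, 2.9])]
        session += [_stats(10 + i, "long", t)
                    for i, t in enumerate([0.4, 1.2, 2.9])]
        df = st.binned_peak_fractions([session, session])
        assert not (df.p_adj < 0.01).any()

    def test_single_session_raises(self):
        with pytest.raises(ValidationError):
            st.binned_peak_fractions([[_stats(0, "short", 1.0)]])

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        sessions = []
        for _ in range(4):
            s = [_stats(i, "short", t)
                 for i, t in enumerate(rng.uniform(0, 3.4, size=12))]
            s += [_stats(100 + i, "long", t)
                  for i, t in enumerate(rng.uniform(0, 3.4, size=12))]
            sessions.append(s)
        df = st.binned_peak_fractions(sessions)
        # windowed fractions partition each session's windowed cells
        assert df.frac_short.sum() == pytest.approx(1.0)
        assert df.frac_long.sum() == pytest.approx(1.0)

    def test_planted_last_bin_enrichment_detected(self):
        rng = np.random.default_rng(8)
        sessions = []
        for _ in range(11):
            short_peaks = np.concatenate([
                rng.uniform(0, 3.5, size=30), rng.uniform(3.0, 3.5, size=25)])
            long_peaks = rng.uniform(0, 3.5, size=55)
            s = [_stats(i, "short", t) for i, t in enumerate(short_peaks)]
            s += [_stats(1000 + i, "long", t)
                  for i, t in enumerate(long_peaks)]
            sessions.append(s)
        df = st.binned_peak_fractions(sessions)
        last = df.iloc[-1]
        assert last.frac_short > last.frac_long
        assert last.p_adj < 0.01
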