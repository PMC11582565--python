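"""Segment selection, histograms, idealization, dwell fits, transition counts."""

import difflib

import numpy as np
import pytest

from nanoak.event_analysis import (
    Event,
    all_point_histogram,
    count_transitions,
    dwell_exponential_fit,
    fit_gaussian_peaks,
    idealize,
    occurrence_percent,
    pick_fit_segments,
    residual_current,
    select_segments,
)
from nanoak.kinetic_model import LigandConcentrations
from nanoak.reference import default_emission_model
from nanoak.trace_simulator import ArtifactSpec, emit_trace, inject_artifacts, sample_ctmc_path

from conftest import make_trace


class TestSelectSegments:
    def _blockade_trace(self, n=25000, seed=0):
        rng = np.random.default_rng(seed)
        return make_trace(-210.0 + 8.0 * rng.standard_normal(n), atp=1.0)

    def test_clean_trace_is_one_full_segment(self):
        tr = self._blockade_trace()
        segs = select_segments(tr)
        assert len(segs) == 1
        assert segs[0].start == 0 and segs[0].stop == tr.n_samples

    def test_open_pore_insertion_splits_into_two(self):
        tr = self._blockade_trace()
        spec = ArtifactSpec(n_open_pore=1, duration_ms=300.0, positions_ms=[2000.0])
        dirty = inject_artifacts(tr, spec, seed=1)
        segs = select_segments(dirty)
        assert len(segs) == 2
        # boundaries blur by up to half the 50 ms screening window
        assert segs[0].stop == pytest.approx(10000, abs=150)
        assert segs[1].start == pytest.approx(11500, abs=150)

    def test_shallow_stretch_excluded_at_default_cutoff(self):
        tr = self._blockade_trace()
        spec = ArtifactSpec(n_shallow=1, shallow_mean_pA=-140.0, duration_ms=300.0, positions_ms=[2000.0])
        dirty = inject_artifacts(tr, spec, seed=2)
        segs = select_segments(dirty)  # default shallow cutoff -160 pA
        assert len(segs) == 2
        kept = np.concatenate([s.samples for s in segs])
        assert kept.mean() < -200.0


class TestPickFitSegments:
    def _segments(self, lengths_ms, dt=0.2):
        out = {}
        for cond, ln in lengths_ms.items():
            tr = make_trace(np.full(int(ln / dt), -210.0), atp=1.0)
            out[cond] = select_segments(tr)
        return out

    def test_truncation_to_shortest(self):
        segs = self._segments({"a": 800.0, "b": 1500.0})
        picked = pick_fit_segments(segs, max_len_ms=1000.0, seed=0)
        assert picked["a"].duration_ms == pytest.approx(800.0)
        assert picked["b"].duration_ms == pytest.approx(800.0)

    def test_single_short_segment_unchanged(self):
        segs = self._segments({"a": 600.0})
        picked = pick_fit_segments(segs, max_len_ms=1000.0, seed=0)
        assert picked["a"].duration_ms == pytest.approx(600.0)

    def test_cap_applies_when_all_longer(self):
        segs = self._segments({"a": 1500.0, "b": 2500.0})
        picked = pick_fit_segments(segs, seed=0)
        assert {round(s.duration_ms) for s in picked.values()} == {1000}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        tr = make_trace(-210 + 8 * rng.standard_normal(20000), atp=1.0)
        segs = {"a": select_segments(tr) * 3}  # three candidate copies
        p1 = pick_fit_segments(segs, seed=3)
        p2 = pick_fit_segments(segs, seed=3)
        assert p1["a"].start == p2["a"].start and p1["a"].stop == p2["a"].stop

    def test_condition_without_segments_rejected(self):
        with pytest.raises(ValueError, match="no usable segments"):
            pick_fit_segments({"a": []})


class TestHistogram:
    def test_constant_segment_single_bin(self):
        h = all_point_histogram(np.full(100, -221.03))
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 100

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        x = -221.0 + 8.0 * rng.standard_normal(5000)
        h = all_point_histogram(x)
        assert h.counts.sum() == 5000
        assert h.bin_width == pytest.approx(0.1)

    def test_modal_bin_near_true_mean(self):
        """The 0.1 pA modal bin sits near the true level; with sigma = 8 the
        peak top is flat, so the mode carries ~1-2 pA of sampling noise at
        1e5 samples while the fitted peak mean is far tighter."""
        rng = np.random.default_rng(2)
        x = -221.0 + 8.0 * rng.standard_normal(100000)
        h = all_point_histogram(x, bin_width=0.1)
        mode = h.centers[np.argmax(h.counts)]
        assert abs(mode - (-221.0)) < 2.0
        peak = fit_gaussian_peaks(h, 1, initial_means=[-221.0])[0]
        assert peak.mean == pytest.approx(-221.0, abs=0.2)

    def test_edges_anchored_at_zero(self):
        h = all_point_histogram(np.array([-200.05, -199.87]), bin_width=0.1)
        assert np.allclose(h.edges / 0.1, np.round(h.edges / 0.1), atol=1e-9)


class TestGaussianPeaks:
    def test_single_peak_recovery(self):
        rng = np.random.default_rng(3)
        x = -199.3 + 8.0 * rng.standard_normal(50000)
        h = all_point_histogram(x)
        peaks = fit_gaussian_peaks(h, 1, initial_means=[-200.0])
        assert peaks[0].mean == pytest.approx(-199.3, abs=0.1)
        assert peaks[0].sd == pytest.approx(8.0, rel=0.05)

    def test_two_separated_peaks(self):
        rng = np.random.default_rng(4)
        x = np.r_[-199.3 + 8.0 * rng.standard_normal(60000), -221.0 + 8.0 * rng.standard_normal(20000)]
        h = all_point_histogram(x)
        peaks = fit_gaussian_peaks(h, 2, initial_means=[-225.0, -195.0])
        assert peaks[0].mean == pytest.approx(-221.0, abs=1.0)
        assert peaks[1].mean == pytest.approx(-199.3, abs=1.0)

    def test_degenerate_constant_data_flagged(self):
        h = all_point_histogram(np.full(1000, -210.0))
        peaks = fit_gaussian_peaks(h, 1, initial_means=[-210.0], min_sd=0.5)
        assert peaks[0].flagged


class TestOccurrence:
    def test_single_peak_is_hundred_percent(self):
        from nanoak.event_analysis import GaussianPeak

        assert occurrence_percent([GaussianPeak(-200, 8, 500)]) == [100.0]

    def test_equal_heights_split_evenly(self):
        from nanoak.event_analysis import GaussianPeak

        p = [GaussianPeak(-220, 8, 300), GaussianPeak(-200, 8, 300)]
        assert occurrence_percent(p) == [50.0, 50.0]

    def test_three_to_one_heights(self):
        from nanoak.event_analysis import GaussianPeak

        p = [GaussianPeak(-220, 8, 900), GaussianPeak(-200, 8, 300)]
        assert occurrence_percent(p) == [75.0, 25.0]

    def test_tracks_occupancy_of_two_level_trace(self, space):
        """Peak-height occurrence approximates state occupancy."""
        Q = np.array([[-120.0, 120.0], [60.0, -60.0]])  # occupancy 1/3 vs 2/3
        path = sample_ctmc_path(Q, 20000.0, initial=0, seed=6)
        from nanoak.trace_simulator import discretize_path

        states = discretize_path(path, 0.2)
        rng = np.random.default_rng(7)
        x = np.where(states == 0, -199.3, -221.0) + 8.0 * rng.standard_normal(states.size)
        h = all_point_histogram(x)
        peaks = fit_gaussian_peaks(h, 2, initial_means=[-221.0, -199.3])
        pct = occurrence_percent(peaks)
        occ_deep = np.mean(states == 1) * 100.0
        assert pct[0] == pytest.approx(occ_deep, abs=5.0)


class TestResidualCurrent:
    def test_reported_levels(self):
        # reported blocked/open currents of the medium blockade
        assert residual_current(-200.3, -433.3) == pytest.approx(46.2, abs=0.05)

    def test_identity_and_zero(self):
        assert residual_current(-433.3, -433.3) == 100.0
        assert residual_current(0.0, -433.3) == 0.0

    def test_zero_open_pore_rejected(self):
        with pytest.raises(ValueError):
            residual_current(-200.0, 0.0)


LEVELS_MM2 = {"M": -199.3, "M2": -221.0}


class TestIdealize:
    def test_constant_segment_single_event(self):
        ev = idealize(np.full(500, -221.0), LEVELS_MM2, dt_ms=0.2)
        assert len(ev) == 1
        assert ev[0].level == "M2"
        assert ev[0].dwell_ms == pytest.approx(100.0)

    def test_noiseless_square_wave_recovered_exactly(self):
        dt = 0.2
        block = np.r_[np.full(25, -199.3), np.full(25, -221.0)]  # 5 ms per level
        x = np.tile(block, 10)
        ev = idealize(x, LEVELS_MM2, dt_ms=dt)
        assert [e.level for e in ev] == ["M", "M2"] * 10
        assert all(e.dwell_ms == pytest.approx(5.0) for e in ev)

    def test_sub_threshold_excursion_dropped(self):
        # 0.05 ms excursion at dt = 0.05 ms, min dwell 0.1 ms
        dt = 0.05
        x = np.r_[np.full(100, -199.3), np.full(1, -221.0), np.full(100, -199.3)]
        ev = idealize(x, LEVELS_MM2, dt_ms=dt, min_dwell_ms=0.1)
        assert [e.level for e in ev] == ["M"]

    def test_overlapping_levels_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            idealize(np.zeros(10), {"a": -200.0, "b": -200.0}, dt_ms=0.2)

    def test_noiseless_ctmc_round_trip(self, space):
        """Idealization of a noiseless emitted trace reproduces the hidden
        event sequence exactly at the event level."""
        Q = np.array([[-80.0, 80.0], [40.0, -40.0]])
        path = sample_ctmc_path(Q, 5000.0, initial=0, seed=11)
        from nanoak.trace_simulator import discretize_path

        states = discretize_path(path, 0.2)
        x = np.where(states == 0, -199.3, -221.0)
        ev = idealize(x, LEVELS_MM2, dt_ms=0.2, min_dwell_ms=0.0)
        want = ["M" if s == 0 else "M2" for s in states[np.r_[True, states[1:] != states[:-1]]]]
        assert [e.level for e in ev] == want

    def test_noisy_recovery_accuracy(self):
        """sigma = 8 pA, levels ~12 pA apart, dwells >= 2 ms: >= 95% of the
        event sequence is recovered."""
        rng = np.random.default_rng(42)
        dt = 0.2
        levels = {"M": -199.3, "M1": -211.0}
        names = ["M", "M1"]
        truth, chunks = [], []
        cur = 0
        for _ in range(400):
            n = int(round(rng.uniform(2.0, 10.0) / dt))
            truth.append(names[cur])
            chunks.append(np.full(n, levels[names[cur]]))
            cur = 1 - cur
        x = np.concatenate(chunks)
        x = x + 8.0 * rng.standard_normal(x.size)
        ev = idealize(x, levels, dt_ms=dt, min_dwell_ms=1.0, smooth_ms=1.0)
        got = [e.level for e in ev]
        sm = difflib.SequenceMatcher(None, truth, got, autojunk=False)
        assert sm.ratio() >= 0.95


class TestDwellFit:
    @pytest.mark.parametrize("mode", ["histogram", "direct"])
    def test_recovers_rate_from_exponential_dwells(self, mode):
        rng = np.random.default_rng(10)
        dwells = rng.exponential(10.0, size=5000)  # ms, rate 100 /s
        stats = dwell_exponential_fit(dwells, mode=mode)
        assert stats.rate_per_s == pytest.approx(100.0, rel=0.05)

    def test_direct_mode_is_sample_mean(self):
        d = np.array([1.0, 2.0, 3.0, 6.0])
        stats = dwell_exponential_fit(d, mode="direct")
        assert stats.tau_ms == pytest.approx(3.0)
        assert stats.rate_per_s == pytest.approx(1000.0 / 3.0)

    def test_modes_agree_on_well_sampled_data(self):
        rng = np.random.default_rng(11)
        dwells = rng.exponential(4.0, size=8000)
        hist = dwell_exponential_fit(dwells, mode="histogram")
        direct = dwell_exponential_fit(dwells, mode="direct")
        assert hist.rate_per_s == pytest.approx(direct.rate_per_s, rel=0.1)

    def test_rate_matches_ctmc_exit_rate(self):
        """Dwells harvested from a 2-state chain recover the exit rate."""
        Q = np.array([[-150.0, 150.0], [500.0, -500.0]])
        path = sample_ctmc_path(Q, 45000.0, initial=0, seed=12)
        dwells = path.sojourns_ms[:-1][path.states[:-1] == 0]
        assert len(dwells) >= 5000
        stats = dwell_exponential_fit(dwells[:5000], mode="direct")
        assert stats.rate_per_s == pytest.approx(150.0, rel=0.1)

    def test_too_few_dwells_for_histogram_mode(self):
        with pytest.raises(ValueError):
            dwell_exponential_fit([1.0] * 5, mode="histogram")


class TestTransitions:
    @staticmethod
    def _events(seq):
        return [Event(level=s, start_ms=i, dwell_ms=1.0, mean_pA=0.0) for i, s in enumerate(seq)]

    def test_hand_enumerated_sequence(self):
        table = count_transitions(self._events(["M", "M2", "M3", "M2", "M"]))
        get = lambda a, b: int(table.set_index(["from", "to"]).loc[(a, b), "count"])
        assert get("M", "M2") == 1
        assert get("M2", "M3") == 1
        assert get("M3", "M2") == 1
        assert get("M2", "M") == 1
        assert get("M", "M3") == 0

    def test_single_event_empty_counts(self):
        table = count_transitions(self._events(["M"]))
        assert table["count"].sum() == 0

    def test_per_origin_percentages_sum_to_100(self):
        table = count_transitions(self._events(["M", "M2", "M", "M3", "M2", "M3", "M2", "M"]))
        sums = table.dropna(subset=["percent"]).groupby("from")["percent"].sum()
        assert np.allclose(sums.to_numpy(), 100.0)
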