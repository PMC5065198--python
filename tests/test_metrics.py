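"""Analysis suite: PSTH, spectra, coincidence, state indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from gammamux import metrics as mt
from gammamux.engine import SlowOscConfig, SpikeRecord


def make_record(events_by_pop, duration=1000.0, repeats=1, slow=None, dt=1.0):
    """Build a SpikeRecord from {pop: [(repeat, cell, time), ...]}."""
    events = {}
    for pop, triples in events_by_pop.items():
        triples = sorted(triples)
        events[pop] = {
            "repeat": np.array([r for r, _, _ in triples], dtype=np.int32),
            "cell": np.array([c for _, c, _ in triples], dtype=np.int32),
            "time": np.array([t for _, _, t in triples], dtype=float),
        }
    return SpikeRecord(events=events, duration=duration, dt=dt,
                       repeats=repeats, seed=0, slow=slow)


SLOW9 = SlowOscConfig(enabled=True, freq_hz=9.0, rate_max=10.0)


class TestPsth:
    def test_no_spikes_all_zero(self):
        rec = make_record({"higher_e": [(0, 0, 100.0)]}, repeats=1)
        hist = mt.psth(rec, cells=[1])  # cell 1 never spikes
        assert np.all(hist.values == 0)

    def test_single_spike_area(self):
        rec = make_record({"higher_e": [(0, 0, 500.0)]}, repeats=4)
        hist = mt.psth(rec, cells=[0])
        # one spike in 1 of 4 repeats: smoothed bump of area 0.25
        assert hist.values.sum() == pytest.approx(0.25, rel=1e-3)
        assert hist.time[np.argmax(hist.values[0])] == pytest.approx(500.0, abs=2)

    def test_zero_smoothing_raw_histogram(self):
        rec = make_record({"higher_e": [(0, 0, 10.0), (0, 0, 20.0)]})
        hist = mt.psth(rec, cells=[0], smoothing_sd=0.0)
        assert hist.values[0, 10] == 1.0
        assert hist.values[0, 20] == 1.0
        assert hist.values.sum() == 2.0

    def test_merged_record_is_weighted_average(self):
        # psth of pooled repeats equals the average of per-repeat psths
        ev1 = [(0, 0, 100.0), (0, 0, 300.0)]
        ev2 = [(0, 0, 150.0)]
        merged = make_record({"higher_e": ev1 + [(1, c, t) for _, c, t in ev2]},
                             repeats=2)
        r1 = make_record({"higher_e": ev1}, repeats=1)
        r2 = make_record({"higher_e": ev2}, repeats=1)
        m = mt.psth(merged, cells=[0]).values
        avg = 0.5 * (mt.psth(r1, cells=[0]).values + mt.psth(r2, cells=[0]).values)
        np.testing.assert_allclose(m, avg, atol=1e-12)


class TestGammaFrequency:
    def test_pure_periodic_train(self):
        times = [(0, 0, float(t)) for t in range(0, 1000, 20)]  # 50 Hz
        rec = make_record({"lower_e": times})
        peak, _, _ = mt.gamma_frequency(rec)
        assert peak == pytest.approx(50.0, abs=1.0)

    def test_empty_record_flagged(self):
        rec = make_record({"lower_e": []})
        peak, _, _ = mt.gamma_frequency(rec)
        assert np.isnan(peak)

    @pytest.mark.parametrize("freq", [35.0, 50.0, 70.0])
    def test_recovers_poisson_modulation_frequency(self, freq):
        rng = np.random.default_rng(int(freq))
        events = []
        for rep in range(5):
            t = np.arange(0, 1000.0)
            lam = 5.0 * 0.5 * (1 + np.cos(2 * np.pi * freq * t / 1000.0))
            counts = rng.poisson(lam)
            for ti, n in zip(t, counts):
                events += [(rep, 0, float(ti))] * int(n)
        rec = make_record({"lower_e": events}, repeats=5)
        peak, _, _ = mt.gamma_frequency(rec)
        assert peak == pytest.approx(freq, abs=2.0)


class TestPhaseHistogram:
    def test_requires_slow_oscillation(self):
        rec = make_record({"higher_e": [(0, 0, 10.0)]})
        with pytest.raises(ValueError, match="slow"):
            mt.phase_histogram(rec)

    def test_uniform_spiking_flat(self):
        rng = np.random.default_rng(0)
        events = [(0, 0, float(t)) for t in np.sort(rng.uniform(0, 1000, 3000))]
        rec = make_record({"higher_e": events}, slow=SLOW9)
        _, vals = mt.phase_histogram(rec, cells=[0])
        assert vals.std() / vals.mean() < 0.2

    def test_locked_spiking_peaked(self):
        period = 1000.0 / 9.0
        events = [(0, 0, k * period + 30.0) for k in range(9)]
        rec = make_record({"higher_e": events}, slow=SLOW9)
        centres, vals = mt.phase_histogram(rec, cells=[0])
        peak_phase = centres[np.argmax(vals[0])]
        assert peak_phase == pytest.approx(2 * np.pi * 30.0 / period, abs=0.3)


def brute_force_coincidence(trains: dict, window: float) -> float:
    """Oracle: direct enumeration over all spike pairs."""
    total, followed = 0, 0
    for cell, times in trains.items():
        for t in times:
            total += 1
            hit = any(
                0.0 <= other_t - t <= window
                for other_cell, other_times in trains.items()
                if other_cell != cell
                for other_t in other_times
            )
            followed += hit
    return followed / total if total else 0.0


class TestCoincidence:
    def test_single_cell_zero(self):
        rec = make_record({"higher_e": [(0, 0, 10.0), (0, 0, 11.0)]})
        assert mt.near_coincidence_fraction(rec) == 0.0

    def test_toy_trains(self):
        rec = make_record({"higher_e": [(0, 1, 10.0), (0, 1, 30.0),
                                        (0, 2, 12.0), (0, 2, 50.0)]})
        # only cell1@10 is followed (cell2@12) within (0, 3]
        assert mt.near_coincidence_fraction(rec) == pytest.approx(0.25)

    def test_cross_cell_simultaneity_counts(self):
        rec = make_record({"higher_e": [(0, 0, 10.0), (0, 1, 10.0)]})
        assert mt.near_coincidence_fraction(rec) == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hst.lists(
        hst.tuples(hst.integers(0, 2), hst.integers(0, 200)),
        min_size=0, max_size=40))
    def test_matches_brute_force_enumeration(self, pairs):
        events = [(0, c, float(t)) for c, t in pairs]
        rec = make_record({"higher_e": events})
        trains = {}
        for c, t in pairs:
            trains.setdefault(c, []).append(float(t))
        assert mt.near_coincidence_fraction(rec) == pytest.approx(
            brute_force_coincidence(trains, 3.0))


class TestSpikeSeparation:
    def test_disjoint_trains_near_zero(self):
        events = [(0, 0, 100.0), (0, 1, 300.0), (0, 2, 500.0)]
        rec = make_record({"higher_e": events})
        S = mt.spike_separation_S(rec, reference_value=1.0)
        assert S < 0.01

    def test_self_normalisation_is_one(self):
        events = [(0, c, t) for c in range(3) for t in (100.0, 200.0, 300.0)]
        rec = make_record({"higher_e": events})
        raw = mt.shared_area(rec)
        assert mt.spike_separation_S(rec, reference_value=raw) == pytest.approx(1.0)

    def test_silent_record_zero(self):
        rec = make_record({"higher_e": []})
        assert mt.spike_separation_S(rec, reference_value=1.0) == 0.0

    def test_false_conjunction_normalisation(self):
        # 1.5 false-conjunction spikes per slow cycle -> S = 0.5
        period = 1000.0 / 9.0
        events = []
        for k in range(9):
            events.append((0, 5, k * period + 10.0))
            if k % 2 == 0:
                events.append((0, 5, k * period + 40.0))
        rec = make_record({"higher_e": events}, slow=SLOW9)
        S = mt.false_conjunction_S(rec, false_cells=[5])
        assert S == pytest.approx((9 + 5) / 9 / 3.0, abs=0.06)


class TestItemIndices:
    def test_silent_higher_area(self):
        rec = make_record({"higher_e": []}, slow=SLOW9)
        assert mt.item_indices(rec, 0, [1, 2]) == (0.0, 0.0)

    def test_pure_f_mode(self):
        period = 1000.0 / 9.0
        events = [(0, 0, k * period + off) for k in range(9)
                  for off in (20.0, 40.0, 60.0)]
        rec = make_record({"higher_e": events}, slow=SLOW9)
        A, B = mt.item_indices(rec, 0, [1, 2])
        assert A == pytest.approx(1.0)
        assert B == 0.0

    def test_lj_saturation(self):
        period = 1000.0 / 9.0
        events = []
        for k in range(9):
            events += [(0, 0, k * period + off) for off in (20.0, 40.0, 60.0)]
            events += [(0, c, k * period + off) for c in (1, 2)
                       for off in (25.0, 45.0)]
        rec = make_record({"higher_e": events}, slow=SLOW9)
        A, B = mt.item_indices(rec, 0, [1, 2])
        assert (A, B) == (1.0, 1.0)


class TestRgbState:
    @pytest.mark.parametrize("sab,expected", [
        ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),   # poor separation -> green
        ((0.0, 1.0, 0.0), (1.0, 0.0, 0.0)),   # selective -> red
        ((0.0, 1.0, 1.0), (0.0, 0.0, 1.0)),   # alternation -> blue
    ])
    def test_exact_corner_formulas(self, sab, expected):
        S, A, B = sab
        assert mt.rgb_state(mt.StateIndices(S=S, A=A, B=B)) == expected

    def test_black_at_low_rates(self):
        rgb = mt.rgb_state(mt.StateIndices(S=0.0, A=0.02, B=0.01))
        assert max(rgb) < 0.05
        assert mt.classify_state(mt.StateIndices(S=0.0, A=0.02, B=0.01)) == "silent"

    def test_red_clipped_nonnegative(self):
        rgb = mt.rgb_state(mt.StateIndices(S=0.2, A=0.3, B=0.9))
        assert rgb[0] == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hst.floats(0, 1), hst.floats(0, 1), hst.floats(0, 1))
    def test_channels_bounded(self, S, A, B):
        rgb = mt.rgb_state(mt.StateIndices(S=S, A=A, B=B))
        assert all(0.0 <= v <= 1.0 for v in rgb)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mt.StateIndices(S=1.2, A=0.0, B=0.0)
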