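"""Event classification and quantification on constructed fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest

from larvacpg import analysis as an


def gaussian_train(time, centres, width=400.0, amplitude=30.0, base=-55.0):
    """Trace with Gaussian activity bumps at the given centre times."""
    v = np.full_like(time, base, dtype=float)
    for c in centres:
        v += amplitude * np.exp(-0.5 * ((time - c) / width) ** 2)
    return v


def make_frame(channel_times: dict, t_end=60000.0, dt=10.0, **kw):
    t = np.arange(0.0, t_end, dt)
    data = {"time_ms": t}
    for ch, centres in channel_times.items():
        data[ch] = gaussian_train(t, centres, **kw)
    return pd.DataFrame(data)


ABD = ["A8", "A7", "A6", "A5", "A4", "A3", "A2", "A1"]


def wave_times(t0, step, channels=ABD):
    """Per-channel peak times of one progressive event starting at t0."""
    return {ch: t0 + i * step for i, ch in enumerate(channels)}


class TestDetectPeaks:
    def test_flat_trace_no_peaks(self):
        t = np.arange(0, 1000.0, 1.0)
        assert an.detect_peaks(np.full_like(t, -60.0), t) == []
        assert an.detect_peaks(np.array([]), np.array([])) == []

    def test_five_bumps_found_at_centres(self):
        t = np.arange(0, 30000.0, 10.0)
        centres = [3000.0, 8000.0, 13000.0, 18000.0, 23000.0]
        v = gaussian_train(t, centres)
        peaks = an.detect_peaks(v, t)
        assert len(peaks) == 5
        for p, c in zip(peaks, centres):
            assert abs(p.time - c) <= 10.0  # within one sample
            assert p.onset < p.time < p.offset

    def test_close_bumps_keep_larger(self):
        t = np.arange(0, 20000.0, 10.0)
        v = gaussian_train(t, [5000.0], amplitude=30.0) + gaussian_train(
            t, [5600.0], amplitude=20.0, base=0.0
        )
        peaks = an.detect_peaks(v, t, min_separation=1000.0)
        assert len(peaks) == 1
        assert abs(peaks[0].time - 5000.0) < 300.0

    def test_onset_offset_fractions(self):
        # triangular bump: crossings are analytically placed
        t = np.arange(0, 10000.0, 1.0)
        v = np.full_like(t, 0.0)
        rise = (t >= 4000) & (t <= 5000)
        fall = (t > 5000) & (t <= 7000)
        v[rise] = (t[rise] - 4000) / 1000 * 10
        v[fall] = 10 - (t[fall] - 5000) / 2000 * 10
        peaks = an.detect_peaks(v, t, min_height=0.3, min_prominence=0.3,
                                baseline_percentile=10.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.onset == pytest.approx(4200.0, abs=5.0)  # 20 % of rise
        assert p.offset == pytest.approx(6600.0, abs=5.0)  # 80 % of fall


class TestClassifyWaves:
    def test_forwards_with_synchronous_posterior(self):
        # A8..A6 co-peak, then 100 ms steps anteriad
        times = {ch: 5000.0 for ch in ["A8", "A7", "A6"]}
        for i, ch in enumerate(["A5", "A4", "A3", "A2", "A1"], start=1):
            times[ch] = 5000.0 + 200.0 * i
        frame = make_frame({ch: [tt] for ch, tt in times.items()})
        ev = an.classify_events(an.build_peak_table(frame))
        assert [e.kind for e in ev] == ["forwards_wave"]

    def test_backwards_strictly_decreasing(self):
        times = wave_times(5000.0, 300.0, channels=ABD[::-1])  # A1 first
        frame = make_frame({ch: [tt] for ch, tt in times.items()})
        ev = an.classify_events(an.build_peak_table(frame))
        assert [e.kind for e in ev] == ["backwards_wave"]

    def test_posterior_only_not_a_wave(self):
        frame = make_frame(
            {**{ch: [5000.0] for ch in ["A8", "A7", "A6"]},
             **{ch: [] for ch in ["A5", "A4", "A3", "A2", "A1"]}}
        )
        ev = an.classify_events(an.build_peak_table(frame),
                                anterior_group=("A1", "A2"))
        assert [e.kind for e in ev] == ["posterior_burst"]

    def test_channel_order_invariance(self):
        times = wave_times(4000.0, 250.0)
        items = list(times.items())
        f1 = make_frame({ch: [tt] for ch, tt in items})
        f2 = make_frame({ch: [tt] for ch, tt in reversed(items)})
        e1 = an.classify_events(an.build_peak_table(f1))
        e2 = an.classify_events(an.build_peak_table(f2))
        assert [e.kind for e in e1] == [e.kind for e in e2]
        assert [e.start for e in e1] == [e.start for e in e2]

    def test_too_few_channels_rejected(self):
        frame = make_frame({"A8": [5000.0]})
        with pytest.raises(ValueError):
            an.classify_waves(an.build_peak_table(frame))

    def test_unknown_channel_label_rejected(self):
        frame = make_frame({"A8": [5000.0], "X9": [5200.0]})
        with pytest.raises(ValueError, match="X9"):
            an.build_peak_table(frame)


class TestClassifyBursts:
    def test_all_channel_synchrony_flagged(self):
        frame = make_frame({ch: [5000.0] for ch in ABD})
        ev = an.classify_events(an.build_peak_table(frame),
                                anterior_group=("A1", "A2"))
        assert [e.kind for e in ev] == ["synchronous_network_event"]

    def test_anterior_burst(self):
        frame = make_frame(
            {**{ch: [] for ch in ABD[:-2]},
             "A2": [7000.0], "A1": [7100.0]}
        )
        ev = an.classify_events(an.build_peak_table(frame),
                                anterior_group=("A1", "A2"))
        assert [e.kind for e in ev] == ["anterior_burst"]

    def test_empty_table_empty_list(self):
        frame = make_frame({ch: [] for ch in ABD})
        assert an.classify_events(an.build_peak_table(frame)) == []

    def test_partition_no_double_assignment(self):
        # one wave followed by one posterior burst: every peak used once
        times = wave_times(5000.0, 300.0)
        frame = make_frame(
            {ch: [times[ch]] + ([20000.0] if ch in ("A8", "A7", "A6") else [])
             for ch in ABD}
        )
        ev = an.classify_events(an.build_peak_table(frame),
                                anterior_group=("A1", "A2"))
        kinds = sorted(e.kind for e in ev)
        assert kinds == ["forwards_wave", "posterior_burst"]


class TestOracleEquivalence:
    """Greedy classification agrees with exhaustive window enumeration."""

    @staticmethod
    def oracle(table, sync=500.0, max_delay=2000.0):
        """Try every one-peak-per-channel combination against the wave rules."""
        chans = table.channels
        found = []
        pools = [table.peaks[c] for c in chans]
        if any(not p for p in pools):
            return found
        for combo in itertools.product(*pools):
            for kind, seq in (("forwards_wave", combo),
                              ("backwards_wave", combo[::-1])):
                ts = [p.time for p in seq]
                ok = all(
                    ts[i] - sync <= ts[i + 1] <= ts[i] + max_delay
                    for i in range(len(ts) - 1)
                )
                if ok and ts[-1] - ts[0] > sync:
                    found.append((kind, min(ts)))
        return sorted(set(found), key=lambda x: x[1])

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        chans = ["A8", "A6", "A4", "A2"]
        events = []
        t = 5000.0
        for _ in range(int(rng.integers(1, 4))):
            kind = rng.choice(["forwards_wave", "backwards_wave"])
            step = float(rng.uniform(250.0, 600.0))
            order = chans if kind == "forwards_wave" else chans[::-1]
            events.append((kind, {ch: t + i * step
                                  for i, ch in enumerate(order)}))
            t += 15000.0  # well separated: assignment unambiguous
        table_times = {ch: sorted(ev[1][ch] for ev in events) for ch in chans}
        frame = make_frame(table_times, t_end=t + 5000.0)
        table = an.build_peak_table(frame)
        got = [(e.kind, min(e.peak_times.values()))
               for e in an.classify_waves(table)]
        expected = self.oracle(table)
        assert [k for k, _ in got] == [k for k, _ in expected]
        for (gk, gt), (ek, et) in zip(got, expected):
            assert abs(gt - et) <= 10.0


class TestHeadSweeps:
    def test_identical_traces_no_sweeps(self):
        t = np.arange(0, 30000.0, 10.0)
        v = gaussian_train(t, [5000.0, 15000.0])
        assert an.detect_head_sweeps(v, v.copy(), t) == []

    def test_one_sided_burst_single_left_sweep(self):
        t = np.arange(0, 30000.0, 10.0)
        right = np.full_like(t, -55.0)
        left = gaussian_train(t, [9000.0])
        ev = an.detect_head_sweeps(left, right, t, threshold=0.5)
        assert [e.kind for e in ev] == ["head_sweep_L"]

    def test_alternating_excursions_alternate(self):
        t = np.arange(0, 60000.0, 10.0)
        left = gaussian_train(t, [5000.0, 25000.0, 45000.0])
        right = gaussian_train(t, [15000.0, 35000.0, 55000.0])
        ev = an.detect_head_sweeps(left, right, t, threshold=0.5)
        kinds = [e.kind for e in ev]
        assert kinds == ["head_sweep_L", "head_sweep_R"] * 3

    def test_same_side_bout_merges(self):
        t = np.arange(0, 40000.0, 10.0)
        left = gaussian_train(t, [5000.0, 9000.0, 13000.0])  # one left bout
        right = np.full_like(t, -55.0)
        ev = an.detect_head_sweeps(left, right, t, threshold=0.5)
        assert len(ev) == 1
        assert ev[0].kind == "head_sweep_L"
        ev_raw = an.detect_head_sweeps(left, right, t, threshold=0.5,
                                       merge_same_side=False)
        assert len(ev_raw) == 3

    def test_mismatched_grids_rejected(self):
        t = np.arange(0, 1000.0, 10.0)
        with pytest.raises(ValueError):
            an.detect_head_sweeps(np.zeros(50), np.zeros(60), t)


class TestMetrics:
    def test_wave_duration_from_fractional_crossings(self):
        # duration = 20 % rise (first channel) to 80 % fall (last channel)
        times = wave_times(5000.0, 300.0)
        frame = make_frame({ch: [times[ch]] for ch in ABD})
        tab = an.build_peak_table(frame)
        (ev,) = an.classify_waves(tab)
        first, last = tab.peaks["A8"][0], tab.peaks["A1"][0]
        m = an.wave_metrics(ev)
        assert m["duration_ms"] == pytest.approx(last.offset - first.onset)

    def test_interval_and_frequency(self):
        t1 = wave_times(5000.0, 300.0)
        t2 = wave_times(15000.0, 300.0)
        frame = make_frame({ch: [t1[ch], t2[ch]] for ch in ABD})
        events = an.classify_waves(an.build_peak_table(frame))
        an.annotate_metrics(events)
        assert "interval_ms" not in events[0].metrics  # absent, not zero
        assert events[1].metrics["interval_ms"] == pytest.approx(10000.0, abs=20)
        assert events[1].metrics["frequency_hz"] == pytest.approx(0.1, rel=0.01)

    def test_interval_requires_same_kind(self):
        e1 = an.FictiveEvent("forwards_wave", 0.0, 1000.0)
        e2 = an.FictiveEvent("backwards_wave", 5000.0, 6000.0)
        with pytest.raises(ValueError):
            an.wave_metrics(e2, previous=e1)


class TestOverlap:
    def test_separated_events_unflagged(self):
        evs = [an.FictiveEvent("forwards_wave", 0.0, 3000.0),
               an.FictiveEvent("forwards_wave", 10000.0, 13000.0)]
        df = an.detect_overlap(evs)
        assert not df["same_program_overlap"].any()
        assert not df["opposite_program_overlap"].any()

    def test_same_and_opposite_flags(self):
        evs = [an.FictiveEvent("forwards_wave", 0.0, 3500.0),
               an.FictiveEvent("forwards_wave", 3000.0, 8000.0),
               an.FictiveEvent("backwards_wave", 4000.0, 9000.0)]
        df = an.detect_overlap(evs)
        assert df["same_program_overlap"].tolist() == [True, True, False]
        assert df["opposite_program_overlap"].tolist() == [False, True, True]


class TestTransitionMatrix:
    def test_strict_alternation(self):
        tm = an.transition_matrix(["F", "B", "F", "B"])
        assert tm.loc["F", "B"] == 1.0
        assert tm.loc["B", "F"] == 1.0

    def test_counted_fractions(self):
        tm = an.transition_matrix(["F", "F", "F", "B"])
        assert tm.loc["F", "F"] == pytest.approx(2 / 3)
        assert tm.loc["F", "B"] == pytest.approx(1 / 3)

    def test_rows_sum_to_one_random(self):
        rng = np.random.default_rng(0)
        kinds = rng.choice(list("FBPA"), size=200)
        tm = an.transition_matrix(kinds)
        np.testing.assert_allclose(tm.sum(axis=1).to_numpy(), 1.0)

    def test_single_event_empty(self):
        assert an.transition_matrix(["F"]).empty


class TestKde:
    def test_identical_traces_mass_at_zero(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=2000)
        grid, dens = an.asymmetry_kde(v, v + rng.normal(0, 1e-3, 2000))
        assert abs(grid[np.argmax(dens)]) < 0.01
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        l = rng.normal(size=2000)
        r = l - 3.0  # diff = +3
        grid, dens = an.asymmetry_kde(l, r)
        assert grid[np.argmax(dens)] == pytest.approx(3.0, abs=0.1)

    def test_two_component_mixture_modes(self):
        rng = np.random.default_rng(3)
        diff = np.concatenate([rng.normal(-5, 0.3, 3000),
                               rng.normal(5, 0.3, 3000)])
        grid, dens = an.asymmetry_kde(diff, np.zeros_like(diff),
                                      bandwidth_factor=4.0)
        from scipy.signal import find_peaks
        pk, _ = find_peaks(dens, prominence=dens.max() * 0.2)
        modes = grid[pk]
        assert len(modes) == 2
        bw = 4.0 * (len(diff)) ** (-1 / 5) * diff.std()  # Scott * factor
        assert abs(modes[0] + 5) < bw and abs(modes[1] - 5) < bw


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        sl, ic, r2 = an.linear_fit_r2(x, 2 * x + 1)
        assert (sl, ic, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(4)
        x = np.arange(2000.0)
        _, _, r2 = an.linear_fit_r2(x, rng.normal(size=2000))
        assert r2 < 0.01

    def test_known_residual_variance(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 500)
        noise = rng.normal(0, 0.1, 500)
        y = 3 * x + noise
        _, _, r2 = an.linear_fit_r2(x, y)
        ss_res = ((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            an.linear_fit_r2(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            an.linear_fit_r2(np.arange(2.0), np.arange(2.0))


class TestFrequencies:
    def test_counts_per_minute_bookkeeping(self):
        evs = [an.FictiveEvent("forwards_wave", i * 10000.0, i * 10000.0 + 3000.0)
               for i in range(6)]
        evs.append(an.FictiveEvent("head_sweep_L", 1000.0, 2000.0))
        f = an.event_frequencies(evs, duration_ms=120000.0)
        assert f["forwards_wave"] == pytest.approx(3.0)
        assert f["head_sweep_L"] == pytest.approx(0.5)
        assert f["total"] == pytest.approx(3.5)

    def test_progression_metrics_fixture(self):
        times1 = wave_times(5000.0, 300.0)
        times2 = wave_times(14000.0, 300.0)
        frame = make_frame({ch: [times1[ch], times2[ch]] for ch in ABD})
        tab = an.build_peak_table(frame)
        df = an.progression_metrics(tab, "A8", "A1")
        assert len(df) == 2
        assert df["period_ms"].iloc[1] == pytest.approx(9000.0, abs=20)
        p0_on = tab.peaks["A8"][0].onset
        p1_off = tab.peaks["A1"][0].offset
        assert df["duration_ms"].iloc[0] == pytest.approx(p1_off - p0_on)
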