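import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from napscape import io, stimlock
from napscape.errors import InsufficientDataError, ParameterError
from napscape.io import EventTable, Hypnogram, Recording


def peaks_table(times, channel="Cz"):
    rows = [
        {"type": "slow_wave", "channel": channel, "onset": t - 0.5, "offset": t + 0.5,
         "neg_peak_time": t, "neg_peak_amp": -80.0, "pos_peak_amp": 20.0, "stage": "N2"}
        for t in times
    ]
    return EventTable(pd.DataFrame(rows))


class TestWindowGeometry:
    def test_on_off_windows_equal_length_and_disjoint(self):
        ws = stimlock.WindowSpec()
        ws.validate()
        assert ws.kc_on[1] - ws.kc_on[0] == pytest.approx(0.250)
        assert ws.kc_off[1] - ws.kc_off[0] == pytest.approx(0.250)
        assert ws.sp_on[1] - ws.sp_on[0] == pytest.approx(3.4)
        assert ws.sp_off[1] - ws.sp_off[0] == pytest.approx(3.4)
        assert ws.kc_off[1] <= ws.kc_on[0]
        assert ws.sp_off[1] <= ws.sp_on[0]


class TestGenerateTrain:
    def test_pair_count_bounds_for_sixty_seconds(self, rng):
        # pair span 2.7 s, gaps 12-18 s: exhaustive bound gives 3-4 pairs
        for seed in range(40):
            train = stimlock.generate_stimulus_train(60.0, seed)
            assert 3 <= len(train.pairs) <= 4

    def test_intra_pair_geometry(self):
        train = stimlock.generate_stimulus_train(300.0, 5)
        assert np.allclose(train.s2_onsets - train.s1_onsets, 1.7)

    def test_deterministic_under_seed(self):
        a = stimlock.generate_stimulus_train(300.0, 11)
        b = stimlock.generate_stimulus_train(300.0, 11)
        assert np.array_equal(a.pairs, b.pairs)

    def test_gaps_within_declared_range(self):
        train = stimlock.generate_stimulus_train(2000.0, 3)
        gaps = train.s1_onsets[1:] - (train.s1_onsets[:-1] + train.pair_span)
        assert gaps.min() >= 12.0 and gaps.max() <= 18.0

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            stimlock.generate_stimulus_train(10.0, 0)


class TestEligibility:
    def _setup(self):
        hyp = Hypnogram(["N2"] * 20)  # 600 s of N2
        train = stimlock.generate_stimulus_train(500.0, 7).shifted(30.0)
        return hyp, train

    def test_stage_boundary_excludes(self):
        hyp = Hypnogram(["N2"] * 10 + ["N3"] * 10)
        train = io.StimulusTrain(np.array([[297.0, 298.7]]))  # segment crosses 300 s
        out = stimlock.select_eligible_stimuli(train, hyp, 600, (-4.4, 4.4), ("N2",))
        assert len(out) == 0

    def test_clean_mid_n2_included(self):
        hyp, _ = self._setup()
        train = io.StimulusTrain(np.array([[300.0, 301.7]]))
        out = stimlock.select_eligible_stimuli(train, hyp, 600, (-4.4, 4.4), ("N2",))
        assert np.array_equal(out, [300.0])

    def test_artifact_in_segment_excludes(self):
        hyp, _ = self._setup()
        mask = np.zeros(600, dtype=bool)
        mask[302] = True
        train = io.StimulusTrain(np.array([[300.0, 301.7]]))
        out = stimlock.select_eligible_stimuli(
            train, hyp, 600, (-4.4, 4.4), ("N2",), artifact_mask=mask
        )
        assert len(out) == 0

    def test_matches_brute_force_definition(self, rng):
        # oracle: per-stimulus scan of every overlapped second
        stages = rng.choice(["N2", "N3", "W"], size=40, p=[0.5, 0.3, 0.2])
        hyp = Hypnogram(list(stages))
        mask = rng.random(1200) < 0.05
        hyp.artifact_mask = mask
        train = stimlock.generate_stimulus_train(1100.0, 3).shifted(20.0)
        seg = (-4.4, 4.4)
        got = stimlock.select_eligible_stimuli(train, hyp, 1200, seg, ("N2",))
        sec = hyp.stages_per_second(1200)
        expected = []
        for s1 in train.s1_onsets:
            ok = True
            for k in range(int(np.floor(s1 + seg[0])), int(np.ceil(s1 + seg[1]))):
                if k < 0 or k >= 1200 or sec[k] != "N2" or mask[k]:
                    ok = False
                    break
            if ok:
                expected.append(s1)
        assert np.array_equal(got, np.array(expected))


class TestEvokedAverage:
    def test_template_recovered_within_sem(self, rng):
        fs = 250.0
        n = int(400 * fs)
        noise_sd = 5.0
        x = rng.normal(0, noise_sd, n)
        t_template = np.arange(0, 1.0, 1 / fs)
        template = -30 * np.sin(np.pi * t_template)
        s1 = np.arange(10.0, 390.0, 7.6)  # 50 stimuli
        for s in s1:
            i0 = int(s * fs)
            x[i0 : i0 + len(template)] += template
        rec = Recording(["Cz"], fs, x[None, :])
        times, erp = stimlock.evoked_average(rec, s1, ("Cz",), window=(-0.5, 1.5))
        sem = noise_sd / np.sqrt(len(s1))
        target = np.zeros_like(times)
        sel = (times >= 0) & (times < 1.0)
        target[sel] = -30 * np.sin(np.pi * times[sel])
        assert np.all(np.abs(erp - target) < 4 * sem + 1e-9)

    def test_single_stimulus_identity(self, rng):
        fs = 100.0
        x = rng.normal(0, 1, int(60 * fs))
        rec = Recording(["Cz"], fs, x[None, :])
        times, erp = stimlock.evoked_average(rec, np.array([30.0]), ("Cz",), window=(0.0, 1.0))
        seg = x[int(30 * fs) : int(31 * fs)]
        assert np.allclose(erp, seg)  # no pre-window -> no baseline shift

    def test_no_stimuli_raises(self, rng):
        rec = Recording(["Cz"], 100.0, rng.normal(0, 1, (1, 1000)))
        with pytest.raises(InsufficientDataError):
            stimlock.evoked_average(rec, np.array([]), ("Cz",))


class TestPeakHistogram:
    def test_planted_latency_mode_in_kc_window(self, rng):
        train = stimlock.generate_stimulus_train(3000.0, 1)
        lat = rng.normal(0.55, 0.04, len(train.pairs)).clip(0.46, 0.69)
        ev = peaks_table(train.s1_onsets + lat)
        h = stimlock.peak_latency_histogram(ev, train, bin_s=0.05, span=(-2, 2))
        centers = (h["bin_edges"][:-1] + h["bin_edges"][1:]) / 2
        mode = centers[np.argmax(h["s1"])]
        assert 0.45 <= mode < 0.70

    def test_uniform_rate_is_flat(self, rng):
        train = stimlock.generate_stimulus_train(3000.0, 2)
        ev = peaks_table(np.sort(rng.uniform(0, 3000, 2000)))
        h = stimlock.peak_latency_histogram(ev, train, bin_s=0.5, span=(-2, 2))
        counts = h["s1"]
        chi2, p = sstats.chisquare(counts)
        assert p > 0.01

    def test_no_events_all_zero(self):
        train = stimlock.generate_stimulus_train(100.0, 3)
        h = stimlock.peak_latency_histogram(peaks_table([]), train)
        assert h["s1"].sum() == 0 and h["s2"].sum() == 0


class TestLikelihoods:
    def test_kc_direct_count(self):
        s1 = np.arange(0.0, 200.0, 20.0)  # 10 eligible stimuli
        peaks = [s1[i] + 0.5 for i in range(4)]  # 4 ON-window peaks
        on, off = stimlock.kcomplex_likelihood(peaks_table(peaks), s1)
        assert on == pytest.approx(0.4)
        assert off == 0.0

    def test_boundary_closed_at_lower_edge(self):
        s1 = np.array([100.0])
        on, _ = stimlock.kcomplex_likelihood(peaks_table([100.45]), s1)
        assert on == 1.0
        on_hi, _ = stimlock.kcomplex_likelihood(peaks_table([100.70]), s1)
        assert on_hi == 0.0  # half-open upper edge

    def test_no_slow_waves(self):
        on, off = stimlock.kcomplex_likelihood(peaks_table([]), np.array([50.0]))
        assert (on, off) == (0.0, 0.0)

    def test_zero_stimuli_raises_not_zero_division(self):
        with pytest.raises(InsufficientDataError):
            stimlock.kcomplex_likelihood(peaks_table([1.0]), np.array([]))

    def test_spindle_counts_by_start_time(self):
        s1 = np.arange(0.0, 400.0, 20.0)  # 20 stimuli
        starts = [s1[i] + 1.0 for i in range(5)] + [s1[i] - 2.0 for i in range(5, 8)]
        rows = [
            {"type": "spindle", "channel": "Cz", "onset": t, "offset": t + 1.0,
             "neg_peak_time": np.nan, "neg_peak_amp": np.nan, "pos_peak_amp": np.nan,
             "stage": "N2"}
            for t in starts
        ]
        ev = EventTable(pd.DataFrame(rows))
        on, off = stimlock.spindle_likelihood(ev, s1)
        assert on == pytest.approx(0.25)
        assert off == pytest.approx(0.15)

    def test_spindle_start_at_zero_is_on(self):
        rows = [{"type": "spindle", "channel": "Cz", "onset": 100.0, "offset": 101.0,
                 "neg_peak_time": np.nan, "neg_peak_amp": np.nan, "pos_peak_amp": np.nan,
                 "stage": "N2"}]
        ev = EventTable(pd.DataFrame(rows))
        on, off = stimlock.spindle_likelihood(ev, np.array([100.0]))
        assert on == 1.0 and off == 0.0

    def test_translation_invariance(self):
        s1 = np.arange(0.0, 200.0, 20.0)
        ev = peaks_table([s1[0] + 0.5, s1[3] + 0.6])
        base = stimlock.kcomplex_likelihood(ev, s1)
        shifted = peaks_table([s1[0] + 100.5, s1[3] + 100.6])
        assert stimlock.kcomplex_likelihood(shifted, s1 + 100.0) == base
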