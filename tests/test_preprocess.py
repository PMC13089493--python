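import numpy as np
import pytest
from scipy import signal as sps

from napscape import io, preprocess
from napscape.errors import AlignmentError, ExclusionError, ParameterError


def _rec(data, fs=500.0, channels=None):
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    return io.Recording(channels, fs, data)


def analytic_two_pass_gain(freq, band=(0.2, 40.0), order=1):
    """Oracle: squared magnitude of the analog Butterworth band-pass at freq
    (zero-phase filtering applies the response twice)."""
    b, a = sps.butter(order, [2 * np.pi * band[0], 2 * np.pi * band[1]], "bandpass", analog=True)
    w, h = sps.freqs(b, a, worN=[2 * np.pi * freq])
    return float(np.abs(h[0]) ** 2)


class TestBandpass:
    @pytest.mark.parametrize("freq", [0.05, 10.0])
    def test_attenuation_matches_analytic_response(self, freq):
        fs = 500.0
        t = np.arange(0, 120, 1 / fs)
        x = np.sin(2 * np.pi * freq * t)
        out = preprocess.bandpass(_rec(x[None, :], fs)).data[0]
        # avoid filter edge transients when measuring RMS
        sel = slice(int(20 * fs), int(100 * fs))
        gain = np.sqrt(np.mean(out[sel] ** 2)) / np.sqrt(np.mean(x[sel] ** 2))
        expected = analytic_two_pass_gain(freq)
        assert gain == pytest.approx(expected, rel=0.03)

    def test_sub_band_tone_strongly_attenuated(self):
        fs = 500.0
        t = np.arange(0, 120, 1 / fs)
        x = np.sin(2 * np.pi * 0.05 * t)
        out = preprocess.bandpass(_rec(x[None, :], fs)).data[0]
        assert np.sqrt(np.mean(out**2)) < 0.5 * np.sqrt(np.mean(x**2))

    def test_in_band_tone_preserved(self):
        fs = 500.0
        t = np.arange(0, 120, 1 / fs)
        x = np.sin(2 * np.pi * 10 * t)
        out = preprocess.bandpass(_rec(x[None, :], fs)).data[0]
        sel = slice(int(20 * fs), int(100 * fs))
        gain = np.sqrt(np.mean(out[sel] ** 2)) / np.sqrt(np.mean(x[sel] ** 2))
        assert gain == pytest.approx(analytic_two_pass_gain(10.0), rel=0.03)

    def test_zero_signal(self):
        out = preprocess.bandpass(_rec(np.zeros((2, 5000))))
        assert np.allclose(out.data, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            preprocess.bandpass(
                _rec(np.zeros((1, 1000)), fs=60.0),
                preprocess.FilterSpec(band=(0.2, 40.0)),
            )

    def test_linearity(self, rng):
        fs = 200.0
        x = rng.normal(0, 1, (1, 4000))
        y = rng.normal(0, 1, (1, 4000))
        f = lambda d: preprocess.bandpass(_rec(d, fs)).data
        assert np.allclose(f(2 * x + 3 * y), 2 * f(x) + 3 * f(y), atol=1e-8)

    def test_notch_above_nyquist_skipped(self):
        # fs=100 -> notches at 50+ Hz are skipped rather than failing
        out = preprocess.bandpass(
            _rec(np.zeros((1, 1000)), fs=100.0), preprocess.FilterSpec(band=(0.2, 40.0))
        )
        assert out.data.shape == (1, 1000)


class TestRereference:
    def _four_channel(self, c_val, m1, m2):
        n = 1000
        data = np.vstack(
            [
                np.full(n, c_val),
                np.full(n, c_val),
                np.full(n, m1),
                np.full(n, m2),
            ]
        )
        return io.Recording(["C3", "C4", "TP9", "TP10"], 100.0, data)

    def test_common_mode_removed(self):
        rec = self._four_channel(5.0, 5.0, 5.0)
        out = preprocess.rereference(rec, "linked_mastoids")
        assert np.allclose(out.data, 0.0)

    def test_linked_arithmetic(self):
        # oracle: x - (M1+M2)/2 = 10 - 3 = 7
        rec = self._four_channel(10.0, 2.0, 4.0)
        out = preprocess.rereference(rec, "linked_mastoids")
        assert np.allclose(out.get("C3"), 7.0)
        assert out.reference == "linked_mastoids"

    def test_contralateral_sides(self):
        rec = self._four_channel(10.0, 2.0, 4.0)
        out = preprocess.rereference(rec, "contralateral_mastoids")
        assert np.allclose(out.get("C3"), 10.0 - 4.0)  # left channel - right mastoid
        assert np.allclose(out.get("C4"), 10.0 - 2.0)  # right channel - left mastoid

    def test_midline_uses_linked_average(self):
        data = np.vstack([np.full(100, 10.0), np.full(100, 2.0), np.full(100, 4.0)])
        rec = io.Recording(["Cz", "TP9", "TP10"], 100.0, data)
        out = preprocess.rereference(rec, "contralateral_mastoids")
        assert np.allclose(out.get("Cz"), 7.0)

    def test_bad_mastoid_excludes_nap(self):
        rec = self._four_channel(1.0, 0.0, 0.0)
        rec.bad_channels.add("TP10")
        with pytest.raises(ExclusionError) as exc:
            preprocess.rereference(rec)
        assert exc.value.reason_code == "bad_mastoid"

    def test_missing_mastoid_excludes_nap(self):
        rec = io.Recording(["Cz", "TP9"], 100.0, np.zeros((2, 100)))
        with pytest.raises(ExclusionError):
            preprocess.rereference(rec)


class TestArtifactDetection:
    def _hyp(self, n_seconds):
        return io.Hypnogram(["N2"] * int(np.ceil(n_seconds / 30)))

    def test_null_rate_below_two_percent(self, rng):
        fs = 250.0
        data = rng.normal(0, 20, (4, int(600 * fs)))
        rec = io.Recording(["F3", "F4", "C3", "C4"], fs, data)
        mask = preprocess.detect_artifacts(rec, self._hyp(600), z_thresh=3.0)
        assert mask.mean() < 0.02

    def test_injected_burst_flagged(self, rng):
        fs = 250.0
        data = rng.normal(0, 20, (4, int(120 * fs)))
        data[:, int(60 * fs) : int(61 * fs)] *= 10  # one 1-s, 10x burst
        rec = io.Recording(["F3", "F4", "C3", "C4"], fs, data)
        mask = preprocess.detect_artifacts(rec, self._hyp(120), z_thresh=3.0)
        assert mask[60]

    def test_zero_recording_unflagged(self):
        rec = io.Recording(["C3", "C4"], 100.0, np.zeros((2, 100 * 120)))
        mask = preprocess.detect_artifacts(rec, self._hyp(120))
        assert not mask.any()

    def test_idempotent(self, rng):
        fs = 100.0
        rec = io.Recording(["C3", "C4"], fs, rng.normal(0, 5, (2, int(120 * fs))))
        m1 = preprocess.detect_artifacts(rec, self._hyp(120))
        m2 = preprocess.detect_artifacts(rec, self._hyp(120))
        assert np.array_equal(m1, m2)

    def test_masked_seconds_equals_sum(self, rng):
        fs = 100.0
        rec = io.Recording(["C3", "C4"], fs, rng.normal(0, 5, (2, int(120 * fs))))
        mask = preprocess.detect_artifacts(rec, self._hyp(120))
        assert preprocess.masked_seconds(mask) == float(mask.sum())

    def test_short_hypnogram_rejected(self, rng):
        rec = io.Recording(["C3", "C4"], 100.0, rng.normal(0, 5, (2, 100 * 300)))
        with pytest.raises(AlignmentError):
            preprocess.detect_artifacts(rec, io.Hypnogram(["N2"] * 2))
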