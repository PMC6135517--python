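import numpy as np
import pytest
from scipy.signal import correlate

from hystnet import (
    BandSpec,
    EEGRecording,
    WindowPlan,
    bandpass_fir,
    read_eeg,
    rereference_average,
    segment,
    write_eeg,
)


def _tone(freq, rate=500.0, dur=20.0, phase=0.0):
    t = np.arange(int(dur * rate)) / rate
    return np.cos(2 * np.pi * freq * t + phase)


class TestRecordingValidation:
    def test_rejects_bad_inputs(self):
        data = np.zeros((2, 100))
        with pytest.raises(ValueError):
            EEGRecording(data, -1.0, ["a", "b"])
        with pytest.raises(ValueError):
            EEGRecording(data, 100.0, ["a", "a"])
        with pytest.raises(ValueError):
            EEGRecording(data[:1], 100.0, ["a"])
        with pytest.raises(ValueError):
            EEGRecording(data, 100.0, ["a", "b"], {"baseline": (50, 150)})


class TestDelimitedRoundTrip:
    def test_bit_identical_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = EEGRecording(
            rng.standard_normal((4, 1000)), 250.0, list("abcd"), {"baseline": (0, 500)}
        )
        p = tmp_path / "rec.tsv"
        write_eeg(rec, p)
        back = read_eeg(p)
        # write -> read -> write is bit-stable for the delimited dialect
        assert np.allclose(back.data, rec.data, rtol=0, atol=1e-9)
        p2 = tmp_path / "rec2.tsv"
        write_eeg(back, p2)
        assert p.read_text() == p2.read_text()
        assert back.labels == rec.labels
        assert back.rate == rec.rate
        assert back.epochs == rec.epochs

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n3\n")
        p.with_suffix(".tsv.json").write_text('{"rate": 100}')
        with pytest.raises(ValueError, match="inconsistent channel lengths"):
            read_eeg(p)

    def test_missing_rate_rejected(self, tmp_path):
        p = tmp_path / "norate.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="missing rate"):
            read_eeg(p)


def _write_minimal_edf(path, data_int16, labels, rate):
    """Hand-rolled EDF writer (independent of any EDF library) for fixtures."""
    ns = len(labels)
    n_records = data_int16.shape[1] // int(rate)
    hdr = b""
    hdr += b"0".ljust(8)
    hdr += b"patient".ljust(80)
    hdr += b"recording".ljust(80)
    hdr += b"01.01.20".ljust(8) + b"00.00.00".ljust(8)
    hdr += str(256 * (1 + ns)).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(n_records).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(ns).encode().ljust(4)
    for lab in labels:
        hdr += lab.encode().ljust(16)
    hdr += b"".ljust(80) * ns
    hdr += b"uV".ljust(8) * ns
    hdr += b"-3277".ljust(8) * ns  # physical min/max map 10x digital
    hdr += b"3277".ljust(8) * ns
    hdr += b"-32768".ljust(8) * ns
    hdr += b"32767".ljust(8) * ns
    hdr += b"".ljust(80) * ns
    hdr += str(int(rate)).encode().ljust(8) * ns
    hdr += b"".ljust(32) * ns
    body = b""
    spr = int(rate)
    for rec_i in range(n_records):
        for ch in range(ns):
            body += data_int16[ch, rec_i * spr : (rec_i + 1) * spr].astype("<i2").tobytes()
    path.write_bytes(hdr + body)


class TestEDF:
    def test_edf_labels_rate_and_signal_preserved(self, tmp_path):
        rate = 500.0
        tone = (_tone(10, rate, 4.0) * 10000).astype(np.int16)
        other = (_tone(6, rate, 4.0) * 10000).astype(np.int16)
        p = tmp_path / "two.edf"
        _write_minimal_edf(p, np.vstack([tone, other]), ["C3", "C4"], rate)
        rec = read_eeg(p)
        assert rec.labels == ["C3", "C4"]
        assert rec.rate == rate
        assert rec.n_samples == tone.size
        # waveform shape survives the round trip
        r = np.corrcoef(rec.data[0], tone.astype(float))[0, 1]
        assert r > 0.999


class TestAverageReference:
    def test_subtracts_channel_mean(self):
        rec = EEGRecording(np.array([[1.0, 5.0], [3.0, 7.0]]), 10.0, ["a", "b"])
        out = rereference_average(rec)
        assert np.allclose(out.data, [[-1.0, -1.0], [1.0, 1.0]])

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(1)
        rec = EEGRecording(rng.standard_normal((5, 200)), 100.0, list("abcde"))
        once = rereference_average(rec)
        assert np.allclose(once.data.mean(axis=0), 0.0, atol=1e-12)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)


class TestBandpass:
    RATE = 500.0

    def _rec(self, data):
        data = np.atleast_2d(data)
        if data.shape[0] == 1:
            data = np.vstack([data, data])
        return EEGRecording(data, self.RATE, [f"c{i}" for i in range(data.shape[0])])

    def test_passband_tone_preserved_zero_lag(self):
        x = _tone(10, self.RATE)
        out = bandpass_fir(self._rec(x), BandSpec(9, 11)).data[0]
        core = slice(2000, -2000)  # away from edge transients
        amp_ratio = out[core].std() / x[core].std()
        assert abs(amp_ratio - 1) < 0.05
        xc = correlate(out[core], x[core], mode="full")
        lag = np.argmax(xc) - (len(x[core]) - 1)
        assert lag == 0  # zero-phase: no shift

    def test_stopband_attenuation(self):
        x = _tone(25, self.RATE)
        out = bandpass_fir(self._rec(x), BandSpec(9, 11)).data[0]
        core = slice(2000, -2000)
        atten_db = 20 * np.log10(out[core].std() / x[core].std())
        assert atten_db < -20

    def test_component_separation(self):
        x5, x10 = _tone(5, self.RATE), _tone(10, self.RATE)
        out = bandpass_fir(self._rec(x5 + x10), BandSpec(9, 11)).data[0]
        core = slice(2000, -2000)
        r = np.corrcoef(out[core], x10[core])[0, 1]
        assert r > 0.99

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(self._rec(_tone(10)), BandSpec(9, 300))

    def test_short_signal_rejected(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((2, 50)), 500.0, ["a", "b"])
        with pytest.raises(ValueError, match="shorter"):
            bandpass_fir(rec, BandSpec(100, 200))

    def test_low_edge_clamped_with_warning(self):
        rec = self._rec(_tone(10, self.RATE, dur=40.0))
        with pytest.warns(UserWarning, match="clamped"):
            bandpass_fir(rec, BandSpec(0.01, 1.0))


class TestSegment:
    def _rec(self, dur=130.0, rate=100.0):
        n = int(dur * rate)
        data = np.random.default_rng(0).standard_normal((2, n))
        return EEGRecording(data, rate, ["a", "b"], {"baseline": (0, n)})

    def test_default_plan_gives_12_windows(self):
        wins = segment(self._rec(), "baseline", WindowPlan())
        assert len(wins) == 12
        assert all(w.shape == (2, 1000) for w in wins)

    def test_half_overlap_gives_23_windows(self):
        wins = segment(self._rec(), "baseline", WindowPlan(overlap=0.5))
        assert len(wins) == 23

    def test_short_epoch_rejected(self):
        rec = self._rec(dur=60.0)
        with pytest.raises(ValueError, match="shorter"):
            segment(rec, "baseline", WindowPlan(epoch_len=120.0))

    def test_filter_then_segment_matches_segment_then_filter_inside(self):
        """Band filtering commutes with windowing away from window edges."""
        rate = 250.0
        n = int(130 * rate)
        t = np.arange(n) / rate
        rng = np.random.default_rng(5)
        data = np.vstack([np.cos(2 * np.pi * 10 * t), rng.standard_normal(n)])
        rec = EEGRecording(data, rate, ["a", "b"], {"baseline": (0, n)})
        band = BandSpec(9, 11)
        whole = bandpass_fir(rec, band)
        w_first = segment(whole, "baseline", WindowPlan())[0]
        alone = EEGRecording(segment(rec, "baseline", WindowPlan())[0], rate, ["a", "b"])
        w_alone = bandpass_fir(alone, band).data
        edge = 300
        assert np.allclose(w_first[:, edge:-edge], w_alone[:, edge:-edge], atol=1e-6)
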