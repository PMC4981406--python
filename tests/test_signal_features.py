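"""The signal front-end: zero-phase FIR filtering, baseline, features."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import evokedmi as em

FS = 4000.0


def make_sweep(values, signal_type="PSP", onset_s=0.015):
    return em.Sweep(
        values=values, stimulus_freq_hz=5527.0, signal_type=signal_type,
        onset_s=onset_s, sampling_rate=FS,
    )


def sine_sweep(freq_hz, n=2000):
    t = np.arange(n) / FS
    return make_sweep(np.sin(2 * np.pi * freq_hz * t))


class TestFilter:
    def test_dc_preserved(self):
        sw = make_sweep(np.full(1000, 2.0))
        out = em.lowpass_filter(sw)
        assert np.allclose(out.values, 2.0, atol=1e-3)

    def test_taps_have_unit_dc_gain(self):
        taps = em.design_lowpass_fir(300.0, FS, order=39)
        assert len(taps) == 40
        assert taps.sum() == pytest.approx(1.0, abs=1e-12)

    def test_passband_sine_gain_matches_frequency_response(self):
        """Steady-state 50 Hz amplitude equals the two-pass gain |H(50)|^2."""
        taps = em.design_lowpass_fir(300.0, FS, order=39)
        expected = em.fir_gain(taps, 50.0, FS, passes=2)
        out = em.lowpass_filter(sine_sweep(50.0)).values
        mid = out[500:1500]  # away from edges
        assert (mid.max() - mid.min()) / 2 == pytest.approx(expected, rel=0.02)
        assert expected == pytest.approx(1.0, rel=0.02)

    def test_stopband_sine_attenuated_to_design_level(self):
        taps = em.design_lowpass_fir(300.0, FS, order=39)
        ceiling = em.fir_gain(taps, 500.0, FS, passes=2)
        out = em.lowpass_filter(sine_sweep(500.0)).values
        mid = out[500:1500]
        assert (mid.max() - mid.min()) / 2 <= ceiling * 1.05 + 1e-6
        assert ceiling < 0.01  # genuinely in the stopband

    def test_sweep_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            em.lowpass_filter(make_sweep(np.zeros(100)))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            em.design_lowpass_fir(2500.0, FS)

    def test_batch_matches_per_sweep(self, rng):
        from evokedmi.sweeps import lowpass_filter_batch

        mat = rng.normal(size=(5, 600))
        batch = lowpass_filter_batch(mat, FS)
        for row, raw in zip(batch, mat):
            single = em.lowpass_filter(make_sweep(raw)).values
            assert np.allclose(row, single, atol=1e-12)

    def test_zero_phase_keeps_symmetric_pulse_centre(self):
        """Forward-backward filtering must not shift a symmetric extremum."""
        t = np.arange(440) / FS
        pulse = np.exp(-(((t - 0.055) / 0.010) ** 2))
        out = em.lowpass_filter(make_sweep(pulse)).values
        assert abs(int(np.argmax(out)) - int(np.argmax(pulse))) <= 1


class TestBaseline:
    def test_constant_goes_to_zero(self):
        out = em.baseline_correct(make_sweep(np.full(500, 3.0)))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_offset_removed_and_peak_time_kept(self):
        t = np.arange(440) / FS
        v = 1.5 + 5.0 * np.exp(-(((t - 0.055) / 0.010) ** 2))
        out = em.baseline_correct(make_sweep(v))
        assert out.values[:60].mean() == pytest.approx(0.0, abs=1e-12)
        assert np.argmax(out.values) == np.argmax(v)
        # baseline is ~1.5 (the bump is negligible in the first 15 ms)
        assert out.values.max() == pytest.approx(5.0, abs=1e-3)

    def test_constant_offsets_give_identical_outputs(self, rng):
        v = rng.normal(size=440)
        a = em.baseline_correct(make_sweep(v)).values
        b = em.baseline_correct(make_sweep(v + 7.25)).values
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_onset_has_no_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            em.baseline_correct(make_sweep(np.zeros(440), onset_s=0.0))


class TestFeatures:
    def test_psp_gaussian_bump(self):
        """Peak of 5exp(-((t-55ms)/10ms)^2): amplitude ~5 mV, latency 40 ms."""
        t = np.arange(440) / FS
        sw = make_sweep(5.0 * np.exp(-(((t - 0.055) / 0.010) ** 2)), "PSP")
        rec = em.extract_features(sw)
        assert rec.amplitude_mv == pytest.approx(5.0, rel=0.01)
        assert rec.latency_ms == 40.0
        assert not rec.degenerate

    def test_lfp_dip(self):
        t = np.arange(440) / FS
        sw = make_sweep(-3.0 * np.exp(-(((t - 0.030) / 0.008) ** 2)), "LFP")
        rec = em.extract_features(sw)
        assert rec.amplitude_mv == pytest.approx(3.0, rel=0.01)
        assert rec.latency_ms == 15.0

    def test_flat_sweep_flagged_degenerate(self):
        rec = em.extract_features(make_sweep(np.zeros(440)))
        assert rec.amplitude_mv == 0.0
        assert rec.latency_ms == 0.0  # earliest-sample tie rule
        assert rec.degenerate

    def test_window_outside_sweep(self):
        with pytest.raises(ValueError, match="window"):
            em.extract_features(make_sweep(np.zeros(200)))

    def test_chain_invariant_under_constant_offset(self, rng):
        t = np.arange(440) / FS
        base = 4.0 * np.exp(-(((t - 0.050) / 0.012) ** 2)) + 0.1 * rng.normal(size=440)

        def chain(v):
            sw = em.baseline_correct(em.lowpass_filter(make_sweep(v)))
            return em.extract_features(sw)

        r1, r2 = chain(base), chain(base + 3.0)
        assert r1.amplitude_mv == pytest.approx(r2.amplitude_mv, abs=1e-9)
        assert r1.latency_ms == r2.latency_ms

    @given(st.integers(min_value=0, max_value=10_000))
    def test_feature_ranges(self, seed):
        """Latency in [0, 85] ms and amplitude >= 0 for arbitrary sweeps."""
        rng = np.random.default_rng(seed)
        sig = "PSP" if rng.random() < 0.5 else "LFP"
        rec = em.extract_features(make_sweep(rng.normal(size=440), sig))
        assert 0.0 <= rec.latency_ms <= 85.0
        assert rec.amplitude_mv >= 0.0


def test_sweep_store_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    sweeps = [
        em.Sweep(rng.normal(size=440), 2000.0 * (i + 1), "PSP" if i % 2 else "LFP",
                 cell_id=f"c{i % 2}", trial_id=i)
        for i in range(6)
    ]
    path = tmp_path / "store.h5"
    em.write_sweep_store(path, sweeps)
    back = em.read_sweep_store(path)
    assert len(back) == 6
    key = lambda s: (s.cell_id, s.trial_id, s.signal_type)
    for orig, new in zip(sorted(sweeps, key=key), sorted(back, key=key)):
        assert np.allclose(orig.values, new.values)
        assert orig.stimulus_freq_hz == new.stimulus_freq_hz
        assert orig.signal_type == new.signal_type


def test_sweeps_csv_reader(tmp_path):
    import pandas as pd

    rng = np.random.default_rng(1)
    mat = rng.normal(size=(3, 440))
    df = pd.DataFrame(mat, columns=[f"t{i}" for i in range(440)])
    df.insert(0, "stimulus_freq_hz", [2000.0, 4000.0, 8000.0])
    df.insert(0, "trial_id", [0, 1, 2])
    path = tmp_path / "cell0.csv"
    df.to_csv(path, index=False)
    from evokedmi.sweeps import read_sweeps_csv

    sweeps = read_sweeps_csv(path, cell_id="cell0", signal_type="PSP")
    assert len(sweeps) == 3
    assert np.allclose(sweeps[1].values, mat[1])
    assert sweeps[2].stimulus_freq_hz == 8000.0
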