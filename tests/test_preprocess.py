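"""Filtering, alignment, windowing, normalization, label encoding."""

import numpy as np
import pytest

from swingseg.errors import (
    FilterLengthError,
    LabelsOutOfWindow,
    NoJumpPeak,
    WindowOutOfRange,
)
from swingseg.preprocess import (
    WindowDataset,
    align_by_jump_peak,
    assemble_input,
    build_windows,
    cut_window,
    decode_cnn_label,
    encode_labels,
    find_impact_proxy,
    lowpass_zero_phase,
    normalize_features,
)
from swingseg.swingdata import DividingPoints, ImuRecording


def _recording(n=800, fs=200.0, acc=None, gyro=None, placement="wrist"):
    t = np.arange(n) / fs
    acc = np.zeros((3, n)) if acc is None else acc
    gyro = np.zeros((3, n)) if gyro is None else gyro
    return ImuRecording(placement, t, acc, gyro, fs)


class TestLowpass:
    def test_constant_signal_unchanged(self):
        x = np.full(500, 3.7)
        assert np.allclose(lowpass_zero_phase(x, 200.0), x, atol=1e-9)

    def test_zero_phase_on_passband_sinusoid(self):
        t = np.arange(2000) / 200.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_zero_phase(x, 200.0)
        xc = np.correlate(x[200:-200], y[200:-200], mode="same")
        assert np.argmax(xc) == xc.size // 2  # peak at zero lag

    def test_stopband_attenuation_at_five_times_cutoff(self):
        # squared order-10 magnitude at 5x cutoff: 1/(1 + 5**20) -> ~1e-14
        t = np.arange(4000) / 200.0
        x = np.sin(2 * np.pi * 50.0 * t)
        y = lowpass_zero_phase(x, 200.0)
        assert np.max(np.abs(y[500:-500])) < 1e-3

    def test_short_signal_raises(self):
        with pytest.raises(FilterLengthError):
            lowpass_zero_phase(np.zeros(30), 200.0)


class TestAlignment:
    def test_injected_jump_spike_offset(self):
        acc = np.zeros((3, 800))
        acc[2] = -1.0
        acc[2, 200] = -5.0  # 4 g spike above gravity at t = 1.0 s
        rec = _recording(acc=acc)
        off = align_by_jump_peak(rec, 1.100, search_interval=(0.5, 1.5))
        assert off == pytest.approx(0.100, abs=1e-9)

    def test_flat_gravity_recording_has_no_peak(self):
        acc = np.zeros((3, 800))
        acc[2] = -1.0
        with pytest.raises(NoJumpPeak):
            align_by_jump_peak(_recording(acc=acc), 1.0, search_interval=(0.0, 2.0))

    def test_offset_reestimation_is_idempotent(self):
        acc = np.zeros((3, 800))
        acc[2] = -1.0
        acc[2, 200] = -5.0
        rec = _recording(acc=acc)
        off = align_by_jump_peak(rec, 1.0, search_interval=(0.5, 1.5))
        shifted = ImuRecording(rec.placement, rec.t + off, rec.acc, rec.gyro, 200.0)
        off2 = align_by_jump_peak(shifted, 1.0, search_interval=(0.5 + off, 1.5 + off))
        assert abs(off2) <= 0.005


class TestImpactProxy:
    def test_simulated_impact_found(self, noiseless_swings):
        for swing in noiseless_swings[:4]:
            for pl, rec in swing.recordings.items():
                assert abs(find_impact_proxy(rec) - swing.truth.imp_s) <= 0.01, pl

    def test_tie_break_is_earliest(self):
        acc = np.zeros((3, 800))
        acc[0, [100, 300]] = 5.0
        assert find_impact_proxy(_recording(acc=acc)) == pytest.approx(0.5)

    def test_pure_noise_returns_argmax_without_error(self, rng):
        acc = rng.normal(0, 0.1, (3, 800)).clip(-16, 16)
        assert 0.0 <= find_impact_proxy(_recording(acc=acc)) < 4.0


class TestCutWindow:
    def test_700_samples_spanning_expected_interval(self):
        rec = _recording(n=1600)  # 0..8 s
        win = cut_window(rec, 5.0)
        assert win.n_samples == 700
        assert win.t[0] == pytest.approx(2.5)
        assert win.t[-1] == pytest.approx(6.0 - 1 / 200.0)

    def test_insufficient_coverage_raises(self):
        with pytest.raises(WindowOutOfRange):
            cut_window(_recording(n=800), 1.0)

    def test_rate_scaling(self):
        rec = _recording(n=800, fs=100.0)  # 8 s at 100 Hz
        assert cut_window(rec, 5.0).n_samples == 350


class TestNormalize:
    def test_examples(self):
        assert np.allclose(normalize_features(np.array([-2.0, 0.0, 2.0])), [-1, 0, 1])
        assert np.allclose(normalize_features(np.array([5.0, 5.0, 5.0])), [0, 0, 0])

    def test_every_nonconstant_row_spans_unit_interval(self, rng):
        m = rng.normal(size=(7, 700))
        out = normalize_features(m)
        assert np.allclose(out.min(axis=1), -1) and np.allclose(out.max(axis=1), 1)


class TestAssembleEncode:
    def test_input_shapes_per_modality(self, noiseless_swings):
        rec = cut_window(noiseless_swings[0].recordings["wrist"],
                         noiseless_swings[0].truth.imp_s)
        assert assemble_input(rec, "a+g").shape == (7, 700)
        assert assemble_input(rec, "a").shape == (4, 700)
        assert assemble_input(rec, "g").shape == (4, 700)

    def test_time_row_is_affine_ramp(self, noiseless_swings):
        rec = cut_window(noiseless_swings[0].recordings["wrist"],
                         noiseless_swings[0].truth.imp_s)
        row = assemble_input(rec, "a+g")[0]
        assert row[0] == -1 and row[-1] == 1
        assert np.allclose(np.diff(row), np.diff(row)[0])

    def test_impact_fraction_and_roundtrip(self, noiseless_swings):
        swing = noiseless_swings[0]
        win = cut_window(swing.recordings["wrist"], swing.truth.imp_s)
        seq, frac = encode_labels(win, swing.truth)
        assert frac[2] == pytest.approx(2.5 / 3.5, abs=0.002)
        dec = decode_cnn_label(frac, float(win.t[0]), 3.5)
        assert np.allclose(dec.as_array(), swing.truth.as_array(), atol=0.005)

    def test_truth_outside_window_raises(self):
        rec = _recording(n=700)
        with pytest.raises(LabelsOutOfWindow):
            encode_labels(rec, DividingPoints(0.5, 1.0, 2.0, 3.6))


def test_filter_window_commutes_away_from_edges(noiseless_swings):
    """Filtering the full recording then windowing matches windowing a padded
    stretch then filtering, except near the window edges."""
    swing = noiseless_swings[0]
    rec = swing.recordings["wrist"]
    imp = swing.truth.imp_s
    full = lowpass_zero_phase(rec.acc, 200.0)
    win_a = cut_window(ImuRecording("wrist", rec.t, full.clip(-16, 16), rec.gyro), imp)
    win_b = cut_window(rec, imp)
    filt_b = lowpass_zero_phase(win_b.acc, 200.0)
    inner = slice(100, 600)
    assert np.max(np.abs(win_a.acc[:, inner] - filt_b[:, inner])) < 1e-3


def test_window_dataset_npz_roundtrip(noiseless_swings, tmp_path):
    ds = build_windows(noiseless_swings[:4], "wrist", "a+g")
    p = tmp_path / "cache.npz"
    ds.save_npz(p)
    back = WindowDataset.load_npz(p)
    assert np.array_equal(back.inputs, ds.inputs)
    assert np.array_equal(back.seq_labels, ds.seq_labels)
    assert np.array_equal(back.point_labels, ds.point_labels)
    assert list(back.subject_ids) == list(ds.subject_ids)
    assert back.modality == "a+g"
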