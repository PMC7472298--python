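"""Signal conditioning, windowing, normalization and label encoding.

Pipeline order for one swing: zero-phase low-pass filter every channel,
locate impact (ground truth during training-set construction, the raw
acceleration-norm peak at inference), cut a 3.5 s window from 2.5 s before
to 1 s after impact, assemble the (time, channels) input matrix, min-max
normalize each feature row into [-1, +1], and encode both label forms
(per-sample phase classes for the sequence classifier, window-normalized
dividing-point fractions for the regressor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import FilterLengthError, LabelsOutOfWindow, NoJumpPeak, WindowOutOfRange
from .swingdata import DividingPoints, ImuRecording, PhaseSequence, phases_from_points

WINDOW_PRE_S = 2.5
WINDOW_POST_S = 1.0
WINDOW_LEN_S = WINDOW_PRE_S + WINDOW_POST_S

MODALITIES = ("a", "g", "a+g")


def lowpass_zero_phase(
    signal: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 10.0,
    order: int = 10,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    ``order`` is the design order of the underlying filter; the bidirectional
    application doubles the effective attenuation and cancels the phase.
    Edges are handled by odd reflection over 3x the design order.  Works on
    the last axis of 1-D or 2-D input.
    """
    signal = np.asarray(signal, dtype=float)
    padlen = 3 * order
    if signal.shape[-1] <= padlen:
        raise FilterLengthError(
            f"signal length {signal.shape[-1]} <= {padlen} (3 x filter order)"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    return sosfiltfilt(sos, signal, axis=-1, padtype="odd", padlen=padlen)


def filter_recording(rec: ImuRecording, cutoff_hz: float = 10.0, order: int = 10) -> ImuRecording:
    """Return a copy of the recording with all six channels low-pass filtered."""
    return ImuRecording(
        rec.placement,
        rec.t,
        np.clip(lowpass_zero_phase(rec.acc, rec.sample_rate_hz, cutoff_hz, order), -16, 16),
        np.clip(lowpass_zero_phase(rec.gyro, rec.sample_rate_hz, cutoff_hz, order), -2000, 2000),
        rec.sample_rate_hz,
    )


def align_by_jump_peak(
    rec: ImuRecording,
    reference_t_peak: float,
    search_interval: tuple = (0.0, 0.5),
    min_prominence_g: float = 1.5,
) -> float:
    """Clock offset from the pre-swing jump spike.

    The jump's acceleration-norm peak inside ``search_interval`` is matched
    to ``reference_t_peak`` on the reference clock; adding the returned
    offset to the recording's times aligns the clocks.  Raises
    ``no_jump_peak`` when no peak rises ``min_prominence_g`` above the
    interval's baseline (median norm).
    """
    mask = (rec.t >= search_interval[0]) & (rec.t <= search_interval[1])
    if not np.any(mask):
        raise NoJumpPeak("empty search interval")
    norm = rec.acc_norm()[mask]
    baseline = float(np.median(norm))
    i = int(np.argmax(norm))
    if norm[i] - baseline < min_prominence_g:
        raise NoJumpPeak(
            f"max norm {norm[i]:.2f} g is < {min_prominence_g} g above baseline"
        )
    t_peak = float(rec.t[mask][i])
    return reference_t_peak - t_peak


def find_impact_proxy(rec: ImuRecording) -> float:
    """Time of the global acceleration-norm maximum (earliest on ties).

    The impact shock is the highest-frequency, highest-amplitude feature of
    a swing, so the proxy is taken on the *raw* signal; low-pass filtering
    would smear the shock and bias the peak.
    """
    return float(rec.t[int(np.argmax(rec.acc_norm()))])


def cut_window(rec: ImuRecording, imp_time_s: float) -> ImuRecording:
    """Cut the impact-centered analysis window (2.5 s before to 1 s after).

    Returns exactly ``round(3.5 * sample_rate)`` samples, the first at or
    after ``imp_time_s - 2.5``.  Raises ``window_out_of_range`` when the
    recording does not cover the window.
    """
    fs = rec.sample_rate_hz
    n_win = int(round(WINDOW_LEN_S * fs))
    t_start = imp_time_s - WINDOW_PRE_S
    i0 = int(np.ceil((t_start - rec.t[0]) * fs - 1e-9))
    if i0 < 0 or i0 + n_win > rec.n_samples:
        raise WindowOutOfRange(
            f"window [{t_start:.3f}, {imp_time_s + WINDOW_POST_S:.3f}] s not covered "
            f"by recording [{rec.t[0]:.3f}, {rec.t[-1]:.3f}] s"
        )
    sl = slice(i0, i0 + n_win)
    return ImuRecording(rec.placement, rec.t[sl], rec.acc[:, sl], rec.gyro[:, sl], fs)


def normalize_features(matrix: np.ndarray) -> np.ndarray:
    """Min-max scale each row into [-1, +1]; a constant row maps to zeros."""
    arr = np.asarray(matrix, dtype=float)
    squeeze = arr.ndim == 1
    m = np.atleast_2d(arr)
    lo = m.min(axis=-1, keepdims=True)
    hi = m.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(m)
    nz = (span > 0).ravel()
    out[nz] = 2.0 * (m[nz] - lo[nz]) / span[nz] - 1.0
    return out[0] if squeeze else out


def assemble_input(window: ImuRecording, modality: str = "a+g") -> np.ndarray:
    """Input matrix for the learned models: rows (time, channels), normalized.

    ``a+g`` gives 7 x N (time, ax, ay, az, gx, gy, gz); a single modality
    gives 4 x N.
    """
    if modality == "a+g":
        rows = [window.t, *window.acc, *window.gyro]
    elif modality == "a":
        rows = [window.t, *window.acc]
    elif modality == "g":
        rows = [window.t, *window.gyro]
    else:
        raise ValueError(f"modality must be one of {MODALITIES}, got {modality!r}")
    return normalize_features(np.vstack(rows))


def encode_labels(window: ImuRecording, truth: DividingPoints):
    """Both label encodings for one window.

    Returns ``(classes, fractions)``: the per-sample phase classes (length N)
    and the four dividing points as fractions of the window in (0, 1).
    Raises ``labels_out_of_window`` when the truth is not inside the window.
    """
    t0 = float(window.t[0])
    dur = window.n_samples / window.sample_rate_hz
    pts = truth.as_array()
    if pts[0] < t0 - 1e-12 or pts[-1] >= t0 + dur:
        raise LabelsOutOfWindow(
            f"truth [{pts[0]:.3f}, {pts[-1]:.3f}] outside window "
            f"[{t0:.3f}, {t0 + dur:.3f})"
        )
    seq = phases_from_points(truth, window.t)
    frac = (pts - t0) / dur
    return seq, frac


def decode_cnn_label(frac: np.ndarray, t0: float, duration_s: float) -> DividingPoints:
    """Invert the regressor encoding back to absolute times."""
    return DividingPoints.from_array(t0 + np.asarray(frac, float) * duration_s)


# ---------------------------------------------------------------------------
# windowed dataset container


@dataclass
class WindowDataset:
    """Assembled model-ready windows for a set of swings.

    inputs: (n, F, T) normalized matrices; seq_labels: (n, T) phase codes;
    point_labels: (n, 4) window fractions; t0_s: (n,) window starts;
    truths: (n, 4) absolute dividing-point times.
    """

    inputs: np.ndarray
    seq_labels: np.ndarray
    point_labels: np.ndarray
    subject_ids: np.ndarray
    t0_s: np.ndarray
    truths: np.ndarray
    sample_rate_hz: float = 200.0
    modality: str = "a+g"

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def duration_s(self) -> float:
        return self.inputs.shape[2] / self.sample_rate_hz

    def subset(self, idx) -> "WindowDataset":
        idx = np.asarray(idx)
        return WindowDataset(
            self.inputs[idx], self.seq_labels[idx], self.point_labels[idx],
            self.subject_ids[idx], self.t0_s[idx], self.truths[idx],
            self.sample_rate_hz, self.modality,
        )

    def save_npz(self, path) -> None:
        np.savez(
            path,
            inputs=self.inputs, seq_labels=self.seq_labels,
            point_labels=self.point_labels, subject_ids=self.subject_ids,
            t0_s=self.t0_s, truths=self.truths,
            sample_rate_hz=self.sample_rate_hz, modality=self.modality,
        )

    @classmethod
    def load_npz(cls, path) -> "WindowDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                z["inputs"], z["seq_labels"], z["point_labels"],
                z["subject_ids"], z["t0_s"], z["truths"],
                float(z["sample_rate_hz"]), str(z["modality"]),
            )


def build_windows(
    swings: Sequence,
    placement: str,
    modality: str = "a+g",
    use_truth_impact: bool = True,
    cutoff_hz: float = 10.0,
    order: int = 10,
) -> WindowDataset:
    """Filter, window and encode a list of swings for one placement.

    ``use_truth_impact=True`` centers windows on the labeled impact (training
    construction); ``False`` uses the raw acceleration-peak proxy (inference).
    """
    inputs, seqs, fracs, subs, t0s, truths = [], [], [], [], [], []
    for swing in swings:
        rec = swing.recordings[placement]
        imp = swing.truth.imp_s if use_truth_impact else find_impact_proxy(rec)
        filt = filter_recording(rec, cutoff_hz, order)
        win = cut_window(filt, imp)
        inputs.append(assemble_input(win, modality))
        seq, frac = encode_labels(win, swing.truth)
        seqs.append(seq.classes)
        fracs.append(frac)
        subs.append(swing.subject_id)
        t0s.append(win.t[0])
        truths.append(swing.truth.as_array())
    return WindowDataset(
        np.asarray(inputs), np.asarray(seqs), np.asarray(fracs),
        np.asarray(subs), np.asarray(t0s), np.asarray(truths),
        swings[0].recordings[placement].sample_rate_hz, modality,
    )
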