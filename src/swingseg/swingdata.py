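"""Domain types and phase/point conversions for golf-swing segmentation.

A full swing is divided into five phases -- before-swing (BF), backswing
(BS), downswing (DS), follow-through (FT) and after-swing (AF) -- by four
dividing points: address (ADD), backswing top (BST), impact (IMP) and
finish (FIN).  Dividing points are stored as continuous times in seconds
relative to the start of the recording, never as sample indices, so the
labels survive resampling.

Boundary convention: intervals are half-open and a boundary sample belongs
to the *later* phase, which makes the phase-sequence <-> dividing-point
conversions exact inverses up to one sample step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict

import numpy as np

from .errors import (
    DegeneratePhase,
    IncompletePhaseSequence,
    LabelsOutOfWindow,
    TimeError,
)

PLACEMENTS = ("wrist", "head", "waist")
POINTS = ("ADD", "BST", "IMP", "FIN")
CLUBS = ("driver", "iron7")

ACC_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0


class Phase(IntEnum):
    """Swing phases in temporal order; the integer codes are ordinal."""

    BF = 0
    BS = 1
    DS = 2
    FT = 3
    AF = 4


PHASES = tuple(Phase)
PHASE_NAMES = tuple(p.name for p in PHASES)


def _check_time_vector(t: np.ndarray, uniform: bool = True) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise TimeError("time vector must be 1-D with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TimeError("time vector must be strictly increasing")
    if uniform and np.ptp(dt) > 1e-9:
        raise TimeError("time vector must be uniformly spaced (tol 1e-9 s)")
    return t


@dataclass
class ImuRecording:
    """One placement's 3-axis accelerometer + 3-axis gyroscope stream.

    acc is in g, gyro in deg/s; both are 3 x N with rows (x, y, z).
    The sensor saturates at +/-16 g and +/-2000 dps.
    """

    placement: str
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sample_rate_hz: float = 200.0

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        self.t = _check_time_vector(self.t)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        n = self.t.size
        if self.acc.shape != (3, n) or self.gyro.shape != (3, n):
            raise ValueError("acc and gyro must be 3 x len(t)")
        if np.any(np.abs(self.acc) > ACC_RANGE_G + 1e-9):
            raise ValueError("acceleration outside +/-16 g sensor range")
        if np.any(np.abs(self.gyro) > GYRO_RANGE_DPS + 1e-9):
            raise ValueError("angular velocity outside +/-2000 dps sensor range")

    @property
    def n_samples(self) -> int:
        return self.t.size

    def acc_norm(self) -> np.ndarray:
        return np.linalg.norm(self.acc, axis=0)

    def gyro_norm(self) -> np.ndarray:
        return np.linalg.norm(self.gyro, axis=0)


@dataclass
class ClubheadTrack:
    """Reference clubhead motion: signed ball-plane coordinate (m, zero at
    the ball) and speed (m/s) versus time.  Source of ground-truth labels."""

    t: np.ndarray
    ball_coord: np.ndarray
    speed: np.ndarray

    def __post_init__(self):
        self.t = _check_time_vector(self.t, uniform=False)
        self.ball_coord = np.asarray(self.ball_coord, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.ball_coord.shape != self.t.shape or self.speed.shape != self.t.shape:
            raise ValueError("ball_coord and speed must match len(t)")
        if np.any(self.speed < -1e-12):
            raise ValueError("clubhead speed must be >= 0")


@dataclass(frozen=True)
class DividingPoints:
    """The four event times in seconds; strictly ordered ADD < BST < IMP < FIN."""

    add_s: float
    bst_s: float
    imp_s: float
    fin_s: float

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.diff(vals) > 0):
            raise ValueError(f"dividing points must be strictly ordered, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.add_s, self.bst_s, self.imp_s, self.fin_s], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "DividingPoints":
        a = np.asarray(arr, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


@dataclass
class PhaseSequence:
    """Per-sample phase labels (length-N vector of Phase codes)."""

    classes: np.ndarray

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if self.classes.ndim != 1:
            raise ValueError("classes must be 1-D")
        if np.any((self.classes < 0) | (self.classes > 4)):
            raise ValueError("class codes must be in 0..4")

    def __len__(self) -> int:
        return self.classes.size

    def counts(self) -> Dict[str, int]:
        return {p.name: int(np.sum(self.classes == p)) for p in PHASES}


@dataclass
class SwingSet:
    """One swing: per-placement IMU recordings, the reference clubhead track
    and the ground-truth dividing points."""

    subject_id: str
    club: str
    recordings: Dict[str, ImuRecording]
    track: ClubheadTrack
    truth: DividingPoints

    def __post_init__(self):
        if self.club not in CLUBS:
            raise ValueError(f"unknown club {self.club!r}")
        for name, rec in self.recordings.items():
            if name not in PLACEMENTS:
                raise ValueError(f"unknown placement {name!r}")
            if rec.t[0] > self.truth.add_s or rec.t[-1] < self.truth.fin_s:
                raise ValueError(
                    f"{name} recording does not cover the truth interval"
                )


# ---------------------------------------------------------------------------
# phase <-> point conversions


def phases_from_points(points: DividingPoints, t: np.ndarray) -> PhaseSequence:
    """Label every sample of ``t`` with its phase (half-open intervals,
    boundary sample belongs to the later phase).

    Raises ``labels_out_of_window`` if any point lies outside t's span.
    An ADD at exactly t[0] (empty BF) or FIN past the last sample is legal
    but flagged with a warning, since real windows may clip BF/AF.
    """
    t = _check_time_vector(t)
    pts = points.as_array()
    if pts[0] < t[0] - 1e-12 or pts[-1] > t[-1] + 1e-12:
        raise LabelsOutOfWindow(
            f"points span [{pts[0]:.4f}, {pts[-1]:.4f}] s outside window "
            f"[{t[0]:.4f}, {t[-1]:.4f}] s"
        )
    classes = np.searchsorted(pts, t, side="right")
    seq = PhaseSequence(classes)
    cnt = seq.counts()
    if cnt["BF"] == 0 or cnt["AF"] == 0:
        warnings.warn("window clips BF or AF (empty edge phase)", stacklevel=2)
    return seq


def points_from_phases(
    seq: PhaseSequence,
    t: np.ndarray,
    median_width: int = 5,
    min_run: int = 10,
) -> DividingPoints:
    """Invert :func:`phases_from_points`: each dividing point is the time of
    the first sample of the later phase's first persistent run.

    The sequence is cleaned first (median filter + persistent-run repair, see
    :func:`clean_phase_sequence`) so isolated mislabeled samples are absorbed.
    Raises ``incomplete_phase_sequence`` if any phase is missing after cleanup.
    """
    t = _check_time_vector(t)
    cleaned = clean_phase_sequence(seq, median_width=median_width, min_run=min_run)
    c = cleaned.classes
    times = []
    for phase in (Phase.BS, Phase.DS, Phase.FT, Phase.AF):
        idx = np.flatnonzero(c == phase)
        times.append(float(t[idx[0]]))
    return DividingPoints(*times)


def clean_phase_sequence(
    seq: PhaseSequence, median_width: int = 5, min_run: int = 10
) -> PhaseSequence:
    """Repair a raw per-sample classification into a monotone BF->AF walk.

    Odd-width median filter over the ordinal class codes removes isolated
    glitches; then boundaries are fixed at the first run of at least
    ``min_run`` samples of each successive phase.  Raises
    ``incomplete_phase_sequence`` when a phase has no persistent run.
    """
    if median_width % 2 != 1:
        raise ValueError("median_width must be odd")
    c = seq.classes.copy()
    n = c.size
    if median_width > 1 and n >= median_width:
        from scipy.ndimage import median_filter

        c = median_filter(c, size=median_width, mode="nearest")
    # run-length encode
    change = np.flatnonzero(np.diff(c)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    values = c[starts]
    boundaries = []
    search_from = 0
    for phase in (Phase.BS, Phase.DS, Phase.FT, Phase.AF):
        hit = None
        for s, ln, v in zip(starts, lengths, values):
            if s < search_from:
                continue
            if v == phase and ln >= min_run:
                hit = s
                break
        if hit is None:
            raise IncompletePhaseSequence(
                f"no persistent run (>= {min_run} samples) of phase {phase.name}"
            )
        boundaries.append(hit)
        search_from = hit
    out = np.zeros(n, dtype=np.int64)
    for k, b in enumerate(boundaries, start=1):
        out[b:] = k
    return PhaseSequence(out)


def phase_lengths(points: DividingPoints):
    """(BS, DS, FT, full-swing) durations in seconds; full = BS + DS + FT."""
    bs = points.bst_s - points.add_s
    ds = points.imp_s - points.bst_s
    ft = points.fin_s - points.imp_s
    return bs, ds, ft, bs + ds + ft


def phase_length_error_pct(est: DividingPoints, truth: DividingPoints):
    """Per-phase absolute length error as percent of the reference length."""
    out = []
    for le, lt in zip(phase_lengths(est)[:3], phase_lengths(truth)[:3]):
        if lt <= 0:
            raise DegeneratePhase("reference phase has zero length")
        out.append(100.0 * abs(le - lt) / lt)
    return tuple(out)
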