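"""Synthetic golf-swing kinematics generator.

The generator emulates the statistical structure of instrumented golf-swing
data recorded from a single body-worn IMU (wrist, head or waist) together
with a reference clubhead track:

* phase durations drawn per swing from truncated normals calibrated to
  reference phase-length statistics (backswing 1.163 +/- 0.232 s, downswing
  0.317 +/- 0.050 s, follow-through 0.670 +/- 0.119 s);
* a clubhead speed profile built from raised-cosine bumps -- a small
  backswing bump returning to a local minimum at backswing top (BST), a large
  rise through the downswing peaking at impact (IMP), a decay through the
  follow-through to a local minimum at finish (FIN) -- with the signed
  ball-plane coordinate crossing zero exactly at IMP;
* per-placement acceleration and angular-velocity channels assembled from
  smooth phase templates.  Bulk motion templates are shifted by a
  proximal-to-distal lag (waist leads, then head, then wrist) plus a
  subject-specific lag offset, while the *indicator events* (the minima /
  zero-crossings a heuristic segmenter keys on) are anchored at the true
  dividing points, so in the noiseless limit every shipped indicator rule
  recovers the truth to within a couple of samples;
* deliberately low signal-to-noise features at ADD and FIN (wide, shallow
  notches) and sharp features at BST and IMP, reproducing the observed
  difficulty ordering of the dividing points;
* a decaying-oscillation acceleration transient starting at impact, a light
  pre-swing jump spike for clock alignment, constant gravity projections,
  white sensor noise, and clipping to the +/-16 g / +/-2000 dps sensor range;
* lognormal per-subject amplitude multipliers and normal per-subject lag
  offsets as between-subject random effects.

Randomness is hierarchical: every (subject, swing) pair gets an independent
``numpy`` SeedSequence spawned from the dataset seed, so enlarging a dataset
never changes previously generated swings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .errors import DurationError, UnlabelableTrack
from .swingdata import (
    ACC_RANGE_G,
    GYRO_RANGE_DPS,
    PLACEMENTS,
    ClubheadTrack,
    DividingPoints,
    ImuRecording,
    SwingSet,
)

# ---------------------------------------------------------------------------
# configuration


def _placement_dict(wrist, head, waist):
    return {"wrist": wrist, "head": head, "waist": waist}


@dataclass
class GeneratorConfig:
    """All tunable knobs of the generator; defaults are the study conditions.

    Durations are seconds, accelerations g, angular velocities deg/s.
    ``gyro_amp`` / ``acc_amp`` multiply the shipped per-placement kinematic
    templates (1.0 = the documented default amplitudes).
    """

    sample_rate_hz: float = 200.0
    # phase-duration statistics (truncated normal draws)
    bs_mean_s: float = 1.163
    bs_sd_s: float = 0.232
    ds_mean_s: float = 0.317
    ds_sd_s: float = 0.050
    ft_mean_s: float = 0.670
    ft_sd_s: float = 0.119
    duration_floor_s: float = 0.1
    duration_z_clip: float = 3.0
    ft_max_s: float = 0.98  # keeps FIN inside a window ending 1 s after impact
    # recording geometry
    imp_time_s: float = 2.8  # impact time within the recording
    af_pad_s: float = 0.8  # recording continues this long past impact + 1 s
    jump_time_s: float = 0.15
    jump_amp_g: float = 1.2
    # proximal-to-distal bulk-motion lags (waist <= head <= wrist)
    lag_s: Dict[str, float] = field(
        default_factory=lambda: _placement_dict(0.030, 0.015, 0.0)
    )
    # master amplitude multipliers per placement
    gyro_amp: Dict[str, float] = field(
        default_factory=lambda: _placement_dict(1.0, 1.0, 1.0)
    )
    acc_amp: Dict[str, float] = field(
        default_factory=lambda: _placement_dict(1.0, 1.0, 1.0)
    )
    # impact transient (decaying oscillation starting at IMP)
    impact_amp_g: Dict[str, float] = field(
        default_factory=lambda: _placement_dict(12.0, 3.5, 4.5)
    )
    impact_decay_s: float = 0.04
    impact_freq_hz: float = 70.0
    # white sensor/soft-tissue noise (raw, before clipping)
    noise_acc_g: float = 0.08
    noise_gyro_dps: float = 8.0
    # subject random effects
    subject_amp_sd: float = 0.15  # lognormal sigma of amplitude multipliers
    subject_lag_sd_s: float = 0.010  # SD of per-placement lag offsets
    # clubhead speed profile
    speed_peak_mps: Dict[str, float] = field(
        default_factory=lambda: {"driver": 40.0, "iron7": 34.0}
    )
    bs_speed_peak_mps: float = 4.0
    waggle_speed_mps: float = 0.3
    speed_noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("bs_sd_s", "ds_sd_s", "ft_sd_s", "subject_amp_sd", "subject_lag_sd_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (
            self.lag_s["waist"] <= self.lag_s["head"] <= self.lag_s["wrist"]
        ):
            raise ValueError("lags must be ordered waist <= head <= wrist")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class SubjectProfile:
    """Between-subject random effects: per-placement amplitude multipliers
    (lognormal, median 1) and bulk-motion lag offsets (normal, mean 0)."""

    subject_id: str
    amp: Dict[str, float]
    lag_offset_s: Dict[str, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.amp.values()):
            raise ValueError("amplitude multipliers must be > 0")


def sample_subject_profile(
    config: GeneratorConfig, rng: np.random.Generator, subject_id: str = "S01"
) -> SubjectProfile:
    amp = {}
    lag = {}
    for p in PLACEMENTS:
        amp[p] = float(np.exp(rng.normal(0.0, config.subject_amp_sd)))
        off = float(rng.normal(0.0, config.subject_lag_sd_s))
        lim = 3.0 * config.subject_lag_sd_s
        lag[p] = float(np.clip(off, -lim, lim))
    return SubjectProfile(subject_id, amp, lag)


# ---------------------------------------------------------------------------
# smooth template primitives


def _br(t, a, b):
    """Raised-cosine bump on [a, b]: 0 at the ends, 1 at the midpoint, C1."""
    if b - a <= 0:
        return np.zeros_like(t)
    u = (t - a) / (b - a)
    out = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return np.where((u >= 0) & (u <= 1), out, 0.0)


def _bc(t, c, w):
    """Raised-cosine bump centered at c with total width w."""
    return _br(t, c - w / 2.0, c + w / 2.0)


def _ss(t, a, b, power=1):
    """Half-sine segment on [a, b] (nonzero end slopes for power 1)."""
    if b - a <= 0:
        return np.zeros_like(t)
    u = (t - a) / (b - a)
    out = np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** power
    return np.where((u >= 0) & (u <= 1), out, 0.0)


def _zc(t, c, w):
    """Smooth antisymmetric shape crossing zero at c with positive slope."""
    return np.sin(2.0 * np.pi * (t - c) / w) * _bc(t, c, w)


def _settle(t, c, w=0.15, span=1.2):
    """Tent-shaped notch: zero exactly at c, rising |t-c|/w to a plateau that
    decays smoothly over +/-span/2.  Subtracted from a gravity-aligned channel
    it gives the signal norm a unique, locally V-shaped minimum at c."""
    return np.minimum(np.abs(t - c) / w, 1.0) * _bc(t, c, span)


def _transient(t, t0, amp, decay, freq):
    """Causal decaying oscillation starting at t0 (the club-side shock)."""
    dt = t - t0
    # cosine phase: the raw peak sits exactly at the impact instant and the
    # oscillation leaks far less energy below the 10 Hz analysis band
    out = amp * np.exp(-np.maximum(dt, 0.0) / decay) * np.cos(2 * np.pi * freq * dt)
    return np.where(dt >= 0, out, 0.0)


def _transient_symmetric(t, t0, amp, width=0.2, freq=25.0):
    """Soft-tissue-damped shock at proximal segments: a symmetric windowed
    oscillation peaking exactly at t0.  Its sub-10 Hz leakage is symmetric
    about the impact, so it cannot bias any extremum-based indicator."""
    return amp * _bc(t, t0, width) * np.cos(2 * np.pi * freq * (t - t0))


# ---------------------------------------------------------------------------
# per-placement kinematic templates
#
# Each entry builds (acc 3xN in g, gyro 3xN in dps) from the event times
# A(DD), B(ST), I(MP), F(IN).  Anchored indicator features (no lag):
#   wrist: omega_y minima at ADD and IMP, omega_z zero-crossing at BST,
#          omega-norm minimum at FIN; acc: a_y min at ADD, a_x min at BST,
#          a_z max at IMP, a-norm min at FIN
#   head:  omega-norm minima at ADD and FIN, a_x min at BST, a-norm min at
#          IMP; gyro-only extras: omega_y z.c. at BST, omega_y min at IMP
#   waist: omega_y min at ADD + z.c. at BST, a_x z.c. at IMP, omega-norm min
#          at FIN; extras: omega_z min at IMP, a_y min at ADD, a_z min at BST
# Bulk phase templates are shifted by tau (placement lag + subject offset).

_GRAVITY = {
    "wrist": np.array([0.45, 0.30, -0.84]),
    "head": np.array([0.10, -0.20, -0.97]),
    "waist": np.array([0.00, 0.25, -0.97]),
}
_GRAVITY = {k: v / np.linalg.norm(v) for k, v in _GRAVITY.items()}


def _wrist_signals(t, A, B, I, F, tau):
    gx = 20.0 * (1.0 - _bc(t, F, 0.8)) \
        + 300.0 * _br(t, A + 0.1 + tau, B + tau) \
        - 450.0 * _br(t, B + tau, I + tau)
    gy = -15.0 * _bc(t, A, 0.8) \
        + 200.0 * _br(t, A + 0.45 + tau, B + tau) \
        - 320.0 * _bc(t, I, 0.12) \
        + 150.0 * _br(t, F, F + 0.5)
    # backswing bulk ends before the BST crossing zone; the crossing itself is
    # locally antisymmetric so zero-phase filtering does not displace it
    gz = 140.0 * _ss(t, A, B - 0.12) \
        - 90.0 * _zc(t, B, 0.4) \
        - 300.0 * _br(t, B + 0.1, I) \
        - 170.0 * _ss(t, I, F, power=4) \
        + 3.0 * _zc(t, F, 0.3)
    ax = -0.35 * _bc(t, B, 0.3) + 0.5 * _br(t, A + 0.1 + tau, B - 0.2 + tau)
    ay = -0.10 * _bc(t, A, 0.8) \
        + 0.4 * _br(t, A + 0.45 + tau, B + tau) \
        + 1.2 * _br(t, B + tau, I + tau)
    az = 2.2 * _bc(t, I, 0.10) \
        - 0.7 * _ss(t, I, F, power=2) \
        - 0.25 * _ss(t, F, F + 1.2, power=2) \
        - 0.05 * _settle(t, F)
    return np.vstack([ax, ay, az]), np.vstack([gx, gy, gz])


def _head_signals(t, A, B, I, F, tau):
    gx = 15.0 * _br(t, A + 0.1 + tau, B + tau) \
        - 35.0 * _br(t, B + tau, I + tau) \
        + 25.0 * _br(t, F, F + 0.5)
    gy = 25.0 * _ss(t, A + 0.25, B - 0.12) \
        - 18.0 * _zc(t, B, 0.4) \
        - 60.0 * _br(t, B + 0.1, I - 0.06) \
        - 45.0 * _bc(t, I, 0.12) \
        - 20.0 * _ss(t, I, F, power=4) \
        + 3.0 * _zc(t, F, 0.3)
    gz = 8.0 * (1.0 - _bc(t, A, 0.8)) * (1.0 - _bc(t, F, 0.8)) \
        + 12.0 * _br(t, B + tau, I + tau)
    ax = -0.18 * _bc(t, B, 0.2)
    ay = -0.08 * _bc(t, A, 0.8) \
        - 0.25 * _ss(t, I, F, power=2) \
        - 0.12 * _ss(t, F, F + 1.2, power=2)
    az = 0.22 * _bc(t, I, 0.2) + 0.3 * _br(t, A + 0.1 + tau, B + tau) \
        - 0.05 * _settle(t, F)
    return np.vstack([ax, ay, az]), np.vstack([gx, gy, gz])


def _waist_signals(t, A, B, I, F, tau):
    gx = 60.0 * _br(t, A + 0.1 + tau, B + tau) - 120.0 * _br(t, B + tau, I + tau)
    gy = -12.0 * _bc(t, A, 0.8) \
        + 50.0 * _ss(t, A + 0.45, B - 0.12) \
        - 10.0 * _zc(t, B, 0.4) \
        - 150.0 * _br(t, B + 0.1, I) \
        - 40.0 * _ss(t, I, F, power=4) \
        + 3.0 * _zc(t, F, 0.3)
    gz = 12.0 * (1.0 - _bc(t, F, 0.8)) \
        - 8.0 * _bc(t, I, 0.12) \
        + 35.0 * _br(t, F, F + 0.5)
    ax = 0.15 * _zc(t, I, 0.6)
    ay = -0.12 * _bc(t, A, 0.8) \
        + 0.5 * _br(t, A + 0.45 + tau, B + tau) \
        + 0.9 * _br(t, B + tau, I + tau)
    az = -0.4 * _bc(t, B, 0.2) \
        - 0.5 * _ss(t, I, F, power=2) \
        - 0.2 * _ss(t, F, F + 1.2, power=2) \
        - 0.05 * _settle(t, F)
    return np.vstack([ax, ay, az]), np.vstack([gx, gy, gz])


_TEMPLATES = {"wrist": _wrist_signals, "head": _head_signals, "waist": _waist_signals}

# shock per placement: (axis index into (x, y, z), sign, kind)
_SHOCK_AXIS = {
    "wrist": (2, 1.0, "causal"),
    "head": (0, -1.0, "symmetric"),
    "waist": (2, -1.0, "symmetric"),
}


# ---------------------------------------------------------------------------
# swing simulation


def _trunc_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        if not (lo <= mean <= hi):
            raise DurationError("degenerate duration outside truncation bounds")
        return float(mean)
    if lo >= hi:
        raise DurationError(f"empty truncation interval [{lo}, {hi}]")
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise DurationError("truncated-normal rejection sampling failed")


def _draw_durations(config: GeneratorConfig, rng: np.random.Generator):
    z = config.duration_z_clip
    fl = config.duration_floor_s
    bs = _trunc_normal(
        rng, config.bs_mean_s, config.bs_sd_s,
        max(fl, config.bs_mean_s - z * config.bs_sd_s),
        config.bs_mean_s + z * config.bs_sd_s,
    )
    ds = _trunc_normal(
        rng, config.ds_mean_s, config.ds_sd_s,
        max(fl, config.ds_mean_s - z * config.ds_sd_s),
        config.ds_mean_s + z * config.ds_sd_s,
    )
    ft = _trunc_normal(
        rng, config.ft_mean_s, config.ft_sd_s,
        max(fl, config.ft_mean_s - z * config.ft_sd_s),
        min(config.ft_mean_s + z * config.ft_sd_s, config.ft_max_s),
    )
    return bs, ds, ft


def _speed_profile(t, A, B, I, F, v_imp, v_bs, v_waggle):
    ds = I - B
    ft = F - I
    speed = v_waggle * _br(t, A - 0.6, A) + v_bs * _br(t, A, B)
    rise = 0.5 * (1.0 - np.cos(np.pi * np.clip((t - B) / ds, 0, 1)))
    speed = speed + v_imp * np.where((t >= B) & (t <= I), rise, 0.0)
    fall = 0.5 * (1.0 + np.cos(np.pi * np.clip((t - I) / ft, 0, 1)))
    speed = speed + v_imp * np.where((t > I) & (t <= F), fall, 0.0)
    speed = speed + v_waggle * _br(t, F, F + 0.5)
    return speed


def simulate_swing(
    profile: SubjectProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    club: str = "driver",
) -> SwingSet:
    """Simulate one swing: per-placement IMU recordings, clubhead track and
    ground-truth dividing points.

    Raises ``duration_error`` when the drawn swing cannot fit the recording
    geometry (impact earlier than the swing is long).
    """
    fs = config.sample_rate_hz
    bs, ds, ft = _draw_durations(config, rng)
    I = config.imp_time_s
    B = I - ds
    A = B - bs
    F = I + ft
    if A < config.jump_time_s + 0.15 or I < 2.5:
        raise DurationError(
            f"swing (bs={bs:.3f}, ds={ds:.3f}) does not fit before impact at {I} s"
        )
    n = int(round((I + 1.0 + config.af_pad_s) * fs)) + 1
    t = np.arange(n) / fs

    # --- reference clubhead track -----------------------------------------
    v_imp = config.speed_peak_mps[club]
    speed = _speed_profile(
        t, A, B, I, F, v_imp, config.bs_speed_peak_mps, config.waggle_speed_mps
    )
    if config.speed_noise_frac > 0:
        speed = speed * (1.0 + config.speed_noise_frac * rng.normal(size=n))
        speed = np.maximum(speed, 0.0)
    signed = np.where(t < B, -speed, speed)
    x = cumulative_trapezoid(signed, t, initial=0.0)
    x = x - np.interp(I, t, x)  # ball-plane coordinate crosses 0 at impact
    track = ClubheadTrack(t, x, speed)

    truth = DividingPoints(A, B, I, F)

    # --- IMU recordings ----------------------------------------------------
    recordings = {}
    for placement in PLACEMENTS:
        tau = config.lag_s[placement] + profile.lag_offset_s[placement]
        acc, gyro = _TEMPLATES[placement](t, A, B, I, F, tau)
        acc = acc * (profile.amp[placement] * config.acc_amp[placement])
        gyro = gyro * (profile.amp[placement] * config.gyro_amp[placement])
        acc = acc + _GRAVITY[placement][:, None]
        # pre-swing jump spike for clock alignment (vertical axis)
        acc[2] -= config.jump_amp_g * _bc(t, config.jump_time_s, 0.12)
        # impact shock
        amp = config.impact_amp_g[placement] * profile.amp[placement]
        if _SHOCK_AXIS[placement][2] == "causal":
            tr = _transient(t, I, amp, config.impact_decay_s, config.impact_freq_hz)
        else:
            tr = _transient_symmetric(t, I, amp)
        # the shock keeps ~0.3 g of energy below the 10 Hz analysis band, as
        # real impacts do; each placement takes it on the axis where that
        # residue reinforces (or least disturbs) its impact indicator
        ax_idx, sign, _kind = _SHOCK_AXIS[placement]
        acc[ax_idx] += sign * tr
        if config.noise_acc_g > 0:
            acc = acc + rng.normal(0.0, config.noise_acc_g, size=acc.shape)
        if config.noise_gyro_dps > 0:
            gyro = gyro + rng.normal(0.0, config.noise_gyro_dps, size=gyro.shape)
        acc = np.clip(acc, -ACC_RANGE_G, ACC_RANGE_G)
        gyro = np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
        recordings[placement] = ImuRecording(placement, t, acc, gyro, fs)

    return SwingSet(profile.subject_id, club, recordings, track, truth)


def simulate_dataset(
    n_subjects: int,
    swings_per_subject: int,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
) -> List[SwingSet]:
    """Simulate a dataset of ``n_subjects`` x ``swings_per_subject`` swings.

    Per-subject profiles are drawn once; swings are independent given the
    profile.  Clubs alternate driver / 7-iron within each subject.  Fully
    reproducible: the (subject, swing) index pair keys the random stream.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    swings = []
    for i in range(n_subjects):
        prof_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        )
        profile = sample_subject_profile(config, prof_rng, subject_id=f"S{i + 1:02d}")
        for j in range(swings_per_subject):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i, j))
            )
            club = "driver" if j % 2 == 0 else "iron7"
            swings.append(simulate_swing(profile, config, rng, club=club))
    return swings


# ---------------------------------------------------------------------------
# reference labeler


def _refine_extremum(t, s, i):
    """Sub-sample extremum time by parabolic interpolation around sample i."""
    if i <= 0 or i >= s.size - 1:
        return float(t[i])
    denom = s[i - 1] - 2 * s[i] + s[i + 1]
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (s[i - 1] - s[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(t[i] + delta * (t[min(i + 1, s.size - 1)] - t[i]))


def label_reference(track: ClubheadTrack, smooth: bool = True) -> DividingPoints:
    """Dividing points from a reference clubhead track.

    The speed is first low-pass filtered (zero phase, 20 Hz: the reference
    track is optical-capture grade, and a gentler cutoff than the IMU
    channels' 10 Hz (40 Hz) preserves the sharp speed minimum at the top of the
    backswing), then: ADD is the last local minimum of speed before speed
    first exceeds 5% of its global maximum ahead of the backswing bump peak;
    BST the minimum speed between the backswing bump peak and impact; IMP the
    first positive-slope zero crossing of the ball-plane coordinate inside
    the high-speed region (speed > 50% of max); FIN the first local minimum
    of speed after impact at which speed < 10% of max.  Raises
    ``unlabelable_track`` if the two-bump structure is absent.
    """
    t, s, x = track.t, track.speed, track.ball_coord
    if smooth and s.size > 30:
        from .preprocess import lowpass_zero_phase

        fs = 1.0 / float(np.median(np.diff(t)))
        s = lowpass_zero_phase(s, fs, cutoff_hz=40.0)
    smax = float(np.max(s))
    if smax <= 0:
        raise UnlabelableTrack("flat speed profile")

    # impact: positive-slope zero crossing of ball_coord in the fast region
    fast = s > 0.5 * smax
    cross = np.flatnonzero((x[:-1] <= 0) & (x[1:] > 0) & (fast[:-1] | fast[1:]))
    if cross.size == 0:
        raise UnlabelableTrack("no ball-plane crossing inside the high-speed region")
    i = int(cross[0])
    imp = float(t[i] + (t[i + 1] - t[i]) * (-x[i]) / (x[i + 1] - x[i]))
    i_imp = int(np.searchsorted(t, imp))

    # backswing bump peak: last prominent local speed maximum before impact
    # (5% prominence rejects noise wiggles riding the downswing rise)
    peaks, _ = find_peaks(s[: i_imp + 1], height=0.02 * smax, prominence=0.05 * smax)
    if peaks.size == 0:
        raise UnlabelableTrack("no backswing speed bump before impact")
    i_pk = int(peaks[-1])

    bst_rel = int(np.argmin(s[i_pk : i_imp + 1]))
    bst = _refine_extremum(t, s, i_pk + bst_rel)

    # address: last (non-strict) local min before the 5% rise ahead of the peak
    above = np.flatnonzero(s[: i_pk + 1] > 0.05 * smax)
    i_rise = int(above[0]) if above.size else i_pk
    interior = np.arange(1, max(i_rise, 2) - 0)
    interior = interior[interior < s.size - 1]
    is_min = (s[interior] <= s[interior - 1]) & (s[interior] <= s[interior + 1])
    mins = interior[is_min]
    mins = mins[mins < i_rise]
    if mins.size == 0:
        raise UnlabelableTrack("no local speed minimum before the backswing rise")
    add = _refine_extremum(t, s, int(mins[-1]))

    # finish: first local min after impact with speed below 10% of max
    j = np.arange(i_imp + 1, s.size - 1)
    is_min = (s[j] <= s[j - 1]) & (s[j] <= s[j + 1]) & (s[j] < 0.1 * smax)
    cand = j[is_min]
    if cand.size == 0:
        raise UnlabelableTrack("no low-speed local minimum after impact")
    fin = _refine_extremum(t, s, int(cand[0]))

    try:
        return DividingPoints(add, bst, imp, fin)
    except ValueError as exc:  # unordered -> structure was not a swing
        raise UnlabelableTrack(str(exc)) from exc


_DEFAULTS_YAML = Path(__file__).parent / "data" / "generator_defaults.yaml"


def default_config() -> GeneratorConfig:
    """The shipped default configuration (also available as YAML)."""
    if _DEFAULTS_YAML.exists():
        return GeneratorConfig.from_yaml(_DEFAULTS_YAML)
    return GeneratorConfig()
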