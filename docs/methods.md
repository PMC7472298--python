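# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the shipped tests do and do not establish.

## Problem and phase definitions

A full golf swing is divided by four instants — address (ADD), backswing top
(BST), impact (IMP) and finish (FIN) — into five phases: before-swing (BF),
backswing (BS), downswing (DS), follow-through (FT) and after-swing (AF).
The reference definitions are kinematic properties of the *clubhead*: ADD is
the last local minimum of clubhead speed before the backswing rise, BST the
speed minimum between the backswing bump and impact, IMP the instant the
clubhead crosses the ball plane (signed coordinate zero, positive slope)
inside the high-speed region, and FIN the first low-speed (<10% of peak)
local minimum after impact. `synthgen.label_reference` implements exactly
this on a `ClubheadTrack`, after a 40 Hz zero-phase low-pass (the reference
track is optical-capture grade; a gentler cutoff than the 10 Hz applied to
IMU channels preserves the sharp speed minimum at BST), with parabolic
sub-sample refinement of the minima and a 5%-of-peak prominence requirement
on the backswing bump so noise wiggles on the downswing rise are not mistaken
for it.

Dividing points are stored as continuous times in seconds, never sample
indices. Phase intervals are half-open with the boundary sample assigned to
the *later* phase; this makes `phases_from_points` and `points_from_phases`
exact mutual inverses up to one sample step.

## Preprocessing

All IMU channels pass through a 10th-order Butterworth low-pass (10 Hz
cutoff) applied forward–backward (zero phase; odd-reflection padding of 3×
the design order). "Order" means the design order of the underlying filter —
the bidirectional pass doubles the effective attenuation. Each swing is cut
to a 3.5 s window from 2.5 s before to 1 s after impact (exactly
`round(3.5·fs)` samples; 700 at 200 Hz). During training-set construction the
window is centered on the labeled impact; at inference it is centered on the
impact *proxy*, the global maximum of the **raw** acceleration norm — the
shock is the highest-frequency feature of the swing and low-pass filtering
would smear and bias its peak. The residual window-placement jitter is part
of the learning problem. Input matrices are (time, 3-axis acceleration,
3-axis angular velocity) → 7×700, or 4×700 for a single modality; every
feature row is min–max scaled to [−1, +1] per window (constant rows map to
zero). Time is normalized like any other row, giving an affine −1→+1 ramp.

## Heuristic segmentation

One `IndicatorRule` per (placement, dividing point): an extremum or
zero-crossing of one filtered channel (or the Euclidean norm of the three
filtered axes) inside a search window anchored on the impact proxy. Default
windows: ADD [−2.45, −0.55] s, BST [−0.80, −0.05] s, IMP [−0.05, +0.05] s,
FIN [+0.10, +1.00] s relative to the proxy; individual rules may override
them (e.g. acceleration-norm FIN rules start at +0.3 s so the impact shock
has rung down). The ADD window's −2.45 s edge is the geometric bound — an
ADD inside the 3.5 s window requires backswing+downswing ≤ 2.45 s — and its
−0.55 s edge clears the earliest plausible backswing top. Ties between equal
extrema resolve to the earliest; zero crossings are linearly interpolated,
filtered by required slope sign, take the candidate nearest the window
center, and ignore sign flips whose amplitude is below 10⁻⁶ of the window's
signal range (numerically silent stretches of a zero-phase-filtered signal
ripple around zero). Three rule tables ship as YAML: the selected 12-rule
table used when both modalities are available, and acceleration-only /
gyro-only tables for the modality ablation. `rank_indicator_candidates`
scores any candidate table by MAE against labeled data (search-window width
as the penalty when an event is not found) and selects the best rule per
cell.

## Learned models

Both models are implemented on a small numpy engine (`swingseg.nn`) with
numba-compiled LSTM kernels and hand-derived backward passes, verified
against finite differences in the test suite; training is exactly
reproducible given the seed.

* **BLSTM** (≈110 K parameters): five stacked bidirectional LSTM layers, 32
  hidden units per direction, a shared per-timestep fully connected layer and
  softmax over the five phase classes; per-timestep cross-entropy loss,
  unweighted (class imbalance between the long BF/BS and the short DS is left
  as-is; inverse-frequency weighting was considered and not enabled by
  default). Prediction takes the per-column argmax, cleans the sequence and
  reads the boundaries.
* **CNN** (≈94 K parameters): conv(kernel 9, 16 filters) → tanh → max-pool 4
  → tanh → conv(kernel 9, 32 filters) → tanh → max-pool 4 → tanh → FC 64 →
  tanh → linear 4. The head regresses window-normalized fractions in (0,1);
  MSE loss. Block sizes were chosen by trial and error to land near 100 K
  parameters.

Sequence cleanup (`clean_sequence`): an odd-width median filter (default 5
samples) over the ordinal class codes removes isolated glitches, then
boundaries are fixed at the first run of ≥10 samples (50 ms — safely below
the shortest plausible downswing, 0.317 − 3·0.050 s) of each successive
phase. `predict_points` retries with a 1-sample persistence if some phase
lacks a persistent run, so marginal network outputs still decode; a phase
that is entirely absent raises `incomplete_phase_sequence`. A CNN output
that is non-monotone after clamping raises `order_violation` rather than
being silently sorted.

Training: Adam (defaults lr 3·10⁻³, β = (0.9, 0.999), batch 8; chosen from
pilot convergence runs), a 90/10 swing-level train/validation split
stratified by subject, validation stopping with an epoch-0 baseline (a run
whose validation loss never improves stops after exactly `patience` epochs),
learning-rate reduction ×0.3 on a validation plateau (restarting from the
best checkpoint), and restoration of the best-validation parameters at the
end. Typical budgets: the CNN converges in 100–200 epochs (seconds), the
BLSTM in ~12 epochs (tens of seconds at the scales used here).

## Evaluation

Leave-one-subject-out: each subject's swings are predicted by models trained
on all other subjects; the heuristic needs no training and is evaluated on
the same folds. Errors are aggregated per subject first — MAE per dividing
point (ms), mean absolute phase-length error (%) per phase with
100·|L̂−L|/L — then averaged across subjects (grand mean) with the
between-subject SD. Driver and 7-iron swings are pooled. The modality
ablation reruns LOSO with 4×700 (acceleration), 4×700 (angular velocity) and
7×700 (both) inputs on matched folds and seeds. Paired contrasts between
arms use a two-sided Wilcoxon signed-rank test on per-subject MAEs (paired
t-test available as an option; identical arms return p = 1 by convention; at
least 5 pairs required). No multiple-testing correction is applied across
contrasts. `render_report` writes tidy CSVs
(`method,placement,modality,metric,target,grand_mean,sd,n_subjects`) and bar
charts with between-subject-SD whiskers.

## Synthetic swing generator

The generator reproduces the *signal phenomenology* that segmentation
methods key on — not swing dynamics. Per swing:

* **Durations** of BS/DS/FT are drawn from normals calibrated to reference
  phase-length statistics (1.163 ± 0.232, 0.317 ± 0.050, 0.670 ± 0.119 s),
  truncated at ±3 SD with a 0.1 s floor, and the follow-through additionally
  capped at 0.98 s so FIN always stays inside the analysis window (which
  ends 1 s after impact). The truncation shifts the means by <0.003 s.
  Impact sits at a fixed recording time (default 2.8 s) and the BF padding
  adapts, which guarantees the 2.5 s pre-impact window always fits and
  always contains ADD (bs+ds ≤ 2.33 s < 2.45 s under the truncation).
* **Clubhead track**: speed is a small raised-cosine backswing bump
  (4 m/s peak) returning to zero at BST, a half-cosine rise to the impact
  peak (40 m/s driver, 34 m/s 7-iron), a half-cosine decay to zero at FIN,
  plus small waggle bumps before ADD and after FIN so ADD/FIN are genuine
  local minima. The ball-plane coordinate is the signed integral of speed
  (negative during the backswing), shifted so it crosses zero exactly at
  impact.
* **IMU channels** are sums of smooth templates. Bulk motion templates are
  shifted by a proximal-to-distal lag (waist 0, head 15 ms, wrist 30 ms by
  default — the ordering is the established finding, the magnitudes are
  package defaults) plus a per-subject lag offset; the *indicator events*
  (the minima/zero-crossings in the shipped rule tables) are anchored at the
  true dividing points, so with zero noise every selected rule recovers the
  truth within two samples even after the 10 Hz zero-phase filter. Getting
  that to hold shaped several constructions: BST zero crossings are locally
  antisymmetric (a symmetric filter cannot displace an antisymmetric
  crossing); FIN is a wide shallow notch in the gyro-norm envelope plus a
  small antisymmetric "settling wobble" so the norm minimum is unique; the
  wrist impact shock is a causal 70 Hz decaying cosine on the gravity-loaded
  axis, while head and waist receive a symmetric, soft-tissue-damped 25 Hz
  packet whose sub-10 Hz leakage (≈0.3 g — real impacts do leak into the
  analysis band) is symmetric about impact and cannot bias any extremum.
* **Feature SNRs encode the difficulty ordering**: ADD and FIN features are
  wide and shallow (near the filtered noise floor), BST and IMP features are
  sharp, and head/waist indicator amplitudes are several times smaller than
  the wrist's. Under default noise the heuristic therefore shows the
  expected pattern — a few ms at BST/IMP on the wrist, tens of ms at
  ADD/FIN, and roughly doubled errors at the proximal placements — while the
  learned models, which integrate over whole feature shapes rather than
  taking pointwise argmins, stay accurate everywhere.
* **Subject random effects**: lognormal per-placement amplitude multipliers
  (σ = 0.15, median 1) and normal lag offsets (SD 10 ms, clipped at ±3 SD).
  Durations carry no subject effect. White Gaussian noise (0.08 g, 8 dps —
  representing soft-tissue artifact more than electronic noise) is added
  before clipping to the ±16 g / ±2000 dps sensor range. A light 1.2 g jump
  spike at 0.15 s supports clock alignment; impact shock amplitudes (12 /
  3.5 / 4.5 g) are set so the acceleration-peak proxy never locks onto the
  jump even for low-amplitude subjects.

Randomness is hierarchical (`SeedSequence(entropy=seed, spawn_key=(subject,
swing))`), so datasets are exactly reproducible and extending a dataset never
changes previously generated swings.

**What the generator does not emulate**: real biomechanics (no dynamics, no
torque/force model), left-handed golfers, mishits or partial swings,
magnetometer or orientation information, temperature drift and bias
instability, club-type differences beyond peak speed, and — most importantly
— the true between-subject diversity of movement *shape*. Signals are the
same templates for every subject up to amplitude, lag and noise, so learned
models generalize across synthetic subjects more easily than across real
ones; passing the reduced-scale learnability tests shows the pipeline is
correct and the models can learn the intended features, not that the
reported accuracy would transfer to real golfers.

## Problem sizes used by the shipped checks

The calibration script simulates 1000 swings (50 subjects × 20). The
noiseless oracle check uses 200 swings; the learnability check runs full
LOSO on 8 subjects × 10 swings (wrist, both modalities) with the CNN
(≤400 epochs) and the BLSTM (12 epochs); cross-placement orderings use 5
subjects × 6 swings; determinism is verified end-to-end at 3 subjects × 4
swings. These sizes were chosen as the smallest at which the Monte-Carlo
margins are comfortable.

## Known limitations

* The CNN, unlike the BLSTM, does not reliably beat the heuristic's sharp
  BST/IMP indicators at the head and waist at reduced scale; with anchored
  (and therefore reasonably clean) synthetic indicators the rule-based
  method is a stronger baseline there than on real data.
* The acceleration-only indicator table is genuinely weak (its FIN/BST
  events sit on shock leakage and shallow features) — by design, mirroring
  the weakness of acceleration-only heuristics.
* `paired_significance` requires ≥5 subjects; the shipped examples run below
  the scale where its power is meaningful.
* The window geometry assumes impact can be located to within a few samples
  by the acceleration peak; swings without a clear shock (practice swings,
  putts, chips) are out of scope.
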