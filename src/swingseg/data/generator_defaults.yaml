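acc_amp:
  head: 1.0
  waist: 1.0
  wrist: 1.0
af_pad_s: 0.8
bs_mean_s: 1.163
bs_sd_s: 0.232
bs_speed_peak_mps: 4.0
ds_mean_s: 0.317
ds_sd_s: 0.05
duration_floor_s: 0.1
duration_z_clip: 3.0
ft_max_s: 0.98
ft_mean_s: 0.67
ft_sd_s: 0.119
gyro_amp:
  head: 1.0
  waist: 1.0
  wrist: 1.0
imp_time_s: 2.8
impact_amp_g:
  head: 3.5
  waist: 4.5
  wrist: 12.0
impact_decay_s: 0.04
impact_freq_hz: 70.0
jump_amp_g: 1.2
jump_time_s: 0.15
lag_s:
  head: 0.015
  waist: 0.0
  wrist: 0.03
noise_acc_g: 0.08
noise_gyro_dps: 8.0
sample_rate_hz: 200.0
seed: 0
speed_noise_frac: 0.0
speed_peak_mps:
  driver: 40.0
  iron7: 34.0
subject_amp_sd: 0.15
subject_lag_sd_s: 0.01
waggle_speed_mps: 0.3
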