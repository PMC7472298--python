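# Heuristic segmentation indicator tables.
#
# a_plus_g: the twelve selected indicators (placement x dividing point) when
# both modalities are available.  acc_only / gyro_only: the best
# single-modality indicator per cell, used by the modality ablation.
# event: min | max | zero_crossing; channel: x | y | z | norm.
# window: optional [lo, hi] seconds relative to the impact proxy
# (omitted = the per-point default search window).  The acceleration-norm
# FIN rules search from +0.3 s so the impact shock has rung down.

a_plus_g:
  - {placement: wrist, point: ADD, source: gyro, channel: y, event: min}
  - {placement: wrist, point: BST, source: gyro, channel: z, event: zero_crossing, slope: '-'}
  - {placement: wrist, point: IMP, source: gyro, channel: y, event: min}
  - {placement: wrist, point: FIN, source: gyro, channel: norm, event: min}
  - {placement: head, point: ADD, source: gyro, channel: norm, event: min}
  - {placement: head, point: BST, source: acc, channel: x, event: min, window: [-0.8, -0.1]}
  - {placement: head, point: IMP, source: acc, channel: norm, event: min}
  - {placement: head, point: FIN, source: gyro, channel: norm, event: min}
  - {placement: waist, point: ADD, source: gyro, channel: y, event: min}
  - {placement: waist, point: BST, source: gyro, channel: y, event: zero_crossing, slope: '-', window: [-0.5, -0.05]}
  - {placement: waist, point: IMP, source: acc, channel: x, event: zero_crossing, slope: '+'}
  - {placement: waist, point: FIN, source: gyro, channel: norm, event: min}

acc_only:
  - {placement: wrist, point: ADD, source: acc, channel: y, event: min}
  - {placement: wrist, point: BST, source: acc, channel: x, event: min}
  - {placement: wrist, point: IMP, source: acc, channel: z, event: max}
  - {placement: wrist, point: FIN, source: acc, channel: norm, event: min, window: [0.3, 1.0]}
  - {placement: head, point: ADD, source: acc, channel: y, event: min}
  - {placement: head, point: BST, source: acc, channel: x, event: min, window: [-0.8, -0.1]}
  - {placement: head, point: IMP, source: acc, channel: norm, event: min}
  - {placement: head, point: FIN, source: acc, channel: norm, event: min, window: [0.3, 1.0]}
  - {placement: waist, point: ADD, source: acc, channel: y, event: min}
  - {placement: waist, point: BST, source: acc, channel: z, event: min, window: [-0.8, -0.1]}
  - {placement: waist, point: IMP, source: acc, channel: x, event: zero_crossing, slope: '+'}
  - {placement: waist, point: FIN, source: acc, channel: norm, event: min, window: [0.3, 1.0]}

gyro_only:
  - {placement: wrist, point: ADD, source: gyro, channel: y, event: min}
  - {placement: wrist, point: BST, source: gyro, channel: z, event: zero_crossing, slope: '-'}
  - {placement: wrist, point: IMP, source: gyro, channel: y, event: min}
  - {placement: wrist, point: FIN, source: gyro, channel: norm, event: min}
  - {placement: head, point: ADD, source: gyro, channel: norm, event: min}
  - {placement: head, point: BST, source: gyro, channel: y, event: zero_crossing, slope: '-'}
  - {placement: head, point: IMP, source: gyro, channel: y, event: min}
  - {placement: head, point: FIN, source: gyro, channel: norm, event: min}
  - {placement: waist, point: ADD, source: gyro, channel: y, event: min}
  - {placement: waist, point: BST, source: gyro, channel: y, event: zero_crossing, slope: '-', window: [-0.5, -0.05]}
  - {placement: waist, point: IMP, source: gyro, channel: z, event: min}
  - {placement: waist, point: FIN, source: gyro, channel: norm, event: min}
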