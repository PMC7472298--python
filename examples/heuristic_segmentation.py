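"""Segment swings with the rule-based indicator method and score it.

Simulates 12 swings, applies the heuristic segmenter to each placement's IMU
and prints the mean absolute error per dividing point, in milliseconds.
"""

import numpy as np

from swingseg import GeneratorConfig, heuristic_segment, simulate_dataset

ATTR = {"ADD": "add_s", "BST": "bst_s", "IMP": "imp_s", "FIN": "fin_s"}

swings = simulate_dataset(3, 4, GeneratorConfig(), seed=7)
for placement in ("wrist", "head", "waist"):
    errs = {p: [] for p in ATTR}
    for swing in swings:
        est = heuristic_segment(swing.recordings[placement])
        for p, a in ATTR.items():
            errs[p].append(abs(getattr(est, a) - getattr(swing.truth, a)))
    mae = {p: 1e3 * float(np.mean(v)) for p, v in errs.items()}
    print(f"{placement:>6}: " + "  ".join(f"{p} {mae[p]:6.1f} ms" for p in ATTR))
# Expected pattern: BST and IMP are sharp events (few ms at the wrist) while
# ADD and FIN ride on shallow low-speed features and are several times worse;
# the head and waist sensors are farther from the club and degrade further.
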