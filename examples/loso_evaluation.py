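"""Leave-one-subject-out comparison of all three methods on wrist data.

Runs heuristic, BLSTM and CNN at a small scale (4 subjects x 6 swings) and
prints the grand-mean MAE per dividing point plus the phase-length errors;
writes the full report (CSV + bar chart) to ./loso_report/.
"""

from swingseg import GeneratorConfig, TrainConfig, simulate_dataset
from swingseg.evaluate import SegmentationReport, loso_cv, render_report
from swingseg.swingdata import POINTS

swings = simulate_dataset(4, 6, GeneratorConfig(), seed=7)

reports = [loso_cv(swings, "heuristic", "wrist", seed=7)]
reports.append(loso_cv(
    swings, "blstm", "wrist",
    train_config=TrainConfig(max_epochs=12, patience=4, seed=7), seed=7,
))
reports.append(loso_cv(
    swings, "cnn", "wrist",
    train_config=TrainConfig(max_epochs=300, patience=30, seed=7), seed=7,
))
report = SegmentationReport.concat(reports)

print("grand-mean MAE (ms), wrist, acc+gyro:")
for method in ("heuristic", "blstm", "cnn"):
    row = "  ".join(
        f"{p} {report.grand_mean(method, 'wrist', 'a+g', 'mae_ms', p):6.1f}"
        for p in POINTS
    )
    print(f"  {method:>9}: {row}")
print("\nphase-length errors (%):")
for method in ("heuristic", "blstm", "cnn"):
    row = "  ".join(
        f"{ph} {report.grand_mean(method, 'wrist', 'a+g', 'phase_len_pct', ph):5.1f}"
        for ph in ("BS", "DS", "FT")
    )
    print(f"  {method:>9}: {row}")

files = render_report(report, "loso_report")
print(f"\nwrote {len(files)} report files to ./loso_report/")
# At this miniature scale (18 training swings per fold) the BLSTM already
# halves the heuristic's error at ADD, while the CNN is data-starved; the
# full reduced-scale evaluation (8 subjects x 10 swings, see the test suite)
# has both learned models beating the heuristic at ADD and FIN.
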