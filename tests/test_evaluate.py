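"""LOSO evaluation machinery, error statistics and reporting."""

import numpy as np
import pandas as pd
import pytest

from swingseg.errors import PairingError
from swingseg.evaluate import (
    SegmentationReport,
    loso_cv,
    mae_by_point,
    modality_ablation,
    paired_significance,
    render_report,
)
from swingseg.models import TrainConfig
from swingseg.preprocess import build_windows
from swingseg.swingdata import DividingPoints, phase_length_error_pct


class TestMaeByPoint:
    def test_two_subject_arithmetic(self):
        per, grand, sd = mae_by_point({"A": [0.010, -0.020], "B": [0.0]})
        assert per == {"A": 15.0, "B": 0.0}
        assert grand == pytest.approx(7.5)
        assert sd == pytest.approx(10.6066, abs=1e-3)

    def test_all_zero(self):
        per, grand, sd = mae_by_point({"A": [0.0], "B": [0.0]})
        assert grand == 0.0 and sd == 0.0

    def test_swing_order_invariance(self):
        a = mae_by_point({"A": [0.01, -0.03, 0.02]})
        b = mae_by_point({"A": [0.02, 0.01, -0.03]})
        assert a == b


class TestPhaseLengthError:
    def test_reference_downswing_example(self):
        truth = DividingPoints(0.0, 1.163, 1.480, 2.150)
        est = DividingPoints(0.0, 1.163, 1.496, 2.166)  # DS 0.333 s
        bs, ds, ft = phase_length_error_pct(est, truth)
        assert ds == pytest.approx(5.05, abs=0.01)

    def test_exact_estimate_has_zero_error(self):
        truth = DividingPoints(0.1, 1.0, 1.4, 2.0)
        assert phase_length_error_pct(truth, truth) == pytest.approx((0, 0, 0))

    def test_scale_invariance(self):
        truth = DividingPoints(0.1, 1.0, 1.4, 2.0)
        est = DividingPoints(0.15, 1.1, 1.5, 2.2)
        t2 = DividingPoints(0.2, 2.0, 2.8, 4.0)
        e2 = DividingPoints(0.3, 2.2, 3.0, 4.4)
        assert phase_length_error_pct(est, truth) == pytest.approx(
            phase_length_error_pct(e2, t2)
        )


class TestPairedSignificance:
    def test_identical_arms_not_significant(self):
        flag, p = paired_significance([1.0] * 8, [1.0] * 8)
        assert not flag and p == 1.0

    def test_constant_shift_detected(self, rng):
        a = rng.normal(50, 5, 20)
        flag, p = paired_significance(a, a + 20.0)
        assert flag and p < 0.05

    def test_too_few_pairs_raise(self):
        with pytest.raises(PairingError):
            paired_significance([1, 2, 3], [2, 3, 4])
        with pytest.raises(PairingError):
            paired_significance([1, 2, 3, 4, 5], [1, 2, 3])

    def test_ttest_alternative(self, rng):
        a = rng.normal(50, 5, 20)
        flag, p = paired_significance(a, a + 20.0, test="ttest")
        assert flag


class TestLoso:
    def test_fold_structure_each_subject_once(self, noiseless_swings):
        report = loso_cv(noiseless_swings, "heuristic", "wrist")
        mae = report.per_subject[report.per_subject.metric == "mae_ms"]
        counts = mae.groupby("subject_id").size()
        assert set(counts.index) == {s.subject_id for s in noiseless_swings}
        assert (counts == 4).all()  # one row per dividing point

    def test_heuristic_is_training_free(self, noiseless_swings):
        r1 = loso_cv(noiseless_swings, "heuristic", "wrist", seed=0)
        r2 = loso_cv(noiseless_swings, "heuristic", "wrist", seed=99)
        pd.testing.assert_frame_equal(r1.per_subject, r2.per_subject)

    def test_report_invariant_to_swing_order(self, noiseless_swings):
        shuffled = list(noiseless_swings)[::-1]
        r1 = loso_cv(noiseless_swings, "heuristic", "wrist")
        r2 = loso_cv(shuffled, "heuristic", "wrist")
        g1 = r1.grand().sort_values(["metric", "target"]).reset_index(drop=True)
        g2 = r2.grand().sort_values(["metric", "target"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(g1, g2)

    def test_grand_mean_is_mean_of_subject_values(self, noiseless_swings):
        report = loso_cv(noiseless_swings, "heuristic", "wrist")
        vals = report.subject_values("heuristic", "wrist", "a+g", "mae_ms", "ADD")
        assert report.grand_mean(
            "heuristic", "wrist", "a+g", "mae_ms", "ADD"
        ) == pytest.approx(vals.mean())


def test_modality_ablation_matched_arms(noiseless_swings):
    # input feature dimension per arm: 4 (a), 4 (g), 7 (a+g)
    dims = {
        m: build_windows(noiseless_swings[:2], "wrist", m).inputs.shape[1]
        for m in ("a", "g", "a+g")
    }
    assert dims == {"a": 4, "g": 4, "a+g": 7}
    report = modality_ablation(noiseless_swings, "heuristic", "wrist")
    got = set(report.per_subject.modality.unique())
    assert got == {"a", "g", "a+g"}
    per_arm = report.per_subject.groupby("modality")["subject_id"].apply(set)
    assert per_arm["a"] == per_arm["g"] == per_arm["a+g"]  # matched folds


def test_render_report_roundtrip(noiseless_swings, tmp_path):
    report = loso_cv(noiseless_swings, "heuristic", "wrist")
    files = render_report(report, tmp_path)
    names = {f.name for f in files}
    assert "report.csv" in names and "per_subject.csv" in names
    back = pd.read_csv(tmp_path / "report.csv")
    grand = report.grand()
    assert len(back) == len(grand)
    merged = back.merge(
        grand, on=["method", "placement", "modality", "metric", "target"],
        suffixes=("_csv", ""),
    )
    assert np.allclose(merged.grand_mean_csv, merged.grand_mean, atol=1e-5)
    assert (tmp_path / "mae_wrist.png").exists()


def test_minimal_single_cell_report(tmp_path):
    df = pd.DataFrame([
        dict(method="heuristic", placement="wrist", modality="a+g",
             metric="mae_ms", target="IMP", subject_id="S01", value=5.0)
    ])
    files = render_report(SegmentationReport(df), tmp_path)
    back = pd.read_csv(tmp_path / "report.csv")
    assert len(back) == 1 and back.grand_mean.iloc[0] == 5.0
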