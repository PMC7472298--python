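"""Leave-one-subject-out evaluation and reporting.

Every subject is held out in turn; the learned models retrain on the
remaining subjects' swings (the heuristic needs no training) and predict the
held-out swings from proxy-centered windows.  Errors are summarized per
subject first -- mean absolute error per dividing point in milliseconds and
mean absolute phase-length error in percent -- then averaged across subjects
(grand mean) with the between-subject SD, mirroring how wearable-sensor
segmentation studies report accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyFold, PairingError, SwingSegError
from .heuristic import heuristic_segment
from .models import (
    BlstmSpec,
    CnnSpec,
    TrainConfig,
    build_blstm,
    build_cnn,
    predict_points,
    train_model,
)
from .preprocess import build_windows
from .swingdata import POINTS, phase_length_error_pct

PHASE_TARGETS = ("BS", "DS", "FT")
METHODS = ("heuristic", "blstm", "cnn")

REPORT_COLUMNS = [
    "method", "placement", "modality", "metric", "target",
    "grand_mean", "sd", "n_subjects",
]


@dataclass
class SegmentationReport:
    """Tidy per-subject error table plus aggregation helpers.

    ``per_subject`` columns: method, placement, modality, metric
    ('mae_ms' | 'phase_len_pct'), target (point or phase), subject_id, value.
    """

    per_subject: pd.DataFrame
    n_failed: int = 0

    def grand(self) -> pd.DataFrame:
        g = (
            self.per_subject.groupby(
                ["method", "placement", "modality", "metric", "target"],
                sort=False,
            )["value"]
            .agg(grand_mean="mean", sd="std", n_subjects="count")
            .reset_index()
        )
        return g[REPORT_COLUMNS]

    def subject_values(self, method, placement, modality, metric, target) -> pd.Series:
        df = self.per_subject
        sel = (
            (df.method == method)
            & (df.placement == placement)
            & (df.modality == modality)
            & (df.metric == metric)
            & (df.target == target)
        )
        return df.loc[sel].set_index("subject_id")["value"].sort_index()

    def grand_mean(self, method, placement, modality, metric, target) -> float:
        return float(self.subject_values(method, placement, modality, metric, target).mean())

    @classmethod
    def concat(cls, reports: Sequence["SegmentationReport"]) -> "SegmentationReport":
        return cls(
            pd.concat([r.per_subject for r in reports], ignore_index=True),
            n_failed=sum(r.n_failed for r in reports),
        )


def mae_by_point(errors_s: Dict[str, List[np.ndarray]]):
    """Subject-level MAE (ms) per subject, grand mean and between-subject SD.

    ``errors_s`` maps subject_id -> list/array of signed errors in seconds
    for one dividing point.
    """
    per_subject = {
        sid: float(np.mean(np.abs(np.asarray(e, float)))) * 1e3
        for sid, e in errors_s.items()
    }
    vals = np.array(list(per_subject.values()))
    grand = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return per_subject, grand, sd


def _predict_fold(method, placement, modality, train_swings, test_swings, seed,
                  train_config):
    """Train (if needed) and predict the held-out swings.  Returns a list of
    (truth, estimate-or-None)."""
    preds = []
    if method == "heuristic":
        for swing in test_swings:
            try:
                est = heuristic_segment(swing.recordings[placement], modality=modality)
            except SwingSegError:
                est = None
            preds.append((swing.truth, est))
        return preds
    train_w = build_windows(train_swings, placement, modality, use_truth_impact=True)
    test_w = build_windows(test_swings, placement, modality, use_truth_impact=False)
    cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
    n_feat = train_w.inputs.shape[1]
    if method == "blstm":
        model = build_blstm(BlstmSpec(input_features=n_feat), seed=seed)
    elif method == "cnn":
        model = build_cnn(
            CnnSpec(input_features=n_feat), seed=seed, input_len=train_w.inputs.shape[2]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    train_model(model, train_w, cfg, task=method)
    for i, swing in enumerate(test_swings):
        try:
            est = predict_points(
                model, test_w.inputs[i], float(test_w.t0_s[i]), method,
                sample_rate_hz=test_w.sample_rate_hz,
            )
        except SwingSegError:
            est = None
        preds.append((swing.truth, est))
    return preds


def loso_cv(
    swings: Sequence,
    method: str,
    placement: str,
    modality: str = "a+g",
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> SegmentationReport:
    """Leave-one-subject-out cross-validation for one (method, placement,
    modality) cell.

    Deterministic given ``seed``: fold f trains with seed ``seed*1009 + f``.
    Swings where prediction fails are counted in ``n_failed`` and excluded
    from that subject's averages.  Raises ``empty_fold`` if a subject has no
    swings (impossible by construction here, but guarded for filtered data).
    """
    train_config = train_config or TrainConfig()
    subjects = sorted({s.subject_id for s in swings})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    rows = []
    n_failed = 0
    attr = {"ADD": "add_s", "BST": "bst_s", "IMP": "imp_s", "FIN": "fin_s"}
    for f, sid in enumerate(subjects):
        test = [s for s in swings if s.subject_id == sid]
        train = [s for s in swings if s.subject_id != sid]
        if not test:
            raise EmptyFold(f"subject {sid} has no test swings")
        preds = _predict_fold(
            method, placement, modality, train, test,
            (seed * 1009 + f) % (2**31 - 1), train_config,
        )
        pt_errors = {p: [] for p in POINTS}
        ph_errors = {p: [] for p in PHASE_TARGETS}
        for truth, est in preds:
            if est is None:
                n_failed += 1
                continue
            for p in POINTS:
                pt_errors[p].append(abs(getattr(est, attr[p]) - getattr(truth, attr[p])))
            for ph, err in zip(PHASE_TARGETS, phase_length_error_pct(est, truth)):
                ph_errors[ph].append(err)
        for p in POINTS:
            if pt_errors[p]:
                rows.append(
                    dict(method=method, placement=placement, modality=modality,
                         metric="mae_ms", target=p, subject_id=sid,
                         value=float(np.mean(pt_errors[p])) * 1e3)
                )
        for ph in PHASE_TARGETS:
            if ph_errors[ph]:
                rows.append(
                    dict(method=method, placement=placement, modality=modality,
                         metric="phase_len_pct", target=ph, subject_id=sid,
                         value=float(np.mean(ph_errors[ph])))
                )
    columns = ["method", "placement", "modality", "metric", "target",
               "subject_id", "value"]
    return SegmentationReport(pd.DataFrame(rows, columns=columns), n_failed=n_failed)


def modality_ablation(
    swings: Sequence,
    method: str,
    placement: str,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
    modalities: Sequence[str] = ("a", "g", "a+g"),
) -> SegmentationReport:
    """Run matched LOSO folds for acceleration-only, gyro-only and combined
    inputs (identical folds and fold seeds across the three arms)."""
    reports = [
        loso_cv(swings, method, placement, m, train_config, seed=seed)
        for m in modalities
    ]
    return SegmentationReport.concat(reports)


def paired_significance(
    arm1: Sequence[float],
    arm2: Sequence[float],
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> Tuple[bool, float]:
    """Two-sided paired test on subject-level MAEs; (significant, p-value).

    Wilcoxon signed-rank by default (paired t-test via ``test='ttest'``).
    Identical arms return p = 1.0.  Raises ``pairing_error`` for unequal
    lengths or fewer than 5 pairs.
    """
    a1 = np.asarray(arm1, float)
    a2 = np.asarray(arm2, float)
    if a1.shape != a2.shape:
        raise PairingError(f"arms have different lengths: {a1.size} vs {a2.size}")
    if a1.size < 5:
        raise PairingError(f"need at least 5 pairs, got {a1.size}")
    diff = a1 - a2
    if np.allclose(diff, 0):
        return False, 1.0
    if test == "wilcoxon":
        res = stats.wilcoxon(a1, a2, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_rel(a1, a2)
    else:
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    p = float(res.pvalue)
    return bool(p < alpha), p


def render_report(report: SegmentationReport, out_dir) -> List[Path]:
    """Write the aggregate CSV, the per-subject CSV and MAE bar charts
    (grand mean +/- between-subject SD) to ``out_dir``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    grand = report.grand()
    agg_path = out_dir / "report.csv"
    grand.to_csv(agg_path, index=False, float_format="%.6f")
    files.append(agg_path)
    per_path = out_dir / "per_subject.csv"
    report.per_subject.to_csv(per_path, index=False, float_format="%.6f")
    files.append(per_path)

    mae = grand[grand.metric == "mae_ms"]
    for placement in mae.placement.unique():
        sub = mae[mae.placement == placement]
        fig, ax = plt.subplots(figsize=(7, 4))
        width = 0.8 / max(1, sub.groupby(["method", "modality"]).ngroups)
        xs = np.arange(len(POINTS))
        for k, ((method, modality), cell) in enumerate(
            sub.groupby(["method", "modality"], sort=False)
        ):
            vals = [
                float(cell[cell.target == p].grand_mean.iloc[0])
                if (cell.target == p).any() else np.nan
                for p in POINTS
            ]
            errs = [
                float(cell[cell.target == p].sd.iloc[0])
                if (cell.target == p).any() else np.nan
                for p in POINTS
            ]
            ax.bar(xs + k * width, vals, width, yerr=errs, capsize=2,
                   label=f"{method} ({modality})")
        ax.set_xticks(xs + 0.4 - width / 2)
        ax.set_xticklabels(POINTS)
        ax.set_ylabel("MAE (ms)")
        ax.set_title(f"Dividing-point MAE, {placement} IMU")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out_dir / f"mae_{placement}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        files.append(p)
    return files
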