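"""Indicator-event detection and rule-based segmentation."""

import numpy as np
import pytest

from swingseg.errors import EventNotFound, OrderViolation
from swingseg.heuristic import (
    IndicatorRule,
    detect_event,
    heuristic_segment,
    load_rules,
    rank_indicator_candidates,
    select_best_rules,
)
from swingseg.preprocess import filter_recording, find_impact_proxy
from swingseg.swingdata import ImuRecording

ATTR = {"ADD": "add_s", "BST": "bst_s", "IMP": "imp_s", "FIN": "fin_s"}


def _rule(**kw):
    base = dict(placement="wrist", point="ADD", source="gyro", channel="y",
                event="min", window=(0.0, 1.0))
    base.update(kw)
    return IndicatorRule(**base)


class TestDetectEvent:
    T = np.arange(0, 2.0, 0.005)

    def test_sine_zero_crossing_negative_slope(self):
        s = np.sin(2 * np.pi * self.T)
        rule = _rule(event="zero_crossing", slope="-", window=(0.2, 0.8))
        assert detect_event(s, self.T, rule, 0.0) == pytest.approx(0.5, abs=1e-9)

    def test_parabola_minimum(self):
        s = (self.T - 0.3) ** 2
        assert detect_event(s, self.T, _rule(), 0.0) == pytest.approx(0.3, abs=0.005)

    def test_constant_signal_has_no_crossing(self):
        with pytest.raises(EventNotFound):
            detect_event(np.ones_like(self.T), self.T,
                         _rule(event="zero_crossing"), 0.0)

    def test_translation_equivariance(self, rng):
        s = rng.normal(size=self.T.size)
        rule = _rule(window=(0.1, 0.9))
        t0 = detect_event(s, self.T, rule, 0.2)
        t1 = detect_event(s, self.T + 0.35, rule, 0.2 + 0.35)
        assert t1 - t0 == pytest.approx(0.35, abs=1e-12)


def test_all_rules_recover_truth_noiseless(noiseless_swings):
    """Joint generator/heuristic oracle: the selected indicator table and the
    gyro-only table land within 2 samples; the weaker acceleration-only table
    within 8 samples (the impact shock leaks into its FIN/BST searches)."""
    tol = {"a+g": 0.010, "g": 0.010, "a": 0.040}
    for swing in noiseless_swings:
        for pl, rec in swing.recordings.items():
            proxy = find_impact_proxy(rec)
            filt = filter_recording(rec)
            for modality, lim in tol.items():
                for rule in [r for r in load_rules(modality) if r.placement == pl]:
                    est = detect_event(rule.extract(filt), filt.t, rule, proxy)
                    truth = getattr(swing.truth, ATTR[rule.point])
                    assert abs(est - truth) <= lim, (pl, modality, rule.point)


def test_heuristic_segment_noiseless(noiseless_swings):
    for swing in noiseless_swings:
        for pl, rec in swing.recordings.items():
            est = heuristic_segment(rec)
            for p, a in ATTR.items():
                assert abs(getattr(est, a) - getattr(swing.truth, a)) <= 0.010, (pl, p)


def test_missing_bst_event_is_reported_by_name(noiseless_swings):
    swing = noiseless_swings[0]
    rec = swing.recordings["wrist"]
    gyro = rec.gyro.copy()
    gyro[2] = 0.0  # erase the z-axis crossing the BST rule needs
    broken = ImuRecording("wrist", rec.t, rec.acc, gyro, rec.sample_rate_hz)
    with pytest.raises(EventNotFound) as exc:
        heuristic_segment(broken)
    assert exc.value.point == "BST"


def test_unordered_rules_flag_order_violation(noiseless_swings):
    swing = noiseless_swings[0]
    rules = [r for r in load_rules("a+g") if r.placement == "wrist"]
    # force the ADD search after impact: its "event" lands after BST's
    swapped = [
        IndicatorRule(r.placement, r.point, r.source, r.channel, r.event,
                      r.slope, (0.2, 0.9) if r.point == "ADD" else r.window)
        for r in rules
    ]
    with pytest.raises(OrderViolation):
        heuristic_segment(swing.recordings["wrist"], rules=swapped)


class TestRanking:
    def test_true_rules_beat_lagged_decoys(self, noiseless_swings):
        rules = [r for r in load_rules("a+g") if r.placement == "wrist"]
        decoys = [
            IndicatorRule(r.placement, r.point, r.source, r.channel, r.event,
                          r.slope,
                          (r.search_window[0] + 0.15, r.search_window[1] + 0.15))
            for r in rules
        ]
        ranked = rank_indicator_candidates(rules + decoys, noiseless_swings)
        best = select_best_rules(ranked)
        assert sorted((b.placement, b.point) for b in best) == sorted(
            (r.placement, r.point) for r in rules
        )
        for b in best:
            assert b.window is None  # the shipped rule, not its lagged decoy

    def test_single_candidate_returned_with_mae(self, noiseless_swings):
        rule = [r for r in load_rules("a+g") if r.placement == "wrist"][0]
        ranked = rank_indicator_candidates([rule], noiseless_swings)
        assert len(ranked) == 1 and 0 <= ranked[0][1] < 0.05

    def test_identical_rules_tie_stably(self, noiseless_swings):
        rule = [r for r in load_rules("a+g") if r.placement == "wrist"][0]
        twin = IndicatorRule(rule.placement, rule.point, rule.source,
                             rule.channel, rule.event, rule.slope, (-2.4, -0.6))
        ranked = rank_indicator_candidates([twin, twin], noiseless_swings[:3])
        assert ranked[0][1] == ranked[1][1]


def test_mae_non_decreasing_in_noise():
    """Heuristic error grows with sensor noise (Monte-Carlo, 3 SE slack)."""
    from swingseg import GeneratorConfig, simulate_dataset

    maes = []
    ses = []
    for sd in (0.0, 8.0, 24.0):
        cfg = GeneratorConfig(noise_gyro_dps=sd, noise_acc_g=0.04 + sd / 200.0)
        data = simulate_dataset(3, 8, cfg, seed=29)
        errs = []
        for swing in data:
            est = heuristic_segment(swing.recordings["wrist"])
            errs.append(abs(est.add_s - swing.truth.add_s))
        maes.append(np.mean(errs))
        ses.append(np.std(errs, ddof=1) / np.sqrt(len(errs)))
    assert maes[0] <= maes[1] + 3 * ses[1]
    assert maes[1] <= maes[2] + 3 * (ses[1] ** 2 + ses[2] ** 2) ** 0.5
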