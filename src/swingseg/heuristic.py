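"""Rule-based swing segmentation from signal extrema and zero crossings.

Each dividing point is located by one indicator rule: the minimum, maximum
or zero crossing of one acceleration or angular-velocity channel (or the
Euclidean norm of the three filtered axes) inside a search window anchored
on the acceleration-peak impact proxy.  The shipped ``a+g`` table holds the
twelve indicators (placement x point); ``a``-only and ``g``-only tables
support the modality ablation, and a candidate list feeds the ranking
helper that selects the best rule per cell on a labeled dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import EventNotFound, OrderViolation
from .preprocess import filter_recording, find_impact_proxy
from .swingdata import POINTS, DividingPoints, ImuRecording

# search windows in seconds relative to the impact proxy; the ADD window's
# lower edge is the geometric bound (an in-window ADD needs bs+ds <= 2.45 s)
# and its upper edge clears the earliest plausible backswing top
DEFAULT_SEARCH_WINDOWS: Dict[str, Tuple[float, float]] = {
    "ADD": (-2.45, -0.55),
    "BST": (-0.80, -0.05),
    "IMP": (-0.05, 0.05),
    "FIN": (0.10, 1.00),
}


@dataclass(frozen=True)
class IndicatorRule:
    """One heuristic indicator.

    event: 'min' | 'max' | 'zero_crossing'; channel: 'x' | 'y' | 'z' | 'norm'
    (norm never pairs with zero_crossing); slope: '+' | '-' | 'either' for
    zero crossings; window: search interval relative to the impact proxy,
    None = the shipped default for the target point.
    """

    placement: str
    point: str
    source: str  # 'acc' | 'gyro'
    channel: str
    event: str
    slope: str = "either"
    window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.point not in POINTS:
            raise ValueError(f"unknown point {self.point!r}")
        if self.source not in ("acc", "gyro"):
            raise ValueError(f"source must be acc|gyro, got {self.source!r}")
        if self.channel not in ("x", "y", "z", "norm"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.event not in ("min", "max", "zero_crossing"):
            raise ValueError(f"unknown event {self.event!r}")
        if self.channel == "norm" and self.event == "zero_crossing":
            raise ValueError("norm channel cannot be paired with zero_crossing")
        win = self.window or DEFAULT_SEARCH_WINDOWS[self.point]
        if win[0] >= win[1]:
            raise ValueError("search window must satisfy lo < hi")

    @property
    def search_window(self) -> Tuple[float, float]:
        return self.window or DEFAULT_SEARCH_WINDOWS[self.point]

    def extract(self, rec: ImuRecording) -> np.ndarray:
        sig = rec.acc if self.source == "acc" else rec.gyro
        if self.channel == "norm":
            return np.linalg.norm(sig, axis=0)
        return sig["xyz".index(self.channel)]


def detect_event(
    signal: np.ndarray,
    t: np.ndarray,
    rule: IndicatorRule,
    t_impact_proxy: float,
) -> float:
    """Time of the rule's event inside its search window.

    min/max: earliest arg-extremum; zero_crossing: linearly interpolated
    crossing with the required slope sign, nearest to the window center when
    several exist.  Raises ``event_not_found`` if absent.
    """
    lo, hi = rule.search_window
    mask = (t >= t_impact_proxy + lo) & (t <= t_impact_proxy + hi)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise EventNotFound("search window outside signal span", point=rule.point)
    s = np.asarray(signal, dtype=float)[idx]
    tt = t[idx]
    if rule.event in ("min", "max"):
        k = int(np.argmin(s)) if rule.event == "min" else int(np.argmax(s))
        return float(tt[k])
    # zero crossing: strict sign change between consecutive samples; sign
    # flips at numerically negligible amplitude (filter ripple in otherwise
    # silent stretches) are not events
    floor = 1e-6 * float(np.max(np.abs(s))) if s.size else 0.0
    prod = s[:-1] * s[1:]
    cand = np.flatnonzero(
        (prod < 0) & (np.maximum(np.abs(s[:-1]), np.abs(s[1:])) > floor)
    )
    # a sample exactly at zero counts when its neighbours change sign
    zero = np.flatnonzero(s[1:-1] == 0)
    zero = zero[s[zero] * s[zero + 2] < 0]
    times, slopes = [], []
    for i in cand:
        frac = -s[i] / (s[i + 1] - s[i])
        times.append(tt[i] + frac * (tt[i + 1] - tt[i]))
        slopes.append(np.sign(s[i + 1] - s[i]))
    for i in zero:
        times.append(tt[i + 1])
        slopes.append(np.sign(s[i + 2] - s[i]))
    if rule.slope in ("+", "-"):
        want = 1.0 if rule.slope == "+" else -1.0
        times = [x for x, sl in zip(times, slopes) if sl == want]
    if not times:
        raise EventNotFound("no zero crossing in window", point=rule.point)
    center = t_impact_proxy + 0.5 * (lo + hi)
    return float(min(times, key=lambda x: abs(x - center)))


# ---------------------------------------------------------------------------
# shipped rule tables

_RULES_YAML = Path(__file__).parent / "data" / "indicator_rules.yaml"
_rules_cache: Optional[dict] = None


def _load_tables() -> dict:
    global _rules_cache
    if _rules_cache is None:
        with open(_RULES_YAML) as fh:
            _rules_cache = yaml.safe_load(fh)
    return _rules_cache


def rules_from_yaml_entries(entries: Sequence[dict]) -> List[IndicatorRule]:
    out = []
    for e in entries:
        e = dict(e)
        if "window" in e and e["window"] is not None:
            e["window"] = tuple(e["window"])
        out.append(IndicatorRule(**e))
    return out


def load_rules(modality: str = "a+g") -> List[IndicatorRule]:
    """Shipped indicator table for a modality ('a+g' is the 12-rule table)."""
    key = {"a+g": "a_plus_g", "a": "acc_only", "g": "gyro_only"}[modality]
    return rules_from_yaml_entries(_load_tables()[key])


def load_candidates() -> List[IndicatorRule]:
    """Shipped candidate indicators (supersets of the selected tables)."""
    tables = _load_tables()
    entries = tables["a_plus_g"] + tables["acc_only"] + tables["gyro_only"]
    seen, out = set(), []
    for e in entries:
        k = tuple(sorted((k, str(v)) for k, v in e.items()))
        if k not in seen:
            seen.add(k)
            out.append(e)
    return rules_from_yaml_entries(out)


def heuristic_segment(
    rec: ImuRecording,
    modality: str = "a+g",
    rules: Optional[Sequence[IndicatorRule]] = None,
    prefiltered: bool = False,
) -> DividingPoints:
    """Apply the placement's four indicator rules and return ordered points.

    The impact proxy comes from the *raw* acceleration norm; events are
    detected on the 10 Hz zero-phase-filtered channels.  Raises
    ``event_not_found`` (naming the failing point) or ``order_violation``.
    """
    if rules is None:
        rules = [r for r in load_rules(modality) if r.placement == rec.placement]
    by_point = {r.point: r for r in rules}
    missing = [p for p in POINTS if p not in by_point]
    if missing:
        raise ValueError(f"no rule for point(s) {missing} at {rec.placement}")
    proxy = find_impact_proxy(rec)
    filt = rec if prefiltered else filter_recording(rec)
    est = {}
    for p in POINTS:
        rule = by_point[p]
        est[p] = detect_event(rule.extract(filt), filt.t, rule, proxy)
    vals = [est[p] for p in POINTS]
    if not all(a < b for a, b in zip(vals, vals[1:])):
        raise OrderViolation(f"estimated points unordered: {dict(zip(POINTS, vals))}")
    return DividingPoints(*vals)


def rank_indicator_candidates(
    candidates: Sequence[IndicatorRule],
    swings: Sequence,
) -> List[Tuple[IndicatorRule, float]]:
    """Mean absolute error of each candidate on a labeled dataset, ascending.

    Swings whose recording lacks the rule's placement are skipped; a swing
    where the event is not found contributes the search-window width as a
    worst-case error.  Ties preserve input order (stable sort).
    """
    truth_attr = {"ADD": "add_s", "BST": "bst_s", "IMP": "imp_s", "FIN": "fin_s"}
    scored = []
    for rule in candidates:
        errs = []
        for swing in swings:
            rec = swing.recordings.get(rule.placement)
            if rec is None:
                continue
            proxy = find_impact_proxy(rec)
            filt = filter_recording(rec)
            truth = getattr(swing.truth, truth_attr[rule.point])
            try:
                est = detect_event(rule.extract(filt), filt.t, rule, proxy)
                errs.append(abs(est - truth))
            except EventNotFound:
                lo, hi = rule.search_window
                errs.append(hi - lo)
        scored.append((rule, float(np.mean(errs)) if errs else np.inf))
    return sorted(scored, key=lambda rm: rm[1])


def select_best_rules(
    ranked: Sequence[Tuple[IndicatorRule, float]]
) -> List[IndicatorRule]:
    """Best rule per (placement, point) cell from a ranked candidate list."""
    best: Dict[Tuple[str, str], IndicatorRule] = {}
    for rule, _mae in ranked:
        best.setdefault((rule.placement, rule.point), rule)
    return list(best.values())
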