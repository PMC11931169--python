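"""Ground-truth matching and sorting-quality metrics.

Sensitivity is computed against ground truth by greedy one-to-one event
matching within a +-1 ms tolerance: for each ground-truth unit, the sorted
unit with the most matched events is selected, its matched events count as
neural and the remainder as non-neural, and

    sensitivity = n_neural / (n_neural + n_non_neural).

Ground-truth-free quality metrics: the ISI-violation rate (intervals below
1.5 ms violate the neuronal refractory period; the default pairwise count
can exceed 100% when events bunch inside one window) and the silhouette
score of each event in segment space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import SortedUnit

ISI_WINDOW_S = 0.0015
ACCEPT_RATE = 0.05
MATCH_TOL_S = 0.001


@dataclass
class UnitMatch:
    gt_unit: int
    best_sorted_unit: int | None
    n_neural: int
    n_non_neural: int

    @property
    def sensitivity(self) -> float | None:
        total = self.n_neural + self.n_non_neural
        return self.n_neural / total if total else None


@dataclass
class MatchReport:
    per_unit: dict[int, UnitMatch] = field(default_factory=dict)
    tolerance_s: float = MATCH_TOL_S


def _greedy_match_count(gt: np.ndarray, sorted_times: np.ndarray, tol: float) -> int:
    """Greedy in-order one-to-one matching; ties go to the earlier gt event."""
    i = j = matched = 0
    while i < gt.size and j < sorted_times.size:
        d = sorted_times[j] - gt[i]
        if abs(d) <= tol:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            j += 1
        else:
            i += 1
    return matched


def match_events(gt_times: dict[int, np.ndarray], sorted_units: list[SortedUnit],
                 tol_ms: float = 1.0) -> MatchReport:
    """Match ground-truth units to sorted units within a time tolerance.

    For each ground-truth unit the sorted unit with the highest number of
    matched events is selected (ties -> lower sorted unit id).
    """
    tol = tol_ms * 1e-3
    report = MatchReport(tolerance_s=tol)
    for gid, times in gt_times.items():
        times = np.asarray(times, dtype=np.float64)
        if np.any(np.diff(times) < 0):
            raise ValueError(f"ground-truth unit {gid}: times not sorted")
        best, best_matched = None, -1
        for unit in sorted_units:
            m = _greedy_match_count(times, unit.event_times, tol)
            if m > best_matched:
                best, best_matched = unit, m
        if best is None or best_matched <= 0:
            report.per_unit[gid] = UnitMatch(gid, None, 0, 0)
        else:
            report.per_unit[gid] = UnitMatch(gid, best.unit_id, best_matched,
                                             best.n_events - best_matched)
    return report


def sensitivity(report: MatchReport) -> float:
    """Pooled sensitivity over all matched ground-truth units."""
    n = sum(m.n_neural for m in report.per_unit.values())
    d = sum(m.n_neural + m.n_non_neural for m in report.per_unit.values())
    if d == 0:
        raise ValueError("no matched events; sensitivity undefined")
    return n / d


def isi_violation_rate(times: np.ndarray, window_s: float = ISI_WINDOW_S,
                       mode: str = "pairwise") -> float:
    """Fraction of refractory-period violations in a spike train.

    ``pairwise`` (default) counts every ordered pair closer than the window
    and divides by the number of events, so dense bunches can push the rate
    above 100%.  ``consecutive`` counts only adjacent intervals, divided by
    n - 1.
    """
    times = np.asarray(times, dtype=np.float64)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    n = times.size
    if n < 2:
        return 0.0
    if mode == "consecutive":
        return float(np.sum(np.diff(times) < window_s) / (n - 1))
    if mode == "pairwise":
        later = np.searchsorted(times, times + window_s, side="left")
        return float(np.sum(later - np.arange(1, n + 1)) / n)
    raise ValueError(f"unknown mode {mode!r}")


def accept_unit(rate: float) -> bool:
    """A unit is accepted when its ISI-violation rate is strictly below 5%."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate < ACCEPT_RATE


def silhouette(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, dict[int, float]]:
    """Per-point silhouette scores and per-cluster means, Euclidean metric.

    S_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to the
    point's own cluster (excluding itself) and b_i the mean distance to the
    nearest other cluster.  A point alone in its cluster has no defined a_i
    and scores 0 by convention.
    """
    from sklearn.metrics import silhouette_samples

    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least two clusters")
    s = silhouette_samples(points, labels, metric="euclidean")
    means = {int(c): float(np.mean(s[labels == c])) for c in np.unique(labels)}
    return s, means


def classification_accuracy(true_labels, decisions) -> float:
    """Fraction of events whose spike / non-neural decision is correct.

    NEURAL maps to SPIKE; TYPE1 and TYPE2 map to NON_NEURAL.
    """
    from .aemodel import EventDecision
    from .synthgen import EventLabel

    if len(true_labels) != len(decisions):
        raise ValueError("label/decision length mismatch")
    correct = 0
    for lab, dec in zip(true_labels, decisions):
        want = EventDecision.SPIKE if lab == EventLabel.NEURAL else EventDecision.NON_NEURAL
        correct += (dec == want)
    return correct / len(true_labels)
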