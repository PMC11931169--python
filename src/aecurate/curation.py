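"""Curation of spike-sorting output by MSLE reconstruction score.

Two entry points mirror the two places curation slots into a sorting
pipeline: :func:`prefilter` drops non-neural events before clustering, and
:func:`curate_sorting` triages clustered units afterwards -- units that are
almost entirely neural are kept intact, units dominated by non-neural
events are discarded, and mixed ("hybrid") units are refined event by
event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import aemodel
from .aemodel import DEFAULT_THRESHOLD, ModelParams

NEURAL_CUT = 0.95
NONNEURAL_CUT = 0.50


@dataclass
class SortedUnit:
    """One cluster: event times (s, strictly increasing) and their segments."""

    unit_id: int
    event_times: np.ndarray
    segments: np.ndarray | None = None  # (n, 90)
    scores: np.ndarray | None = None    # per-event MSLE, filled by score_unit

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=np.float64)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError(f"unit {self.unit_id}: event times must be strictly increasing")
        if self.segments is not None and len(self.segments) != self.event_times.size:
            raise ValueError(f"unit {self.unit_id}: segments/times length mismatch")

    @property
    def n_events(self) -> int:
        return self.event_times.size


class UnitKind(str, Enum):
    NEURAL_UNIT = "NEURAL_UNIT"
    HYBRID_UNIT = "HYBRID_UNIT"
    NON_NEURAL_UNIT = "NON_NEURAL_UNIT"

    __str__ = str.__str__


@dataclass(frozen=True)
class UnitClass:
    kind: UnitKind
    neural_fraction: float


@dataclass
class CurationReport:
    unit_classes: dict[int, UnitClass] = field(default_factory=dict)
    removed_per_unit: dict[int, int] = field(default_factory=dict)
    kept_per_unit: dict[int, int] = field(default_factory=dict)
    dropped_units: list[int] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD
    neural_cut: float = NEURAL_CUT
    nonneural_cut: float = NONNEURAL_CUT


def score_unit(unit: SortedUnit, model: ModelParams) -> SortedUnit:
    """Return a copy of the unit with per-event MSLE scores filled in."""
    if unit.segments is None:
        raise ValueError(f"unit {unit.unit_id} has no segments to score")
    scores = aemodel.score_batch(model, unit.segments) if unit.n_events else np.empty(0)
    return SortedUnit(unit.unit_id, unit.event_times.copy(),
                      None if unit.segments is None else unit.segments.copy(), scores)


def prefilter(segments, model: ModelParams,
              threshold: float = DEFAULT_THRESHOLD) -> tuple[list, "pd.DataFrame"]:
    """Pre-clustering event filter: keep events whose MSLE <= threshold.

    Returns the kept events (input order preserved) and a removal log with
    one row per input event (event index, score, kept flag).
    """
    import pandas as pd

    scores = aemodel.score_batch(model, segments) if len(segments) else np.empty(0)
    keep = scores <= threshold
    log = pd.DataFrame({"event_id": np.arange(len(segments)), "msle": scores, "kept": keep})
    kept = [s for s, k in zip(segments, keep) if k]
    return kept, log


def classify_unit(unit: SortedUnit, threshold: float = DEFAULT_THRESHOLD,
                  neural_cut: float = NEURAL_CUT,
                  nonneural_cut: float = NONNEURAL_CUT) -> UnitClass:
    """Triage a scored unit by its fraction of spike-classified events.

    fraction >= neural_cut -> NEURAL_UNIT; fraction in [nonneural_cut,
    neural_cut) -> HYBRID_UNIT; below -> NON_NEURAL_UNIT.
    """
    if unit.scores is None:
        raise ValueError(f"unit {unit.unit_id} is not scored")
    if unit.n_events == 0:
        raise ValueError(f"unit {unit.unit_id} is empty")
    frac = float(np.mean(unit.scores <= threshold))
    if frac >= neural_cut:
        kind = UnitKind.NEURAL_UNIT
    elif frac >= nonneural_cut:
        kind = UnitKind.HYBRID_UNIT
    else:
        kind = UnitKind.NON_NEURAL_UNIT
    return UnitClass(kind, frac)


def refine_unit(unit: SortedUnit, threshold: float = DEFAULT_THRESHOLD) -> SortedUnit:
    """Event-level refinement: drop every event with MSLE above threshold."""
    if unit.scores is None:
        raise ValueError(f"unit {unit.unit_id} is not scored")
    keep = unit.scores <= threshold
    if not np.any(keep):
        warnings.warn(f"refinement emptied unit {unit.unit_id}")
    return SortedUnit(unit.unit_id, unit.event_times[keep],
                      None if unit.segments is None else unit.segments[keep],
                      unit.scores[keep])


def curate_sorting(units: list[SortedUnit], model: ModelParams | None = None,
                   threshold: float = DEFAULT_THRESHOLD,
                   neural_cut: float = NEURAL_CUT,
                   nonneural_cut: float = NONNEURAL_CUT,
                   ) -> tuple[list[SortedUnit], CurationReport]:
    """Post-clustering curation policy over a whole sorting.

    Neural units pass through unchanged, non-neural units are dropped
    (recorded in the report, never silently), hybrid units are refined.
    Unscored units are scored first when a model is provided.
    """
    report = CurationReport(threshold=threshold, neural_cut=neural_cut,
                            nonneural_cut=nonneural_cut)
    out: list[SortedUnit] = []
    for unit in units:
        if unit.scores is None:
            if model is None:
                raise ValueError(f"unit {unit.unit_id} unscored and no model given")
            unit = score_unit(unit, model)
        uc = classify_unit(unit, threshold, neural_cut, nonneural_cut)
        report.unit_classes[unit.unit_id] = uc
        if uc.kind == UnitKind.NON_NEURAL_UNIT:
            report.dropped_units.append(unit.unit_id)
            report.removed_per_unit[unit.unit_id] = unit.n_events
            report.kept_per_unit[unit.unit_id] = 0
            continue
        if uc.kind == UnitKind.HYBRID_UNIT:
            refined = refine_unit(unit, threshold)
        else:
            refined = unit
        report.removed_per_unit[unit.unit_id] = unit.n_events - refined.n_events
        report.kept_per_unit[unit.unit_id] = refined.n_events
        out.append(refined)
    return out, report
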