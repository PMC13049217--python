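"""Expert OPI norms, gated 12-item rubric scoring, and level assignment.

Items 1–6 come from video review and act as a gate: the first failed video
item zeroes every later item. Items 7–12 score OPI values against expert
norms (within two standard deviations of the expert mean earns credit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientDataError, InvalidArgumentError
from .opi import METRIC_NAMES, OpiVector

N_ITEMS = 12
LEVELS = ("completion", "safety", "economy", "optimized")
BELOW = "below_completion"

#: Items of each level, 1-based, in construct order.
LEVEL_ITEMS: dict[str, tuple[int, int, int]] = {
    "completion": (1, 2, 3),
    "safety": (4, 5, 6),
    "economy": (7, 8, 9),
    "optimized": (10, 11, 12),
}

#: Default OPI-category item mapping. Economy of motion (items 7–9) covers
#: energy usage, clutching and instrument movement distance; optimized
#: performance (items 10–12) covers wrist articulation, smoothness and
#: instrument active time.
DEFAULT_OPI_ITEM_MAP: dict[int, str] = {
    7: "energy_proportion",
    8: "clutch_count",
    9: "linear_path_length_mm",
    10: "angular_path_length_rad",
    11: "speed_peaks",
    12: "idle_time_s",
}

FAILURE_MODES = ("bleeding", "poor_tissue_handling", "lost_tension", "incomplete", "none")


@dataclass(frozen=True)
class VideoOutcome:
    """Rater outcome for the six video items plus the failure tag."""

    item_results: tuple[int, ...]
    failure_mode: str = "none"

    def __post_init__(self) -> None:
        if len(self.item_results) != 6:
            raise InvalidArgumentError("item_results must have 6 entries")
        if any(v not in (0, 1) for v in self.item_results):
            raise InvalidArgumentError("item_results must be binary")
        if self.failure_mode not in FAILURE_MODES:
            raise InvalidArgumentError(f"unknown failure_mode {self.failure_mode!r}")
        clean = all(v == 1 for v in self.item_results)
        if clean != (self.failure_mode == "none"):
            raise InvalidArgumentError("failure_mode must be 'none' iff all items pass")


@dataclass(frozen=True)
class RubricConfig:
    """Rubric layout: item→OPI mapping, gating scope, and the level rule."""

    opi_item_map: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_OPI_ITEM_MAP)
    )
    gating_items: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    level_rule: str = "cumulative"
    merge_below_completion: bool = False
    threshold_sidedness: str = "two"

    def __post_init__(self) -> None:
        if sorted(self.opi_item_map) != list(range(7, 13)):
            raise InvalidArgumentError("opi_item_map must cover items 7..12")
        if sorted(self.opi_item_map.values()) != sorted(METRIC_NAMES):
            raise InvalidArgumentError(
                "each OPI category must map to exactly one item"
            )
        if self.level_rule not in ("cumulative", "count"):
            raise InvalidArgumentError("level_rule must be 'cumulative' or 'count'")
        if self.threshold_sidedness not in ("two", "upper"):
            raise InvalidArgumentError("threshold_sidedness must be 'two' or 'upper'")

    def level_of_item(self, item: int) -> str:
        for level, items in LEVEL_ITEMS.items():
            if item in items:
                return level
        raise InvalidArgumentError(f"item {item} out of range 1..12")


@dataclass(frozen=True)
class NormEntry:
    mean: float
    sd: float

    @property
    def lower(self) -> float:
        return self.mean - 2.0 * self.sd

    @property
    def upper(self) -> float:
        return self.mean + 2.0 * self.sd


@dataclass(frozen=True)
class ExpertNorms:
    """Per-OPI mean/SD and the ±2 SD credit interval, from expert performances."""

    entries: Mapping[str, NormEntry]
    n_experts: int

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise InsufficientDataError("norms require at least 2 experts")

    def as_frame(self) -> pd.DataFrame:
        rows = {
            name: {"mean": e.mean, "sd": e.sd, "lower": e.lower, "upper": e.upper}
            for name, e in self.entries.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ItemResponseMatrix:
    """Persons × 12 binary scores with gating provenance.

    ``gated_from[n]`` is the 1-based item index at which the gate fired for
    person ``n`` (0 when it did not). All items at or after that index are 0.
    """

    subject_ids: list[str]
    scores: np.ndarray
    gated_from: np.ndarray
    group: list[str] | None = None
    levels: list[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        if self.scores.ndim != 2:
            raise InvalidArgumentError("scores must be 2-D")
        if len(self.subject_ids) != self.scores.shape[0]:
            raise InvalidArgumentError("subject_ids must align with score rows")
        if not np.isin(self.scores, (0, 1)).all():
            raise InvalidArgumentError("scores must be binary")
        self.gated_from = np.asarray(self.gated_from, dtype=int)
        if self.gated_from.shape != (self.scores.shape[0],):
            raise InvalidArgumentError("gated_from must align with score rows")
        for n, g in enumerate(self.gated_from):
            if g and self.scores[n, g - 1 :].any():
                raise InvalidArgumentError(
                    f"row {n}: nonzero score at or after gate position {g}"
                )

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]


def fit_expert_norms(expert_opis: Sequence[OpiVector]) -> ExpertNorms:
    """Sample mean and SD (n−1 denominator) per OPI across experts."""
    if len(expert_opis) < 2:
        raise InsufficientDataError("need at least 2 expert performances")
    table = pd.DataFrame([o.as_dict() for o in expert_opis])
    entries = {
        name: NormEntry(mean=float(table[name].mean()), sd=float(table[name].std(ddof=1)))
        for name in METRIC_NAMES
    }
    return ExpertNorms(entries=entries, n_experts=len(expert_opis))


def score_opi_item(value: float, norm: NormEntry, sidedness: str = "two") -> int:
    """1 iff the value sits within the expert credit interval (boundaries in).

    ``sidedness='upper'`` applies only the upper bound, for metrics where
    smaller is unambiguously better.
    """
    if sidedness == "upper":
        return int(value <= norm.upper)
    return int(norm.lower <= value <= norm.upper)


def apply_gate(
    raw_items: Sequence[int], rubric: RubricConfig | None = None
) -> tuple[np.ndarray, int]:
    """Zero every item at/after the first failed gating item.

    Returns the final 12-vector and the 1-based gate position (0 = no gate).
    Only the gating items (1–6 by default) can trigger the gate; a 0 on a
    later OPI item does not zero subsequent items.
    """
    rubric = rubric or RubricConfig()
    raw = np.asarray(raw_items, dtype=np.int8)
    if raw.shape != (N_ITEMS,):
        raise InvalidArgumentError(f"raw_items must have length {N_ITEMS}")
    final = raw.copy()
    for item in sorted(rubric.gating_items):
        if raw[item - 1] == 0:
            final[item - 1 :] = 0
            return final, item
    return final, 0


def assign_level(
    final: Sequence[int], rubric: RubricConfig | None = None
) -> str:
    """Map a gated 12-vector to its competency level.

    Cumulative rule: the highest level whose items — and those of every lower
    level — are all passed. Failing any completion item yields
    ``below_completion`` (or ``completion`` when merged for four-bucket
    summaries). The count rule buckets by total score in triples.
    """
    rubric = rubric or RubricConfig()
    vec = np.asarray(final, dtype=int)
    if vec.shape != (N_ITEMS,):
        raise InvalidArgumentError(f"final must have length {N_ITEMS}")
    if rubric.level_rule == "count":
        total = int(vec.sum())
        if total < 3:
            label = BELOW
        else:
            label = LEVELS[min(3, total // 3 - 1)]
    else:
        label = BELOW
        for level in LEVELS:
            lo, _, hi = LEVEL_ITEMS[level]
            if vec[lo - 1 : hi].all():
                label = level
            else:
                break
    if label == BELOW and rubric.merge_below_completion:
        return "completion"
    return label


def score_cohort(
    opis: pd.DataFrame,
    video: Mapping[str, VideoOutcome],
    norms: ExpertNorms,
    rubric: RubricConfig | None = None,
    group: Mapping[str, str] | None = None,
) -> ItemResponseMatrix:
    """Score every subject: video items 1–6, OPI items 7–12, then the gate.

    ``opis`` is indexed by subject_id with the six metric columns. Subjects
    must match between ``opis`` and ``video`` exactly.
    """
    rubric = rubric or RubricConfig()
    opi_subjects = set(opis.index)
    video_subjects = set(video)
    if opi_subjects != video_subjects:
        missing = sorted(opi_subjects ^ video_subjects)
        raise AlignmentError(f"subject mismatch between OPI and video tables: {missing}")
    subject_ids = list(opis.index)
    scores = np.zeros((len(subject_ids), N_ITEMS), dtype=np.int8)
    gated = np.zeros(len(subject_ids), dtype=int)
    levels: list[str] = []
    for n, sid in enumerate(subject_ids):
        raw = np.zeros(N_ITEMS, dtype=np.int8)
        raw[:6] = video[sid].item_results
        for item, metric in rubric.opi_item_map.items():
            raw[item - 1] = score_opi_item(
                float(opis.loc[sid, metric]),
                norms.entries[metric],
                rubric.threshold_sidedness,
            )
        final, g = apply_gate(raw, rubric)
        scores[n] = final
        gated[n] = g
        levels.append(assign_level(final, rubric))
    groups = [group.get(sid, "") for sid in subject_ids] if group else None
    return ItemResponseMatrix(
        subject_ids=subject_ids,
        scores=scores,
        gated_from=gated,
        group=groups,
        levels=levels,
    )
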