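"""Cohort curation: continuity, location and visibility pre-selection, the
train/test split and the 2x2 experiment arms.

A case survives pre-selection iff it passes every enabled criterion.  Removal
accounting attributes each removed case to the *first* failed criterion in
the fixed order continuity -> location -> visibility; the surviving set does
not depend on that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import StructureMask
from .visibility import CNR_BAND, CONTRAST_BAND, VisibilityMetrics, apply_visibility_filter

__all__ = [
    "CohortEntry",
    "ExperimentArm",
    "PreselectionCriteria",
    "PreselectionResult",
    "check_continuity",
    "check_location",
    "preselect",
    "split_cohort",
    "build_experiment_arms",
]

CRITERION_ORDER = ("continuity", "location", "visibility")

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CohortEntry:
    """Per-case curation state."""

    case_id: str
    metrics: VisibilityMetrics | None = None
    visibility_score: int | None = None
    continuous: bool | None = None
    in_fossa: bool | None = None
    partition: str | None = None  # "train" / "test"
    verdicts: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class ExperimentArm:
    """One cell of the 2x2 design: which training set x which test set."""

    model: str  # "model1_full_training" | "model2_preselected_training"
    test_set: str  # "full_test" | "preselected_test"
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        leaked = set(self.train_ids) & set(self.test_ids)
        if leaked:
            raise ValueError(f"train/test leakage in arm {self.model}/{self.test_set}: {sorted(leaked)}")


@dataclass(frozen=True)
class PreselectionCriteria:
    continuity: bool = True
    location: bool = True
    visibility_mode: str | None = "contrast"  # None disables the filter
    contrast_band: tuple[float, float] = CONTRAST_BAND
    cnr_band: tuple[float, float] = CNR_BAND
    min_fossa_fraction: float = 0.95


@dataclass(frozen=True)
class PreselectionResult:
    kept: list[CohortEntry]
    removed: list[CohortEntry]
    removal_counts: dict[str, int]


def check_continuity(gtv: StructureMask) -> bool:
    """True iff the GTV is a single 26-connected component."""
    if gtv.is_empty():
        raise ValueError("continuity undefined for an empty GTV")
    _, n = ndimage.label(gtv.voxels, structure=_CONN26)
    return n == 1


def check_location(gtv: StructureMask, fossa: StructureMask, min_fraction: float = 0.95) -> bool:
    """True iff at least ``min_fraction`` of GTV voxels lie inside the fossa."""
    if gtv.is_empty():
        raise ValueError("location undefined for an empty GTV")
    if not gtv.same_grid(fossa):
        raise ValueError("GTV and posterior fossa masks are on different grids")
    inside = int((gtv.voxels & fossa.voxels).sum())
    return inside / gtv.count() >= min_fraction


def _entry_passes(entry: CohortEntry, criterion: str, criteria: PreselectionCriteria) -> bool:
    if criterion == "continuity":
        if entry.continuous is None:
            raise ValueError(f"{entry.case_id}: continuity flag missing")
        return bool(entry.continuous)
    if criterion == "location":
        if entry.in_fossa is None:
            raise ValueError(f"{entry.case_id}: in-fossa flag missing")
        return bool(entry.in_fossa)
    if criterion == "visibility":
        if entry.metrics is None:
            raise ValueError(f"{entry.case_id}: visibility metrics missing")
        return apply_visibility_filter(
            entry.metrics,
            mode=criteria.visibility_mode,
            contrast_band=criteria.contrast_band,
            cnr_band=criteria.cnr_band,
        )
    raise ValueError(f"unknown criterion {criterion!r}")


def preselect(cohort: list[CohortEntry], criteria: PreselectionCriteria) -> PreselectionResult:
    """Filter a cohort; idempotent, order-insensitive in membership.

    Each entry's per-criterion verdicts are recorded; a removed entry is
    counted against the first criterion it fails.
    """
    enabled = [
        c
        for c in CRITERION_ORDER
        if {"continuity": criteria.continuity, "location": criteria.location,
            "visibility": criteria.visibility_mode is not None}[c]
    ]
    kept: list[CohortEntry] = []
    removed: list[CohortEntry] = []
    counts = {c: 0 for c in enabled}
    for entry in cohort:
        verdicts = {c: _entry_passes(entry, c, criteria) for c in enabled}
        entry.verdicts = verdicts
        failed = [c for c in enabled if not verdicts[c]]
        if failed:
            counts[failed[0]] += 1
            removed.append(entry)
        else:
            kept.append(entry)
    return PreselectionResult(kept=kept, removed=removed, removal_counts=counts)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_cohort(
    cohort: list[CohortEntry], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[CohortEntry], list[CohortEntry]]:
    """Deterministic shuffled split; train size = round(train_fraction * n),
    half away from zero.  Partition labels are written back onto the entries."""
    n = len(cohort)
    if n < 2:
        raise ValueError("cohort too small to split")
    n_train = _round_half_away(train_fraction * n)
    if n_train < 1 or n_train >= n:
        raise ValueError(f"degenerate split: {n_train} train of {n}")
    order = np.random.default_rng(seed).permutation(n)
    train = [cohort[i] for i in order[:n_train]]
    test = [cohort[i] for i in order[n_train:]]
    for e in train:
        e.partition = "train"
    for e in test:
        e.partition = "test"
    return train, test


def build_experiment_arms(
    full_train: list[str],
    full_test: list[str],
    preselected_ids: set[str],
) -> list[ExperimentArm]:
    """The four (training set, test set) bindings of the 2x2 design.

    The pre-selected training/test sets are the intersections of the full
    split with the pre-selected cohort, so the pre-selected test set is a
    subset of the full test set and no arm leaks test cases into training.
    """
    pre_train = [c for c in full_train if c in preselected_ids]
    pre_test = [c for c in full_test if c in preselected_ids]
    unknown = preselected_ids - set(full_train) - set(full_test)
    if unknown:
        raise ValueError(f"pre-selected ids outside the full cohort: {sorted(unknown)}")
    arms = []
    for model, train_ids in (
        ("model1_full_training", full_train),
        ("model2_preselected_training", pre_train),
    ):
        for test_name, test_ids in (("full_test", full_test), ("preselected_test", pre_test)):
            arms.append(
                ExperimentArm(
                    model=model,
                    test_set=test_name,
                    train_ids=tuple(train_ids),
                    test_ids=tuple(test_ids),
                )
            )
    return arms
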