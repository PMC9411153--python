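"""Patient manifests, cohort-level filters and cross-validation fold plans.

A cohort is a list of :class:`PatientRecord`. Each patient carries one
survival label — follow-up time in years and a disease-specific death
indicator — shared by all of the patient's tissue-microarray cores. Cores
only multiply the number of image patches (MIL instances) downstream; they
never carry their own label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalLabel",
    "PatientRecord",
    "FoldPlan",
    "ManifestFormatError",
    "CohortValidationError",
    "load_manifest",
    "filter_min_cores",
    "make_folds",
    "fold_plan_to_frame",
    "save_fold_plan",
    "load_fold_plan",
]

MANIFEST_COLUMNS = ("patient_id", "core_id", "time_years", "event")


class ManifestFormatError(ValueError):
    """The manifest file does not have the expected shape/columns."""


class CohortValidationError(ValueError):
    """The manifest parses but its content violates cohort invariants."""


@dataclass(frozen=True)
class SurvivalLabel:
    """Right-censored survival outcome (t_i, delta_i).

    time:  follow-up duration in years, >= 0.
    event: 1 if disease-specific death was observed, 0 if censored.
    """

    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise CohortValidationError(f"follow-up time must be finite and >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise CohortValidationError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    core_ids: tuple[str, ...]
    label: SurvivalLabel

    def __post_init__(self) -> None:
        if len(self.core_ids) == 0:
            raise CohortValidationError(f"patient {self.patient_id!r} has no cores")

    @property
    def n_cores(self) -> int:
        return len(self.core_ids)


@dataclass(frozen=True)
class FoldPlan:
    """Cross-validation plan: per fold a disjoint (train, val, test) triple.

    Test sets across folds partition the cohort; within each fold the non-test
    portion is split ~70/30 into train/validation (validation takes the floor).
    """

    n_folds: int
    assignments: tuple[tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]], ...]
    seed: int

    def fold(self, i: int) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
        return self.assignments[i]

    @property
    def test_sizes(self) -> list[int]:
        return [len(test) for _, _, test in self.assignments]


def load_manifest(path: str | Path) -> list[PatientRecord]:
    """Read a patient manifest CSV into a cohort.

    The CSV must have a header ``patient_id,core_id,time_years,event`` (UTF-8,
    '.' decimal separator). One record per distinct patient; all rows of a
    patient must agree on the survival label.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "core_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"manifest {path} is missing columns {missing}")
    records: list[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        labels = grp[["time_years", "event"]].drop_duplicates()
        if len(labels) > 1:
            raise CohortValidationError(
                f"patient {pid!r} has conflicting labels: {labels.to_dict('records')}"
            )
        time = float(labels["time_years"].iloc[0])
        event_raw = labels["event"].iloc[0]
        event = int(event_raw)
        if event != event_raw:
            raise CohortValidationError(f"patient {pid!r}: non-integer event {event_raw}")
        records.append(
            PatientRecord(
                patient_id=str(pid),
                core_ids=tuple(grp["core_id"].tolist()),
                label=SurvivalLabel(time=time, event=event),
            )
        )
    return records


def filter_min_cores(
    cohort: Sequence[PatientRecord], min_cores: int
) -> tuple[list[PatientRecord], int]:
    """Drop patients with fewer than ``min_cores`` cores.

    Returns ``(filtered_cohort, n_removed)``; input order is preserved.
    With the published cohort composition (236 patients x 3 cores, 7 x 2
    cores, 1 x 1 core) and ``min_cores=2`` this retains 243 patients.
    """
    if min_cores < 1:
        raise ValueError("min_cores must be >= 1")
    kept = [rec for rec in cohort if rec.n_cores >= min_cores]
    return kept, len(cohort) - len(kept)


def make_folds(
    cohort: Sequence[PatientRecord] | Sequence[str],
    n_folds: int,
    seed: int,
    val_fraction: float = 0.3,
    stratify_by_event: bool = False,
) -> FoldPlan:
    """Build a k-fold plan with an inner train/validation split.

    Patients are permuted uniformly at random under ``seed`` and dealt into
    ``n_folds`` test sets whose sizes differ by at most one. The remaining
    ~80% of each fold is split into train/validation with the validation set
    receiving ``floor(val_fraction * n_nontest)`` patients (default 30%).

    ``stratify_by_event=True`` permutes events and censored patients
    separately before interleaving, balancing event counts across folds.
    """
    ids = [rec.patient_id if isinstance(rec, PatientRecord) else str(rec) for rec in cohort]
    if len(set(ids)) != len(ids):
        raise CohortValidationError("duplicate patient ids in cohort")
    n = len(ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError(f"cohort of {n} patients cannot be split into {n_folds} folds")
    rng = np.random.default_rng(seed)
    if stratify_by_event:
        events = {
            rec.patient_id: rec.label.event
            for rec in cohort
            if isinstance(rec, PatientRecord)
        }
        if len(events) != n:
            raise ValueError("stratify_by_event requires PatientRecord inputs")
        pos = [i for i in ids if events[i] == 1]
        neg = [i for i in ids if events[i] == 0]
        order = [pos[i] for i in rng.permutation(len(pos))] + [
            neg[i] for i in rng.permutation(len(neg))
        ]
        # deal round-robin so event-positive patients spread across folds
        chunks: list[list[str]] = [[] for _ in range(n_folds)]
        for j, pid in enumerate(order):
            chunks[j % n_folds].append(pid)
    else:
        order = [ids[i] for i in rng.permutation(n)]
        base, extra = divmod(n, n_folds)
        chunks = []
        start = 0
        for f in range(n_folds):
            size = base + (1 if f < extra else 0)
            chunks.append(order[start : start + size])
            start += size
    assignments = []
    for f in range(n_folds):
        test = sorted(chunks[f])
        nontest = [pid for g in range(n_folds) if g != f for pid in chunks[g]]
        nontest = [nontest[i] for i in rng.permutation(len(nontest))]
        n_val = int(np.floor(val_fraction * len(nontest)))
        val = sorted(nontest[:n_val])
        train = sorted(nontest[n_val:])
        assignments.append((tuple(train), tuple(val), tuple(test)))
    return FoldPlan(n_folds=n_folds, assignments=tuple(assignments), seed=seed)


def fold_plan_to_frame(plan: FoldPlan) -> pd.DataFrame:
    """Serialize a plan as long-format rows ``patient_id,fold,role``."""
    rows = []
    for f, (train, val, test) in enumerate(plan.assignments):
        for role, members in (("train", train), ("val", val), ("test", test)):
            rows.extend({"patient_id": pid, "fold": f, "role": role} for pid in members)
    return pd.DataFrame(rows, columns=["patient_id", "fold", "role"])


def save_fold_plan(plan: FoldPlan, path: str | Path) -> None:
    fold_plan_to_frame(plan).to_csv(path, index=False)


def load_fold_plan(path: str | Path, seed: int = -1) -> FoldPlan:
    df = pd.read_csv(path, dtype={"patient_id": str})
    n_folds = int(df["fold"].max()) + 1
    assignments = []
    for f in range(n_folds):
        sub = df[df["fold"] == f]
        triple = tuple(
            tuple(sorted(sub.loc[sub["role"] == role, "patient_id"])) for role in ("train", "val", "test")
        )
        assignments.append(triple)
    return FoldPlan(n_folds=n_folds, assignments=tuple(assignments), seed=seed)
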