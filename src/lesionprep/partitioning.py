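"""Patient-wise splitting and k-fold cross-validation planning.

All splitting is by whole patient, never by image: slices of one patient in
both train and test would leak near-duplicate images across the boundary and
inflate every metric.

The k-fold plan deals a seeded shuffle of the patients into ``k`` equal folds
of ``floor(n/k)``; the ``n mod k`` leftover patients are marked REMAINDER and
join every training set, so they are never tested.  For a 922-patient cohort
at k=10 this yields ten test folds of 92 and train sets of 830 (828 fold
members + 2 remainder patients).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["REMAINDER", "FoldPlan", "split_patients", "make_fold_plan", "fold_split"]

REMAINDER = "REMAINDER"


@dataclass
class FoldPlan:
    """Assignment of every patient to a fold index in [0, k) or REMAINDER."""

    k: int
    seed: int
    assignments: dict[str, int | str] = field(default_factory=dict)

    def fold_members(self, fold_index: int) -> list[str]:
        return [p for p, f in self.assignments.items() if f == fold_index]

    def remainder(self) -> list[str]:
        return [p for p, f in self.assignments.items() if f == REMAINDER]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            fh.write(f"# k={self.k} seed={self.seed}\n")
            w = csv.writer(fh)
            w.writerow(["patient_id", "fold"])
            for pid, f in self.assignments.items():
                w.writerow([pid, f])

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoldPlan":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split())
            rows = list(csv.DictReader(fh))
        assignments: dict[str, int | str] = {}
        for r in rows:
            f = r["fold"]
            assignments[r["patient_id"]] = f if f == REMAINDER else int(f)
        return cls(k=int(meta["k"]), seed=int(meta["seed"]), assignments=assignments)


def split_patients(
    patient_ids: list[str], test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Single seeded train/test split at the patient level.

    ``|test| = round(n * test_fraction)``; deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = len(patient_ids)
    if n < 2:
        raise ValueError(f"need at least 2 patients, got {n}")
    rng = np.random.default_rng(seed)
    order = [patient_ids[i] for i in rng.permutation(n)]
    n_test = int(round(n * test_fraction))
    n_test = max(1, min(n - 1, n_test))
    return sorted(order[n_test:]), sorted(order[:n_test])


def make_fold_plan(patient_ids: list[str], k: int = 10, seed: int = 0) -> FoldPlan:
    """Shuffle patients and deal them into ``k`` folds of ``floor(n/k)``.

    The ``n mod k`` patients left over are tagged REMAINDER (always train).
    """
    n = len(patient_ids)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} patients, got {n}")
    rng = np.random.default_rng(seed)
    order = [patient_ids[i] for i in rng.permutation(n)]
    fold_size = n // k
    assignments: dict[str, int | str] = {}
    for i, pid in enumerate(order):
        assignments[pid] = i // fold_size if i < k * fold_size else REMAINDER
    return FoldPlan(k=k, seed=seed, assignments=assignments)


def fold_split(plan: FoldPlan, fold_index: int) -> tuple[list[str], list[str]]:
    """Train/test sets for one fold: test = fold members, train = everyone else.

    Remainder patients appear in the train set of every fold.
    """
    if not 0 <= fold_index < plan.k:
        raise ValueError(f"fold_index must be in [0, {plan.k}), got {fold_index}")
    test = sorted(plan.fold_members(fold_index))
    test_set = set(test)
    train = sorted(p for p in plan.assignments if p not in test_set)
    return train, test
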