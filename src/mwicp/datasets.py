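"""Dataset-variant creation (Ds1-Ds4) and trial-disjoint splitting.

Each processed trial yields four overlapping sample windows: the full
trial, its first 80 %, its last 80 % and the middle 80 % (10 %-90 %).
Train/test/validation splitting is by whole trials only (80/10/10 by trial
count), so no time sample of one trial can appear on both sides of a
model-evaluation boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import InvalidConfigError
from .preprocess import ProcessedTrial

__all__ = ["DatasetVariant", "SplitAssignment", "create_variants",
           "split_trials"]

VARIANT_NAMES = ("Ds1", "Ds2", "Ds3", "Ds4")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DatasetVariant:
    """One slice of a processed trial, 1-based inclusive sweep range."""

    k: int                      # 1..4
    trial: ProcessedTrial
    start: int
    stop: int

    @property
    def name(self) -> str:
        return VARIANT_NAMES[self.k - 1]

    @property
    def n_sweeps(self) -> int:
        return self.stop - self.start + 1

    @property
    def slice(self) -> slice:
        return slice(self.start - 1, self.stop)

    def pressure(self) -> np.ndarray:
        return self.trial.p_at_sweep[self.slice]

    def channel(self, name: str) -> np.ndarray:
        return self.trial.channels[name][self.slice]


def create_variants(trial: ProcessedTrial) -> list[DatasetVariant]:
    """The four sample windows of one trial.

    Ds1 = [1, N]; Ds2 = first 80 %; Ds3 = last 80 %; Ds4 = middle 80 %
    (10 %-90 %), with round-half-up on sample counts.
    """
    n = trial.n_sweeps
    if n < 10:
        raise InvalidConfigError(
            f"need at least 10 sweeps for the variant windows, got {n}")
    m = _round_half_up(0.8 * n)
    lo = _round_half_up(0.1 * n)
    hi = lo + m  # same retained length as Ds2/Ds3 by construction
    return [
        DatasetVariant(1, trial, 1, n),
        DatasetVariant(2, trial, 1, m),
        DatasetVariant(3, trial, n - m + 1, n),
        DatasetVariant(4, trial, lo + 1, hi),
    ]


@dataclass(frozen=True)
class SplitAssignment:
    """Trial-level 80/10/10 partition into train/test/validation."""

    roles: dict[object, str]
    seed: int

    def ids(self, role: str) -> list:
        return [t for t, r in self.roles.items() if r == role]


def split_trials(trial_ids: list, seed: int = 0) -> SplitAssignment:
    """Randomly partition trials 80/10/10 by count.

    Counts use largest-remainder rounding; every role is non-empty whenever
    at least three trials are supplied. Deterministic under ``seed``.
    """
    ids = list(trial_ids)
    if len(set(ids)) != len(ids):
        raise InvalidConfigError("trial ids must be unique")
    n = len(ids)
    if n < 3:
        raise InvalidConfigError("need at least 3 trials to split")
    fractions = {"train": 0.8, "test": 0.1, "validation": 0.1}
    counts = {r: int(math.floor(f * n)) for r, f in fractions.items()}
    remainders = {r: f * n - counts[r] for r, f in fractions.items()}
    leftover = n - sum(counts.values())
    for r in sorted(fractions, key=lambda r: (-remainders[r], r)):
        if leftover == 0:
            break
        counts[r] += 1
        leftover -= 1
    # guarantee non-empty roles by borrowing from the largest role
    for r in ("test", "validation", "train"):
        while counts[r] == 0:
            donor = max(counts, key=counts.get)
            counts[donor] -= 1
            counts[r] += 1

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    roles = {}
    cursor = 0
    for r in ("train", "test", "validation"):
        for i in order[cursor:cursor + counts[r]]:
            roles[ids[i]] = r
        cursor += counts[r]
    return SplitAssignment(roles=roles, seed=seed)
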