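"""Age-of-acquisition tables, monthly schedules, and bootstrapped distributions.

The acquisition table holds, for each concept ``i`` and month ``m``, the
cumulative probability ``p[i, m]`` that a child produces the word by that
month (the WordBank / MB-CDI item-trajectory layout, months 16..24 by
default).  From it we derive:

* the monthly schedule — how many concepts a simulated learner adds each
  month, ``N_m = round(sum_i p[i, m])`` with per-month increments by
  differencing;
* sampling distributions over not-yet-acquired concepts, proportional to
  the month's acquisition probabilities;
* bootstrapped inclusion-probability tables used as regression targets when
  training the AoA-matched generative agent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionTable",
    "MonthSchedule",
    "BootstrapSet",
    "load_acquisition_table",
    "save_acquisition_table",
    "monthly_counts",
    "acquisition_distribution",
    "sample_acquisition_sequence",
    "bootstrap_distributions",
]

DEFAULT_MONTH_RANGE = (16, 24)


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class AcquisitionTable:
    """Cumulative per-concept, per-month acquisition probabilities."""

    concepts: tuple[str, ...]
    months: tuple[int, ...]
    probs: np.ndarray  # shape (n_concepts, n_months), values in [0, 1]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "concepts", tuple(self.concepts))
        object.__setattr__(self, "months", tuple(int(m) for m in self.months))
        if probs.shape != (len(self.concepts), len(self.months)):
            raise ValueError(
                f"probs shape {probs.shape} != "
                f"({len(self.concepts)}, {len(self.months)})"
            )
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("duplicate concept labels in acquisition table")
        if list(self.months) != sorted(self.months):
            raise ValueError("months must be increasing")
        if not np.all(np.isfinite(probs)):
            raise ValueError("acquisition probabilities must be finite")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("acquisition probabilities must lie in [0, 1]")
        # Cumulative monotonicity over months; repair by running max.
        mono = np.maximum.accumulate(probs, axis=1)
        if not np.allclose(mono, probs):
            n_bad = int(np.sum(~np.isclose(mono, probs)))
            warnings.warn(
                f"clipped {n_bad} non-monotone acquisition cell(s) to the "
                "running maximum",
                stacklevel=3,
            )
            probs = mono
        object.__setattr__(self, "probs", probs)

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.concepts)}

    def month_column(self, month: int) -> np.ndarray:
        try:
            j = self.months.index(int(month))
        except ValueError:
            raise KeyError(f"month {month} not in table") from None
        return self.probs[:, j]

    def restrict(self, concepts: Sequence[str]) -> "AcquisitionTable":
        """Subset rows to ``concepts`` (kept in table order)."""
        keep = set(concepts)
        rows = [i for i, c in enumerate(self.concepts) if c in keep]
        if not rows:
            raise ValueError("restriction removes every concept")
        return AcquisitionTable(
            tuple(self.concepts[i] for i in rows),
            self.months,
            self.probs[rows],
        )


@dataclass(frozen=True)
class MonthSchedule:
    """Per-month acquisition counts ``n_m`` and cumulative counts ``N_m``."""

    months: tuple[int, ...]
    n_per_month: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "months", tuple(int(m) for m in self.months))
        object.__setattr__(
            self, "n_per_month", tuple(int(n) for n in self.n_per_month)
        )
        if len(self.months) != len(self.n_per_month):
            raise ValueError("months and n_per_month length mismatch")
        if any(n < 0 for n in self.n_per_month):
            raise ValueError("negative monthly count")

    @property
    def cumulative(self) -> tuple[int, ...]:
        return tuple(np.cumsum(self.n_per_month).astype(int))

    @property
    def total(self) -> int:
        return int(sum(self.n_per_month))

    def scaled(self, factor: float) -> "MonthSchedule":
        """Scale monthly counts by ``factor`` (each at least 1)."""
        return MonthSchedule(
            self.months,
            tuple(max(1, _round_half_away(n * factor)) for n in self.n_per_month),
        )


@dataclass(frozen=True)
class BootstrapSet:
    """B bootstrapped inclusion-probability tables with a train/val split."""

    concepts: tuple[str, ...]
    months: tuple[int, ...]
    dists: np.ndarray  # shape (B, n_concepts, n_months)
    train_idx: tuple[int, ...]
    val_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        dists = np.asarray(self.dists, dtype=float)
        object.__setattr__(self, "dists", dists)
        B = dists.shape[0]
        if dists.shape[1:] != (len(self.concepts), len(self.months)):
            raise ValueError("bootstrap distribution shape mismatch")
        if np.any(dists < 0) or np.any(dists > 1):
            raise ValueError("bootstrap probabilities must lie in [0, 1]")
        if np.any(np.diff(dists, axis=2) < -1e-12):
            raise ValueError("bootstrap probabilities must be monotone in month")
        tr, va = set(self.train_idx), set(self.val_idx)
        if tr & va or tr | va != set(range(B)):
            raise ValueError("train/val indices must partition 0..B-1")

    @property
    def B(self) -> int:
        return int(self.dists.shape[0])

    @property
    def train(self) -> np.ndarray:
        return self.dists[list(self.train_idx)]

    @property
    def validation(self) -> np.ndarray:
        return self.dists[list(self.val_idx)]


def load_acquisition_table(
    path: str | Path,
    *,
    month_range: tuple[int, int] = DEFAULT_MONTH_RANGE,
    item_column: str = "item",
    concepts: Sequence[str] | None = None,
    lowercase: bool = True,
) -> AcquisitionTable:
    """Read an item-trajectory CSV (one row per word, one column per month).

    Month columns may be labelled either with the bare month number (``"18"``)
    or any label whose trailing integer is the month.  The table is restricted
    to ``month_range`` (inclusive); ``concepts``, when given, further restricts
    the rows (e.g. to the vocabulary shared with the embedding systems).
    """
    df = pd.read_csv(path)
    if item_column not in df.columns:
        raise ValueError(f"missing item column {item_column!r}")

    def month_of(col: str) -> int | None:
        tail = str(col).strip().split("_")[-1]
        try:
            return int(tail)
        except ValueError:
            return None

    lo, hi = month_range
    month_cols = {
        month_of(c): c for c in df.columns if c != item_column
        if month_of(c) is not None
    }
    wanted = list(range(lo, hi + 1))
    missing = [m for m in wanted if m not in month_cols]
    if missing:
        raise ValueError(f"missing month column(s) for months {missing}")

    labels = df[item_column].astype(str)
    if lowercase:
        labels = labels.str.lower()
    probs = df[[month_cols[m] for m in wanted]].to_numpy(dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("acquisition probabilities outside [0, 1]")
    table = AcquisitionTable(tuple(labels), tuple(wanted), probs)
    if concepts is not None:
        table = table.restrict([c.lower() if lowercase else c for c in concepts])
    return table


def save_acquisition_table(table: AcquisitionTable, path: str | Path) -> None:
    """Write the CSV dialect that :func:`load_acquisition_table` reads."""
    df = pd.DataFrame(table.probs, columns=[str(m) for m in table.months])
    df.insert(0, "item", list(table.concepts))
    df.to_csv(path, index=False)


def monthly_counts(table: AcquisitionTable) -> MonthSchedule:
    """Schedule of concepts acquired per month.

    Cumulative count ``N_m = round(sum_i p[i, m])`` (ties away from zero);
    monthly increments by differencing, with the first month's increment
    equal to its cumulative count.
    """
    if table.n_concepts == 0:
        raise ValueError("empty acquisition table")
    cumulative = [_round_half_away(s) for s in table.probs.sum(axis=0)]
    n_per_month = list(np.diff([0] + cumulative))
    if any(n < 0 for n in n_per_month):
        raise ValueError(
            "negative monthly increment after rounding (non-monotone table?)"
        )
    return MonthSchedule(table.months, tuple(int(n) for n in n_per_month))


def acquisition_distribution(
    table: AcquisitionTable,
    month: int,
    known: Sequence[str],
) -> tuple[tuple[str, ...], np.ndarray]:
    """Sampling distribution over unacquired table concepts for ``month``.

    Mass is proportional to the month's cumulative acquisition probability
    ``p[i, m]``, renormalized over the concepts not in ``known``.  When every
    remaining probability is zero the distribution falls back to uniform
    (with a warning); the empirical table never triggers this, but arbitrary
    synthetic tables can.

    Returns the eligible concept labels and their probabilities.
    """
    known_set = set(known)
    remaining = [c for c in table.concepts if c not in known_set]
    if not remaining:
        raise ValueError("no unacquired concepts remain in the table")
    col = table.month_column(month)
    idx = table.index()
    mass = np.array([col[idx[c]] for c in remaining], dtype=float)
    total = mass.sum()
    if total <= 0:
        warnings.warn(
            f"all remaining acquisition probabilities are 0 at month {month}; "
            "falling back to uniform",
            stacklevel=2,
        )
        mass = np.ones(len(remaining))
        total = mass.sum()
    return tuple(remaining), mass / total


def sample_acquisition_sequence(
    table: AcquisitionTable,
    schedule: MonthSchedule,
    rng: np.random.Generator,
) -> list[list[str]]:
    """One simulated acquisition trajectory.

    For each month, draws that month's quota one concept at a time, without
    replacement, from :func:`acquisition_distribution`.  Returns the
    cumulative knowledge-state membership after each month.
    """
    if schedule.total > table.n_concepts:
        raise ValueError(
            f"schedule demands {schedule.total} concepts; table has "
            f"{table.n_concepts}"
        )
    known: list[str] = []
    states: list[list[str]] = []
    for month, n_m in zip(schedule.months, schedule.n_per_month):
        for _ in range(n_m):
            eligible, p = acquisition_distribution(table, month, known)
            choice = rng.choice(len(eligible), p=p)
            known.append(eligible[choice])
        states.append(list(known))
    return states


def bootstrap_distributions(
    table: AcquisitionTable,
    B: int,
    seqs_per_boot: int,
    schedule: MonthSchedule,
    rng: np.random.Generator,
    *,
    train_frac: float = 0.7,
) -> BootstrapSet:
    """Bootstrapped inclusion-probability tables from simulated trajectories.

    Each of the ``B`` bootstrap tables is the per-concept, per-month
    proportion of ``seqs_per_boot`` simulated acquisition sequences in which
    the concept had been acquired by that month.  A 70/30 train/validation
    split over the B tables is recorded for generative-agent model selection.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap distributions")
    if seqs_per_boot < 1:
        raise ValueError("seqs_per_boot must be >= 1")
    if schedule.total > table.n_concepts:
        raise ValueError(
            f"schedule demands {schedule.total} concepts; table has "
            f"{table.n_concepts}"
        )
    idx = table.index()
    n, M = table.n_concepts, len(schedule.months)
    dists = np.empty((B, n, M))
    for b in range(B):
        counts = np.zeros((n, M))
        for _ in range(seqs_per_boot):
            states = sample_acquisition_sequence(table, schedule, rng)
            for j, members in enumerate(states):
                counts[[idx[c] for c in members], j] += 1
        dists[b] = counts / seqs_per_boot
    order = rng.permutation(B)
    n_train = int(round(train_frac * B))
    n_train = min(max(n_train, 1), B - 1)
    return BootstrapSet(
        table.concepts,
        tuple(schedule.months),
        dists,
        tuple(int(i) for i in order[:n_train]),
        tuple(int(i) for i in order[n_train:]),
    )
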