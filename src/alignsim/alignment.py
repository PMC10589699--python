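"""Alignment scores and the two-alternative forced-choice probe task.

The alignment score between two systems is the Spearman rank correlation
``rho_s`` between the upper-triangular parts of their pairwise distance
matrices, with item order given by the candidate cross-system mapping.
Mirrored similarity relations (second-order isomorphism) give high scores
for the correct mapping.

In the forced-choice task an agent sees two unknown words and two unknown
objects and must pick one of the two possible word-object mappings.  Since
only the two probe items move between the candidate mappings, the higher-
scoring candidate can be found from the concatenated probe columns alone:
the vector of each probe item's distances to every knowledge-state concept,
concatenated in candidate order, correlated across modalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .systems import DistanceMatrix, SystemPair, pairwise_distances

__all__ = [
    "KnowledgeState",
    "ProbePair",
    "ForcedChoiceResult",
    "alignment_score",
    "probe_alignment_score",
    "forced_choice",
    "full_alignment_decision",
]

Mapping_ = Literal["correct", "swapped"]

#: scores closer than this are a tie
TIE_TOL = 1e-12


class DegenerateCorrelationError(ValueError):
    """A correlation input vector is constant: rho_s is undefined."""


@dataclass(frozen=True)
class KnowledgeState:
    """The ordered set of concepts whose cross-modal mappings are known."""

    concepts: tuple[str, ...]
    month: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "concepts", tuple(self.concepts))
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("knowledge state has duplicate concepts")

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept: str) -> bool:
        return concept in set(self.concepts)


@dataclass(frozen=True)
class ProbePair:
    """Two concepts outside the knowledge state, probed in a forced choice."""

    concept_a: str
    concept_b: str

    def __post_init__(self) -> None:
        if self.concept_a == self.concept_b:
            raise ValueError("probe concepts must differ")

    def validate(self, state: KnowledgeState, pair: SystemPair) -> None:
        vocab = set(pair.shared_concepts)
        for c in (self.concept_a, self.concept_b):
            if c not in vocab:
                raise ValueError(f"probe concept {c!r} not in shared vocabulary")
            if c in state:
                raise ValueError(f"probe concept {c!r} already in knowledge state")


@dataclass(frozen=True)
class ForcedChoiceResult:
    """Outcome of one forced-choice trial."""

    chosen_mapping: Mapping_
    score_correct: float
    score_incorrect: float
    tie_broken: bool

    @property
    def margin(self) -> float:
        return self.score_correct - self.score_incorrect

    @property
    def correct(self) -> bool:
        return self.chosen_mapping == "correct"


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average-rank ties; raises on constant input."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCorrelationError(
            "constant distance vector: Spearman correlation undefined"
        )
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def alignment_score(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    mapping: Sequence[int] | None = None,
) -> float:
    """Alignment score rho_s between two systems under a candidate mapping.

    ``mapping[i]`` is the index in ``dist_b`` mapped to item ``i`` of
    ``dist_a``; ``None`` means the identity (index-aligned systems).  The
    score is the Spearman correlation of the two upper triangles.
    """
    n = dist_a.n_concepts
    if dist_b.n_concepts != n:
        raise ValueError("distance matrices must have the same size")
    if n < 3:
        raise ValueError("alignment score needs at least 3 items")
    if mapping is None:
        mapping = np.arange(n)
    mapping = np.asarray(mapping, dtype=int)
    if sorted(mapping.tolist()) != list(range(n)):
        raise ValueError("mapping must be a permutation of 0..n-1")
    b = dist_b.values[np.ix_(mapping, mapping)]
    iu = np.triu_indices(n, k=1)
    return _spearman(dist_a.values[iu], b[iu])


def _probe_columns(
    dist: DistanceMatrix,
    state: KnowledgeState,
    first: str,
    second: str,
) -> np.ndarray:
    """Distances from each of two probe items to every state concept,
    concatenated (length 2*|state|)."""
    idx = {c: i for i, c in enumerate(dist.concepts)}
    rows = [idx[c] for c in state.concepts]
    return np.concatenate(
        [dist.values[idx[first], rows], dist.values[idx[second], rows]]
    )


def probe_alignment_score(
    pair: SystemPair,
    state: KnowledgeState,
    probes: ProbePair,
    candidate: Mapping_ = "correct",
    *,
    metric: str = "euclidean",
    dists: tuple[DistanceMatrix, DistanceMatrix] | None = None,
) -> float:
    """Alignment score of one candidate probe mapping via probe columns.

    Builds, per modality, the concatenated vector of distances from the two
    probe items to every knowledge-state concept; the ``swapped`` candidate
    exchanges the probe order on the linguistic side.  Returns the Spearman
    correlation of the visual and linguistic concatenated vectors.

    ``dists`` can carry precomputed (visual, linguistic) distance matrices
    to avoid recomputation across many trials.
    """
    if len(state) < 2:
        raise ValueError("knowledge state must contain at least 2 concepts")
    probes.validate(state, pair)
    if candidate not in ("correct", "swapped"):
        raise ValueError(f"unknown candidate mapping {candidate!r}")
    d_vis, d_lin = dists if dists is not None else pair.distance_matrices(metric)
    a, b = probes.concept_a, probes.concept_b
    x = _probe_columns(d_vis, state, a, b)
    if candidate == "correct":
        y = _probe_columns(d_lin, state, a, b)
    else:
        y = _probe_columns(d_lin, state, b, a)
    return _spearman(x, y)


def forced_choice(
    pair: SystemPair,
    state: KnowledgeState,
    probes: ProbePair,
    rng: np.random.Generator,
    *,
    metric: str = "euclidean",
    dists: tuple[DistanceMatrix, DistanceMatrix] | None = None,
) -> ForcedChoiceResult:
    """Score both candidate probe mappings and choose the higher.

    Ties (scores equal within :data:`TIE_TOL`) are broken uniformly at
    random and flagged in the result.
    """
    s_correct = probe_alignment_score(
        pair, state, probes, "correct", metric=metric, dists=dists
    )
    s_swapped = probe_alignment_score(
        pair, state, probes, "swapped", metric=metric, dists=dists
    )
    if abs(s_correct - s_swapped) <= TIE_TOL:
        chosen: Mapping_ = "correct" if rng.random() < 0.5 else "swapped"
        tie = True
    else:
        chosen = "correct" if s_correct > s_swapped else "swapped"
        tie = False
    return ForcedChoiceResult(chosen, s_correct, s_swapped, tie)


def full_alignment_decision(
    pair: SystemPair,
    state: KnowledgeState,
    probes: ProbePair,
    *,
    metric: str = "euclidean",
) -> tuple[Mapping_ | None, float, float]:
    """Forced-choice decision from full alignment scores (reference route).

    Computes the full alignment score over knowledge state plus probes for
    both candidate mappings (the swapped candidate permutes the two probe
    items on the linguistic side) instead of using the probe-column
    shortcut.  Returns ``(decision, score_correct, score_swapped)`` with
    ``decision=None`` on a tie.  Used to check that the shortcut and the
    full computation agree.
    """
    probes.validate(state, pair)
    items = list(state.concepts) + [probes.concept_a, probes.concept_b]
    vis = pair.visual.subset(items)
    lin = pair.linguistic.subset(items)
    d_vis = pairwise_distances(vis, metric)
    d_lin = pairwise_distances(lin, metric)
    n = len(items)
    identity = np.arange(n)
    swapped = identity.copy()
    swapped[[n - 2, n - 1]] = swapped[[n - 1, n - 2]]
    s_correct = alignment_score(d_vis, d_lin, identity)
    s_swapped = alignment_score(d_vis, d_lin, swapped)
    if abs(s_correct - s_swapped) <= TIE_TOL:
        return None, s_correct, s_swapped
    return (
        "correct" if s_correct > s_swapped else "swapped",
        s_correct,
        s_swapped,
    )
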