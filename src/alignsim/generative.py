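"""Generative structural agents: AoA-Matched and Task-Optimized.

Both agents carry an *internal model*: a vector of target values ``x_hat``
(one per structural feature, in normalized [0, 1] feature units) and a
weight vector ``w`` of feature importances.  To pick its next concept an
agent scores every candidate by the weighted distance between the
candidate-augmented state's features and the targets,

    s_i = -sum_k |A_ik - x_hat_k| * w_k,

standardizes the scores within the candidate set, and samples from a
softmax with temperature ``T``.  The agents differ only in the loss that
trains ``(x_hat, w)``:

* *AoA-Matched*: mean squared error between the model's per-concept
  inclusion probabilities at each month's end (1 for acquired concepts,
  the current selection probability otherwise) and bootstrapped
  acquisition-probability tables;
* *Task-Optimized*: the soft alignment loss — the probability-weighted
  margin by which the incorrect probe mapping's alignment score exceeds
  the correct one's, averaged over a slate of probe pairs.

Raw losses are z-normalized per month against a sampled reference
distribution and shifted by the z-score of the theoretical floor (0 for
the MSE, -2 for the margin) so losses are nonnegative.

Gradients are analytic (reverse-mode chain rule in numpy): losses are
differentiable in the selection probabilities, with the feature matrix and
the distance ranks treated as constants at each step.  Parameters are
updated by Adam at each month's end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .aoa import AcquisitionTable, BootstrapSet, MonthSchedule
from .alignment import KnowledgeState
from .features import FeatureConfig, StructuralFeatureExtractor
from .systems import SystemPair

logger = logging.getLogger(__name__)

__all__ = [
    "AgentKind",
    "GenerativeConfig",
    "InternalModel",
    "MonthNormalizer",
    "FeatureSpace",
    "GenerativeWorld",
    "generative_scores",
    "candidate_distribution",
    "selection_distribution",
    "selection_backward",
    "aoa_matched_loss",
    "soft_alignment_loss",
    "weighted_pearson",
    "calibrate_normalizers",
    "train_agent",
    "generate_sequence",
]

AgentKind = Literal["aoa_matched", "task_optimized"]

#: paper-scale vocabulary the default split sizes assume
_REFERENCE_VOCAB = 418


@dataclass(frozen=True)
class GenerativeConfig:
    """Hyperparameters of generative-agent training.

    Defaults are the empirical-scale settings: softmax temperature 5e-2,
    150 epochs, 5 restarts, Adam with learning rate 0.003 (AoA-Matched) or
    0.01 (Task-Optimized), candidate set of 300 concepts, two held-out
    concept sets of 59 with 750 probe pairs sampled from each, and 5000
    reference-loss samples per month for the normalizers.
    ``scaled_for_vocab`` shrinks the split sizes proportionally for smaller
    vocabularies.
    """

    temperature: float = 5e-2
    epochs: int = 150
    restarts: int = 5
    learning_rate: float | None = None  # kind default: 0.003 aoa / 0.01 task
    candidate_set_size: int = 300
    heldout_size: int = 59
    pairs_per_slate: int = 750
    normalizer_samples: int = 5000
    final_epochs_for_selection: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.epochs < 1 or self.restarts < 1:
            raise ValueError("epochs and restarts must be >= 1")

    def lr_for(self, kind: AgentKind) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 0.003 if kind == "aoa_matched" else 0.01

    def scaled_for_vocab(self, n_vocab: int) -> "GenerativeConfig":
        """Shrink candidate/held-out/slate sizes proportionally.

        Sizes scale by ``n_vocab / 418`` (the vocabulary the defaults
        assume), keeping candidate + 2 held-out sets within the vocabulary.
        """
        f = n_vocab / _REFERENCE_VOCAB
        heldout = max(2, int(round(self.heldout_size * f)))
        n_c = max(4, min(int(round(self.candidate_set_size * f)),
                         n_vocab - 2 * heldout))
        pairs = max(20, int(round(self.pairs_per_slate * f)))
        return replace(
            self,
            candidate_set_size=n_c,
            heldout_size=heldout,
            pairs_per_slate=pairs,
        )


@dataclass(frozen=True)
class InternalModel:
    """A generative agent's learned target values and feature weights."""

    feature_names: tuple[str, ...]
    x_hat: np.ndarray
    w: np.ndarray
    kind: str = "aoa_matched"

    def __post_init__(self) -> None:
        x = np.asarray(self.x_hat, dtype=float)
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "x_hat", x)
        object.__setattr__(self, "w", w)
        k = len(self.feature_names)
        if x.shape != (k,) or w.shape != (k,):
            raise ValueError("x_hat and w must have one entry per feature")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(w))):
            raise ValueError("internal model entries must be finite")


@dataclass(frozen=True)
class MonthNormalizer:
    """Per-month z-normalization of a raw loss with a floor shift.

    ``normalize(raw) = z(raw) - z(floor) = (raw - floor) / sigma``, which is
    nonnegative whenever ``raw >= floor`` (floor 0 for the MSE loss, -2 for
    the soft-alignment margin).
    """

    month: int
    mu: float
    sigma: float
    floor: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(
                f"month {self.month}: degenerate loss distribution (sigma=0)"
            )

    def normalize(self, raw: float) -> float:
        return (raw - self.floor) / self.sigma

    @property
    def scale(self) -> float:
        """d(normalized)/d(raw)."""
        return 1.0 / self.sigma


class FeatureSpace:
    """Structural features mapped to a fixed [0, 1] normalization.

    Min-max bounds are fitted once per world from random knowledge states
    at every scheduled state size, so that target values ``x_hat`` live in
    a stable normalized space across months.
    """

    def __init__(
        self,
        extractor: StructuralFeatureExtractor,
        schedule: MonthSchedule,
        rng: np.random.Generator,
        *,
        states_per_size: int = 30,
    ):
        self.extractor = extractor
        self.names = tuple(extractor.feature_names)
        n = len(extractor.concepts)
        samples = []
        for size in sorted(set(schedule.cumulative)):
            size = max(size, 3)
            for _ in range(states_per_size):
                members = rng.choice(n, size=min(size, n), replace=False)
                samples.append(
                    self.extractor.feature_vector(
                        [extractor.concepts[i] for i in members]
                    )
                )
        X = np.vstack(samples)
        self.lo = X.min(axis=0)
        span = X.max(axis=0) - self.lo
        self.span = np.where(span > 0, span, 1.0)

    def normalize(self, A: np.ndarray) -> np.ndarray:
        return (A - self.lo) / self.span

    def candidate_matrix(
        self, state: Sequence[str], candidates: Sequence[str]
    ) -> np.ndarray:
        """Normalized feature matrix of every single-concept augmentation."""
        return self.normalize(
            self.extractor.candidate_features(state, candidates)
        )


@dataclass
class GenerativeWorld:
    """Precomputed world bundle shared by training, calibration, generation."""

    pair: SystemPair
    table: AcquisitionTable
    schedule: MonthSchedule
    feature_space: FeatureSpace
    d_visual: np.ndarray = field(repr=False, default=None)
    d_linguistic: np.ndarray = field(repr=False, default=None)
    #: concepts the agent may never acquire (e.g. a held-out probe reserve)
    excluded: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.d_visual is None or self.d_linguistic is None:
            d_vis, d_lin = self.pair.distance_matrices(
                self.feature_space.extractor.config.metric
            )
            self.d_visual = d_vis.values
            self.d_linguistic = d_lin.values
        self.index = {c: i for i, c in enumerate(self.pair.shared_concepts)}
        self.table_index = self.table.index()

    @classmethod
    def build(
        cls,
        pair: SystemPair,
        table: AcquisitionTable,
        schedule: MonthSchedule,
        rng: np.random.Generator,
        *,
        feature_config: FeatureConfig = FeatureConfig(),
    ) -> "GenerativeWorld":
        extractor = StructuralFeatureExtractor(pair, feature_config)
        return cls(pair, table, schedule, FeatureSpace(extractor, schedule, rng))


# ---------------------------------------------------------------------------
# differentiable selection head
# ---------------------------------------------------------------------------


def generative_scores(
    A: np.ndarray, x_hat: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Generative score per candidate: minus the weighted absolute
    deviation of the augmented state's (normalized) features from the
    targets.  A candidate hitting every target exactly scores 0, the
    maximum under nonnegative weights."""
    return -np.abs(A - x_hat) @ w


def candidate_distribution(scores: np.ndarray, temperature: float) -> np.ndarray:
    """Softmax over standardized scores.

    Scores are standardized (zero mean, unit variance within the candidate
    set) before dividing by the temperature, making the temperature
    meaningful across worlds of different scales; a constant score vector
    yields the uniform distribution.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd < 1e-300 or len(scores) == 1:
        return np.full(len(scores), 1.0 / len(scores))
    z = (scores - scores.mean()) / sd
    e = np.exp(z / temperature - np.max(z / temperature))
    return e / e.sum()


def selection_distribution(
    A: np.ndarray, x_hat: np.ndarray, w: np.ndarray, temperature: float
) -> tuple[np.ndarray, dict]:
    """Forward pass of the selection head; returns probabilities and the
    cache needed by :func:`selection_backward`."""
    D = A - x_hat
    absD = np.abs(D)
    s = -absD @ w
    n = len(s)
    sd = s.std()
    degenerate = sd < 1e-12 or n == 1
    if degenerate:
        q = np.full(n, 1.0 / n)
        z = np.zeros(n)
        sd = 1.0
    else:
        z = (s - s.mean()) / sd
        q = candidate_distribution(s, temperature)
    cache = {
        "signD": np.sign(D),
        "absD": absD,
        "w": w.copy(),
        "z": z,
        "sd": sd,
        "q": q,
        "T": temperature,
        "degenerate": degenerate,
    }
    return q, cache


def selection_backward(
    cache: dict, grad_q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Chain dL/dq back to (dL/dx_hat, dL/dw).

    Backpropagates through the softmax, the score standardization, and the
    weighted-absolute-deviation score.  A degenerate (constant-score)
    forward pass returns zero gradients.
    """
    if cache["degenerate"]:
        k = cache["w"].shape[0]
        return np.zeros(k), np.zeros(k)
    q, z, sd, T = cache["q"], cache["z"], cache["sd"], cache["T"]
    n = len(q)
    # softmax: dL/dz
    h = q * (grad_q - q @ grad_q) / T
    # standardization: dL/ds
    gs = (h - h.mean()) / sd - z * (h @ z) / (n * sd)
    gw = -(cache["absD"].T @ gs)
    gx = (cache["signD"].T @ gs) * cache["w"]
    return gx, gw


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def aoa_matched_loss(
    q: np.ndarray,
    cand_table_pos: np.ndarray,
    acquired_table_pos: np.ndarray,
    boots: np.ndarray,
    normalizer: MonthNormalizer,
) -> tuple[float, float, np.ndarray]:
    """Normalized AoA-matching loss and its gradient in ``q``.

    ``q`` is the selection distribution over unacquired candidates;
    ``cand_table_pos[i]`` is candidate i's row in the acquisition table (-1
    if the candidate is outside the AoA set); ``acquired_table_pos`` lists
    table rows already acquired (inclusion probability 1); ``boots`` is an
    array of bootstrapped inclusion-probability columns for this month,
    shape (B, n_table).  Table concepts outside the candidate set get
    inclusion probability 0.

    Returns ``(normalized_loss, raw_mse, dL/dq)``.
    """
    if boots.ndim != 2:
        raise ValueError("boots must be (B, n_table)")
    n_table = boots.shape[1]
    p = np.zeros(n_table)
    if len(acquired_table_pos):
        p[acquired_table_pos] = 1.0
    in_table = cand_table_pos >= 0
    p[cand_table_pos[in_table]] = q[in_table]
    resid = p[None, :] - boots
    raw = float(np.mean(resid**2))
    # d raw / d p_i = 2/(n_table) * mean_b resid_bi
    gp = 2.0 * resid.mean(axis=0) / n_table
    gq = np.zeros_like(q)
    gq[in_table] = gp[cand_table_pos[in_table]]
    return normalizer.normalize(raw), raw, gq * normalizer.scale


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, wts: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted Pearson correlation and its gradient in the weights.

    All weights must be positive.  Returns ``(r, dr/dwts)``.
    """
    W = wts.sum()
    mx = (wts @ x) / W
    my = (wts @ y) / W
    a = x - mx
    b = y - my
    sxy = wts @ (a * b)
    sxx = wts @ (a * a)
    syy = wts @ (b * b)
    if sxx <= 0 or syy <= 0:
        raise ValueError("constant vector under the weighting: r undefined")
    denom = np.sqrt(sxx * syy)
    r = sxy / denom
    dr = (a * b) / denom - 0.5 * r * (a * a / sxx + b * b / syy)
    return float(r), dr


def soft_alignment_loss(
    q: np.ndarray,
    n_acquired: int,
    probe_cols_vis: np.ndarray,
    probe_cols_lin: np.ndarray,
    normalizer: MonthNormalizer,
) -> tuple[float, float, np.ndarray]:
    """Normalized soft alignment loss and its gradient in ``q``.

    The candidate set is ordered acquired-first: the weight vector is
    ``p = [1]*n_acquired + q``.  ``probe_cols_vis``/``probe_cols_lin`` have
    shape (n_pairs, 2, n_cand): distances from each probe pair's two items
    to every candidate-set concept, per modality.  For each pair the
    concatenated probe columns are rank-transformed and correlated with a
    weighted Pearson correlation under weights ``[p, p]``; the swapped
    (incorrect) candidate mapping exchanges the two linguistic halves.  The
    raw loss is the mean margin ``s_incorrect - s_correct``; it is bounded
    below by -2 and z-shifted by that floor.

    Returns ``(normalized_loss, raw_margin, dL/dq)``.
    """
    n_pairs, two, n_cand = probe_cols_vis.shape
    if two != 2 or probe_cols_lin.shape != probe_cols_vis.shape:
        raise ValueError("probe column arrays must be (n_pairs, 2, n_cand)")
    if n_pairs == 0:
        raise ValueError("empty probe slate")
    p = np.concatenate([np.ones(n_acquired), q])
    if len(p) != n_cand:
        raise ValueError("q length + n_acquired must equal n_cand")
    wts = np.concatenate([p, p])
    raw = 0.0
    gwts = np.zeros(2 * n_cand)
    for i in range(n_pairs):
        rx = rankdata(np.concatenate(probe_cols_vis[i]))
        ry = rankdata(np.concatenate(probe_cols_lin[i]))
        ry_swapped = np.concatenate([ry[n_cand:], ry[:n_cand]])
        s_corr, d_corr = weighted_pearson(rx, ry, wts)
        s_inc, d_inc = weighted_pearson(rx, ry_swapped, wts)
        raw += s_inc - s_corr
        gwts += d_inc - d_corr
    raw /= n_pairs
    gwts /= n_pairs
    # fold the two probe halves and keep only unacquired entries
    gp = gwts[:n_cand] + gwts[n_cand:]
    gq = gp[n_acquired:] * normalizer.scale
    return normalizer.normalize(raw), raw, gq


# ---------------------------------------------------------------------------
# normalizer calibration
# ---------------------------------------------------------------------------


def _probe_columns_for(
    world: GenerativeWorld, pairs: np.ndarray, cand_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance columns from probe pairs to candidate-set concepts."""
    vis = world.d_visual[pairs][:, :, cand_idx]
    lin = world.d_linguistic[pairs][:, :, cand_idx]
    return vis, lin


def calibrate_normalizers(
    kind: AgentKind,
    world: GenerativeWorld,
    rng: np.random.Generator,
    *,
    boot: BootstrapSet | None = None,
    n_samples: int = 5000,
    candidate_set_size: int | None = None,
) -> dict[int, MonthNormalizer]:
    """Sample the per-month reference loss distribution (mu, sigma).

    For the AoA-Matched kind, each sample selects the month's cumulative
    concept count uniformly at random from the AoA set, assigns those
    concepts probability 1 and the remaining AoA concepts a uniform
    selection probability, and records the MSE against the bootstrapped
    tables.  For the Task-Optimized kind, each sample draws a
    pseudo-partition of candidate-set size, a knowledge state within it,
    uniform probabilities over the rest, and records the margin
    ``s_incorrect - s_correct`` for one random outside probe pair.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 calibration samples")
    months = world.schedule.months
    cumulative = world.schedule.cumulative
    normalizers: dict[int, MonthNormalizer] = {}

    if kind == "aoa_matched":
        if boot is None:
            raise ValueError("aoa_matched calibration needs a BootstrapSet")
        n_table = world.table.n_concepts
        boot_train = boot.train
        for j, (month, N_m) in enumerate(zip(months, cumulative)):
            boots_m = boot_train[:, :, j]
            raws = np.empty(n_samples)
            for s in range(n_samples):
                chosen = rng.choice(n_table, size=min(N_m, n_table),
                                    replace=False)
                p = np.zeros(n_table)
                p[chosen] = 1.0
                rest = n_table - len(chosen)
                if rest:
                    p[p == 0] = 1.0 / rest
                raws[s] = np.mean((p[None, :] - boots_m) ** 2)
            mu, sigma = float(raws.mean()), float(raws.std())
            normalizers[month] = MonthNormalizer(month, mu, sigma, floor=0.0)
        return normalizers

    if kind != "task_optimized":
        raise ValueError(f"unknown agent kind {kind!r}")
    n_vocab = world.pair.n_concepts
    n_c = candidate_set_size or min(300, n_vocab - 2)
    dummy = MonthNormalizer(0, 0.0, 1.0, floor=-2.0)
    for j, (month, N_m) in enumerate(zip(months, cumulative)):
        raws = np.empty(n_samples)
        for s in range(n_samples):
            perm = rng.permutation(n_vocab)
            partition = perm[:n_c]
            outside = perm[n_c:]
            if len(outside) < 2:
                raise ValueError("vocabulary too small for candidate set")
            state_size = min(N_m, n_c - 1)
            p = np.full(n_c, 1.0 / (n_c - state_size))
            p[:state_size] = 1.0  # partition order is already random
            a, b = outside[:2]
            pairs = np.array([[a, b]])
            vis, lin = _probe_columns_for(world, pairs, partition)
            _, raw, _ = soft_alignment_loss(
                p[state_size:], state_size, vis, lin, dummy
            )
            raws[s] = raw
        mu, sigma = float(raws.mean()), float(raws.std())
        normalizers[month] = MonthNormalizer(month, mu, sigma, floor=-2.0)
    return normalizers


# ---------------------------------------------------------------------------
# training and generation
# ---------------------------------------------------------------------------


class _Adam:
    """Adam optimizer over a flat parameter vector."""

    def __init__(self, lr: float, n: int, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        m_hat = self.m / (1 - self.b1**self.t)
        v_hat = self.v / (1 - self.b2**self.t)
        return theta - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _seed_state(
    vocab: Sequence[str],
    rng: np.random.Generator,
    excluded: frozenset = frozenset(),
) -> list[str]:
    """Two uniformly chosen concepts to seed a generative trajectory.

    Structural state features need at least three members, so the first
    two concepts of the first month's quota are drawn uniformly; the model
    drives every selection after that.
    """
    eligible = [c for c in vocab if c not in excluded]
    i, j = rng.choice(len(eligible), size=2, replace=False)
    return [eligible[i], eligible[j]]


def _segment_month(
    world: GenerativeWorld,
    acquired: list[str],
    config: GenerativeConfig,
    rng: np.random.Generator,
    *,
    with_heldout: bool,
) -> tuple[list[str], np.ndarray | None, np.ndarray | None]:
    """Candidate-set refill and (for the task agent) held-out concept sets.

    The candidate set keeps every acquired concept and refills to the
    configured size uniformly from the unacquired remainder; held-out train
    and validation sets are disjoint from it.
    """
    vocab = world.pair.shared_concepts
    acquired_set = set(acquired) | set(world.excluded)
    remaining = [c for c in vocab if c not in acquired_set]
    n_fill = min(config.candidate_set_size - len(acquired), len(remaining))
    if n_fill < 1:
        raise ValueError("candidate pool exhausted")
    perm = rng.permutation(len(remaining))
    cand_unacq = [remaining[i] for i in perm[:n_fill]]
    if not with_heldout:
        return cand_unacq, None, None
    leftover = perm[n_fill:]
    need = 2 * config.heldout_size
    if len(leftover) < need:
        raise ValueError(
            f"{len(leftover)} concepts left for held-out sets; need {need}"
        )
    train_ids = np.array(
        [world.index[remaining[i]] for i in leftover[: config.heldout_size]]
    )
    val_ids = np.array(
        [world.index[remaining[i]]
         for i in leftover[config.heldout_size: need]]
    )
    return cand_unacq, train_ids, val_ids


def _sample_slate(
    concept_ids: np.ndarray, n_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_pairs`` random (distinct-member) probe pairs from a concept set."""
    out = np.empty((n_pairs, 2), dtype=int)
    for i in range(n_pairs):
        a, b = rng.choice(len(concept_ids), size=2, replace=False)
        out[i] = concept_ids[a], concept_ids[b]
    return out


def _run_sequence(
    model_params: tuple[np.ndarray, np.ndarray],
    world: GenerativeWorld,
    config: GenerativeConfig,
    rng: np.random.Generator,
    *,
    kind: AgentKind | None = None,
    boot: BootstrapSet | None = None,
    normalizers: dict[int, MonthNormalizer] | None = None,
    optimizer: _Adam | None = None,
    greedy: bool = False,
):
    """One pass over the monthly schedule: select concepts, and (when an
    optimizer is supplied) backpropagate the month-end loss and update.

    Returns (acquired per month, train losses per month, val losses per
    month, updated params).
    """
    x_hat, w = model_params
    fs = world.feature_space
    vocab = world.pair.shared_concepts
    training = optimizer is not None
    with_heldout = training and kind == "task_optimized"

    acquired = _seed_state(vocab, rng, world.excluded)
    states: list[list[str]] = []
    train_losses: list[float] = []
    val_losses: list[float] = []
    seeded = len(acquired)

    for j, (month, n_m) in enumerate(
        zip(world.schedule.months, world.schedule.n_per_month)
    ):
        cand_unacq, train_ids, val_ids = _segment_month(
            world, acquired, config, rng, with_heldout=with_heldout
        )
        quota = n_m - seeded if j == 0 else n_m
        seeded = 0
        for _ in range(max(quota, 0)):
            if not cand_unacq:
                raise ValueError(f"candidate pool exhausted in month {month}")
            A = fs.candidate_matrix(acquired, cand_unacq)
            q, _ = selection_distribution(A, x_hat, w, config.temperature)
            pick = int(np.argmax(q)) if greedy else int(rng.choice(len(q), p=q))
            acquired.append(cand_unacq.pop(pick))
        states.append(list(acquired))

        if not training:
            continue
        if not cand_unacq:
            raise ValueError(f"no unacquired candidates at end of month {month}")
        A = fs.candidate_matrix(acquired, cand_unacq)
        q, cache = selection_distribution(A, x_hat, w, config.temperature)
        norm = normalizers[month]
        if kind == "aoa_matched":
            cand_pos = np.array(
                [world.table_index.get(c, -1) for c in cand_unacq]
            )
            acq_pos = np.array(
                [world.table_index[c] for c in acquired
                 if c in world.table_index],
                dtype=int,
            )
            loss, _, gq = aoa_matched_loss(
                q, cand_pos, acq_pos, boot.train[:, :, j], norm
            )
            val_loss, _, _ = aoa_matched_loss(
                q, cand_pos, acq_pos, boot.validation[:, :, j], norm
            )
        else:
            cand_ids = np.array(
                [world.index[c] for c in acquired + cand_unacq]
            )
            slate = _sample_slate(train_ids, config.pairs_per_slate, rng)
            vis, lin = _probe_columns_for(world, slate, cand_ids)
            loss, _, gq = soft_alignment_loss(
                q, len(acquired), vis, lin, norm
            )
            val_slate = _sample_slate(val_ids, config.pairs_per_slate, rng)
            vis_v, lin_v = _probe_columns_for(world, val_slate, cand_ids)
            val_loss, _, _ = soft_alignment_loss(
                q, len(acquired), vis_v, lin_v, norm
            )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at month {month}")
        gx, gw = selection_backward(cache, gq)
        theta = optimizer.step(
            np.concatenate([x_hat, w]), np.concatenate([gx, gw])
        )
        k = len(x_hat)
        x_hat, w = theta[:k], theta[k:]
        train_losses.append(float(loss))
        val_losses.append(float(val_loss))

    return states, train_losses, val_losses, (x_hat, w)


def train_agent(
    kind: AgentKind,
    config: GenerativeConfig,
    world: GenerativeWorld,
    *,
    boot: BootstrapSet | None = None,
    normalizers: dict[int, MonthNormalizer] | None = None,
) -> tuple[InternalModel, pd.DataFrame]:
    """Train a generative structural agent.

    Runs ``config.restarts`` restarts of the epoch loop (each epoch
    simulates the monthly schedule by sampling from the current selection
    distribution, backpropagating the kind's loss at each month's end) and
    returns the restart with the lowest validation loss averaged over the
    final epochs, together with the full training history.

    ``normalizers`` may carry pre-calibrated month normalizers; otherwise
    they are calibrated here (seeded from ``config.seed``).
    """
    if kind not in ("aoa_matched", "task_optimized"):
        raise ValueError(f"unknown agent kind {kind!r}")
    if kind == "aoa_matched" and boot is None:
        raise ValueError("aoa_matched training needs bootstrap distributions")
    master = np.random.SeedSequence([config.seed, 7])
    if normalizers is None:
        normalizers = calibrate_normalizers(
            kind,
            world,
            np.random.default_rng(master.spawn(1)[0]),
            boot=boot if kind == "aoa_matched" else None,
            n_samples=config.normalizer_samples,
            candidate_set_size=config.candidate_set_size,
        )

    k = len(world.feature_space.names)
    history = []
    best: tuple[float, InternalModel] | None = None
    for r in range(config.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        x_hat = rng.uniform(0.0, 1.0, k)
        w = rng.uniform(0.01, 0.1, k)
        optimizer = _Adam(config.lr_for(kind), 2 * k)
        val_by_epoch = []
        try:
            for epoch in range(config.epochs):
                _, tr, va, (x_hat, w) = _run_sequence(
                    (x_hat, w),
                    world,
                    config,
                    rng,
                    kind=kind,
                    boot=boot,
                    normalizers=normalizers,
                    optimizer=optimizer,
                )
                val_by_epoch.append(float(np.sum(va)))
                history.append(
                    {
                        "restart": r,
                        "epoch": epoch,
                        "train_loss": float(np.sum(tr)),
                        "val_loss": float(np.sum(va)),
                    }
                )
        except FloatingPointError as exc:  # pragma: no cover - rare
            logger.warning("restart %d aborted: %s", r, exc)
            continue
        tail = val_by_epoch[-config.final_epochs_for_selection:]
        score = float(np.mean(tail))
        model = InternalModel(world.feature_space.names, x_hat, w, kind)
        if best is None or score < best[0]:
            best = (score, model)
        logger.info("restart %d: final val loss %.4f", r, score)
    if best is None:
        raise RuntimeError("all training restarts failed")
    return best[1], pd.DataFrame(history)


def generate_sequence(
    model: InternalModel,
    world: GenerativeWorld,
    config: GenerativeConfig,
    rng: np.random.Generator,
    *,
    greedy: bool = False,
) -> list[KnowledgeState]:
    """Generate a concept-acquisition trajectory from a frozen model.

    Concepts are sampled one at a time from the selection distribution
    under the trained targets and weights until each month's quota is met.
    ``greedy=True`` takes the argmax instead (the zero-temperature limit).
    """
    states, _, _, _ = _run_sequence(
        (model.x_hat, model.w), world, config, rng, greedy=greedy
    )
    return [
        KnowledgeState(tuple(members), month=month)
        for month, members in zip(world.schedule.months, states)
    ]
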