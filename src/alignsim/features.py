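"""Structural features of concepts and knowledge states, and the
AoA-vs-Control knowledge-state classifier.

Two feature families characterize a knowledge state:

* *global similarity* features, from raw interconcept distances (mean and
  minimum distance of each member to the full system or to the other
  members of the state);
* *neighborhood graph* features, from the graph that keeps only the concept
  pairs whose distance lies below the 10th percentile of all interconcept
  distances (mean node degree with respect to the full system or within the
  state, and the skew of the within-state degree distribution).

A whole-state feature, mean dimension coverage, measures the share of each
embedding dimension's full-system range that the state spans.

Features are computed per modality and averaged by default.  The
classifier (L2 logistic regression with recursive feature elimination,
AIC-selected feature count) predicts whether a state was sampled under the
AoA or the Control condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import train_test_split

from .alignment import KnowledgeState
from .systems import DistanceMatrix, SystemPair, pairwise_distances

__all__ = [
    "DEFAULT_FEATURES",
    "NeighborGraph",
    "FeatureConfig",
    "StructuralFeatureExtractor",
    "ClassifierReport",
    "build_neighbor_graph",
    "concept_features",
    "state_features",
    "classify_states",
]

#: the seven features retained by recursive elimination in the
#: AoA-vs-Control characterization (state-level aggregates)
DEFAULT_FEATURES = (
    "degree_knowledge",
    "degree_full",
    "mean_dist_knowledge",
    "mean_dim_coverage",
    "min_dist_knowledge",
    "min_dist_full",
    "skew_degree_knowledge",
)

Modality = Literal["visual", "linguistic", "mean"]


@dataclass(frozen=True)
class NeighborGraph:
    """Concept graph keeping only sub-threshold (short-range) distances."""

    graph: nx.Graph
    threshold: float
    percentile: float

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, concept: str) -> int:
        return int(self.graph.degree[concept])


def build_neighbor_graph(
    dist: DistanceMatrix, percentile: float = 10.0
) -> NeighborGraph:
    """Graph of concept pairs with distance strictly below the percentile
    threshold of the upper-triangle distance distribution.

    The threshold is the linear-interpolation percentile; edges require
    strict inequality, so ties at the threshold are excluded.  The graph may
    be disconnected.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if dist.n_concepts < 2:
        raise ValueError("need at least 2 concepts")
    upper = dist.upper_triangle()
    threshold = float(np.percentile(upper, percentile))
    g = nx.Graph()
    g.add_nodes_from(dist.concepts)
    ii, jj = np.where(np.triu(dist.values < threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(dist.concepts[i], dist.concepts[j])
    if g.number_of_edges() == 0 and np.ptp(upper) == 0:
        warnings.warn("all interconcept distances equal: zero-edge graph",
                      stacklevel=2)
    return NeighborGraph(g, threshold, percentile)


def _skew(values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness; 0 for constant input."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.ptp(values) == 0:
        return 0.0
    return float(stats.skew(values, bias=False))


@dataclass(frozen=True)
class FeatureConfig:
    """How structural features are computed.

    ``modality="mean"`` averages each feature over the visual and
    linguistic systems; ``percentile`` sets the neighbor-graph threshold;
    ``include_expensive`` adds clustering-coefficient and betweenness
    features (excluded from classifier selection by default because of
    their cost).
    """

    metric: str = "euclidean"
    percentile: float = 10.0
    modality: Modality = "mean"
    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    include_expensive: bool = False

    def all_names(self) -> tuple[str, ...]:
        names = tuple(self.feature_names)
        if self.include_expensive:
            names = names + ("clustering_knowledge", "betweenness_knowledge")
        return names


class _ModalityCache:
    """Precomputed distance/adjacency structures for one modality."""

    def __init__(self, dist: DistanceMatrix, coords: np.ndarray, percentile: float):
        self.dist = dist.values
        n = dist.n_concepts
        upper = dist.upper_triangle()
        self.threshold = float(np.percentile(upper, percentile))
        self.adj = (self.dist < self.threshold) & ~np.eye(n, dtype=bool)
        self.degree_full = self.adj.sum(axis=1).astype(float)
        offdiag = self.dist + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
        self.min_dist_full = offdiag.min(axis=1)
        self.mean_dist_full = self.dist.sum(axis=1) / max(n - 1, 1)
        self.coords = coords
        self.full_lo = coords.min(axis=0)
        self.full_hi = coords.max(axis=0)
        span = self.full_hi - self.full_lo
        self.valid_dims = span > 0
        if not np.all(self.valid_dims):
            warnings.warn(
                f"skipping {int(np.sum(~self.valid_dims))} zero-range "
                "embedding dimension(s) in coverage",
                stacklevel=4,
            )
        self.span = np.where(self.valid_dims, span, 1.0)


class StructuralFeatureExtractor:
    """Computes state-level structural features for a system pair.

    Precomputes per-modality distance matrices, neighbor-graph adjacency,
    and full-system per-concept statistics, then answers two queries:
    features of a given state (:meth:`state_features`), and the feature
    matrix of all single-concept augmentations of a state
    (:meth:`candidate_features`, vectorized — the generative agents call it
    once per selection step).
    """

    def __init__(self, pair: SystemPair, config: FeatureConfig = FeatureConfig()):
        self.pair = pair
        self.config = config
        self.concepts = pair.shared_concepts
        self._index = {c: i for i, c in enumerate(self.concepts)}
        d_vis = pairwise_distances(pair.visual, config.metric)
        d_lin = pairwise_distances(pair.linguistic, config.metric)
        caches = {
            "visual": _ModalityCache(d_vis, pair.visual.vectors, config.percentile),
            "linguistic": _ModalityCache(d_lin, pair.linguistic.vectors, config.percentile),
        }
        if config.modality == "mean":
            self._caches = [caches["visual"], caches["linguistic"]]
        else:
            self._caches = [caches[config.modality]]
        self.feature_names = config.all_names()

    def indices(self, concepts: Sequence[str]) -> np.ndarray:
        return np.array([self._index[c] for c in concepts], dtype=int)

    # -- single-state features ------------------------------------------

    def _state_features_one(self, cache: _ModalityCache, members: np.ndarray) -> dict:
        t = len(members)
        if t < 3:
            raise ValueError("state features require at least 3 concepts")
        sub_adj = cache.adj[np.ix_(members, members)]
        degrees_within = sub_adj.sum(axis=1).astype(float)
        d_sub = cache.dist[np.ix_(members, members)]
        offdiag = d_sub + np.where(np.eye(t, dtype=bool), np.inf, 0.0)
        lo = cache.coords[members].min(axis=0)
        hi = cache.coords[members].max(axis=0)
        coverage = ((hi - lo) / cache.span)[cache.valid_dims]
        out = {
            "degree_full": float(cache.degree_full[members].mean()),
            "degree_knowledge": float(degrees_within.mean()),
            "mean_dist_knowledge": float(d_sub.sum() / (t * (t - 1))),
            "min_dist_knowledge": float(offdiag.min(axis=1).mean()),
            "min_dist_full": float(cache.min_dist_full[members].mean()),
            "mean_dist_full": float(cache.mean_dist_full[members].mean()),
            "mean_dim_coverage": float(coverage.mean()),
            "skew_degree_knowledge": _skew(degrees_within),
        }
        if self.config.include_expensive:
            g = nx.from_numpy_array(sub_adj)
            out["clustering_knowledge"] = float(
                np.mean(list(nx.clustering(g).values()))
            )
            out["betweenness_knowledge"] = float(
                np.mean(list(nx.betweenness_centrality(g).values()))
            )
        return out

    def state_features(self, state: KnowledgeState | Sequence[str]) -> dict[str, float]:
        """Named feature values for one knowledge state (modality-averaged)."""
        concepts = state.concepts if isinstance(state, KnowledgeState) else state
        members = self.indices(concepts)
        per_modality = [self._state_features_one(c, members) for c in self._caches]
        return {
            name: float(np.mean([m[name] for m in per_modality]))
            for name in self.feature_names
        }

    def feature_vector(self, state: KnowledgeState | Sequence[str]) -> np.ndarray:
        feats = self.state_features(state)
        return np.array([feats[n] for n in self.feature_names])

    # -- vectorized candidate augmentation ------------------------------

    def _candidate_features_one(
        self, cache: _ModalityCache, members: np.ndarray, cands: np.ndarray
    ) -> dict[str, np.ndarray]:
        t = len(members)
        nc = len(cands)
        if t < 2:
            raise ValueError("candidate features require a state of >= 2 concepts")
        d_cs = cache.dist[np.ix_(cands, members)]             # (nc, t)
        adj_cs = cache.adj[np.ix_(cands, members)]            # (nc, t)
        neigh_in_state = adj_cs.sum(axis=1).astype(float)     # candidate's within-state degree

        deg_full_sum = cache.degree_full[members].sum()
        degree_full = (deg_full_sum + cache.degree_full[cands]) / (t + 1)

        # within-state degrees after augmentation: members gain an edge to
        # adjacent candidates; the candidate's own degree is its neighbor count
        base_deg = cache.adj[np.ix_(members, members)].sum(axis=1).astype(float)
        deg_matrix = np.concatenate(
            [base_deg[None, :] + adj_cs, neigh_in_state[:, None]], axis=1
        )                                                     # (nc, t+1)
        degree_knowledge = deg_matrix.mean(axis=1)

        pair_sum = cache.dist[np.ix_(members, members)].sum()  # ordered pairs
        mean_dist_knowledge = (pair_sum + 2.0 * d_cs.sum(axis=1)) / ((t + 1) * t)

        d_mm = cache.dist[np.ix_(members, members)] + np.where(
            np.eye(t, dtype=bool), np.inf, 0.0
        )
        base_min = d_mm.min(axis=1)                           # (t,)
        member_mins = np.minimum(base_min[None, :], d_cs)     # (nc, t)
        min_dist_knowledge = (
            member_mins.sum(axis=1) + d_cs.min(axis=1)
        ) / (t + 1)

        min_dist_full = (
            cache.min_dist_full[members].sum() + cache.min_dist_full[cands]
        ) / (t + 1)
        mean_dist_full = (
            cache.mean_dist_full[members].sum() + cache.mean_dist_full[cands]
        ) / (t + 1)

        lo = cache.coords[members].min(axis=0)
        hi = cache.coords[members].max(axis=0)
        new_lo = np.minimum(lo[None, :], cache.coords[cands])
        new_hi = np.maximum(hi[None, :], cache.coords[cands])
        cov = ((new_hi - new_lo) / cache.span[None, :])[:, cache.valid_dims]
        mean_dim_coverage = cov.mean(axis=1)

        skew = np.array([_skew(row) for row in deg_matrix])

        return {
            "degree_full": degree_full,
            "degree_knowledge": degree_knowledge,
            "mean_dist_knowledge": mean_dist_knowledge,
            "min_dist_knowledge": min_dist_knowledge,
            "min_dist_full": min_dist_full,
            "mean_dist_full": mean_dist_full,
            "mean_dim_coverage": mean_dim_coverage,
            "skew_degree_knowledge": skew,
        }

    def candidate_features(
        self, state: Sequence[str], candidates: Sequence[str]
    ) -> np.ndarray:
        """Feature matrix A of shape ``(n_candidates, k)``.

        Row ``i`` holds the state-level features of the knowledge state that
        results from adding candidate ``i`` to ``state`` (computed
        incrementally, equivalent to calling :meth:`state_features` on each
        augmented state).
        """
        members = self.indices(
            state.concepts if isinstance(state, KnowledgeState) else state
        )
        cands = self.indices(candidates)
        per_modality = [
            self._candidate_features_one(c, members, cands) for c in self._caches
        ]
        cols = []
        for name in self.feature_names:
            if name in ("clustering_knowledge", "betweenness_knowledge"):
                # expensive graph features are not part of the incremental path
                raise ValueError(
                    f"{name} is not available for candidate augmentation"
                )
            cols.append(np.mean([m[name] for m in per_modality], axis=0))
        return np.column_stack(cols)


def concept_features(
    concept: str,
    state: KnowledgeState,
    pair: SystemPair,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Per-concept structural features (modality-averaged).

    Degree and distance features with respect to the full system and to the
    members of ``state`` (excluding the concept itself).  Raises if a
    "knowledge" feature has an empty reference set.
    """
    extractor = StructuralFeatureExtractor(pair, config)
    i = extractor.indices([concept])[0]
    others = [c for c in state.concepts if c != concept]
    if not others:
        raise ValueError(
            f"empty knowledge reference set for concept {concept!r}"
        )
    members = extractor.indices(others)
    out: dict[str, list[float]] = {}
    for cache in extractor._caches:
        d_row = cache.dist[i, members]
        vals = {
            "degree_full": cache.degree_full[i],
            "degree_knowledge": float(cache.adj[i, members].sum()),
            "mean_dist_full": cache.mean_dist_full[i],
            "min_dist_full": cache.min_dist_full[i],
            "mean_dist_knowledge": float(d_row.mean()),
            "min_dist_knowledge": float(d_row.min()),
        }
        for k, v in vals.items():
            out.setdefault(k, []).append(float(v))
    return {k: float(np.mean(v)) for k, v in out.items()}


def state_features(
    state: KnowledgeState | Sequence[str],
    pair: SystemPair,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Named structural features of one knowledge state.

    Convenience wrapper; build a :class:`StructuralFeatureExtractor` once
    when evaluating many states of the same pair.
    """
    return StructuralFeatureExtractor(pair, config).state_features(state)


# -- classification ------------------------------------------------------


@dataclass(frozen=True)
class ClassifierReport:
    """Recursive-feature-elimination logistic regression summary."""

    selected_features: tuple[str, ...]
    betas: dict[str, float]
    intercept: float
    k: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    aic_by_k: dict[int, float] = field(repr=False, default_factory=dict)
    converged: bool = True


def _aic(model: LogisticRegression, X: np.ndarray, y: np.ndarray, k: int) -> float:
    """Akaike information criterion from the training log-likelihood."""
    p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return 2 * (k + 1) - 2 * loglik


def classify_states(
    samples: Sequence[tuple[dict[str, float], str]],
    *,
    feature_names: Sequence[str] | None = None,
    test_size: float = 0.2,
    max_iter: int = 10_000,
    seed: int = 0,
) -> ClassifierReport:
    """Train the AoA-vs-Control knowledge-state classifier.

    ``samples`` are ``(feature dict, label)`` pairs with labels ``"aoa"``
    (positive class) or ``"control"``.  Uses an 80/20 train/test split,
    min-max normalization of features to [0, 1] fitted on the training
    split only, L2-penalized logistic regression (liblinear), and recursive
    feature elimination over every feature count k, keeping the k that
    minimizes the AIC on the training split.  Held-out metrics are reported
    for the selected model.
    """
    if feature_names is None:
        feature_names = list(samples[0][0].keys())
    labels = {lab for _, lab in samples}
    if labels != {"aoa", "control"}:
        raise ValueError(f"need both 'aoa' and 'control' labels, got {labels}")
    X = np.array([[f[n] for n in feature_names] for f, _ in samples])
    y = np.array([1 if lab == "aoa" else 0 for _, lab in samples])
    if min(np.sum(y == 1), np.sum(y == 0)) < 10:
        raise ValueError("need at least 10 samples per class")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    lo, hi = X_tr.min(axis=0), X_tr.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    X_tr = (X_tr - lo) / span
    X_te = (X_te - lo) / span

    def fit(Xs: np.ndarray) -> LogisticRegression:
        return LogisticRegression(
            solver="liblinear", max_iter=max_iter
        ).fit(Xs, y_tr)

    aic_by_k: dict[int, float] = {}
    masks: dict[int, np.ndarray] = {}
    K = len(feature_names)
    for k in range(1, K + 1):
        if k == K:
            mask = np.ones(K, dtype=bool)
        else:
            rfe = RFE(
                LogisticRegression(
                    solver="liblinear", max_iter=max_iter
                ),
                n_features_to_select=k,
            ).fit(X_tr, y_tr)
            mask = rfe.support_
        model = fit(X_tr[:, mask])
        aic_by_k[k] = _aic(model, X_tr[:, mask], y_tr, k)
        masks[k] = mask

    best_k = min(aic_by_k, key=aic_by_k.get)
    mask = masks[best_k]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = fit(X_tr[:, mask])
        converged = not any("onverge" in str(w.message) for w in caught)

    selected = tuple(n for n, m in zip(feature_names, mask) if m)
    y_pred = model.predict(X_te[:, mask])
    return ClassifierReport(
        selected_features=selected,
        betas={n: float(b) for n, b in zip(selected, model.coef_[0])},
        intercept=float(model.intercept_[0]),
        k=best_k,
        accuracy=float(accuracy_score(y_te, y_pred)),
        precision=float(precision_score(y_te, y_pred, zero_division=0)),
        recall=float(recall_score(y_te, y_pred, zero_division=0)),
        f1=float(f1_score(y_te, y_pred, zero_division=0)),
        aic_by_k=aic_by_k,
        converged=converged,
    )
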