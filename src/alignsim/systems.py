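"""Embedding systems: loading, vocabulary intersection, interconcept distances.

A *system* is the set of similarity relations among items in one
representational space — here a visual or a linguistic embedding.  Systems
are read from whitespace-delimited text (GloVe ``.txt`` dialect: one token
followed by D floats per line).  Alignment analyses operate on the pairwise
interconcept distance matrices of two systems restricted to their shared
vocabulary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSystem",
    "DistanceMatrix",
    "SystemPair",
    "load_embeddings",
    "save_embeddings",
    "intersect_systems",
    "pairwise_distances",
]


class EmbeddingFormatError(ValueError):
    """Raised for malformed embedding text files."""


@dataclass(frozen=True)
class EmbeddingSystem:
    """A named set of concepts with one coordinate vector each.

    Parameters
    ----------
    modality:
        Label for the representational space, e.g. ``"visual"`` or
        ``"linguistic"``.
    concepts:
        Ordered, unique, nonempty concept labels.
    vectors:
        Array of shape ``(n_concepts, dim)``; unitless embedding coordinates.
    """

    modality: str
    concepts: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "concepts", tuple(self.concepts))
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array (n_concepts, dim)")
        if len(self.concepts) != vectors.shape[0]:
            raise ValueError(
                f"{len(self.concepts)} concepts but {vectors.shape[0]} vectors"
            )
        if len(self.concepts) == 0:
            raise ValueError("empty system: at least one concept required")
        if any(not c for c in self.concepts):
            raise ValueError("concept labels must be nonempty")
        if len(set(self.concepts)) != len(self.concepts):
            dupes = {c for c in self.concepts if self.concepts.count(c) > 1}
            raise ValueError(f"duplicate concept labels: {sorted(dupes)}")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("all embedding coordinates must be finite")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    def index(self) -> dict[str, int]:
        """Concept label -> row index."""
        return {c: i for i, c in enumerate(self.concepts)}

    def subset(self, concepts: Sequence[str]) -> "EmbeddingSystem":
        """Restrict to ``concepts`` in the given order."""
        idx = self.index()
        try:
            rows = [idx[c] for c in concepts]
        except KeyError as exc:
            raise KeyError(f"concept not in system: {exc.args[0]!r}") from None
        return EmbeddingSystem(self.modality, tuple(concepts), self.vectors[rows])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative interconcept distance matrix with zero diagonal."""

    concepts: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "concepts", tuple(self.concepts))
        n = len(self.concepts)
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(values)):
            raise ValueError("distances must be finite")
        if np.any(values < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    def upper_triangle(self) -> np.ndarray:
        """The n(n-1)/2 above-diagonal entries, row-major order."""
        iu = np.triu_indices(self.n_concepts, k=1)
        return self.values[iu]

    def subset(self, concepts: Sequence[str]) -> "DistanceMatrix":
        idx = {c: i for i, c in enumerate(self.concepts)}
        rows = np.array([idx[c] for c in concepts], dtype=int)
        return DistanceMatrix(
            tuple(concepts), self.values[np.ix_(rows, rows)], self.metric
        )


@dataclass(frozen=True)
class SystemPair:
    """A visual and a linguistic system restricted to their shared vocabulary.

    Both member systems are stored already restricted to ``shared_concepts``
    and index-aligned: row ``i`` of each system is the same concept, i.e. the
    ground-truth cross-modal mapping is the identity permutation.
    """

    visual: EmbeddingSystem
    linguistic: EmbeddingSystem
    shared_concepts: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        shared = self.shared_concepts or self.visual.concepts
        object.__setattr__(self, "shared_concepts", tuple(shared))
        if len(self.shared_concepts) == 0:
            raise ValueError("shared vocabulary is empty")
        if (
            self.visual.concepts != self.shared_concepts
            or self.linguistic.concepts != self.shared_concepts
        ):
            raise ValueError(
                "member systems must be restricted to shared_concepts "
                "in matching order (use intersect_systems)"
            )

    @property
    def n_concepts(self) -> int:
        return len(self.shared_concepts)

    def distance_matrices(
        self, metric: str = "euclidean"
    ) -> tuple[DistanceMatrix, DistanceMatrix]:
        """Pairwise distances within each modality, same concept order."""
        return (
            pairwise_distances(self.visual, metric),
            pairwise_distances(self.linguistic, metric),
        )


def load_embeddings(
    path: str | Path,
    modality: str,
    *,
    lowercase: bool = True,
) -> EmbeddingSystem:
    """Read an embedding system from GloVe-dialect text.

    Each line is a token followed by D decimal floats, whitespace-delimited,
    UTF-8.  The file order of tokens is preserved.  ``lowercase`` folds
    tokens to lower case before uniqueness checking (GloVe-6B and MB-CDI
    vocabularies are lowercase).
    """
    path = Path(path)
    concepts: list[str] = []
    rows: list[np.ndarray] = []
    dim: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: expected token + >=1 coordinates"
                )
            token = fields[0].lower() if lowercase else fields[0]
            if dim is None:
                dim = len(fields) - 1
            elif len(fields) - 1 != dim:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: {len(fields) - 1} coordinates, expected {dim}"
                )
            try:
                vec = np.array([float(x) for x in fields[1:]], dtype=float)
            except ValueError:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: non-numeric coordinate"
                ) from None
            if token in set(concepts):
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: duplicate token {token!r}"
                )
            concepts.append(token)
            rows.append(vec)
    if not concepts:
        raise EmbeddingFormatError(f"{path}: empty embedding file")
    return EmbeddingSystem(modality, tuple(concepts), np.vstack(rows))


def save_embeddings(
    system: EmbeddingSystem, path: str | Path, *, fmt: str = "%.6g"
) -> None:
    """Write a system in the same text dialect ``load_embeddings`` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for concept, vec in zip(system.concepts, system.vectors):
            coords = " ".join(fmt % x for x in vec)
            fh.write(f"{concept} {coords}\n")


def intersect_systems(
    visual: EmbeddingSystem,
    linguistic: EmbeddingSystem,
    *,
    alias_map: Mapping[str, str] | None = None,
) -> SystemPair:
    """Restrict two systems to their shared vocabulary.

    The intersection is ordered by the linguistic system's concept order so
    that downstream sampling is reproducible.  Multiword labels (containing
    whitespace) are dropped with a warning unless ``alias_map`` supplies a
    single-token alias for them.
    """
    alias_map = dict(alias_map or {})

    def normalise(concepts: Sequence[str]) -> list[str]:
        out = []
        for c in concepts:
            c = alias_map.get(c, c)
            if " " in c or "\t" in c:
                warnings.warn(
                    f"dropping multiword concept {c!r} (no alias supplied)",
                    stacklevel=3,
                )
                out.append(None)
            else:
                out.append(c)
        return out

    vis_labels = normalise(visual.concepts)
    lin_labels = normalise(linguistic.concepts)
    vis_keep = [c for c in vis_labels if c is not None]
    shared = [
        c for c in lin_labels if c is not None and c in set(vis_keep)
    ]
    if not shared:
        raise ValueError("no shared concepts between the two systems")

    vis_idx = {c: i for i, c in enumerate(vis_labels) if c is not None}
    lin_idx = {c: i for i, c in enumerate(lin_labels) if c is not None}
    vis_sub = EmbeddingSystem(
        visual.modality,
        tuple(shared),
        visual.vectors[[vis_idx[c] for c in shared]],
    )
    lin_sub = EmbeddingSystem(
        linguistic.modality,
        tuple(shared),
        linguistic.vectors[[lin_idx[c] for c in shared]],
    )
    logger.debug("intersection: %d shared concepts", len(shared))
    return SystemPair(vis_sub, lin_sub, tuple(shared))


def pairwise_distances(
    system: EmbeddingSystem, metric: str = "euclidean"
) -> DistanceMatrix:
    """Interconcept distance matrix for one system.

    ``euclidean`` is the L2 norm of the coordinate difference; ``cosine`` is
    1 − cosine similarity (undefined, hence an error, for zero-norm vectors).
    """
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")
    if metric == "cosine":
        norms = np.linalg.norm(system.vectors, axis=1)
        bad = np.where(norms == 0)[0]
        if bad.size:
            raise ValueError(
                "cosine distance undefined for zero-norm vector(s): "
                + ", ".join(system.concepts[i] for i in bad)
            )
    condensed = pdist(system.vectors, metric=metric)
    values = squareform(condensed)
    np.fill_diagonal(values, 0.0)
    # pdist's cosine can return tiny negatives for near-parallel vectors
    values = np.clip(values, 0.0, None)
    return DistanceMatrix(system.concepts, values, metric)
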