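"""Synthetic paired embedding systems and acquisition tables.

The generator realizes the statistical premise of the analysis — that the
two modalities carry mirrored similarity structure — with a single noise
dial.  Latent concept positions are drawn from a mixture of Gaussian
clusters; each modality observes the latents through its own random
orthonormal linear map (an isometry, so with zero noise the two systems are
second-order isomorphic and the true mapping's alignment score is 1) plus
independent Gaussian noise of scale ``alignment_noise``.

The acquisition table emulates the empirical finding that children's early
concepts have dense similarity neighborhoods: each concept gets a *density
score* (its degree in the latent-space 10th-percentile neighbor graph), and
with bias ``beta > 0`` dense concepts are both likelier to be in the AoA
subset and likelier to be acquired early within it.  ``beta = 0`` removes
every density effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from .aoa import AcquisitionTable, MonthSchedule, monthly_counts, save_acquisition_table
from .systems import EmbeddingSystem, SystemPair, save_embeddings

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "generate_paired_systems",
    "generate_acquisition_table",
    "generate_world",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_world",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic paired-system world.

    ``alignment_noise`` is the per-modality additive Gaussian noise scale in
    embedding-coordinate units (the latent signal has unit-order scale);
    ``density_bias`` is the strength beta of the early-acquisition
    preference for dense concepts (log-odds units per standardized density
    score); ``aoa_fraction`` is the share of the vocabulary covered by the
    acquisition table.
    """

    n_concepts: int = 60
    dim_visual: int = 10
    dim_linguistic: int = 50
    n_clusters: int = 4
    cluster_spread: float = 0.6
    center_scale: float = 1.0
    alignment_noise: float = 0.0
    noise_density_coupling: float = 2.0
    density_bias: float = 0.0
    aoa_fraction: float = 0.5
    months: tuple[int, ...] = tuple(range(16, 25))
    onset_margin: float = 3.0
    ramp_width: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_concepts:
            raise ValueError("more clusters than concepts")
        if self.alignment_noise < 0 or self.density_bias < 0:
            raise ValueError("noise and bias must be nonnegative")
        if not 0 < self.aoa_fraction <= 1:
            raise ValueError("aoa_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticWorld:
    """A paired system, its acquisition table, and the generating truth."""

    pair: SystemPair
    table: AcquisitionTable
    truth: dict = field(repr=False)
    config: SyntheticConfig = field(repr=False, default=SyntheticConfig())

    @property
    def schedule(self) -> MonthSchedule:
        return monthly_counts(self.table)

    @property
    def aoa_concepts(self) -> tuple[str, ...]:
        return self.table.concepts

    @property
    def control_concepts(self) -> tuple[str, ...]:
        aoa = set(self.table.concepts)
        return tuple(c for c in self.pair.shared_concepts if c not in aoa)


def _random_orthonormal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Matrix with orthonormal columns (rows >= cols): an isometry."""
    if cols > rows:
        raise ValueError("isometric map needs target dim >= latent dim")
    a = rng.standard_normal((rows, cols))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _density_scores(latents: np.ndarray, percentile: float = 10.0) -> np.ndarray:
    """Degree of each concept in the latent 10th-percentile neighbor graph."""
    d = squareform(pdist(latents))
    iu = np.triu_indices(len(latents), k=1)
    threshold = np.percentile(d[iu], percentile)
    adj = (d < threshold) & ~np.eye(len(latents), dtype=bool)
    return adj.sum(axis=1).astype(float)


def generate_paired_systems(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[SystemPair, dict]:
    """Sample a visual/linguistic system pair with mirrored structure.

    Returns the pair and the latent truth: cluster assignments, latent
    coordinates, and per-concept density scores.
    """
    n = config.n_concepts
    latent_dim = min(config.dim_visual, config.dim_linguistic)
    centers = rng.standard_normal((config.n_clusters, latent_dim)) * config.center_scale
    # balanced clusters, so density is a core-vs-periphery property within
    # every cluster rather than an artifact of cluster size
    assign = rng.permutation(np.arange(n) % config.n_clusters)
    # radial profile: every cluster has tight core members and a sparser
    # periphery (emulating prototypical vs idiosyncratic concepts)
    radius = rng.uniform(0.3, 2.2, size=n)
    offsets = rng.standard_normal((n, latent_dim)) * config.cluster_spread
    latents = centers[assign] + offsets * radius[:, None]

    concepts = tuple(f"c{i:03d}" for i in range(n))
    density = _density_scores(latents)
    # positions of densely-embedded concepts are more stable: per-concept
    # noise grows with sparsity (coupling 0 = homogeneous noise)
    if config.noise_density_coupling > 0 and n > 1:
        sparsity = 1.0 - stats.rankdata(density) / n  # in (0, 1)
        scale = 1.0 + config.noise_density_coupling * sparsity
    else:
        scale = np.ones(n)
    vectors = {}
    for modality, dim in (
        ("visual", config.dim_visual),
        ("linguistic", config.dim_linguistic),
    ):
        basis = _random_orthonormal(rng, dim, latent_dim)
        coords = latents @ basis.T
        # noise sd shrinks with sqrt(dim) so the expected distance
        # perturbation is the same in both modalities
        sd = config.alignment_noise * np.sqrt(latent_dim / dim)
        noise = rng.standard_normal(coords.shape) * sd
        coords = coords + noise * scale[:, None]
        vectors[modality] = coords

    visual = EmbeddingSystem("visual", concepts, vectors["visual"])
    linguistic = EmbeddingSystem("linguistic", concepts, vectors["linguistic"])
    pair = SystemPair(visual, linguistic, concepts)
    truth = {
        "clusters": assign,
        "latents": latents,
        "density": density,
    }
    return pair, truth


def generate_acquisition_table(
    pair: SystemPair,
    truth: dict,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    density_scores: np.ndarray | None = None,
) -> AcquisitionTable:
    """Synthesize a monthwise cumulative acquisition-probability table.

    An AoA subset of the vocabulary is drawn with log-odds increasing in
    ``density_bias * z(density)``; within the subset, acquisition onsets are
    ordered the same way (plus logistic noise) and spread over the month
    range, and each concept's cumulative curve is a logistic ramp of width
    ``ramp_width`` months centered on its onset.  ``density_scores``
    overrides the truth's density with an arbitrary planted driver.
    """
    n = pair.n_concepts
    density = np.asarray(
        truth["density"] if density_scores is None else density_scores, float
    )
    sd = density.std()
    z = (density - density.mean()) / sd if sd > 0 else np.zeros(n)

    n_aoa = max(2, int(round(config.aoa_fraction * n)))
    # Gumbel-max trick: top-n_aoa of (beta*z + Gumbel noise) is a
    # Plackett-Luce sample without replacement, uniform when beta = 0.
    gumbel = rng.gumbel(size=n)
    pick = np.argsort(-(config.density_bias * z + gumbel))[:n_aoa]
    pick = np.sort(pick)
    aoa_concepts = tuple(pair.shared_concepts[i] for i in pick)

    # earliness within the subset: density-biased with logistic noise
    earliness = config.density_bias * z[pick] + rng.logistic(size=n_aoa)
    order = np.argsort(-earliness)  # earliest first
    lo, hi = config.months[0], config.months[-1]
    # onsets start just below the first month (so early states are nonempty)
    # and run past the last (so some concepts stay unacquired for probing)
    start = lo - 1.0
    span = (hi + config.onset_margin) - start
    ranks = np.empty(n_aoa)
    ranks[order] = np.arange(n_aoa)
    onsets = start + span * ranks / n_aoa

    months = np.asarray(config.months, dtype=float)
    probs = expit((months[None, :] - onsets[:, None]) / config.ramp_width)
    table = AcquisitionTable(aoa_concepts, config.months, probs)
    return table


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a full synthetic world (pair + table + truth) from a config."""
    rng = np.random.default_rng(config.seed)
    pair, truth = generate_paired_systems(config, rng)
    table = generate_acquisition_table(pair, truth, config, rng)
    idx = {c: i for i, c in enumerate(pair.shared_concepts)}
    truth = dict(truth)
    truth["aoa_indices"] = np.array([idx[c] for c in table.concepts])
    return SyntheticWorld(pair, table, truth, config)


#: deterministic worlds reused across the test suite
_FIXTURES: dict[str, SyntheticConfig] = {
    "mirror10": SyntheticConfig(
        n_concepts=10,
        n_clusters=3,
        alignment_noise=0.0,
        density_bias=0.0,
        aoa_fraction=0.5,
        seed=101,
    ),
    "noisy30": SyntheticConfig(
        n_concepts=30,
        n_clusters=4,
        alignment_noise=0.3,
        noise_density_coupling=6.0,
        density_bias=3.0,
        aoa_fraction=0.5,
        onset_margin=6.0,
        seed=202,
    ),
    "planted60": SyntheticConfig(
        n_concepts=60,
        n_clusters=4,
        alignment_noise=0.6,
        noise_density_coupling=6.0,
        density_bias=5.0,
        aoa_fraction=0.5,
        onset_margin=10.0,
        seed=303,
    ),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def make_fixture(name: str) -> SyntheticWorld:
    """Return one of the registered deterministic test worlds."""
    try:
        config = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    return generate_world(config)


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write a world as embedding text files, an AoA CSV, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "visual": outdir / "visual_embeddings.txt",
        "linguistic": outdir / "linguistic_embeddings.txt",
        "aoa": outdir / "aoa_table.csv",
        "truth": outdir / "truth.json",
    }
    save_embeddings(world.pair.visual, paths["visual"])
    save_embeddings(world.pair.linguistic, paths["linguistic"])
    save_acquisition_table(world.table, paths["aoa"])
    truth = {
        "clusters": world.truth["clusters"].tolist(),
        "density": world.truth["density"].tolist(),
        "aoa_concepts": list(world.table.concepts),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
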