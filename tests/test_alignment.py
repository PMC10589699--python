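"""Alignment scores and the forced-choice probe task."""

import numpy as np
import pytest
from scipy import stats

import alignsim as al
from alignsim.alignment import DegenerateCorrelationError


def dist_from(values, metric="euclidean"):
    values = np.asarray(values, dtype=float)
    labels = tuple(f"c{i}" for i in range(len(values)))
    return al.DistanceMatrix(labels, values, metric)


def symmetric(n, rng):
    m = rng.random((n, n)) + 0.1
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def copy_pair(rng, n=6, dim=3, prefix="c"):
    """Visual and linguistic systems with identical coordinates."""
    concepts = tuple(f"{prefix}{i}" for i in range(n))
    coords = rng.standard_normal((n, dim))
    return al.SystemPair(
        al.EmbeddingSystem("visual", concepts, coords),
        al.EmbeddingSystem("linguistic", concepts, coords.copy()),
        concepts,
    )


class TestAlignmentScore:
    def test_self_correlation_is_one(self, rng):
        d = dist_from(symmetric(5, rng))
        assert al.alignment_score(d, d) == pytest.approx(1.0)

    def test_monotone_decreasing_transform_gives_minus_one(self, rng):
        m = symmetric(5, rng)
        d1 = dist_from(m)
        inv = np.max(m) + 1 - m
        np.fill_diagonal(inv, 0.0)
        d2 = dist_from(inv)
        assert al.alignment_score(d1, d2) == pytest.approx(-1.0)

    def test_adjacent_swap_matches_closed_form(self):
        """Upper triangles whose ranks differ by one adjacent swap: the
        closed form 1 - 6*sum(d^2)/(n(n^2-1)) with n=6 rank pairs and
        sum(d^2)=2 gives 1 - 12/210."""
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        a[iu] = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b[iu] = [1.0, 2.0, 3.0, 4.0, 6.0, 5.0]  # swap last two ranks
        a, b = a + a.T, b + b.T
        expected = 1 - 6 * 2 / (6 * (36 - 1))
        assert al.alignment_score(dist_from(a), dist_from(b)) == pytest.approx(
            expected
        )

    def test_monotone_transform_invariance(self, rng):
        m1, m2 = symmetric(6, rng), symmetric(6, rng)
        d1, d2 = dist_from(m1), dist_from(m2)
        base = al.alignment_score(d1, d2)
        squared = dist_from(m2**2)
        assert al.alignment_score(d1, squared) == pytest.approx(base)
        assert al.alignment_score(d2, d1) == pytest.approx(base)

    def test_small_and_degenerate_inputs(self, rng):
        d2 = dist_from(symmetric(2, rng))
        with pytest.raises(ValueError, match="at least 3"):
            al.alignment_score(d2, d2)
        const = dist_from(np.ones((4, 4)) - np.eye(4))
        other = dist_from(symmetric(4, rng))
        with pytest.raises(DegenerateCorrelationError):
            al.alignment_score(const, other)

    def test_mapping_permutes_second_system(self, rng):
        m = symmetric(5, rng)
        d = dist_from(m)
        perm = np.array([2, 0, 1, 4, 3])
        permuted = dist_from(m[np.ix_(perm, perm)])
        # permuting b by the inverse of perm undoes the scramble
        inv = np.argsort(perm)
        assert al.alignment_score(d, permuted, inv) == pytest.approx(1.0)


class TestProbeAlignmentScore:
    def test_copy_systems_correct_candidate_scores_one(self, rng):
        pair = copy_pair(rng, n=7)
        state = al.KnowledgeState(pair.shared_concepts[:4])
        probes = al.ProbePair(pair.shared_concepts[4], pair.shared_concepts[5])
        assert al.probe_alignment_score(pair, state, probes, "correct") == (
            pytest.approx(1.0)
        )
        assert (
            al.probe_alignment_score(pair, state, probes, "swapped") < 1.0
        )

    def test_rank_then_correlate_oracle(self, rng):
        """Matches an independent straight-line reimplementation: build the
        concatenated probe-distance vectors, rank them, Pearson on ranks."""
        pair = copy_pair(rng, n=5)
        # perturb linguistic so the score is not trivially 1
        lin = al.EmbeddingSystem(
            "linguistic",
            pair.shared_concepts,
            pair.linguistic.vectors + 0.3 * rng.standard_normal((5, 3)),
        )
        pair = al.SystemPair(pair.visual, lin, pair.shared_concepts)
        state = al.KnowledgeState(pair.shared_concepts[:3])
        a, b = pair.shared_concepts[3], pair.shared_concepts[4]
        probes = al.ProbePair(a, b)

        def naive(candidate):
            dv = al.pairwise_distances(pair.visual).values
            dl = al.pairwise_distances(pair.linguistic).values
            idx = {c: i for i, c in enumerate(pair.shared_concepts)}
            srows = [idx[c] for c in state.concepts]
            x = np.concatenate([dv[idx[a], srows], dv[idx[b], srows]])
            first, second = (a, b) if candidate == "correct" else (b, a)
            y = np.concatenate([dl[idx[first], srows], dl[idx[second], srows]])
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            return np.corrcoef(rx, ry)[0, 1]

        for candidate in ("correct", "swapped"):
            assert al.probe_alignment_score(
                pair, state, probes, candidate
            ) == pytest.approx(naive(candidate), abs=1e-12)

    def test_probe_validation(self, rng):
        pair = copy_pair(rng)
        state = al.KnowledgeState(pair.shared_concepts[:3])
        with pytest.raises(ValueError, match="already in knowledge state"):
            al.probe_alignment_score(
                pair,
                state,
                al.ProbePair(pair.shared_concepts[0], pair.shared_concepts[4]),
            )
        with pytest.raises(ValueError, match="at least 2"):
            al.probe_alignment_score(
                pair,
                al.KnowledgeState(pair.shared_concepts[:1]),
                al.ProbePair(pair.shared_concepts[4], pair.shared_concepts[5]),
            )


class TestForcedChoice:
    def test_mirrored_noiseless_world_always_correct(self, mirror10, rng):
        state = al.KnowledgeState(mirror10.pair.shared_concepts[:4])
        remaining = mirror10.pair.shared_concepts[4:]
        for i in range(len(remaining) - 1):
            probes = al.ProbePair(remaining[i], remaining[i + 1])
            result = al.forced_choice(mirror10.pair, state, probes, rng)
            assert result.correct and not result.tie_broken
            assert result.margin > 0

    def test_chance_on_independent_systems(self):
        """Unrelated random systems carry no alignment signal: accuracy is
        1/2 by label-exchange symmetry.  Each trial uses a fresh world so
        trials are independent and the binomial CI applies."""
        rng = np.random.default_rng(77)
        concepts = tuple(f"c{i}" for i in range(8))
        n_correct = 0
        trials = 400
        for _ in range(trials):
            pair = al.SystemPair(
                al.EmbeddingSystem(
                    "visual", concepts, rng.standard_normal((8, 5))
                ),
                al.EmbeddingSystem(
                    "linguistic", concepts, rng.standard_normal((8, 8))
                ),
                concepts,
            )
            state = al.KnowledgeState(concepts[:4])
            result = al.forced_choice(
                pair, state, al.ProbePair(concepts[6], concepts[7]), rng
            )
            n_correct += result.correct
        ci = 1.96 * np.sqrt(0.25 / trials)
        assert abs(n_correct / trials - 0.5) < ci + 0.02

    def test_tie_detected_for_exchangeable_probes(self, rng):
        """Probes placed mirror-symmetrically about the knowledge state give
        identical concatenated vectors for both candidates: a tie."""
        concepts = ("s1", "s2", "a", "b")
        # state on the x-axis at unequal offsets, probes mirrored across it:
        # each probe is equidistant from both, the concatenated vectors are
        # non-constant, and swapping the probes changes nothing
        coords = np.array(
            [[1.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]]
        )
        pair = al.SystemPair(
            al.EmbeddingSystem("visual", concepts, coords),
            al.EmbeddingSystem("linguistic", concepts, coords.copy()),
            concepts,
        )
        state = al.KnowledgeState(("s1", "s2"))
        result = al.forced_choice(pair, state, al.ProbePair("a", "b"), rng)
        assert result.tie_broken
        assert result.score_correct == pytest.approx(result.score_incorrect)

    def test_fig1_style_scenario(self, rng):
        """Known apple/banana/car; pear sits near the fruit and truck near
        the car in both modalities: the correct mapping wins."""
        concepts = ("apple", "banana", "car", "pear", "truck")
        visual = np.array(
            [[0.0, 0.1], [0.2, 0.0], [5.0, 5.0], [0.1, 0.3], [5.2, 4.8]]
        )
        linguistic = np.array(
            [[0.1, 0.0, 1.0], [0.0, 0.2, 1.1], [4.8, 5.1, 0.2],
             [0.2, 0.1, 0.9], [5.1, 5.0, 0.1]]
        )
        pair = al.SystemPair(
            al.EmbeddingSystem("visual", concepts, visual),
            al.EmbeddingSystem("linguistic", concepts, linguistic),
            concepts,
        )
        state = al.KnowledgeState(("apple", "banana", "car"))
        result = al.forced_choice(
            pair, state, al.ProbePair("pear", "truck"), rng
        )
        assert result.correct and result.margin > 0


class TestShortcutVsFullScore:
    def test_agreement_on_small_random_worlds(self, rng):
        """The probe-column shortcut and the full alignment score over
        state+probes pick the same mapping on small random worlds."""
        agree = total = 0
        for trial in range(60):
            n = int(rng.integers(5, 9))
            config = al.SyntheticConfig(
                n_concepts=n,
                n_clusters=2,
                alignment_noise=float(rng.uniform(0, 0.6)),
                noise_density_coupling=0.0,
                seed=int(rng.integers(2**31)),
            )
            pair, _ = al.generate_paired_systems(
                config, np.random.default_rng(trial)
            )
            concepts = pair.shared_concepts
            state = al.KnowledgeState(concepts[: n - 2])
            probes = al.ProbePair(concepts[-2], concepts[-1])
            full, _, _ = al.full_alignment_decision(pair, state, probes)
            if full is None:
                continue
            shortcut = al.forced_choice(pair, state, probes, rng)
            if shortcut.tie_broken:
                continue
            total += 1
            agree += shortcut.chosen_mapping == full
        assert total > 40
        assert agree / total >= 0.95
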