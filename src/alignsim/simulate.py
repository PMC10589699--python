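"""Month-by-month agent simulation and forced-choice evaluation.

Agents grow knowledge states over the monthly schedule: the *AoA* agent
samples concepts one at a time from the children's acquisition-probability
distribution; the *Control* agent samples uniformly from the concepts
outside the AoA set.  At the end of every month each agent answers a batch
of forced-choice probes under one or both probe conditions (*aoa* probes
come from unacquired AoA-set concepts, *unconstrained* probes from the full
unacquired vocabulary), and accuracies are aggregated across a population
of agents with 95% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .alignment import KnowledgeState, ProbePair, forced_choice
from .aoa import AcquisitionTable, MonthSchedule, sample_acquisition_sequence
from .systems import SystemPair

logger = logging.getLogger(__name__)

__all__ = [
    "AgentConfig",
    "TrajectoryResult",
    "simulate_trajectory",
    "sample_probes",
    "evaluate_trajectory",
    "run_experiment",
]

AgentCondition = Literal["aoa", "control", "generative"]
ProbeCondition = Literal["aoa", "unconstrained"]


@dataclass(frozen=True)
class AgentConfig:
    """Configuration of one simulated-agent experiment."""

    agent_condition: AgentCondition = "aoa"
    probe_conditions: tuple[ProbeCondition, ...] = ("aoa", "unconstrained")
    n_agents: int = 100
    probes_per_month: int = 50
    seed: int = 0
    metric: str = "euclidean"
    #: "non_aoa" restricts the Control pool to concepts outside the AoA set;
    #: "all" draws from the full shared vocabulary
    control_pool: Literal["non_aoa", "all"] = "non_aoa"
    ci_method: Literal["normal", "percentile"] = "normal"
    #: optional held-out evaluation reserve: probes are drawn only from
    #: these concepts, and they are excluded from acquisition, so every
    #: agent faces the same probe distribution (useful in small
    #: vocabularies where acquisition would deplete the probe pool)
    probe_reserve: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1 or self.probes_per_month < 1:
            raise ValueError("n_agents and probes_per_month must be >= 1")
        if not self.probe_conditions:
            raise ValueError("at least one probe condition required")


@dataclass(frozen=True)
class TrajectoryResult:
    """Per-agent-month forced-choice accuracies and their summary.

    ``accuracies`` has one row per (agent, month, probe_condition);
    ``summary`` one row per (month, probe_condition) with mean accuracy and
    95% CI across agents.
    """

    accuracies: pd.DataFrame
    summary: pd.DataFrame = field(repr=False)
    config: AgentConfig = field(repr=False, default=AgentConfig())

    def to_csv(self, path) -> None:
        self.accuracies.to_csv(path, index=False)


def simulate_trajectory(
    condition: AgentCondition,
    schedule: MonthSchedule,
    table: AcquisitionTable,
    pair: SystemPair,
    rng: np.random.Generator,
    *,
    control_pool: str = "non_aoa",
    excluded: Sequence[str] = (),
) -> list[KnowledgeState]:
    """One agent's knowledge-state trajectory, one state per month.

    The month-``m`` state contains exactly the cumulative schedule count of
    concepts.  AoA agents sample without replacement from the monthly
    acquisition distribution; Control agents sample uniformly without
    replacement from the eligible pool (by default the concepts absent from
    the AoA table).
    """
    excluded_set = set(excluded)
    if condition == "aoa":
        if excluded_set:
            table = table.restrict(
                [c for c in table.concepts if c not in excluded_set]
            )
        member_lists = sample_acquisition_sequence(table, schedule, rng)
        return [
            KnowledgeState(tuple(members), month=month)
            for month, members in zip(schedule.months, member_lists)
        ]
    if condition != "control":
        raise ValueError(
            f"unknown agent condition {condition!r} (generative trajectories "
            "are produced by generative.generate_sequence)"
        )
    aoa_set = set(table.concepts)
    if control_pool == "all":
        pool = list(pair.shared_concepts)
    else:
        pool = [c for c in pair.shared_concepts if c not in aoa_set]
    pool = [c for c in pool if c not in excluded_set]
    if schedule.total > len(pool):
        raise ValueError(
            f"control pool has {len(pool)} concepts; schedule needs "
            f"{schedule.total}"
        )
    chosen = rng.choice(len(pool), size=schedule.total, replace=False)
    ordered = [pool[i] for i in chosen]
    states, cum = [], 0
    for month, n_m in zip(schedule.months, schedule.n_per_month):
        cum += n_m
        states.append(KnowledgeState(tuple(ordered[:cum]), month=month))
    return states


def sample_probes(
    condition: ProbeCondition,
    state: KnowledgeState,
    table: AcquisitionTable,
    pair: SystemPair,
    k: int,
    rng: np.random.Generator,
    *,
    reserve: Sequence[str] | None = None,
) -> list[ProbePair]:
    """Draw ``k`` forced-choice probe pairs for one month.

    The eligible pool is the unacquired AoA-set concepts (``aoa``) or all
    unacquired shared concepts (``unconstrained``); a ``reserve`` overrides
    both with a fixed held-out probe set.  Pairs are drawn independently:
    the two members of a pair are distinct, but a concept may recur across
    pairs.
    """
    known = set(state.concepts)
    if reserve is not None:
        pool = [c for c in reserve if c not in known]
    elif condition == "aoa":
        pool = [c for c in table.concepts if c not in known]
    elif condition == "unconstrained":
        pool = [c for c in pair.shared_concepts if c not in known]
    else:
        raise ValueError(f"unknown probe condition {condition!r}")
    if len(pool) < 2:
        raise ValueError(
            f"probe pool for condition {condition!r} has {len(pool)} "
            "concepts; need >= 2"
        )
    probes = []
    for _ in range(k):
        i, j = rng.choice(len(pool), size=2, replace=False)
        probes.append(ProbePair(pool[i], pool[j]))
    return probes


def evaluate_trajectory(
    states: Sequence[KnowledgeState],
    probe_conditions: Sequence[ProbeCondition],
    table: AcquisitionTable,
    pair: SystemPair,
    probes_per_month: int,
    rng: np.random.Generator,
    *,
    metric: str = "euclidean",
    dists=None,
    reserve: Sequence[str] | None = None,
    per_probe: bool = False,
) -> list[dict]:
    """Forced-choice accuracy of one agent at every month.

    Returns one record per (month, probe condition), or — with
    ``per_probe=True`` — one tidy record per probe trial carrying both
    candidate scores, the margin, correctness, and the tie flag.  Probes
    are drawn fresh at each month.
    """
    if dists is None:
        dists = pair.distance_matrices(metric)
    records = []
    for state in states:
        for probe_condition in probe_conditions:
            probes = sample_probes(
                probe_condition, state, table, pair, probes_per_month, rng,
                reserve=reserve,
            )
            n_correct = n_ties = 0
            for probe_id, probe in enumerate(probes):
                result = forced_choice(
                    pair, state, probe, rng, metric=metric, dists=dists
                )
                n_correct += result.correct
                n_ties += result.tie_broken
                if per_probe:
                    records.append(
                        {
                            "month": state.month,
                            "probe_condition": probe_condition,
                            "probe_id": probe_id,
                            "concept_a": probe.concept_a,
                            "concept_b": probe.concept_b,
                            "score_correct": result.score_correct,
                            "score_incorrect": result.score_incorrect,
                            "margin": result.margin,
                            "correct": result.correct,
                            "tie_broken": result.tie_broken,
                        }
                    )
            if not per_probe:
                records.append(
                    {
                        "month": state.month,
                        "probe_condition": probe_condition,
                        "n_probes": len(probes),
                        "n_correct": n_correct,
                        "n_ties": n_ties,
                        "accuracy": n_correct / len(probes),
                    }
                )
    return records


def _summarize(acc: pd.DataFrame, method: str) -> pd.DataFrame:
    rows = []
    for (month, cond), grp in acc.groupby(["month", "probe_condition"]):
        a = grp["accuracy"].to_numpy()
        mean = float(a.mean())
        if method == "percentile":
            lo, hi = np.percentile(a, [2.5, 97.5])
        else:
            sem = a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0
            lo, hi = mean - 1.96 * sem, mean + 1.96 * sem
        rows.append(
            {
                "month": month,
                "probe_condition": cond,
                "mean_accuracy": mean,
                "ci_low": float(min(lo, mean)),
                "ci_high": float(max(hi, mean)),
                "n_agents": len(a),
            }
        )
    return pd.DataFrame(rows)


def run_experiment(
    config: AgentConfig,
    pair: SystemPair,
    table: AcquisitionTable,
    schedule: MonthSchedule,
    *,
    trajectory_sampler: Callable[[np.random.Generator], Sequence[KnowledgeState]]
    | None = None,
) -> TrajectoryResult:
    """Simulate and evaluate a population of agents.

    Each agent gets an independent seeded RNG stream derived from
    ``config.seed``, making the full result reproducible.  For the
    ``generative`` agent condition, supply ``trajectory_sampler`` (e.g. a
    frozen model's ``generate_sequence`` closure); for ``aoa``/``control``
    trajectories are simulated internally.
    """
    if config.agent_condition == "generative" and trajectory_sampler is None:
        raise ValueError("generative condition needs a trajectory_sampler")
    dists = pair.distance_matrices(config.metric)
    all_records = []
    for agent in range(config.n_agents):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, agent])
        )
        if trajectory_sampler is not None:
            states = trajectory_sampler(rng)
        else:
            states = simulate_trajectory(
                config.agent_condition,
                schedule,
                table,
                pair,
                rng,
                control_pool=config.control_pool,
                excluded=config.probe_reserve or (),
            )
        records = evaluate_trajectory(
            states,
            config.probe_conditions,
            table,
            pair,
            config.probes_per_month,
            rng,
            metric=config.metric,
            dists=dists,
            reserve=config.probe_reserve,
        )
        for rec in records:
            rec["agent"] = agent
            rec["agent_condition"] = config.agent_condition
            logger.debug(
                "agent=%d month=%s probe=%s acc=%.3f",
                agent, rec["month"], rec["probe_condition"], rec["accuracy"],
            )
        all_records.extend(records)
    acc = pd.DataFrame(all_records)[
        [
            "agent",
            "agent_condition",
            "month",
            "probe_condition",
            "n_probes",
            "n_correct",
            "n_ties",
            "accuracy",
        ]
    ]
    return TrajectoryResult(acc, _summarize(acc, config.ci_method), config)
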