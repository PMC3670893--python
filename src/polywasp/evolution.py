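"""Tournament selection of an evolutionarily stable sex-allocation strategy.

A pool of random *viable* strategies (viable: a population using the
strategy exclusively does not go extinct over a screening horizon) is split
into subsets of five; each subset competes in one shared environment, where
successful strategies take over by producing more offspring that inherit
their parents' (recombined) sex-choice values.  Subset winners are re-split
and compete again until a single strategy remains — with 125 starters, 25
winners emerge from round one, 5 from round two and 1 from round three.  The
whole protocol is replicated with independent seeds and the winning sex
allocation reported as mean ± SD.

There is no mutation operator: inheritance is a convex (linear) combination
of the parents' values, so every evolved sex-choice value stays within the
convex hull of the initial random draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lifecycle import (
    Environment,
    GenerationStats,
    initial_population,
    step_generation,
)
from .model_core import (
    FEMALE,
    IdAllocator,
    SimulationConfig,
    Strategy,
    make_random_strategy,
    sex_choice_keys,
)

__all__ = [
    "ViabilityError",
    "RoundExtinctionError",
    "RoundRecord",
    "TournamentResult",
    "viability_screen",
    "find_viable_strategies",
    "run_round",
    "tournament",
    "replicate_tournaments",
]

#: Default screening horizon (generations) for the viability check.
VIABILITY_GENERATIONS = 50
#: Default host count used during viability screening; smaller than a
#: competition round because screening only needs persistence, not dynamics.
VIABILITY_HOST_COUNT = 60
#: A round ends early once a single strategy has held 100% of the adults for
#: this many consecutive generations.
FIXATION_RUN = 10
#: Hard generation cap of a competition round.
GENERATION_CAP = 500


class ViabilityError(RuntimeError):
    """Raised when no viable strategy can be found within the retry budget."""


class RoundExtinctionError(RuntimeError):
    """Raised when every strategy in a round's subset went extinct."""


def _founding_females(
    strategies: Sequence[Strategy],
    count: int,
    ids: IdAllocator,
) -> list:
    """Seed a round: ``count`` mated females per strategy, no males.

    Founder females are mated to a male of their own strategy, so the first
    clutch of daughters inherits an unblended strategy.
    """
    config = SimulationConfig(initial_sex_distribution=0.0, initial_virgin_ratio=0.0)
    return initial_population([(s, count) for s in strategies], config, ids)


def viability_screen(
    strategy: Strategy,
    config: SimulationConfig,
    rng: np.random.Generator,
    generations: int = VIABILITY_GENERATIONS,
    host_count: int | None = None,
) -> bool:
    """True iff a population using ``strategy`` exclusively persists.

    Runs a single-strategy population (100 mated founder females) under the
    config's acceptance threshold for the screening horizon; the verdict is
    deterministic given the generator state.
    """
    screen_config = replace(
        config,
        host_count=host_count if host_count is not None else config.host_count,
        generations=generations,
    )
    ids = IdAllocator()
    env = Environment(
        _founding_females([strategy], config.initial_wasp_count, ids), ids
    )
    for _ in range(generations):
        env, stats, _ = step_generation(env, screen_config, rng)
        if stats.extinct:
            return False
    return True


def find_viable_strategies(
    n: int,
    config: SimulationConfig,
    template: Strategy,
    rng: np.random.Generator,
    screen_generations: int = VIABILITY_GENERATIONS,
    screen_host_count: int | None = VIABILITY_HOST_COUNT,
    max_tries_per_strategy: int = 25,
    scalar: bool = True,
) -> list[Strategy]:
    """Draw ``n`` random strategies, redrawing any that fail the viability screen.

    By default each candidate is a single unconditional sex-allocation value
    shared by every host state (the evolving trait is one random variable);
    ``scalar=False`` draws an independent value per host-state key instead.
    """
    strategies: list[Strategy] = []
    tries = 0
    budget = n * max_tries_per_strategy
    while len(strategies) < n:
        if tries >= budget:
            raise ViabilityError(
                f"could not find {n} viable strategies in {budget} draws "
                f"(threshold {config.host_acceptance_threshold}); the "
                f"environment may not sustain any population")
        tries += 1
        candidate = make_random_strategy(rng, template, config.info_level,
                                         scalar=scalar)
        if viability_screen(candidate, config, rng,
                            generations=screen_generations,
                            host_count=screen_host_count):
            strategies.append(candidate)
    return strategies


@dataclass
class RoundRecord:
    """Trajectory of one competition round."""

    winner_index: int
    winner: Strategy
    stats: list[GenerationStats]
    shares: pd.DataFrame = field(repr=False)
    fixed: bool = False

    def final_window_means(self, window: int = 50) -> tuple[float, float]:
        """(primary, secondary) sex ratio means over the last ``window`` generations."""
        tail = self.stats[-window:]
        primary = [s.primary_ratio for s in tail if s.eggs_total]
        secondary = [s.secondary_ratio for s in tail if s.adults_total]
        return (float(np.mean(primary)) if primary else float("nan"),
                float(np.mean(secondary)) if secondary else float("nan"))


def _label_mean_vectors(
    env: Environment, keys: tuple[str, ...]
) -> dict[int, np.ndarray]:
    """Clone-size-weighted mean female sex-choice vector per label, one pass."""
    sums: dict[int, np.ndarray] = {}
    weights: dict[int, int] = {}
    for c in env.cohorts:
        if c.sex != FEMALE or c.size <= 0:
            continue
        vec = c.strategy.sex_choice_vector(keys) * c.size
        if c.label in sums:
            sums[c.label] += vec
            weights[c.label] += c.size
        else:
            sums[c.label] = vec
            weights[c.label] = c.size
    return {label: sums[label] / weights[label] for label in sums}


def run_round(
    strategies: Sequence[Strategy],
    config: SimulationConfig,
    rng: np.random.Generator,
    generation_cap: int = GENERATION_CAP,
    fixation_run: int = FIXATION_RUN,
    initial_count: int | None = None,
) -> RoundRecord:
    """Let a subset of strategies compete in one shared environment.

    Each strategy is seeded with ``initial_count`` (default: the config's
    ``initial_wasp_count``, canonically 100) mated females carrying its
    matrilineal label.  The round runs until one label has held the whole
    adult population for ``fixation_run`` consecutive generations, or until
    the generation cap.  The winner is the label with the highest long-term
    mean population share (ties: final-generation count, then lowest index);
    the returned winning strategy is the clone-size-weighted mean sex-choice
    vector of that label's females in the last generation it was alive,
    recombination having blended the founder vectors long before fixation.
    """
    if not strategies:
        raise ValueError("round subset must be non-empty")
    count = config.initial_wasp_count if initial_count is None else initial_count
    keys = sex_choice_keys(config.info_level)
    ids = IdAllocator()
    env = Environment(_founding_females(strategies, count, ids), ids)

    n = len(strategies)
    stats_list: list[GenerationStats] = []
    share_rows: list[dict[int, float]] = []
    last_vectors: dict[int, np.ndarray] = {}
    streak = 0
    fixed = False
    for _ in range(generation_cap):
        env, stats, _ = step_generation(env, config, rng)
        stats_list.append(stats)
        shares = stats.strategy_shares
        share_rows.append({i: shares.get(i, 0.0) for i in range(n)})
        last_vectors.update(_label_mean_vectors(env, keys))
        if stats.extinct:
            break
        if max(shares.values(), default=0.0) >= 1.0:
            streak += 1
            if streak >= fixation_run:
                fixed = True
                break
        else:
            streak = 0

    share_frame = pd.DataFrame(share_rows, columns=list(range(n))).fillna(0.0)
    if not last_vectors:
        raise RoundExtinctionError(
            f"all {n} strategies in the subset went extinct "
            f"(threshold {config.host_acceptance_threshold})")

    mean_share = share_frame.mean(axis=0)
    final_counts = stats_list[-1].strategy_counts if stats_list else {}
    order = sorted(
        range(n),
        key=lambda i: (-mean_share[i], -final_counts.get(i, 0), i),
    )
    winner_index = next(i for i in order if i in last_vectors)
    winner = replace(
        strategies[winner_index],
        sex_choice=dict(zip(keys, last_vectors[winner_index])),
    )
    return RoundRecord(winner_index=winner_index, winner=winner,
                       stats=stats_list, shares=share_frame, fixed=fixed)


@dataclass
class TournamentResult:
    """Outcome of one full multi-round tournament."""

    winner: Strategy
    round_winners: list[list[Strategy]]
    round_winner_indices: list[list[int]]
    final_round: RoundRecord | None
    n_strategies: int
    seed: int | None = None

    @property
    def winners_per_round(self) -> list[int]:
        return [len(w) for w in self.round_winners]


def tournament(
    config: SimulationConfig,
    template: Strategy,
    n_strategies: int = 125,
    subset_size: int = 5,
    rng: np.random.Generator | int | None = None,
    round_runner: Callable[[Sequence[Strategy], SimulationConfig,
                            np.random.Generator], RoundRecord] | None = None,
    generation_cap: int = GENERATION_CAP,
    screen_generations: int = VIABILITY_GENERATIONS,
    screen_host_count: int | None = VIABILITY_HOST_COUNT,
    scalar: bool = True,
) -> TournamentResult:
    """Evolve a single winning strategy from ``n_strategies`` random viable ones.

    Strategies are randomly split into subsets of ``subset_size``; each subset
    runs one competition round; winners are randomly re-split and compete
    again until one remains (125 -> 25 -> 5 -> 1 with the defaults; a pool no
    larger than one subset collapses to a single round).  ``round_runner``
    replaces :func:`run_round` when injected (e.g. for structural tests).
    """
    seed = rng if isinstance(rng, int) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    runner = round_runner or (
        lambda subset, cfg, r: run_round(subset, cfg, r,
                                         generation_cap=generation_cap)
    )
    current = find_viable_strategies(
        n_strategies, config, template, rng,
        screen_generations=screen_generations,
        screen_host_count=screen_host_count,
        scalar=scalar,
    )
    round_winners: list[list[Strategy]] = []
    round_indices: list[list[int]] = []
    final_record: RoundRecord | None = None
    while len(current) > 1:
        order = rng.permutation(len(current))
        winners: list[Strategy] = []
        indices: list[int] = []
        for start in range(0, len(order), subset_size):
            subset_ids = order[start:start + subset_size]
            subset = [current[i] for i in subset_ids]
            record = runner(subset, config, rng)
            winners.append(record.winner)
            indices.append(int(subset_ids[record.winner_index]))
            final_record = record
        round_winners.append(winners)
        round_indices.append(indices)
        current = winners
    return TournamentResult(
        winner=current[0],
        round_winners=round_winners,
        round_winner_indices=round_indices,
        final_round=final_record,
        n_strategies=n_strategies,
        seed=seed,
    )


def replicate_tournaments(
    config: SimulationConfig,
    template: Strategy,
    n_replicates: int = 5,
    base_seed: int = 0,
    final_window: int = 50,
    **tournament_kwargs,
) -> dict:
    """Run independent tournaments and summarize the winning sex allocation.

    Each replicate gets a seed derived from ``base_seed`` via
    ``numpy.random.SeedSequence.spawn``.  Two allocations are reported per
    replicate — the winner's empty-host sex-choice value and the realized
    primary sex ratio over the final generations of the last round — along
    with the realized secondary ratio; means use the sample SD (0 for a
    single replicate).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_replicates)
    rows = []
    for i, child in enumerate(children):
        result = tournament(config, template,
                            rng=np.random.default_rng(child),
                            **tournament_kwargs)
        primary, secondary = (result.final_round.final_window_means(final_window)
                              if result.final_round else (float("nan"),) * 2)
        rows.append({
            "replicate": i,
            "allocation_empty": result.winner.sex_choice["empty"],
            "primary_ratio": primary,
            "secondary_ratio": secondary,
        })
    frame = pd.DataFrame(rows)

    def _mean_sd(column: str) -> tuple[float, float]:
        values = frame[column].to_numpy()
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return float(np.mean(values)), sd

    summary = {"replicates": frame}
    for column in ("allocation_empty", "primary_ratio", "secondary_ratio"):
        mean, sd = _mean_sd(column)
        summary[f"mean_{column}"] = mean
        summary[f"sd_{column}"] = sd
    return summary
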