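"""One discrete, non-overlapping generation of the host-parasitoid system.

The generation schedule is: fresh hosts are laid out; for ``lifespan`` time
steps every living female is presented one uniformly random host and lays a
single egg into it if the host's attractiveness strictly exceeds the
acceptance threshold (virgin females lay male eggs only; mated females draw
the egg's sex from their strategy's sex-choice probability for the sensed
host state); all hosts are then resolved into broods (overcrowded hosts die
with all their eggs; otherwise each egg proliferates into a clone whose size
is drawn from the context-appropriate survival distribution, and a fraction
of the emerging females mate with brood males before dispersal); leftover
virgins mate at dispersal, males' virility permitting; the offspring replace
their parents.

Internally the population is held as :class:`~polywasp.model_core.Cohort`
groups of identical wasps (a clone, or the mated/virgin split of one) so that
runs with tens of thousands of wasps stay cheap; all semantics are
individual-level, and every random choice flows through one
``numpy.random.Generator``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .model_core import (
    FEMALE,
    MALE,
    Cohort,
    Egg,
    Host,
    IdAllocator,
    SimulationConfig,
    Strategy,
    SurvivalDistributions,
    host_state_key,
    sample_clone_size,
    sex_choice_keys,
)

__all__ = [
    "BroodOutcome",
    "GenerationStats",
    "Environment",
    "SimulationResult",
    "attractiveness",
    "accept_host",
    "choose_egg_sex",
    "inherit_strategy",
    "resolve_host",
    "disperse_and_mate",
    "initial_population",
    "step_generation",
    "run_simulation",
]


def attractiveness(host: Host, egg_count_influence: float) -> float:
    """Host attractiveness: 1 for an empty host, dropping linearly per egg, floored at 0."""
    return max(0.0, 1.0 - egg_count_influence * len(host.eggs))


def accept_host(host: Host, threshold: float, egg_count_influence: float) -> bool:
    """A host is accepted for oviposition iff its attractiveness strictly exceeds the threshold."""
    return attractiveness(host, egg_count_influence) > threshold


def choose_egg_sex(female, key: str, rng: np.random.Generator) -> str:
    """Sex of the next egg: virgins can only lay male (unfertilized) eggs;
    mated females lay a male egg with their strategy's probability for ``key``."""
    if getattr(female, "virgin", False):
        return MALE
    p_male = female.strategy.sex_choice[key]
    return MALE if rng.random() < p_male else FEMALE


def inherit_strategy(mother: Strategy, father: Strategy, w: float) -> Strategy:
    """A daughter's strategy: component-wise ``w * father + (1 - w) * mother``
    over the sex-choice values; all other fields are the (shared) constants.

    Sons are haploid and inherit their mother's strategy object unchanged --
    callers simply reuse ``mother`` for male eggs.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("inheritance weight must lie in [0, 1]")
    if w == 0.0:
        return mother
    if w == 1.0:
        return father
    blended = {
        key: w * father.sex_choice[key] + (1.0 - w) * p
        for key, p in mother.sex_choice.items()
    }
    return Strategy(
        sex_choice=blended,
        egg_count_influence=mother.egg_count_influence,
        in_host_mating_ratio=mother.in_host_mating_ratio,
        strategy_inheritance=mother.strategy_inheritance,
        virility=mother.virility,
        virgin_son_virility=mother.virgin_son_virility,
        lifespan=mother.lifespan,
        survival=mother.survival,
    )


@dataclass(slots=True)
class BroodOutcome:
    """Resolution of one host: the adults that emerged, or a premature death."""

    host: Host
    emerging_males: int = 0
    emerging_females: int = 0
    premature_death: bool = False
    cohorts: list[Cohort] = field(default_factory=list)


def _egg_context(egg: Egg, eggs: list[Egg], single_sex: bool) -> str:
    """Survival context of one egg within its brood.

    Single-sex broods use the single-sex distributions.  In a mixed-sex brood
    an egg whose companions are all kin develops in the related-mixed context;
    any unrelated companion exposes it to soldier interference, the
    unrelated-mixed context.
    """
    if single_sex:
        return f"{egg.sex}_single_sex"
    related_to_all = all(
        other is egg or other.mother_lineage == egg.mother_lineage for other in eggs
    )
    return f"{egg.sex}_in_{'related' if related_to_all else 'unrelated'}_mixed"


def _allocate_matings(
    k: int,
    male_sizes: np.ndarray,
    remaining: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distribute ``k`` matings over male cohorts.

    Each female picks a male uniformly at random, so cohorts draw matings in
    proportion to their head count; assignments are clipped to each cohort's
    remaining virility capacity and the excess redrawn among cohorts with
    capacity left.  Returns per-cohort counts summing to at most ``k``
    (less only if total capacity runs out).
    """
    alloc = np.zeros(male_sizes.size, dtype=np.int64)
    k_left = int(k)
    while k_left > 0:
        open_cap = remaining - alloc
        weights = np.where(open_cap > 0, male_sizes, 0).astype(float)
        total = weights.sum()
        if total <= 0:
            break
        if np.count_nonzero(weights) == 1:
            j = int(np.flatnonzero(weights)[0])
            take = min(k_left, int(open_cap[j]))
            alloc[j] += take
            k_left -= take
            continue
        draw = rng.multinomial(k_left, weights / total)
        take = np.minimum(draw, open_cap)
        alloc += take
        k_left -= int(take.sum())
    return alloc


def resolve_host(
    host: Host,
    host_limit: int,
    rng: np.random.Generator,
    survival: SurvivalDistributions | None = None,
    in_host_mating_ratio: float | None = None,
) -> BroodOutcome:
    """Resolve a host after the oviposition phase into its brood.

    More eggs than ``host_limit`` kill the host prematurely: no adults emerge.
    Otherwise each egg yields a clone whose size is drawn from the survival
    distribution for its context (single-sex / related-mixed /
    unrelated-mixed, by the egg's sex); daughters' strategies blend their
    parents' sex-choice values; then a fraction of the emerging females
    (``in_host_mating_ratio``, taken from each clone's strategy unless
    overridden) mate with a uniformly chosen emerging male of the same brood,
    within the males' virility limits.

    ``survival`` overrides the per-strategy survival distributions when given.
    """
    outcome = BroodOutcome(host=host)
    if not host.eggs:
        return outcome
    if len(host.eggs) > host_limit:
        host.alive = False
        outcome.premature_death = True
        return outcome

    single_sex = len({egg.sex for egg in host.eggs}) == 1
    male_cohorts: list[Cohort] = []
    female_clones: list[Cohort] = []
    for egg in host.eggs:
        context = _egg_context(egg, host.eggs, single_sex)
        dists = survival if survival is not None else egg.mother_strategy.survival
        mean, sd = dists.params(context)
        n = sample_clone_size(mean, sd, rng)
        if n == 0:
            continue
        if egg.sex == MALE:
            male_cohorts.append(
                Cohort(
                    size=n,
                    sex=MALE,
                    strategy=egg.mother_strategy,
                    label=egg.mother_label,
                    lineage=egg.mother_id,
                    virgins_son=egg.mother_virgin,
                )
            )
        else:
            if egg.father_strategy is None:
                raise ValueError("female egg from a virgin mother violates haplodiploidy")
            daughter = inherit_strategy(
                egg.mother_strategy,
                egg.father_strategy,
                egg.mother_strategy.strategy_inheritance,
            )
            female_clones.append(
                Cohort(
                    size=n,
                    sex=FEMALE,
                    strategy=daughter,
                    label=egg.mother_label,
                    lineage=egg.mother_id,
                    virgin=True,
                )
            )

    # In-host (pre-dispersal) mating: both sexes emerge together, so brood
    # males are available to brood females before anyone disperses.
    final_females: list[Cohort] = []
    male_sizes = np.array([c.size for c in male_cohorts], dtype=np.int64)
    for clone in female_clones:
        ratio = (clone.strategy.in_host_mating_ratio
                 if in_host_mating_ratio is None else in_host_mating_ratio)
        if ratio >= 1.0:
            willing = clone.size
        elif ratio <= 0.0:
            willing = 0
        else:
            willing = int(rng.binomial(clone.size, ratio))
        mated_total = 0
        if willing > 0 and male_cohorts:
            if len(male_cohorts) == 1:  # overwhelmingly the common case
                only = male_cohorts[0]
                mated_total = min(willing, only.mating_capacity())
                only.matings_used += mated_total
                mate_strategy, mate_strategies = only.strategy, None
            else:
                remaining = np.array(
                    [c.mating_capacity() for c in male_cohorts], dtype=np.int64)
                alloc = _allocate_matings(willing, male_sizes, remaining, rng)
                mated_total = int(alloc.sum())
                for j, count in enumerate(alloc):
                    male_cohorts[j].matings_used += int(count)
                nonzero = np.flatnonzero(alloc)
                if nonzero.size == 1:
                    mate_strategy = male_cohorts[int(nonzero[0])].strategy
                    mate_strategies = None
                else:
                    mate_strategy = None
                    mate_strategies = [
                        male_cohorts[j].strategy
                        for j in np.repeat(np.arange(alloc.size), alloc)
                    ]
            if mated_total > 0:
                final_females.append(
                    Cohort(
                        size=mated_total,
                        sex=FEMALE,
                        strategy=clone.strategy,
                        label=clone.label,
                        lineage=clone.lineage,
                        virgin=False,
                        mate_strategy=mate_strategy,
                        mate_strategies=mate_strategies,
                    )
                )
        if mated_total < clone.size:
            # Unmated emergers (whether unwilling or out of brood males)
            # disperse as virgins and may still mate in the dispersal pool.
            final_females.append(
                Cohort(
                    size=clone.size - mated_total,
                    sex=FEMALE,
                    strategy=clone.strategy,
                    label=clone.label,
                    lineage=clone.lineage,
                    virgin=True,
                )
            )

    outcome.cohorts = final_females + male_cohorts
    outcome.emerging_females = sum(c.size for c in final_females)
    outcome.emerging_males = int(male_sizes.sum())
    return outcome


def disperse_and_mate(
    cohorts: Sequence[Cohort],
    rng: np.random.Generator,
) -> list[Cohort]:
    """Dispersal mating: pair leftover virgin females with males at random.

    Every virgin female attempts to mate with a uniformly chosen male from
    the whole dispersing population; each male fertilizes at most ``virility``
    females (``virgin_son_virility`` for virgins' sons), counting any matings
    he already performed on the natal host.  When capacity falls short, the
    females that mate are a uniform random subset; the rest stay virgin and
    will lay only male eggs.
    """
    males: list[Cohort] = []
    virgins: list[Cohort] = []
    others: list[Cohort] = []
    for c in cohorts:
        if c.size <= 0:
            continue
        if c.sex == MALE:
            males.append(c)
        elif c.virgin:
            virgins.append(c)
        else:
            others.append(c)
    others += males
    if not males or not virgins:
        return others + virgins

    capacity = np.array([c.mating_capacity() for c in males], dtype=np.int64)
    male_sizes = np.array([c.size for c in males], dtype=np.int64)
    total_capacity = int(capacity.sum())
    virgin_sizes = np.array([c.size for c in virgins], dtype=np.int64)
    n_virgin = int(virgin_sizes.sum())
    n_mate = min(n_virgin, total_capacity)
    if n_mate == 0:
        return others + virgins

    if n_mate == n_virgin:
        mate_counts = virgin_sizes.copy()
    else:
        mate_counts = rng.multivariate_hypergeometric(virgin_sizes, n_mate)

    # Global male-cohort assignment, then a shuffled slot list partitioned
    # across the virgin cohorts -- equivalent to each mating female choosing
    # a male uniformly among those with capacity left.
    totals = _allocate_matings(n_mate, male_sizes, capacity, rng)
    for j, count in enumerate(totals):
        males[j].matings_used += int(count)
    slots = np.repeat(np.arange(len(males)), totals)
    rng.shuffle(slots)

    result: list[Cohort] = list(others)
    pos = 0
    for cohort, k in zip(virgins, mate_counts):
        seg = slots[pos:pos + int(k)]
        pos += int(k)
        mated_total = int(seg.size)
        if mated_total > 0:
            unique = np.unique(seg)
            if unique.size == 1:
                mate_strategy = males[int(unique[0])].strategy
                mate_strategies = None
            else:
                mate_strategy = None
                mate_strategies = [males[int(j)].strategy for j in seg]
            result.append(
                Cohort(
                    size=mated_total,
                    sex=FEMALE,
                    strategy=cohort.strategy,
                    label=cohort.label,
                    lineage=cohort.lineage,
                    virgin=False,
                    mate_strategy=mate_strategy,
                    mate_strategies=mate_strategies,
                )
            )
        if mated_total < cohort.size:
            result.append(
                Cohort(
                    size=cohort.size - mated_total,
                    sex=FEMALE,
                    strategy=cohort.strategy,
                    label=cohort.label,
                    lineage=cohort.lineage,
                    id_start=cohort.id_start,
                    virgin=True,
                )
            )
    return result


@dataclass
class GenerationStats:
    """Per-generation observables of the simulated population."""

    generation: int
    eggs_laid_male: int = 0
    eggs_laid_female: int = 0
    adults_male: int = 0
    adults_female: int = 0
    premature_host_deaths: int = 0
    hosts_parasitized: int = 0
    hosts_superparasitized: int = 0
    extinct: bool = False
    strategy_counts: dict[int, int] = field(default_factory=dict)

    @property
    def eggs_total(self) -> int:
        return self.eggs_laid_male + self.eggs_laid_female

    @property
    def adults_total(self) -> int:
        return self.adults_male + self.adults_female

    @property
    def primary_ratio(self) -> float:
        """Proportion of male eggs at laying; NaN if no eggs were laid."""
        total = self.eggs_total
        return self.eggs_laid_male / total if total else float("nan")

    @property
    def secondary_ratio(self) -> float:
        """Proportion of males among emerging adults; NaN if none emerged."""
        total = self.adults_total
        return self.adults_male / total if total else float("nan")

    @property
    def strategy_shares(self) -> dict[int, float]:
        total = self.adults_total
        if not total:
            return {label: 0.0 for label in self.strategy_counts}
        return {label: n / total for label, n in self.strategy_counts.items()}


@dataclass
class Environment:
    """The live state of a simulation: the adult cohorts and the id source."""

    cohorts: list[Cohort]
    ids: IdAllocator = field(default_factory=IdAllocator)
    generation: int = 0


def initial_population(
    strategies_with_counts: Sequence[tuple[Strategy, int]],
    config: SimulationConfig,
    ids: IdAllocator,
) -> list[Cohort]:
    """Found the population per the config's initial composition.

    Each founder female is her own size-1 cohort with a unique maternal
    lineage (founders are mutually unrelated); mated founders are paired with
    a male of their own strategy.  The strategy order defines the matrilineal
    labels used in the per-generation frequency table.
    """
    cohorts: list[Cohort] = []
    for label, (strategy, count) in enumerate(strategies_with_counts):
        if count < 1:
            raise ValueError(f"strategy {label} has non-positive count {count}")
        n_males = int(round(count * config.initial_sex_distribution))
        n_females = count - n_males
        n_virgin = int(round(n_females * config.initial_virgin_ratio))
        for i in range(n_females):
            wid = ids.take(1)
            cohorts.append(
                Cohort(
                    size=1,
                    sex=FEMALE,
                    strategy=strategy,
                    label=label,
                    lineage=wid,
                    id_start=wid,
                    virgin=i < n_virgin,
                    mate_strategy=None if i < n_virgin else strategy,
                )
            )
        if n_males:
            start = ids.take(n_males)
            cohorts.append(
                Cohort(size=n_males, sex=MALE, strategy=strategy, label=label,
                       lineage=start, id_start=start)
            )
    return cohorts


def _max_acceptable_eggs(threshold: float, influence: float, host_limit: int) -> int:
    """Largest prior egg count at which a host is still accepted (cheap bound
    used only to stop the presentation loop early once every host saturated)."""
    if influence <= 0:
        return host_limit + 1  # attractiveness never drops; capped by host death
    count = 0
    while 1.0 - influence * (count + 1) > threshold:
        count += 1
    return count


def step_generation(
    env: Environment,
    config: SimulationConfig,
    rng: np.random.Generator,
    host_sequence: Sequence[np.ndarray] | None = None,
) -> tuple[Environment, GenerationStats, list[BroodOutcome]]:
    """Advance the population by one non-overlapping generation.

    Returns the next environment (the offspring, already mated), the
    generation's statistics, and the per-host brood outcomes.  If no females
    are present the generation is flagged extinct and the next environment is
    empty.

    ``host_sequence`` fixes the host presented to each female at each time
    step (one array of host indices per step, indexed by female in cohort
    order); when given, females are processed in that fixed order, which is
    what exhaustive-enumeration oracles use to check the engine exactly.
    """
    stats = GenerationStats(generation=env.generation)
    cohorts = [c for c in env.cohorts if c.size > 0]
    female_cohorts = [c for c in cohorts if c.sex == FEMALE]
    if not female_cohorts:
        stats.extinct = True
        return Environment([], env.ids, env.generation + 1), stats, []

    ids = env.ids
    hosts = [Host() for _ in range(config.host_count)]
    host_egg_counts = np.zeros(config.host_count, dtype=np.int64)

    sizes = np.array([c.size for c in female_cohorts], dtype=np.int64)
    n_females = int(sizes.sum())
    cohort_index = np.repeat(np.arange(len(female_cohorts)), sizes)
    cohort_start = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    # Individual ids are materialized here, when females become layers; an
    # egg's mother id doubles as its offspring's maternal-lineage marker.
    female_ids = env.ids.take(n_females) + np.arange(n_females)
    for ci, c in enumerate(female_cohorts):
        c.id_start = int(female_ids[cohort_start[ci]])
    virgin = np.repeat([c.virgin for c in female_cohorts], sizes)
    lineage = np.repeat([c.lineage for c in female_cohorts], sizes)
    influence = np.repeat(
        [c.strategy.egg_count_influence for c in female_cohorts], sizes
    )
    lifespan = np.repeat([c.strategy.lifespan for c in female_cohorts], sizes)
    eggs_laid = np.zeros(n_females, dtype=np.int64)

    threshold = config.host_acceptance_threshold
    min_influence = float(influence.min())
    saturation_count = _max_acceptable_eggs(threshold, min_influence,
                                            config.host_limit)
    # With one shared egg-count influence (the canonical situation: it never
    # evolves) host acceptability is female-independent, so the laying scan
    # can stop as soon as every host has saturated.
    uniform_influence = min_influence > 0 and float(influence.max()) == min_influence
    open_hosts = config.host_count

    for t in range(int(lifespan.max())):
        active = np.flatnonzero(eggs_laid < lifespan)
        if active.size == 0:
            break
        if min_influence > 0 and host_egg_counts.min() > saturation_count:
            break  # no host can be accepted by anyone any more
        if host_sequence is not None:
            drawn_all = np.asarray(host_sequence[t])
            order = active  # fixed female order for oracle comparability
            drawn = drawn_all[order]
        else:
            order = active[rng.permutation(active.size)]
            drawn = rng.integers(0, config.host_count, size=order.size)
        # Pre-filter on the counts at the start of the step: attractiveness
        # only falls within a step, so this removes no valid candidate.
        candidate = 1.0 - influence[order] * host_egg_counts[drawn] > threshold
        for fi, hi in zip(order[candidate], drawn[candidate]):
            if uniform_influence and open_hosts == 0:
                break
            if 1.0 - influence[fi] * host_egg_counts[hi] <= threshold:
                continue
            cohort = female_cohorts[cohort_index[fi]]
            host = hosts[hi]
            if virgin[fi]:
                egg_sex = MALE
            else:
                key = host_state_key(host, int(lineage[fi]), config.info_level)
                egg_sex = (MALE if rng.random() < cohort.strategy.sex_choice[key]
                           else FEMALE)
            host.eggs.append(
                Egg(
                    mother_id=int(female_ids[fi]),
                    sex=egg_sex,
                    clone_id=ids.take(1),
                    mother_lineage=int(lineage[fi]),
                    mother_label=cohort.label,
                    mother_strategy=cohort.strategy,
                    father_strategy=(
                        None if virgin[fi]
                        else cohort.mate_of(int(fi - cohort_start[cohort_index[fi]]))
                    ),
                    mother_virgin=bool(virgin[fi]),
                )
            )
            host_egg_counts[hi] += 1
            eggs_laid[fi] += 1
            if host_egg_counts[hi] == saturation_count + 1:
                open_hosts -= 1
            if egg_sex == MALE:
                stats.eggs_laid_male += 1
            else:
                stats.eggs_laid_female += 1

    broods: list[BroodOutcome] = []
    offspring: list[Cohort] = []
    for host in hosts:
        if not host.eggs:
            continue
        stats.hosts_parasitized += 1
        if len(host.eggs) >= 2:
            stats.hosts_superparasitized += 1
        outcome = resolve_host(host, config.host_limit, rng)
        broods.append(outcome)
        if outcome.premature_death:
            stats.premature_host_deaths += 1
        else:
            offspring.extend(outcome.cohorts)
            stats.adults_male += outcome.emerging_males
            stats.adults_female += outcome.emerging_females

    counts: dict[int, int] = {}
    for c in offspring:
        counts[c.label] = counts.get(c.label, 0) + c.size
    stats.strategy_counts = counts

    if stats.adults_female == 0:
        stats.extinct = True
        return Environment([], ids, env.generation + 1), stats, broods

    offspring = disperse_and_mate(offspring, rng)
    return Environment(offspring, ids, env.generation + 1), stats, broods


@dataclass
class SimulationResult:
    """Outcome of a multi-generation run: the stats series and final state."""

    stats: list[GenerationStats]
    final: Environment
    extinct: bool
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-generation table, one frequency column per strategy label."""
        labels = sorted({lb for s in self.stats for lb in s.strategy_counts})
        rows = []
        for s in self.stats:
            row = {
                "generation": s.generation,
                "eggs_male": s.eggs_laid_male,
                "eggs_female": s.eggs_laid_female,
                "adults_male": s.adults_male,
                "adults_female": s.adults_female,
                "premature_host_deaths": s.premature_host_deaths,
                "hosts_parasitized": s.hosts_parasitized,
                "hosts_superparasitized": s.hosts_superparasitized,
                "primary_ratio": s.primary_ratio,
                "secondary_ratio": s.secondary_ratio,
                "extinct": s.extinct,
            }
            shares = s.strategy_shares
            for lb in labels:
                row[f"share_{lb}"] = shares.get(lb, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def run_simulation(
    config: SimulationConfig,
    strategies_with_counts: Sequence[tuple[Strategy, int]],
    rng_seed: int | None = None,
) -> SimulationResult:
    """Run ``config.generations`` generations (or stop at extinction).

    Deterministic given the seed (``config.rng_seed`` unless overridden).
    """
    config.validate()
    if not strategies_with_counts:
        raise ValueError("at least one strategy with a positive count is required")
    keys = set(sex_choice_keys(config.info_level))
    for strategy, _count in strategies_with_counts:
        strategy.validate()
        missing = keys - set(strategy.sex_choice)
        if missing:
            raise ValueError(
                f"strategy sex_choice lacks keys {sorted(missing)} required by "
                f"info_level {config.info_level!r}")

    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    ids = IdAllocator()
    env = Environment(initial_population(strategies_with_counts, config, ids), ids)

    stats_series: list[GenerationStats] = []
    extinct = False
    for _ in range(config.generations):
        env, stats, _broods = step_generation(env, config, rng)
        stats_series.append(stats)
        logger.debug(
            "generation %d: %d eggs (%d male), %d adults (%d male), "
            "%d premature host deaths", stats.generation, stats.eggs_total,
            stats.eggs_laid_male, stats.adults_total, stats.adults_male,
            stats.premature_host_deaths)
        if stats.extinct:
            extinct = True
            logger.info("population extinct at generation %d", stats.generation)
            break
    return SimulationResult(stats_series, env, extinct, config)
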