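"""Core domain types for the polyembryonic-parasitoid sex-allocation model.

The model world contains three kinds of entities: *hosts* (moth eggs that can
receive parasitoid eggs), *wasps* (haplodiploid parasitoids; fertilized eggs
become diploid daughters, unfertilized eggs haploid sons) and *strategies*
(the heritable parameters of a wasp lineage, chiefly the probability of
laying a male egg conditional on the sensed state of the host).

Each parasitoid egg cleaves into a clone of genetically identical same-sex
wasps (polyembryony).  The number of adults emerging from one egg is drawn
from a context-dependent normal distribution, truncated at zero and rounded:
female clones are larger than male clones, and male clones shrink further in
mixed-sex broods that contain unrelated competitors, which is how the
soldier larvae (precocious female larvae that kill unrelated competitors)
enter the model.

Only the sex-choice probabilities evolve; every other strategy component is
held constant and copied from a template.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "INFO_NONE",
    "INFO_RELATEDNESS",
    "INFO_SEX_AND_RELATEDNESS",
    "INFO_LEVELS",
    "EMPTY",
    "PARASITIZED",
    "SURVIVAL_CONTEXTS",
    "SurvivalDistributions",
    "Strategy",
    "SimulationConfig",
    "Egg",
    "Host",
    "Cohort",
    "Wasp",
    "IdAllocator",
    "sex_choice_keys",
    "default_template",
    "make_random_strategy",
    "host_state_key",
    "sample_clone_size",
]

MALE = "male"
FEMALE = "female"

#: Host-sensing information levels: (a) a female only tells empty from
#: parasitized hosts, (b) she additionally senses the relatedness of the
#: occupants, (c) she senses relatedness and sex of the occupants.
INFO_NONE = "none"
INFO_RELATEDNESS = "relatedness"
INFO_SEX_AND_RELATEDNESS = "sex_and_relatedness"
INFO_LEVELS = (INFO_NONE, INFO_RELATEDNESS, INFO_SEX_AND_RELATEDNESS)

EMPTY = "empty"
PARASITIZED = "parasitized"

_RELATEDNESS_STATES = ("related", "unrelated", "mixed")
_SEX_STATES = (MALE, FEMALE, "mixed")

#: Survival (clone proliferation) contexts: single-sex broods versus mixed-sex
#: broods with related or unrelated competitors, by the sex of the egg.
MALE_SINGLE_SEX = "male_single_sex"
FEMALE_SINGLE_SEX = "female_single_sex"
MALE_IN_RELATED_MIXED = "male_in_related_mixed"
FEMALE_IN_RELATED_MIXED = "female_in_related_mixed"
MALE_IN_UNRELATED_MIXED = "male_in_unrelated_mixed"
FEMALE_IN_UNRELATED_MIXED = "female_in_unrelated_mixed"
SURVIVAL_CONTEXTS = (
    MALE_SINGLE_SEX,
    FEMALE_SINGLE_SEX,
    MALE_IN_RELATED_MIXED,
    FEMALE_IN_RELATED_MIXED,
    MALE_IN_UNRELATED_MIXED,
    FEMALE_IN_UNRELATED_MIXED,
)


def sex_choice_keys(info_level: str) -> tuple[str, ...]:
    """Canonical, ordered key set of the sex-choice map at an information level.

    Under ``none`` a female distinguishes only empty from parasitized hosts;
    under ``relatedness`` parasitized hosts split by occupant relatedness
    (related / unrelated / mixed); under ``sex_and_relatedness`` they split by
    the full relatedness x occupant-sex cross.
    """
    if info_level == INFO_NONE:
        return (EMPTY, PARASITIZED)
    if info_level == INFO_RELATEDNESS:
        return (EMPTY,) + _RELATEDNESS_STATES
    if info_level == INFO_SEX_AND_RELATEDNESS:
        return (EMPTY,) + tuple(
            f"{rel}_{sex}"
            for rel, sex in itertools.product(_RELATEDNESS_STATES, _SEX_STATES)
        )
    raise ValueError(f"unknown info_level {info_level!r}; expected one of {INFO_LEVELS}")


@dataclass(frozen=True)
class SurvivalDistributions:
    """Per-context (mean, sd) of the number of adults emerging from one egg.

    Defaults: the single-sex clone sizes are the published field estimates
    (45.7 +- 10.9 adults per female clone, 32.4 +- 10.4 per male clone); the
    unrelated-mixed values are stand-ins calibrated so males make up roughly a
    third of the adults in mixed-sex broods, reflecting soldier attacks on
    unrelated male clones.  Related mixed broods behave like single-sex broods
    because soldiers spare kin.
    """

    male_single_sex: tuple[float, float] = (32.4, 10.4)
    female_single_sex: tuple[float, float] = (45.7, 10.9)
    male_in_related_mixed: tuple[float, float] = (32.4, 10.4)
    female_in_related_mixed: tuple[float, float] = (45.7, 10.9)
    male_in_unrelated_mixed: tuple[float, float] = (20.0, 8.0)
    female_in_unrelated_mixed: tuple[float, float] = (40.0, 10.0)

    def params(self, context: str) -> tuple[float, float]:
        if context not in SURVIVAL_CONTEXTS:
            raise ValueError(f"unknown survival context {context!r}")
        return getattr(self, context)

    @classmethod
    def symmetric(cls, mean: float = 45.7, sd: float = 10.9) -> "SurvivalDistributions":
        """All six contexts identical -- equal proliferation and survival of the sexes."""
        return cls(**{c: (mean, sd) for c in SURVIVAL_CONTEXTS})

    def validate(self) -> None:
        for context in SURVIVAL_CONTEXTS:
            mean, sd = self.params(context)
            if mean < 0 or sd < 0:
                raise ValueError(f"survival {context}: mean and sd must be >= 0")


@dataclass
class Strategy:
    """Heritable parameters of a wasp lineage.

    ``sex_choice`` maps a host-state key (see :func:`sex_choice_keys`) to the
    probability of laying a male egg in a host in that state.  Only this map
    evolves; the remaining fields are life-history constants shared by every
    lineage in a run.
    """

    sex_choice: dict[str, float]
    #: Attractiveness decrement per egg already in a host (0 = ignores prior eggs).
    egg_count_influence: float = 0.3
    #: Fraction of freshly emerged females that mate on the natal host.
    in_host_mating_ratio: float = 1.0
    #: Weight of the father's sex-choice values in a daughter's strategy.
    strategy_inheritance: float = 0.5
    #: Females a mated female's son can fertilize.  The default makes the
    #: mating market binding (males are a limiting resource), which is what
    #: lets the sexes' unequal developmental prospects feed back on the
    #: evolved allocation; see the methods note for the calibration rationale.
    virility: int = 1
    #: Females a virgin's son can fertilize (never more than ``virility``).
    virgin_son_virility: int = 1
    #: Eggs a female can lay == number of time steps she is active.
    lifespan: int = 20
    survival: SurvivalDistributions = field(default_factory=SurvivalDistributions)

    def validate(self) -> None:
        for key, p in self.sex_choice.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sex_choice[{key!r}] = {p} outside [0, 1]")
        if not 0.0 <= self.in_host_mating_ratio <= 1.0:
            raise ValueError("in_host_mating_ratio outside [0, 1]")
        if not 0.0 <= self.strategy_inheritance <= 1.0:
            raise ValueError("strategy_inheritance outside [0, 1]")
        if self.egg_count_influence < 0:
            raise ValueError("egg_count_influence must be >= 0")
        if self.virility < 0 or self.virgin_son_virility < 0:
            raise ValueError("virility values must be >= 0")
        if self.virgin_son_virility > self.virility:
            raise ValueError("virgin_son_virility must not exceed virility")
        if self.lifespan < 1:
            raise ValueError("lifespan must be >= 1")
        self.survival.validate()

    def sex_choice_vector(self, keys: tuple[str, ...]) -> np.ndarray:
        return np.array([self.sex_choice[k] for k in keys], dtype=float)


def default_template(info_level: str = INFO_SEX_AND_RELATEDNESS, **overrides) -> Strategy:
    """A template strategy with every sex-choice probability at 0.5."""
    template = Strategy(sex_choice={k: 0.5 for k in sex_choice_keys(info_level)})
    return replace(template, **overrides) if overrides else template


@dataclass
class SimulationConfig:
    """Environment-level constants of one simulation run."""

    #: Hosts replenished at the start of every generation.
    host_count: int = 200
    #: Eggs beyond which a host dies prematurely, killing all its eggs.
    host_limit: int = 3
    generations: int = 100
    #: Wasps seeded per strategy at generation zero.
    initial_wasp_count: int = 100
    #: Proportion of males among the seeded wasps.
    initial_sex_distribution: float = 0.5
    #: Proportion of the seeded females that start unmated.
    initial_virgin_ratio: float = 0.0
    #: A host is accepted iff its attractiveness strictly exceeds this; low
    #: thresholds admit already-parasitized hosts, i.e. superparasitism.
    host_acceptance_threshold: float = 0.5
    info_level: str = INFO_SEX_AND_RELATEDNESS
    rng_seed: int = 0

    def validate(self) -> None:
        if self.host_count < 1:
            raise ValueError("host_count must be >= 1")
        if self.host_limit < 1:
            raise ValueError("host_limit must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.initial_wasp_count < 1:
            raise ValueError("initial_wasp_count must be >= 1")
        for name in ("initial_sex_distribution", "initial_virgin_ratio",
                     "host_acceptance_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} outside [0, 1]")
        if self.info_level not in INFO_LEVELS:
            raise ValueError(
                f"info_level {self.info_level!r} not one of {INFO_LEVELS}")


class IdAllocator:
    """Hands out contiguous blocks of unique integer identifiers."""

    __slots__ = ("next_id",)

    def __init__(self, start: int = 0) -> None:
        self.next_id = start

    def take(self, n: int = 1) -> int:
        start = self.next_id
        self.next_id += n
        return start


@dataclass(slots=True)
class Egg:
    """A parasitoid egg inside a host.

    ``mother_lineage`` is the laying female's maternal-lineage marker (her
    mother's id; a founder's own id): two eggs are related iff their mothers
    are the same individual or sisters.  ``father_strategy`` is the strategy
    of the mother's mate and is ``None`` for eggs of virgin mothers, which are
    necessarily male (haplodiploidy).
    """

    mother_id: int
    sex: str
    clone_id: int
    mother_lineage: int
    mother_label: int
    mother_strategy: Strategy
    father_strategy: Strategy | None
    mother_virgin: bool


@dataclass(slots=True)
class Host:
    """A host egg: an ordered container of parasitoid eggs."""

    eggs: list[Egg] = field(default_factory=list)
    alive: bool = True


@dataclass(slots=True)
class Cohort:
    """A group of wasps identical in every state variable.

    A cohort starts as the clone emerging from one egg and may later be split
    by mating into a mated part and a virgin part.  ``lineage`` is the
    members' mother's id and doubles as the maternal-lineage marker for
    relatedness sensing.  Mated members either all share one mate cohort
    (``mate_strategy``) or carry per-member mates (``mate_strategies``,
    indexed by member offset); either way a member's mate is fixed for life.
    ``id_start`` is the first individual id of the block assigned to the
    members, or -1 while ids have not been needed yet (ids are only
    materialized for females when they lay).
    """

    size: int
    sex: str
    strategy: Strategy
    label: int
    lineage: int
    id_start: int = -1
    virgin: bool = False
    virgins_son: bool = False
    mate_strategy: Strategy | None = None
    #: Per-member mate strategies (length ``size``); overrides ``mate_strategy``.
    mate_strategies: list[Strategy] | None = None
    #: Matings already performed by this (male) cohort, summed over members.
    matings_used: int = 0

    def mate_of(self, offset: int) -> Strategy | None:
        """Strategy of the mate of member ``offset`` (None if unmated)."""
        if self.mate_strategies is not None:
            return self.mate_strategies[offset]
        return self.mate_strategy

    def mating_capacity(self) -> int:
        if self.sex != MALE:
            return 0
        per_male = (self.strategy.virgin_son_virility if self.virgins_son
                    else self.strategy.virility)
        return max(0, self.size * per_male - self.matings_used)

    def iter_wasps(self) -> Iterator["Wasp"]:
        for i in range(self.size):
            yield Wasp(
                id=self.id_start + i,
                sex=self.sex,
                mother_id=self.lineage,
                strategy=self.strategy,
                lifespan=self.strategy.lifespan,
                virgin=self.virgin if self.sex == FEMALE else False,
                virgins_son=self.virgins_son,
                lineage=self.lineage,
            )


@dataclass(slots=True)
class Wasp:
    """An individual wasp record (a per-member view of a :class:`Cohort`).

    Haploid males develop from unfertilized eggs and therefore have no father;
    ``father_id`` is always ``None`` for males.
    """

    id: int
    sex: str
    mother_id: int | None
    strategy: Strategy
    lifespan: int
    father_id: int | None = None
    eggs_laid: int = 0
    virgin: bool = False
    virgins_son: bool = False
    females_fertilized: int = 0
    lineage: int | None = None


def make_random_strategy(
    rng: np.random.Generator,
    template: Strategy,
    info_level: str = INFO_SEX_AND_RELATEDNESS,
    scalar: bool = False,
) -> Strategy:
    """Draw a strategy with uniform [0, 1] sex-choice values.

    Every non-evolving field is copied from ``template``; only the sex-choice
    map is randomized.  By default each host-state key gets an independent
    uniform draw (in canonical key order, so equal seeds give identical
    strategies); with ``scalar=True`` a single uniform draw is shared by all
    keys — the strategy is one unconditional sex-allocation value, which is
    how tournament starting strategies are seeded.  Because inheritance is
    component-wise and all components start equal, scalar strategies stay
    scalar under any amount of recombination.
    """
    keys = sex_choice_keys(info_level)
    if scalar:
        values = np.full(len(keys), rng.uniform(0.0, 1.0))
    else:
        values = rng.uniform(0.0, 1.0, size=len(keys))
    return replace(template, sex_choice=dict(zip(keys, values)))


def _lineage_of(observer) -> int:
    if isinstance(observer, (int, np.integer)):
        return int(observer)
    lineage = getattr(observer, "lineage", None)
    if lineage is None:
        raise TypeError("observer must be an int lineage id or expose .lineage")
    return int(lineage)


def host_state_key(host: Host, observer, info_level: str) -> str:
    """The sensed state of ``host`` from the perspective of an observing female.

    Relatedness of each egg is judged against the observer's maternal lineage
    (the egg's mother is the observer herself or one of her sisters); occupant
    sexes and relatedness are each classified as uniform or mixed and then
    coarsened according to the information level.  Raises on a dead host,
    which is not a valid oviposition target.
    """
    if not host.alive:
        raise ValueError("cannot assess a dead host: invalid oviposition target")
    if not host.eggs:
        return EMPTY
    if info_level == INFO_NONE:
        return PARASITIZED
    lineage = _lineage_of(observer)
    related_flags = {egg.mother_lineage == lineage for egg in host.eggs}
    relatedness = ("mixed" if len(related_flags) == 2
                   else "related" if True in related_flags else "unrelated")
    if info_level == INFO_RELATEDNESS:
        return relatedness
    if info_level != INFO_SEX_AND_RELATEDNESS:
        raise ValueError(
            f"unknown info_level {info_level!r}; expected one of {INFO_LEVELS}")
    sexes = {egg.sex for egg in host.eggs}
    sex_state = "mixed" if len(sexes) == 2 else next(iter(sexes))
    return f"{relatedness}_{sex_state}"


def sample_clone_size(mean: float, sd: float, rng: np.random.Generator) -> int:
    """Number of adults emerging from one egg: normal draw, floored at 0, rounded.

    With ``sd == 0`` the draw is deterministic (the rounded mean).
    """
    if mean < 0 or sd < 0:
        raise ValueError("clone-size mean and sd must be >= 0")
    draw = rng.normal(mean, sd) if sd > 0 else mean
    return int(round(max(0.0, draw)))
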