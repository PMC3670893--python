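"""Brood-census sex-ratio estimators and a synthetic census generator.

A brood census classifies each host's emerging brood as all-male,
all-female or mixed-sex and counts the wasps per class.  Because mixed-sex
broods can only arise from superparasitized hosts (two clones of opposite
sex), the proportion of mixed-sex broods estimates the frequency of
superparasitism; assuming the same fraction of single-sex broods also came
from two same-sex eggs, the primary sex ratio (proportion of male *eggs*)
can be backed out of brood class counts alone.  The secondary sex ratio
(proportion of male *adults*) uses the per-class wasp totals and the
fraction of males among mixed-brood adults.

The synthetic generator emulates only the statistical structure these
estimators assume — hosts receiving one or two eggs, egg sex from a primary
ratio, emergence from per-context survival distributions — not the full
evolutionary simulation (no soldiers beyond the survival contexts, no
strategy dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import SurvivalDistributions, sample_clone_size

__all__ = [
    "BroodCensus",
    "mixed_brood_proportion",
    "estimate_primary_sex_ratio",
    "estimate_secondary_sex_ratio",
    "generate_brood_census",
    "arcsine_sqrt",
    "read_census",
    "write_census",
]

#: Column schema of a per-brood census table.
CENSUS_COLUMNS = ("brood_id", "n_males", "n_females")


@dataclass
class BroodCensus:
    """Counts of all-male / all-female / mixed-sex broods and their wasps."""

    n_male_broods: int
    n_female_broods: int
    n_mixed_broods: int
    wasps_in_male_broods: int
    wasps_in_female_broods: int
    wasps_in_mixed_broods: int
    #: Optional per-brood table (see ``CENSUS_COLUMNS``); synthetic censuses
    #: add the true egg composition per brood.
    records: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("n_male_broods", "n_female_broods", "n_mixed_broods",
                     "wasps_in_male_broods", "wasps_in_female_broods",
                     "wasps_in_mixed_broods"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_broods(self) -> int:
        return self.n_male_broods + self.n_female_broods + self.n_mixed_broods

    @property
    def total_wasps(self) -> int:
        return (self.wasps_in_male_broods + self.wasps_in_female_broods
                + self.wasps_in_mixed_broods)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "BroodCensus":
        """Aggregate a per-brood table (``n_males``/``n_females`` per brood)."""
        males = records["n_males"].to_numpy()
        females = records["n_females"].to_numpy()
        if (males < 0).any() or (females < 0).any():
            raise ValueError("per-brood counts must be >= 0")
        nonempty = (males + females) > 0
        males, females = males[nonempty], females[nonempty]
        is_male = (males > 0) & (females == 0)
        is_female = (females > 0) & (males == 0)
        is_mixed = (males > 0) & (females > 0)
        return cls(
            n_male_broods=int(is_male.sum()),
            n_female_broods=int(is_female.sum()),
            n_mixed_broods=int(is_mixed.sum()),
            wasps_in_male_broods=int(males[is_male].sum()),
            wasps_in_female_broods=int(females[is_female].sum()),
            wasps_in_mixed_broods=int((males + females)[is_mixed].sum()),
            records=records,
        )


def mixed_brood_proportion(census: BroodCensus) -> float:
    """Proportion of mixed-sex broods — the census estimate of the
    superparasitized-host frequency."""
    total = census.total_broods
    if total == 0:
        raise ValueError("census contains no broods")
    return census.n_mixed_broods / total


def estimate_primary_sex_ratio(
    census: BroodCensus,
    p_super: float = 0.35,
    method: str = "expectation",
) -> float:
    """Estimated proportion of male eggs from brood class counts.

    Assumes a fraction ``p_super`` of the single-sex broods arose from two
    same-sex eggs and every mixed-sex brood from one male plus one female
    egg.  Under ``method="expectation"`` each single-sex brood therefore
    represents ``1 + p_super`` eggs in expectation:

        male eggs  = (1 + p_super) * n_male_broods + n_mixed_broods
        total eggs = (1 + p_super) * (n_male_broods + n_female_broods)
                     + 2 * n_mixed_broods

    ``method="integer"`` instead allocates a whole number of double-egg
    broods per class, ``round(p_super * n_class)``.
    """
    if census.total_broods == 0:
        raise ValueError("census contains no broods")
    if not 0.0 <= p_super <= 1.0:
        raise ValueError("p_super must lie in [0, 1]")
    n_m, n_f, n_x = (census.n_male_broods, census.n_female_broods,
                     census.n_mixed_broods)
    if method == "expectation":
        male_eggs = (1.0 + p_super) * n_m + n_x
        total_eggs = (1.0 + p_super) * (n_m + n_f) + 2.0 * n_x
    elif method == "integer":
        male_eggs = n_m + round(p_super * n_m) + n_x
        total_eggs = (n_m + round(p_super * n_m) + n_f + round(p_super * n_f)
                      + 2 * n_x)
    else:
        raise ValueError(f"unknown method {method!r}; use 'expectation' or 'integer'")
    return male_eggs / total_eggs


def estimate_secondary_sex_ratio(
    census: BroodCensus,
    male_frac_mixed: float = 1.0 / 3.0,
) -> float:
    """Estimated proportion of male adults:
    (wasps in all-male broods + male_frac_mixed * wasps in mixed broods) / all wasps."""
    total = census.total_wasps
    if total == 0:
        raise ValueError("census contains no wasps")
    if not 0.0 <= male_frac_mixed <= 1.0:
        raise ValueError("male_frac_mixed must lie in [0, 1]")
    return (census.wasps_in_male_broods
            + male_frac_mixed * census.wasps_in_mixed_broods) / total


def generate_brood_census(
    true_primary_ratio: float,
    p_host_double_egg: float,
    n_hosts: int,
    rng: np.random.Generator,
    survival: SurvivalDistributions | None = None,
) -> BroodCensus:
    """Synthesize a brood census with known ground truth.

    Each host receives two eggs with probability ``p_host_double_egg``, else
    one; each egg is male with probability ``true_primary_ratio``; emergence
    counts per egg are drawn from the survival distributions (single-sex
    context for same-sex broods, unrelated-mixed context for mixed broods,
    since co-parasitizing clones are typically unrelated).  Broods are
    classified by the sexes that actually emerge, so a mixed-egg brood whose
    male clone yields no adults is recorded — as in a real census — as
    all-female.  Hosts with no emerging adults are not observed as broods.

    The per-brood record table keeps the true egg composition, so the
    realized single-sex double-egg fraction (the correct ``p_super`` for
    :func:`estimate_primary_sex_ratio`) can be recovered.
    """
    if not 0.0 <= true_primary_ratio <= 1.0:
        raise ValueError("true_primary_ratio must lie in [0, 1]")
    if not 0.0 <= p_host_double_egg <= 1.0:
        raise ValueError("p_host_double_egg must lie in [0, 1]")
    if n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    dists = survival if survival is not None else SurvivalDistributions()

    n_eggs = np.where(rng.random(n_hosts) < p_host_double_egg, 2, 1)
    rows = []
    for i in range(n_hosts):
        sexes = rng.random(n_eggs[i]) < true_primary_ratio  # True = male egg
        male_eggs = int(sexes.sum())
        female_eggs = int(n_eggs[i]) - male_eggs
        mixed = male_eggs > 0 and female_eggs > 0
        n_males = n_females = 0
        for is_male in sexes:
            if is_male:
                context = "male_in_unrelated_mixed" if mixed else "male_single_sex"
                n_males += sample_clone_size(*dists.params(context), rng)
            else:
                context = "female_in_unrelated_mixed" if mixed else "female_single_sex"
                n_females += sample_clone_size(*dists.params(context), rng)
        rows.append({
            "brood_id": i,
            "n_males": n_males,
            "n_females": n_females,
            "male_eggs": male_eggs,
            "female_eggs": female_eggs,
        })
    records = pd.DataFrame(rows)
    observed = records[(records["n_males"] + records["n_females"]) > 0]
    return BroodCensus.from_records(observed.reset_index(drop=True))


def realized_single_sex_double_fraction(census: BroodCensus) -> float:
    """Among broods *observed* as single-sex, the fraction that truly held
    two eggs — the unbiased ``p_super`` for the primary-ratio estimator.
    Requires a synthetic census whose records carry the true egg counts."""
    records = census.records
    if records is None or "male_eggs" not in records:
        raise ValueError("census records with true egg counts are required")
    single = records[(records["n_males"] == 0) | (records["n_females"] == 0)]
    if len(single) == 0:
        raise ValueError("census has no single-sex broods")
    return float(((single["male_eggs"] + single["female_eggs"]) == 2).mean())


def arcsine_sqrt(proportions) -> np.ndarray:
    """Arcsine–square-root transform, the classical variance stabilizer for
    proportions ahead of ANOVA."""
    p = np.asarray(proportions, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def read_census(path: str | Path) -> BroodCensus:
    """Read a per-brood census table (CSV with ``brood_id,n_males,n_females``)."""
    frame = pd.read_csv(path)
    missing = set(CENSUS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"census table lacks columns {sorted(missing)}")
    return BroodCensus.from_records(frame)


def write_census(census: BroodCensus, path: str | Path) -> None:
    if census.records is None:
        raise ValueError("census has no per-brood records to write")
    census.records.to_csv(path, index=False)
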