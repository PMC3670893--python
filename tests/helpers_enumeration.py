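"""Exhaustive-enumeration oracle for one generation of the wasp lifecycle.

An independent, deliberately naive per-individual reimplementation of the
generation schedule, valid only for degenerate configurations where every
random element is pinned down:

* clone-size SDs are zero (deterministic clone sizes),
* every sex-choice probability is 0 or 1,
* the in-host mating ratio is 0 or 1,
* the host presented to each female at each step is given explicitly.

Under those conditions the brood outcome of every host is a pure function of
the inputs, so the engine can be checked for exact agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class OracleFemale:
    virgin: bool
    p_male: float  # 0.0 or 1.0; ignored for virgins
    lineage: int   # unique per founder


@dataclass
class OracleBrood:
    eggs: list[tuple[int, str]] = field(default_factory=list)  # (female idx, sex)
    premature: bool = False
    males: int = 0
    females: int = 0


def enumerate_generation(
    females: list[OracleFemale],
    host_sequence: list[list[int]],
    n_hosts: int,
    threshold: float,
    influence: float,
    host_limit: int,
    lifespan: int,
    clone_sizes: dict[str, int],
    in_host_mating_ratio: float,
    virility: int,
) -> dict:
    """Replay the laying phase and resolve every host by hand.

    ``clone_sizes`` maps the six survival contexts to their deterministic
    clone sizes.  Returns per-host broods plus population totals, including
    the mated/virgin split of the emerging females (in-host mating only;
    dispersal mating at ratio 0 or with no males is a no-op).
    """
    hosts = [OracleBrood() for _ in range(n_hosts)]
    eggs_laid = [0] * len(females)
    egg_counts = [0] * n_hosts

    for t in range(lifespan):
        for i, female in enumerate(females):
            if eggs_laid[i] >= lifespan:
                continue
            h = host_sequence[t][i]
            if 1.0 - influence * egg_counts[h] <= threshold:
                continue
            if female.virgin:
                sex = "male"
            else:
                sex = "male" if female.p_male >= 1.0 else "female"
            hosts[h].eggs.append((i, sex))
            egg_counts[h] += 1
            eggs_laid[i] += 1

    totals = {"males": 0, "females": 0, "premature": 0,
              "mated_females": 0, "virgin_females": 0,
              "eggs_male": 0, "eggs_female": 0}
    for brood in hosts:
        if not brood.eggs:
            continue
        for _, sex in brood.eggs:
            totals[f"eggs_{sex}"] += 1
        if len(brood.eggs) > host_limit:
            brood.premature = True
            totals["premature"] += 1
            continue
        sexes = {sex for _, sex in brood.eggs}
        single = len(sexes) == 1
        for idx, sex in brood.eggs:
            if single:
                context = f"{sex}_single_sex"
            else:
                related_to_all = all(
                    other_idx == idx or females[other_idx].lineage == females[idx].lineage
                    for other_idx, _ in brood.eggs
                )
                context = f"{sex}_in_{'related' if related_to_all else 'unrelated'}_mixed"
            n = clone_sizes[context]
            if sex == "male":
                brood.males += n
            else:
                brood.females += n
        totals["males"] += brood.males
        totals["females"] += brood.females
        if in_host_mating_ratio >= 1.0 and brood.males > 0:
            mated = min(brood.females, brood.males * virility)
        else:
            mated = 0
        totals["mated_females"] += mated
        totals["virgin_females"] += brood.females - mated
    return {"hosts": hosts, "totals": totals}
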