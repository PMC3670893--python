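"""Scenario presets and host-acceptance threshold sweeps.

Three scenarios probe how the competitive asymmetry between the sexes and
the mating structure shape the evolved sex allocation:

``symmetric``
    Equal proliferation and survival of male and female larvae (all six
    survival contexts share the female single-sex parameters) and mating on
    the natal host before dispersal — the classic Local Mate Competition
    setting, expected to favor female-biased allocation.
``asymmetric_premating``
    Female clones outnumber male clones and soldiers suppress males in
    superparasitized hosts; mating still happens before dispersal.
``asymmetric_postmating``
    Same asymmetry, but all mating happens after dispersal.

Each scenario is swept over a grid of host-acceptance thresholds: a *low*
threshold admits already-parasitized hosts, so low thresholds mean high
superparasitism and more between-clone competition.  Extreme thresholds can
destabilize the population (every host overcrowded and dying, or no host
ever accepted); instability is recorded as an output state, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evolution import (
    GENERATION_CAP,
    RoundExtinctionError,
    ViabilityError,
    tournament,
)
from .model_core import SimulationConfig, Strategy, SurvivalDistributions, default_template

__all__ = [
    "SCENARIOS",
    "ScenarioPreset",
    "SweepResult",
    "scenario_config",
    "threshold_sweep",
    "plot_sweep",
    "DEFAULT_THRESHOLDS",
]

#: Default nine-threshold grid; with the default egg-count influence of 0.3
#: it spans "only empty hosts accepted" down to "hosts accepted until they
#: overcrowd and die".
DEFAULT_THRESHOLDS = tuple(round(0.05 + 0.1 * i, 2) for i in range(9))


@dataclass(frozen=True)
class ScenarioPreset:
    """Survival and mating-structure overrides defining one scenario."""

    name: str
    survival: SurvivalDistributions
    in_host_mating_ratio: float
    description: str = ""


SCENARIOS: dict[str, ScenarioPreset] = {
    "symmetric": ScenarioPreset(
        name="symmetric",
        survival=SurvivalDistributions.symmetric(45.7, 10.9),
        in_host_mating_ratio=1.0,
        description="equal proliferation/survival of the sexes; mating before dispersal",
    ),
    "asymmetric_premating": ScenarioPreset(
        name="asymmetric_premating",
        survival=SurvivalDistributions(),
        in_host_mating_ratio=1.0,
        description="female developmental advantage; mating before dispersal",
    ),
    "asymmetric_postmating": ScenarioPreset(
        name="asymmetric_postmating",
        survival=SurvivalDistributions(),
        in_host_mating_ratio=0.0,
        description="female developmental advantage; mating after dispersal",
    ),
}


def scenario_config(
    name: str,
    base_config: SimulationConfig | None = None,
    template: Strategy | None = None,
) -> tuple[SimulationConfig, Strategy]:
    """Apply a scenario preset to a base config and strategy template."""
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {sorted(SCENARIOS)}")
    preset = SCENARIOS[name]
    config = base_config if base_config is not None else SimulationConfig()
    base = template if template is not None else default_template(config.info_level)
    strategy = replace(
        base,
        survival=preset.survival,
        in_host_mating_ratio=preset.in_host_mating_ratio,
    )
    return config, strategy


@dataclass
class SweepResult:
    """Per-(threshold, replicate) tournament outcomes for one scenario."""

    scenario: str
    frame: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """Per-threshold means and SDs over the stable replicates."""
        rows = []
        for threshold, group in self.frame.groupby("threshold"):
            stable = group[group["stable"]]
            row = {
                "threshold": threshold,
                "n_replicates": len(group),
                "n_stable": len(stable),
            }
            for column in ("allocation_empty", "primary_ratio",
                           "secondary_ratio", "superparasitism"):
                values = stable[column].dropna().to_numpy()
                row[f"mean_{column}"] = float(np.mean(values)) if values.size else float("nan")
                row[f"sd_{column}"] = (float(np.std(values, ddof=1))
                                       if values.size > 1 else 0.0)
            rows.append(row)
        return pd.DataFrame(rows).sort_values("threshold", ignore_index=True)


def threshold_sweep(
    scenario: str,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    replicates: int = 5,
    base_seed: int = 0,
    base_config: SimulationConfig | None = None,
    template: Strategy | None = None,
    n_strategies: int = 125,
    generation_cap: int = GENERATION_CAP,
    final_window: int = 50,
    **tournament_kwargs,
) -> SweepResult:
    """Run replicated tournaments at each host-acceptance threshold.

    Records, per replicate: the winner's empty-host allocation, the realized
    primary and secondary sex ratios and the realized superparasitism level
    (fraction of parasitized hosts holding two or more eggs) over the final
    generations of the last round, and a stability flag.  A replicate whose
    population cannot persist at the threshold (no viable strategies, or all
    competitors extinct) is recorded as unstable with no ratio values.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    rows = []
    for ti, threshold in enumerate(thresholds):
        children = np.random.SeedSequence(base_seed + 1000 * ti).spawn(replicates)
        for ri, child in enumerate(children):
            config, strat_template = scenario_config(
                scenario, base_config=base_config, template=template)
            config = replace(config, host_acceptance_threshold=float(threshold))
            row = {
                "scenario": scenario,
                "threshold": float(threshold),
                "replicate": ri,
                "stable": False,
                "allocation_empty": float("nan"),
                "primary_ratio": float("nan"),
                "secondary_ratio": float("nan"),
                "superparasitism": float("nan"),
            }
            try:
                result = tournament(
                    config, strat_template, n_strategies=n_strategies,
                    rng=np.random.default_rng(child),
                    generation_cap=generation_cap, **tournament_kwargs)
            except (ViabilityError, RoundExtinctionError):
                rows.append(row)
                continue
            record = result.final_round
            primary, secondary = (record.final_window_means(final_window)
                                  if record else (float("nan"),) * 2)
            super_levels = []
            if record:
                for s in record.stats[-final_window:]:
                    if s.hosts_parasitized:
                        super_levels.append(
                            s.hosts_superparasitized / s.hosts_parasitized)
            row.update(
                stable=True,
                allocation_empty=result.winner.sex_choice["empty"],
                primary_ratio=primary,
                secondary_ratio=secondary,
                superparasitism=(float(np.mean(super_levels))
                                 if super_levels else float("nan")),
            )
            rows.append(row)
    return SweepResult(scenario=scenario, frame=pd.DataFrame(rows))


def plot_sweep(summaries: dict[str, pd.DataFrame], path: str | None = None):
    """Two-panel figure: evolved primary (top) and realized secondary
    (bottom) sex ratios against the threshold grid, dashed line at 0.5."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_top, ax_bottom) = plt.subplots(2, 1, sharex=True, figsize=(6, 7))
    markers = {"symmetric": "D", "asymmetric_premating": "s",
               "asymmetric_postmating": "^"}
    for name, summary in summaries.items():
        stable = summary[summary["n_stable"] > 0]
        marker = markers.get(name, "o")
        ax_top.errorbar(stable["threshold"], stable["mean_primary_ratio"],
                        yerr=stable["sd_primary_ratio"], marker=marker,
                        capsize=3, label=name)
        ax_bottom.errorbar(stable["threshold"], stable["mean_secondary_ratio"],
                           yerr=stable["sd_secondary_ratio"], marker=marker,
                           capsize=3, label=name)
    for ax, label in ((ax_top, "evolved primary sex ratio"),
                      (ax_bottom, "realized secondary sex ratio")):
        ax.axhline(0.5, linestyle="--", color="grey", linewidth=1)
        ax.set_ylabel(label)
        ax.set_ylim(0, 1)
    ax_bottom.set_xlabel("host acceptance threshold (low = high superparasitism)")
    ax_bottom.invert_xaxis()
    ax_top.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
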