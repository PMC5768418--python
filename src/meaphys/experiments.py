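"""Reference simulation experiments.

Self-contained parameter-recovery and manipulation-signature runs built
from the presets in :mod:`meaphys.config`; used to validate that the
detection-plus-categorization pipeline recovers the generating
population structure and the qualitative effect of acute manipulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import antagonist_config, control_male_config
from .ephys import profile_units
from .popstats import category_shift_table, paired_strength_test
from .synthetic import make_population, make_schedule, simulate_spike_trains


def categorized_fractions(
    seed: int, alpha: float = 0.01, n_units: int = 106
) -> dict[str, float]:
    """Simulate one control-male session and return the fraction of
    units categorized per stimulus."""
    cfg = control_male_config(seed=seed, n_units=n_units)
    population = make_population(cfg)
    events = make_schedule(cfg)
    spikes = simulate_spike_trains(population, events, cfg)
    profiles = profile_units(
        spikes, events, alpha=alpha, unit_ids=population["unit_id"]
    )
    per_unit = profiles.groupby("unit_id")["category"].first()
    return {
        stim: float((per_unit == stim).mean()) for stim in cfg.stimuli
    }


def recover_control_fractions(
    seed: int, n_seeds: int = 20, alpha: float = 0.01
) -> pd.DataFrame:
    """Parameter recovery over ``n_seeds`` control-male populations.

    Returns per-category mean recovered fraction alongside the
    generating prevalence and its single-session binomial SD.
    """
    cfg = control_male_config(seed=seed)
    rows = []
    fracs = pd.DataFrame(
        [categorized_fractions(seed + i, alpha=alpha) for i in range(n_seeds)]
    )
    for stim in cfg.stimuli:
        truth = cfg.category_prevalence.get(stim, 0.0)
        sd = np.sqrt(truth * (1 - truth) / cfg.n_units)
        rows.append(
            {
                "category": stim,
                "generating_prevalence": truth,
                "recovered_fraction": float(fracs[stim].mean()),
                "binomial_sd": float(sd),
                "n_seeds": n_seeds,
                "n_units": cfg.n_units,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AntagonistOutcome:
    """Per-seed qualitative signature of the simulated antagonist run."""

    female_frac_before: float
    female_frac_after: float
    female_shift_p: float
    female_strength_p: float
    female_strength_fell: bool
    male_significant_fall: bool
    predator_significant_fall: bool

    @property
    def matches_signature(self) -> bool:
        """Female category fraction and strengths fall significantly;
        male and predator fractions show no significant fall."""
        return (
            self.female_frac_after < self.female_frac_before
            and self.female_shift_p < 0.05
            and self.female_strength_fell
            and self.female_strength_p < 0.05
            and not self.male_significant_fall
            and not self.predator_significant_fall
        )


def antagonist_run(
    seed: int, alpha: float = 0.01, n_perm: int = 2000
) -> AntagonistOutcome:
    """Simulate one paired pre/post antagonist session and score the
    categorical and strength changes."""
    cfg = antagonist_config(seed=seed)
    population = make_population(cfg)
    events = make_schedule(cfg)
    spikes = simulate_spike_trains(population, events, cfg)
    prof_pre = profile_units(
        spikes, events[events["epoch"] == "pre"], alpha=alpha,
        unit_ids=population["unit_id"],
    )
    prof_post = profile_units(
        spikes, events[events["epoch"] == "post"], alpha=alpha,
        unit_ids=population["unit_id"],
    )
    shift = category_shift_table(
        prof_pre, prof_post, n_perm=n_perm, seed=seed
    ).set_index("category")

    fem_b = prof_pre[prof_pre["stimulus"] == "female"].set_index("unit_id")
    fem_a = prof_post[prof_post["stimulus"] == "female"].set_index("unit_id")
    responding = fem_b.index[fem_b["significant"] | fem_a["significant"]]
    before = fem_b.loc[responding, "strength"].to_numpy()
    after = fem_a.loc[responding, "strength"].to_numpy()
    strength_p = paired_strength_test(before, after)

    def significant_fall(cat: str) -> bool:
        row = shift.loc[cat]
        return bool(
            row["frac_after"] < row["frac_before"] and row["p_value"] < 0.05
        )

    fem = shift.loc["female"]
    return AntagonistOutcome(
        female_frac_before=float(fem["frac_before"]),
        female_frac_after=float(fem["frac_after"]),
        female_shift_p=float(fem["p_value"]),
        female_strength_p=float(strength_p),
        female_strength_fell=bool(np.mean(after) < np.mean(before)),
        male_significant_fall=significant_fall("male"),
        predator_significant_fall=significant_fall("predator"),
    )
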