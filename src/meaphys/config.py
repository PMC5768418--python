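"""Generative configuration for synthetic recordings and behavior cohorts.

The synthetic generator emulates the structure of stimulus-locked
single-unit recordings from the medial amygdala (MeA): a population of
units, each assigned to a response category (``female``, ``male``,
``predator`` or ``nonresponsive``), fires as an inhomogeneous Poisson
process whose rate is elevated by a multiplicative gain during a fixed
response window after each matching stimulus onset.  An optional drug
effect (e.g. an oxytocin-receptor antagonist or chemogenetic CNO
manipulation) multiplies baseline rates and stimulus gains after an
epoch boundary, with stimulus-free baseline periods flanking the
injection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

CATEGORIES: tuple[str, ...] = ("female", "male", "predator", "nonresponsive")
#: Stimulus categories that can win a unit's classification, in the fixed
#: tie-break order used throughout.
CATEGORY_ORDER: tuple[str, ...] = ("female", "male", "predator")
DEFAULT_STIMULI: tuple[str, ...] = ("female", "male", "predator")
#: Stimulus labels treated as vehicle controls: they are tested for
#: responsiveness but never win a unit's category.
CONTROL_STIMULI: frozenset[str] = frozenset({"control", "ringers", "saline"})


class ConfigurationError(ValueError):
    """Raised when a generative configuration violates its invariants."""


@dataclass(frozen=True)
class DrugEffect:
    """Step change in firing applied after ``epoch_boundary``.

    Parameters
    ----------
    baseline_factor
        Multiplies every unit's baseline rate after the boundary.
    gain_factor
        Per-stimulus scaling of the evoked gain component after the
        boundary: a pre-drug gain g becomes 1 + factor * (g - 1), so
        factor 0 abolishes the response, factor 1 leaves it intact, and
        units that never responded (g = 1) are unaffected.  Stimuli
        absent from the map keep their gain.
    epoch_boundary
        Injection time in seconds from session start.  ``None`` places it
        ``baseline_epoch_s`` after the last pre-drug trial ends.
    baseline_epoch_s
        Duration of the stimulus-free baseline recorded on each side of
        the boundary (10 min by default).
    """

    baseline_factor: float = 1.0
    gain_factor: Mapping[str, float] = field(default_factory=dict)
    epoch_boundary: float | None = None
    baseline_epoch_s: float = 600.0

    def __post_init__(self) -> None:
        if self.baseline_factor < 0:
            raise ConfigurationError("drug baseline_factor must be >= 0")
        if any(v < 0 for v in self.gain_factor.values()):
            raise ConfigurationError("drug gain factors must be >= 0")
        if self.baseline_epoch_s < 60:
            raise ConfigurationError("baseline epochs must be >= 60 s")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of a synthetic MeA recording session.

    ``category_prevalence`` gives the population mix; units of category
    ``c`` respond to stimulus ``c`` with multiplicative gain
    ``response_gain`` (or per-category/per-stimulus values from ``gain``)
    and to every other stimulus with gain 1.  Baseline rates are
    log-normal; window lengths mirror the analysis convention of 20 s
    pre / 40 s post stimulus.
    """

    n_units: int = 100
    category_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "female": 0.2,
            "male": 0.05,
            "predator": 0.15,
            "nonresponsive": 0.6,
        }
    )
    baseline_log_mean: float = math.log(3.0)
    baseline_log_sd: float = 0.5
    response_gain: float = 4.0
    gain: Mapping[str, Mapping[str, float]] | None = None
    response_duration: float = 40.0
    pre_window: float = 20.0
    stimuli: Sequence[str] = DEFAULT_STIMULI
    reps_range: tuple[int, int] = (6, 12)
    inter_trial_interval: float = 80.0
    drug_effect: DrugEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ConfigurationError("n_units must be >= 0")
        total = sum(self.category_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"category prevalences must sum to 1, got {total!r}"
            )
        if any(v < 0 for v in self.category_prevalence.values()):
            raise ConfigurationError("prevalences must be >= 0")
        unknown = set(self.category_prevalence) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        if self.baseline_log_sd < 0 or self.response_gain < 0:
            raise ConfigurationError("rates and gains must be >= 0")
        lo, hi = self.reps_range
        if not (1 <= lo <= hi <= 100):
            raise ConfigurationError("reps_range must lie within [1, 100]")
        if not self.stimuli:
            raise ConfigurationError("at least one stimulus label required")
        if len(set(self.stimuli)) != len(self.stimuli):
            raise ConfigurationError("stimulus labels must be unique")
        if self.response_duration <= 0 or self.pre_window <= 0:
            raise ConfigurationError("windows must be > 0")
        if self.inter_trial_interval < self.pre_window + self.response_duration:
            raise ConfigurationError(
                "inter_trial_interval must cover pre + post windows "
                f"({self.pre_window + self.response_duration:.0f} s)"
            )
        if self.gain is not None:
            for cat, table in self.gain.items():
                if any(g < 0 for g in table.values()):
                    raise ConfigurationError("gains must be >= 0")

    def gain_for(self, category: str, stimulus: str) -> float:
        """Resolve the response-window gain of a unit category to a stimulus."""
        if self.gain is not None and category in self.gain:
            return float(self.gain[category].get(stimulus, 1.0))
        if category == stimulus:
            return float(self.response_gain)
        return 1.0


@dataclass(frozen=True)
class BehaviorGroupParams:
    """Moments of one behavioral group in one assay phase.

    ``measures`` maps a zone or odor label to ``(mean_s, sd_s)`` of the
    per-animal duration; durations are drawn from a gamma distribution
    with those moments so they cannot go negative.
    """

    group: str
    phase: str
    n_animals: int
    measures: Mapping[str, tuple[float, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        for label, (mean, sd) in self.measures.items():
            if mean < 0:
                raise ConfigurationError(f"negative mean for {label!r}")
            if sd < 0:
                raise ConfigurationError(f"negative dispersion for {label!r}")


# ---------------------------------------------------------------------------
# Presets: study conditions used in the package's reference simulations.
# Prevalences are expressed as unit counts over the recorded population so
# that expected fractions round to the reported percentages.


def control_male_config(seed: int = 0, n_units: int = 106) -> SyntheticConfig:
    """Control-male MeA population: 106 units, female- and predator-dominant.

    Category mix 25/106 female, 1/106 male, 14/106 predator; strong
    excitatory responses (gain 4) and 8 interleaved repetitions per
    stimulus.
    """
    return SyntheticConfig(
        n_units=n_units,
        category_prevalence={
            "female": 25 / 106,
            "male": 1 / 106,
            "predator": 14 / 106,
            "nonresponsive": 66 / 106,
        },
        response_gain=4.0,
        reps_range=(8, 8),
        seed=seed,
    )


def antagonist_config(seed: int = 0, n_units: int = 129) -> SyntheticConfig:
    """Paired pre/post drug session emulating acute OXTR antagonism.

    129 maintained units with a female-dominant responsive minority;
    after the injection boundary the female response gain collapses to 1
    and baseline rates drop, while male and predator gains are untouched.
    """
    return SyntheticConfig(
        n_units=n_units,
        category_prevalence={
            "female": 21 / 129,
            "male": 1 / 129,
            "predator": 1 / 129,
            "nonresponsive": 106 / 129,
        },
        response_gain=4.0,
        reps_range=(8, 8),
        drug_effect=DrugEffect(
            baseline_factor=0.8,
            gain_factor={"female": 0.0},
        ),
        seed=seed,
    )


def null_config(seed: int = 0, n_units: int = 1000,
                stimuli: Sequence[str] = ("female",),
                reps: int = 10) -> SyntheticConfig:
    """All-nonresponsive population used for detector calibration."""
    return SyntheticConfig(
        n_units=n_units,
        category_prevalence={"nonresponsive": 1.0},
        stimuli=tuple(stimuli),
        reps_range=(reps, reps),
        seed=seed,
    )


#: Reference behavior-cohort moments (mean, SD in seconds) for the assays the
#: pipeline analyzes.  SDs are reconstructed from group SEMs via SEM * sqrt(n).
BEHAVIOR_PRESETS: dict[str, BehaviorGroupParams] = {
    "wt_male_bedding": BehaviorGroupParams(
        group="wt_male", phase="choice", n_animals=9,
        measures={"female_bedding": (76.3, 33.6), "male_bedding": (34.3, 15.3)},
    ),
    "mea_rescue_bedding": BehaviorGroupParams(
        group="mea_rescue", phase="choice", n_animals=13,
        measures={"female_bedding": (71.0, 24.9), "male_bedding": (35.7, 16.6)},
    ),
    "pvn_hm4di_saline": BehaviorGroupParams(
        group="pvn_hm4di_saline", phase="choice", n_animals=10,
        measures={"female_zone": (171.5, 67.0), "male_zone": (90.2, 38.6)},
    ),
    "pvn_hm4di_cno_1wk": BehaviorGroupParams(
        group="pvn_hm4di_cno_1wk", phase="choice", n_animals=10,
        measures={"female_zone": (187.3, 65.8), "male_zone": (111.8, 43.3)},
    ),
    "ymaze_wt": BehaviorGroupParams(
        group="wt_male", phase="choice", n_animals=10,
        measures={"food_zone": (73.4, 17.4), "fox_zone": (35.8, 7.6)},
    ),
}
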