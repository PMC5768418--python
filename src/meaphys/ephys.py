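"""Per-unit sensory-response analysis for stimulus-locked spike trains.

The analysis convention follows standard practice for chemosensory
recordings with slow vomeronasal dynamics: firing is averaged over a
20 s pre-stimulus and a 40 s post-stimulus window per trial,
responsiveness is a non-parametric (Kruskal-Wallis) comparison of the
per-trial pre vs post rates, and the response strength of a unit to a
stimulus is the normalized index

    strength = (post - pre) / (post + pre)

computed on trial-averaged rates, bounded in [-1, 1].  A unit's category
is the stimulus (female, male or predator) with the strongest
significant excitatory response; units with no significant excitatory
response are ``nonresponsive``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CATEGORY_ORDER, CONTROL_STIMULI

logger = logging.getLogger(__name__)

NONRESPONSIVE = "nonresponsive"


class InsufficientDataError(ValueError):
    """Raised when too few trials are available for a statistical test."""


class WindowError(ValueError):
    """Raised when trial windows collide or extend outside the session."""


@dataclass(frozen=True)
class TrialWindowRates:
    """Per-trial firing rates around one stimulus's presentations."""

    pre_rates: np.ndarray
    post_rates: np.ndarray
    pre_s: float = 20.0
    post_s: float = 40.0

    @property
    def n_trials(self) -> int:
        return len(self.pre_rates)


@dataclass(frozen=True)
class TernaryCoords:
    """Selectivity coordinates on the female/male/predator simplex."""

    female: float
    male: float
    predator: float
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.female, self.male, self.predator)


@dataclass(frozen=True)
class BaselineChange:
    """Stimulus-free firing-rate comparison across a drug boundary."""

    rate_before: float
    rate_after: float
    p_value: float


def trial_rates(
    spike_times: np.ndarray,
    onsets: Sequence[float],
    pre_s: float = 20.0,
    post_s: float = 40.0,
) -> TrialWindowRates:
    """Firing rate in the half-open windows [onset-pre, onset) and
    [onset, onset+post) for every presentation of one stimulus.

    Windows of distinct trials must not overlap and must lie within the
    session (no window may start before t = 0).  Event order is
    preserved in the returned per-trial arrays.
    """
    if pre_s <= 0 or post_s <= 0:
        raise WindowError("window lengths must be > 0")
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size and np.any(np.diff(spikes) <= 0):
        raise ValueError("spike times must be strictly increasing")
    onsets_arr = np.asarray(onsets, dtype=float)
    if np.any(onsets_arr - pre_s < 0):
        bad = onsets_arr[onsets_arr - pre_s < 0]
        raise WindowError(f"pre window extends before t=0 for onsets {bad}")
    order = np.sort(onsets_arr)
    collisions = np.nonzero(order[1:] - pre_s < order[:-1] + post_s)[0]
    if collisions.size:
        i = collisions[0]
        raise WindowError(
            f"trial windows overlap between onsets {order[i]} and {order[i + 1]}"
        )
    pre_counts = np.searchsorted(spikes, onsets_arr, side="left") - np.searchsorted(
        spikes, onsets_arr - pre_s, side="left"
    )
    post_counts = np.searchsorted(
        spikes, onsets_arr + post_s, side="left"
    ) - np.searchsorted(spikes, onsets_arr, side="left")
    return TrialWindowRates(
        pre_rates=pre_counts / pre_s,
        post_rates=post_counts / post_s,
        pre_s=pre_s,
        post_s=post_s,
    )


def responsiveness_test(rates: TrialWindowRates) -> float:
    """Non-parametric test of pre vs post per-trial rates.

    Kruskal-Wallis over the two groups {pre trials} and {post trials}
    (the two-group reduction of a non-parametric ANOVA, equivalent to a
    rank-sum test up to tie handling).  Identical groups return p = 1 by
    convention.
    """
    if rates.n_trials < 3:
        raise InsufficientDataError(
            f"need >= 3 trials, got {rates.n_trials}"
        )
    pooled = np.concatenate([rates.pre_rates, rates.post_rates])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.kruskal(rates.pre_rates, rates.post_rates).pvalue)


def response_strength(rates: TrialWindowRates) -> float:
    """Normalized response index (post - pre)/(post + pre) on
    trial-averaged rates; 0 when both means are 0."""
    pre = float(np.mean(rates.pre_rates))
    post = float(np.mean(rates.post_rates))
    if pre + post == 0:
        return 0.0
    return (post - pre) / (post + pre)


def categorize_unit(
    p_values: Mapping[str, float],
    strengths: Mapping[str, float],
    alpha: float = 0.01,
) -> str:
    """Label a unit by the stimulus with its strongest significant
    excitatory response.

    Only stimuli with p <= alpha *and* strength > 0 compete, so purely
    suppressed units are not labeled with the suppressing stimulus;
    vehicle-control stimuli never win.  Ties in strength are broken by
    smaller p-value, then by the fixed stimulus order female, male,
    predator (logged when it happens).
    """
    candidates = [
        s
        for s in p_values
        if s.lower() not in CONTROL_STIMULI
        and p_values[s] <= alpha
        and strengths.get(s, 0.0) > 0
    ]
    if not candidates:
        return NONRESPONSIVE

    def order_key(s: str) -> int:
        return CATEGORY_ORDER.index(s) if s in CATEGORY_ORDER else len(
            CATEGORY_ORDER
        )

    candidates.sort(key=lambda s: (-strengths[s], p_values[s], order_key(s)))
    best = candidates[0]
    ties = [
        s
        for s in candidates[1:]
        if strengths[s] == strengths[best] and p_values[s] == p_values[best]
    ]
    if ties:
        logger.warning(
            "strength tie between %s broken by stimulus order", [best, *ties]
        )
    return best


def selectivity_coordinates(
    strengths: Mapping[str, float],
    significant: Mapping[str, bool],
) -> TernaryCoords:
    """Project a responsive unit's strengths onto the selectivity simplex.

    Strengths are rectified at zero and normalized to sum to 1; a unit
    whose every rectified strength is 0 maps to the centroid with the
    ``degenerate`` flag set.  Calling this on a unit with no significant
    response is an error (such units are not plotted).
    """
    if not any(significant.get(s, False) for s in CATEGORY_ORDER):
        raise ValueError("selectivity undefined for a nonresponsive unit")
    rect = np.array([max(strengths.get(s, 0.0), 0.0) for s in CATEGORY_ORDER])
    total = rect.sum()
    if total == 0:
        return TernaryCoords(1 / 3, 1 / 3, 1 / 3, degenerate=True)
    f, m, p = rect / total
    return TernaryCoords(float(f), float(m), float(p))


def baseline_rate_change(
    spike_times: np.ndarray,
    epoch_before: tuple[float, float],
    epoch_after: tuple[float, float],
    bin_s: float = 10.0,
    stimulus_onsets: Sequence[float] | None = None,
    response_duration: float = 40.0,
) -> BaselineChange:
    """Compare stimulus-free firing across a drug boundary.

    Rates are spike count / epoch duration; significance is a rank-sum
    test on per-bin spike counts (``bin_s`` wide).  If stimulus onsets
    are supplied, epochs overlapping any response window raise an error.
    """
    spikes = np.asarray(spike_times, dtype=float)
    for label, (start, end) in (("before", epoch_before), ("after", epoch_after)):
        if end <= start:
            raise WindowError(f"{label} epoch is empty")
    if stimulus_onsets is not None:
        for onset in np.asarray(stimulus_onsets, dtype=float):
            for start, end in (epoch_before, epoch_after):
                if onset < end and onset + response_duration > start:
                    raise WindowError(
                        f"baseline epoch ({start}, {end}) overlaps the "
                        f"response window of the stimulus at {onset} s"
                    )

    def epoch_stats(start: float, end: float) -> tuple[float, np.ndarray]:
        n = np.searchsorted(spikes, end, side="left") - np.searchsorted(
            spikes, start, side="left"
        )
        edges = np.arange(start, end + 1e-9, bin_s)
        counts, _ = np.histogram(spikes, bins=edges)
        return n / (end - start), counts

    rate_before, bins_before = epoch_stats(*epoch_before)
    rate_after, bins_after = epoch_stats(*epoch_after)
    pooled = np.concatenate([bins_before, bins_after])
    if pooled.size == 0 or np.all(pooled == pooled[0]):
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(
                stats.mannwhitneyu(
                    bins_before, bins_after, alternative="two-sided"
                ).pvalue
            )
    return BaselineChange(float(rate_before), float(rate_after), p)


def profile_units(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    alpha: float = 0.01,
    pre_s: float = 20.0,
    post_s: float = 40.0,
    unit_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """End-to-end per-unit response profiling.

    Takes tidy ``(unit_id, spike_time_s)`` spikes and
    ``(stimulus, onset_s, ...)`` events and returns one row per unit and
    stimulus with the trial-averaged window rates, responsiveness
    p-value, response strength, significance at ``alpha`` and the
    unit-level category (repeated on each of the unit's rows).
    """
    stimuli = list(dict.fromkeys(events["stimulus"]))
    if unit_ids is None:
        unit_ids = list(dict.fromkeys(spikes["unit_id"]))
    grouped = {uid: g["spike_time_s"].to_numpy() for uid, g in spikes.groupby("unit_id")}
    onsets_by_stim = {
        s: events.loc[events["stimulus"] == s, "onset_s"].to_numpy() for s in stimuli
    }
    rows = []
    for uid in unit_ids:
        times = np.sort(grouped.get(uid, np.empty(0)))
        p_values: dict[str, float] = {}
        strengths: dict[str, float] = {}
        per_stim = {}
        for stim in stimuli:
            rates = trial_rates(times, onsets_by_stim[stim], pre_s, post_s)
            p_values[stim] = responsiveness_test(rates)
            strengths[stim] = response_strength(rates)
            per_stim[stim] = rates
        category = categorize_unit(p_values, strengths, alpha)
        for stim in stimuli:
            rates = per_stim[stim]
            rows.append(
                {
                    "unit_id": uid,
                    "stimulus": stim,
                    "n_trials": rates.n_trials,
                    "pre_rate": float(np.mean(rates.pre_rates)),
                    "post_rate": float(np.mean(rates.post_rates)),
                    "p_value": p_values[stim],
                    "strength": strengths[stim],
                    "significant": bool(p_values[stim] <= alpha),
                    "category": category,
                }
            )
    return pd.DataFrame(rows)
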