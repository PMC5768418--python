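"""Synthetic spike-train recordings and behavior cohorts.

Everything here is seeded and reproducible: the master seed in
:class:`~meaphys.config.SyntheticConfig` is split into named streams (one
per generator stage, one per unit for spiking) so that, e.g., enlarging a
population leaves the spike trains of existing units unchanged.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    BehaviorGroupParams,
    ConfigurationError,
    SyntheticConfig,
)

# Named RNG stream identifiers derived from the master seed.
_STREAM_POPULATION = 0
_STREAM_SCHEDULE = 1
_STREAM_SPIKES = 2
_STREAM_BEHAVIOR = 3


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, index))
    )


# ---------------------------------------------------------------------------
# Population


def make_population(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a unit population from the configured category prevalences.

    Returns a frame with one row per unit: ``unit_id``, ``category``,
    ``baseline_rate`` (spikes/s, log-normal) and one ``gain_<stimulus>``
    column per stimulus.  Category counts are a single seeded multinomial
    draw of the prevalence vector.
    """
    rng = _rng(config.seed, _STREAM_POPULATION)
    cats = list(config.category_prevalence)
    probs = np.array([config.category_prevalence[c] for c in cats], dtype=float)
    counts = rng.multinomial(config.n_units, probs / probs.sum())
    labels = np.repeat(cats, counts)
    rng.shuffle(labels)
    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_units
    )
    frame = pd.DataFrame(
        {
            "unit_id": [f"u{i:04d}" for i in range(config.n_units)],
            "category": labels,
            "baseline_rate": baseline,
        }
    )
    for stim in config.stimuli:
        frame[f"gain_{stim}"] = [
            config.gain_for(cat, stim) for cat in frame["category"]
        ]
    return frame


# ---------------------------------------------------------------------------
# Stimulus schedule and drug epochs


def _one_block(config: SyntheticConfig, rng: np.random.Generator,
               t0: float, epoch: str) -> pd.DataFrame:
    lo, hi = config.reps_range
    reps = {s: int(rng.integers(lo, hi + 1)) for s in config.stimuli}
    labels = np.repeat(list(reps), list(reps.values()))
    order = rng.permutation(len(labels))
    labels = labels[order]
    onsets = t0 + config.inter_trial_interval * np.arange(len(labels))
    rep_index = {s: 0 for s in config.stimuli}
    rows = []
    for stim, onset in zip(labels, onsets):
        rep_index[stim] += 1
        rows.append((stim, float(onset), rep_index[stim], epoch))
    return pd.DataFrame(rows, columns=["stimulus", "onset_s", "rep_index", "epoch"])


def make_schedule(config: SyntheticConfig) -> pd.DataFrame:
    """Randomly interleaved stimulus schedule.

    Each stimulus receives a repetition count drawn from ``reps_range``
    and presentations are interleaved in seeded random order with onsets
    ``inter_trial_interval`` apart (always >= pre + post window).  With a
    drug effect configured, a second independent block is scheduled after
    the injection boundary and its two flanking baseline epochs; events
    carry an ``epoch`` column (``pre``/``post``).
    """
    rng = _rng(config.seed, _STREAM_SCHEDULE)
    before = _one_block(config, rng, config.pre_window, "pre")
    if config.drug_effect is None:
        return before
    end_before = before["onset_s"].max() + config.response_duration
    boundary = drug_boundary(config, before)
    if boundary - config.drug_effect.baseline_epoch_s < end_before:
        raise ConfigurationError(
            "epoch_boundary leaves no room for the pre-drug baseline epoch"
        )
    t0_after = (
        boundary + config.drug_effect.baseline_epoch_s + config.pre_window
    )
    after = _one_block(config, rng, t0_after, "post")
    return pd.concat([before, after], ignore_index=True)


def drug_boundary(config: SyntheticConfig, events: pd.DataFrame) -> float:
    """Injection time: configured explicitly or one baseline epoch after
    the last pre-drug trial ends."""
    if config.drug_effect is None:
        raise ConfigurationError("no drug effect configured")
    if config.drug_effect.epoch_boundary is not None:
        return float(config.drug_effect.epoch_boundary)
    pre = events[events["epoch"] == "pre"]
    end_before = pre["onset_s"].max() + config.response_duration
    return float(end_before + config.drug_effect.baseline_epoch_s)


def baseline_epochs(config: SyntheticConfig, events: pd.DataFrame) -> pd.DataFrame:
    """Stimulus-free baseline windows flanking the injection boundary."""
    boundary = drug_boundary(config, events)
    dur = config.drug_effect.baseline_epoch_s
    return pd.DataFrame(
        {
            "label": ["baseline_pre", "baseline_post"],
            "start_s": [boundary - dur, boundary],
            "end_s": [boundary, boundary + dur],
        }
    )


# ---------------------------------------------------------------------------
# Spike trains


def _rate_profile(
    baseline: float,
    gains: Mapping[str, float],
    events: pd.DataFrame,
    config: SyntheticConfig,
    t_end: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate function as (breakpoints, rates).

    ``rates[i]`` applies on ``[breakpoints[i], breakpoints[i+1])``.
    """
    drug = config.drug_effect
    boundary = drug_boundary(config, events) if drug is not None else None

    # Segment the session into baseline stretches and response windows.
    segments: list[tuple[float, float, str | None]] = []
    cur = 0.0
    for _, ev in events.sort_values("onset_s").iterrows():
        onset = float(ev["onset_s"])
        stop = onset + config.response_duration
        if onset > cur:
            segments.append((cur, onset, None))
        segments.append((onset, stop, str(ev["stimulus"])))
        cur = stop
    if t_end > cur:
        segments.append((cur, t_end, None))

    # Split any segment straddling the injection so drug factors switch
    # exactly at the boundary (only baseline stretches can straddle it,
    # since both trial blocks sit clear of the flanking epochs).
    if boundary is not None:
        split: list[tuple[float, float, str | None]] = []
        for start, stop, stim in segments:
            if start < boundary < stop:
                split.append((start, boundary, stim))
                split.append((boundary, stop, stim))
            else:
                split.append((start, stop, stim))
        segments = split

    edges = [seg[0] for seg in segments] + [segments[-1][1]]
    rates = []
    for start, _stop, stim in segments:
        rate = baseline
        if boundary is not None and start >= boundary:
            rate *= drug.baseline_factor
        if stim is not None:
            g = float(gains.get(stim, 1.0))
            if boundary is not None and start >= boundary:
                g = 1.0 + drug.gain_factor.get(stim, 1.0) * (g - 1.0)
            rate *= g
        rates.append(rate)
    return np.asarray(edges), np.asarray(rates)


def _sample_piecewise_poisson(
    edges: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact inhomogeneous-Poisson sample for a piecewise-constant rate."""
    durations = np.diff(edges)
    counts = rng.poisson(rates * durations)
    starts = np.repeat(edges[:-1], counts)
    widths = np.repeat(durations, counts)
    times = starts + rng.random(counts.sum()) * widths
    times = np.unique(times)  # sorts; a.s. no duplicates to drop
    return times


def simulate_spike_trains(
    population: pd.DataFrame,
    events: pd.DataFrame,
    config: SyntheticConfig,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Simulate every unit as an inhomogeneous Poisson process.

    Rate = baseline outside response windows, baseline x gain[stimulus]
    during the ``response_duration`` after each onset; drug factors apply
    after the injection boundary.  Returns a tidy frame
    ``(unit_id, spike_time_s)`` with strictly increasing times per unit.
    """
    if t_end is None:
        t_end = float(events["onset_s"].max() + config.response_duration + 10.0)
    gain_cols = {c for c in population.columns if c.startswith("gain_")}
    out_ids: list[str] = []
    out_times: list[np.ndarray] = []
    for idx, unit in population.reset_index(drop=True).iterrows():
        gains = {c[len("gain_"):]: unit[c] for c in gain_cols}
        edges, rates = _rate_profile(
            float(unit["baseline_rate"]), gains, events, config, t_end
        )
        rng = _rng(config.seed, _STREAM_SPIKES, idx)
        times = _sample_piecewise_poisson(edges, rates, rng)
        out_ids.extend([unit["unit_id"]] * len(times))
        out_times.append(times)
    spike_times = (
        np.concatenate(out_times) if out_times else np.empty(0, dtype=float)
    )
    return pd.DataFrame({"unit_id": out_ids, "spike_time_s": spike_times})


# ---------------------------------------------------------------------------
# Behavior cohorts


def simulate_behavior_cohort(params: BehaviorGroupParams) -> pd.DataFrame:
    """Draw per-animal durations for one group/phase from gamma laws.

    The gamma shape/scale are matched to the configured mean and SD, so
    durations are non-negative and the cohort mean converges to the
    configured mean as the cohort grows.  A zero SD yields the mean
    exactly for every animal.
    """
    rng = _rng(params.seed, _STREAM_BEHAVIOR)
    rows = []
    for animal in range(params.n_animals):
        animal_id = f"{params.group}_a{animal:03d}"
        for label, (mean, sd) in params.measures.items():
            if sd == 0 or mean == 0:
                dur = float(mean)
            else:
                shape = (mean / sd) ** 2
                scale = sd**2 / mean
                dur = float(rng.gamma(shape, scale))
            rows.append((animal_id, params.group, params.phase, label, dur))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "phase", "zone_or_odor", "duration_s"]
    )


def trajectory_from_dwell(
    anchors: Mapping[str, tuple[float, float]],
    dwell_s: Mapping[str, float],
    dt: float = 0.1,
) -> pd.DataFrame:
    """Piecewise-constant trajectory visiting ``anchors`` for set dwell times.

    Used to build zone-occupancy fixtures with exactly known ground
    truth: the animal sits at each anchor point for ``dwell_s[label]``
    seconds, sampled every ``dt``.
    """
    ts, xs, ys = [], [], []
    t = 0.0
    for label, dwell in dwell_s.items():
        x, y = anchors[label]
        n = int(round(dwell / dt))
        ts.extend(t + dt * np.arange(n))
        xs.extend([x] * n)
        ys.extend([y] * n)
        t += n * dt
    return pd.DataFrame({"t_s": ts, "x_cm": xs, "y_cm": ys})
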