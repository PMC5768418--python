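"""Behavioral scoring and statistics.

Covers the three assays the pipeline analyzes:

* three-chamber social preference — dwell time in the interaction zone
  (within a fixed margin of each enclosure-cup boundary) and the social
  preference score (t_female - t_male)/(t_female + t_male);
* bedding/odor investigation — the identical preference score on
  pre-scored investigation durations;
* odor habituation/dishabituation — repeated-measures ANOVA over nine
  ordered presentations (3 saline, 3 odor 1, 3 odor 2) with Fisher's LSD
  comparisons of adjacent slots;
* Y-maze goal-zone occupancy.

Family-wise error over a declared family of preference comparisons is
controlled with the Holm-Sidak step-down procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class TrajectoryError(ValueError):
    """Raised for malformed trajectories (non-uniform sampling, ...)."""


@dataclass(frozen=True)
class ZoneSpec:
    """A scoring zone: a cup interaction annulus or a chamber polygon.

    A ``cup`` zone contains every point within ``margin_cm`` of the cup
    boundary circle (|d - radius| <= margin, closed); a ``polygon`` zone
    contains every point of the polygon including its boundary.
    """

    label: str
    kind: str = "cup"  # "cup" | "polygon"
    center: tuple[float, float] | None = None
    radius_cm: float | None = None
    margin_cm: float = 5.0
    vertices: Sequence[tuple[float, float]] | None = None
    _polygon: object = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind == "cup":
            if self.center is None or self.radius_cm is None:
                raise ValueError("cup zone needs center and radius_cm")
            if self.margin_cm <= 0:
                raise ValueError("margin_cm must be > 0")
        elif self.kind == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon zone needs >= 3 vertices")
            object.__setattr__(
                self, "_polygon", shapely.Polygon(self.vertices)
            )
        else:
            raise ValueError(f"unknown zone kind {self.kind!r}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized closed-boundary membership test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "cup":
            cx, cy = self.center
            d = np.hypot(x - cx, y - cy)
            return np.abs(d - self.radius_cm) <= self.margin_cm
        return shapely.intersects_xy(self._polygon, x, y)


def zone_durations(
    trajectory: pd.DataFrame, zones: Sequence[ZoneSpec]
) -> dict[str, float]:
    """Occupancy duration per zone from a uniformly sampled trajectory.

    Duration = (number of samples inside the zone) x sample step, with
    no interpolation; boundary points count as inside.  Zones may
    overlap, in which case durations are not disjoint.
    """
    t = trajectory["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise TrajectoryError("trajectory needs >= 2 samples")
    steps = np.diff(t)
    dt = steps[0]
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise TrajectoryError("timestamps must be uniform and increasing")
    x = trajectory["x_cm"].to_numpy(dtype=float)
    y = trajectory["y_cm"].to_numpy(dtype=float)
    return {
        zone.label: float(zone.contains(x, y).sum() * dt) for zone in zones
    }


def preference_score(t_a: float, t_b: float) -> float:
    """Normalized preference (t_a - t_b)/(t_a + t_b) in [-1, 1].

    +1 means all time with stimulus A, -1 all time with stimulus B;
    0/0 maps to 0 by convention.
    """
    if t_a < 0 or t_b < 0:
        raise ValueError("durations must be >= 0")
    if t_a + t_b == 0:
        return 0.0
    return (t_a - t_b) / (t_a + t_b)


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values for one comparison family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


@dataclass(frozen=True)
class PreferenceResult:
    """Per-animal scores and family-corrected group comparisons."""

    scores: pd.DataFrame  # animal_id, group, phase, score
    summary: pd.DataFrame  # one row per group
    reduction: str
    paired: bool


def _animal_scores(
    records: pd.DataFrame, measure_a: str, measure_b: str, phase: str
) -> pd.DataFrame:
    sub = records[
        (records["phase"] == phase)
        & (records["zone_or_odor"].isin([measure_a, measure_b]))
    ]
    wide = sub.pivot_table(
        index=["animal_id", "group"],
        columns="zone_or_odor",
        values="duration_s",
        aggfunc="first",
    )
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        logger.info(
            "excluded %d animals missing a measure in phase %r",
            len(missing),
            phase,
        )
        wide = wide.dropna()
    scores = wide.apply(
        lambda row: preference_score(row[measure_a], row[measure_b]), axis=1
    )
    out = scores.rename("score").reset_index()
    out["phase"] = phase
    return out


def group_preference(
    records: pd.DataFrame,
    measure_a: str,
    measure_b: str,
    choice_phase: str = "choice",
    habituation_phase: str = "habituation",
    paired: bool = True,
    reduction: str = "mean_of_ratios",
) -> PreferenceResult:
    """Preference scores per animal and the bias-vs-habituation test.

    For each group, per-animal scores are computed in the choice phase
    (with the stimuli present) and in the habituation phase (same
    arena, no stimuli), and compared with a two-sided t test — paired
    when the same animals ran both phases.  The set of groups passed in
    one call is treated as one Holm-Sidak family (``p_adj`` column).

    ``reduction`` controls the reported group score only:
    ``mean_of_ratios`` averages per-animal scores (default);
    ``ratio_of_means`` scores the group-mean durations.
    """
    if reduction not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown reduction {reduction!r}")
    choice = _animal_scores(records, measure_a, measure_b, choice_phase)
    habit = _animal_scores(records, measure_a, measure_b, habituation_phase)
    all_scores = pd.concat([choice, habit], ignore_index=True)
    rows = []
    for group in dict.fromkeys(records["group"]):
        c = choice[choice["group"] == group]
        h = habit[habit["group"] == group]
        if paired:
            common = np.intersect1d(c["animal_id"], h["animal_id"])
            cs = c.set_index("animal_id").loc[common, "score"].to_numpy()
            hs = h.set_index("animal_id").loc[common, "score"].to_numpy()
            if len(common) < 2:
                raise ValueError(f"group {group!r}: too few paired animals")
            if np.allclose(cs, hs):
                p_raw = 1.0
            else:
                p_raw = float(stats.ttest_rel(cs, hs).pvalue)
        else:
            cs = c["score"].to_numpy()
            hs = h["score"].to_numpy()
            p_raw = float(stats.ttest_ind(cs, hs).pvalue)
        if reduction == "mean_of_ratios":
            group_score = float(np.mean(cs))
        else:
            means = records[
                (records["group"] == group)
                & (records["phase"] == choice_phase)
            ].groupby("zone_or_odor")["duration_s"].mean()
            group_score = preference_score(means[measure_a], means[measure_b])
        rows.append(
            {
                "group": group,
                "n": len(cs),
                "choice_score": group_score,
                "choice_sem": float(stats.sem(cs)) if len(cs) > 1 else np.nan,
                "habituation_score": float(np.mean(hs)),
                "p_raw": p_raw,
            }
        )
    summary = pd.DataFrame(rows)
    summary["p_adj"] = holm_sidak(summary["p_raw"].to_numpy())
    return PreferenceResult(all_scores, summary, reduction, paired)


@dataclass(frozen=True)
class HabituationResult:
    """Omnibus repeated-measures ANOVA plus adjacent-slot LSD tests."""

    f_statistic: float
    p_omnibus: float
    ms_error: float
    df_error: int
    n_animals: int
    pairwise: pd.DataFrame


def rm_anova(matrix: np.ndarray) -> tuple[float, float, float, int]:
    """One-way repeated-measures ANOVA on an (animals x slots) matrix.

    Returns (F, p, MS_error, df_error) with the subject-by-condition
    interaction as the error term.
    """
    x = np.asarray(matrix, dtype=float)
    n, a = x.shape
    if n < 2 or a < 2:
        raise ValueError("need >= 2 animals and >= 2 slots")
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = a * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = a - 1
    df_err = (a - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return np.inf if ss_cond > 0 else 0.0, 1.0 if ss_cond == 0 else 0.0, 0.0, df_err
    f = (ss_cond / df_cond) / ms_err
    p = float(stats.f.sf(f, df_cond, df_err))
    return float(f), p, float(ms_err), df_err


def fisher_lsd(
    means: np.ndarray,
    ms_error: float,
    df_error: int,
    n: int,
    pairs: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Fisher's least-significant-difference t tests for selected pairs,
    using the ANOVA error term.  In the two-group case this reduces to
    the unadjusted t test."""
    rows = []
    for i, j in pairs:
        diff = means[i] - means[j]
        if ms_error == 0:
            t = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            t = diff / np.sqrt(2 * ms_error / n)
            p = float(2 * stats.t.sf(abs(t), df_error))
        rows.append({"slot_i": i, "slot_j": j, "mean_i": means[i],
                     "mean_j": means[j], "t": float(t), "p_value": p})
    return pd.DataFrame(rows)


#: Presentation-slot layout of the habituation/dishabituation protocol:
#: three saline, three of a first odor, three of a second odor.
HABITUATION_BLOCKS = (("saline", (0, 1, 2)), ("odor1", (3, 4, 5)),
                      ("odor2", (6, 7, 8)))


def habituation_analysis(
    durations: pd.DataFrame,
    alpha: float = 0.05,
    require_omnibus: bool = True,
) -> HabituationResult:
    """Habituation/dishabituation statistics over nine ordered
    presentations.

    ``durations`` is tidy with columns ``animal_id``, ``slot`` (0-8 in
    presentation order) and ``duration_s``; animals missing any slot are
    excluded.  An omnibus repeated-measures ANOVA across the nine slots
    is followed by Fisher's LSD comparisons of adjacent slots.  Within a
    block, a significant decline marks habituation; at a block
    transition, a significant increase marks dishabituation.  With
    ``require_omnibus`` (classic LSD protection), pairs are flagged
    significant only when the omnibus test passes ``alpha``.
    """
    wide = durations.pivot_table(
        index="animal_id", columns="slot", values="duration_s", aggfunc="first"
    ).reindex(columns=range(9))
    complete = wide.dropna()
    if len(complete) < len(wide):
        logger.info(
            "excluded %d animals with missing presentations",
            len(wide) - len(complete),
        )
    x = complete.to_numpy()
    f, p_omni, ms_err, df_err = rm_anova(x)
    means = x.mean(axis=0)
    pairs = [(i, i + 1) for i in range(8)]
    table = fisher_lsd(means, ms_err, df_err, x.shape[0], pairs)
    transition_types = []
    directions = []
    for i, j in pairs:
        block_i = next(b for b, slots in HABITUATION_BLOCKS if i in slots)
        block_j = next(b for b, slots in HABITUATION_BLOCKS if j in slots)
        transition_types.append(
            "within_block" if block_i == block_j else "block_transition"
        )
        directions.append("decline" if means[j] < means[i] else "increase")
    table["transition"] = transition_types
    table["direction"] = directions
    gate = (p_omni <= alpha) if require_omnibus else True
    table["significant"] = gate & (table["p_value"] <= alpha)
    return HabituationResult(f, p_omni, ms_err, df_err, x.shape[0], table)


def ymaze_summary(
    records: pd.DataFrame,
    zone_a: str,
    zone_b: str,
    paired: bool = False,
) -> dict:
    """Goal-zone duration summary and two-sided t test for the Y-maze.

    Each animal contributes one duration per goal zone; means +/- SEM
    per zone and the zone comparison p-value are returned.
    """
    wide = records.pivot_table(
        index="animal_id", columns="zone_or_odor", values="duration_s",
        aggfunc="first",
    )[[zone_a, zone_b]].dropna()
    a = wide[zone_a].to_numpy()
    b = wide[zone_b].to_numpy()
    if np.allclose(a, b):
        p = 1.0
    elif paired:
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    return {
        "zone_a": zone_a,
        "zone_b": zone_b,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sem_a": float(stats.sem(a)) if len(a) > 1 else np.nan,
        "sem_b": float(stats.sem(b)) if len(b) > 1 else np.nan,
        "difference": float(a.mean() - b.mean()),
        "n": int(len(a)),
        "p_value": p,
    }
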