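"""Group-level statistics on unit populations.

Responsive-unit fractions, seeded permutation tests comparing fractions
between two populations (unpaired pooled re-split) or between two epochs
of the same tracked units (paired within-unit label swap), and the
Wilcoxon signed-rank comparison of paired response strengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_CHUNK = 20_000  # permutation rows materialized at once


class PermutationSettingsError(ValueError):
    """Raised for an unreliable Monte-Carlo setting (too few permutations)."""


@dataclass(frozen=True)
class FractionResult:
    """A responsive fraction with its numerator and denominator."""

    fraction: float
    n_true: int
    n_total: int


@dataclass(frozen=True)
class PermutationTestResult:
    p_value: float
    observed: float
    n_perm: int
    mode: str  # "pooled" or "paired"


def responsive_fraction(flags: np.ndarray) -> FractionResult:
    """Fraction of units flagged responsive (or category members)."""
    arr = np.asarray(flags, dtype=bool)
    if arr.size == 0:
        raise ValueError("empty flag set")
    return FractionResult(float(arr.mean()), int(arr.sum()), int(arr.size))


def _check_n_perm(n_perm: int, force: bool) -> None:
    if n_perm < 1000 and not force:
        raise PermutationSettingsError(
            f"n_perm={n_perm} < 1000 gives unstable p-values; pass force=True "
            "to override"
        )


def permutation_fraction_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    force: bool = False,
) -> PermutationTestResult:
    """Two-sided pooled permutation test on the difference in fractions.

    The statistic is |fraction(a) - fraction(b)|; the null is built by
    pooling both unit sets and re-splitting at the original sizes
    ``n_perm`` times.  Add-one smoothing,
    p = (1 + #{null >= observed}) / (1 + n_perm), keeps p > 0.

    For 0/1 flag vectors the re-split count of true flags landing in
    group a is exactly hypergeometric, so the null is drawn from that
    distribution directly (identical in law to shuffling, much faster);
    general-valued inputs fall back to explicit shuffles.
    """
    _check_n_perm(n_perm, force)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both unit sets must be non-empty")
    observed = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a, n_b = a.size, b.size
    if np.isin(pool, (0.0, 1.0)).all():
        n_true = int(pool.sum())
        k_a = rng.hypergeometric(n_true, pool.size - n_true, n_a, size=n_perm)
        null = np.abs(k_a / n_a - (n_true - k_a) / n_b)
        exceed = int(np.sum(null >= observed - 1e-12))
    else:
        exceed = 0
        done = 0
        while done < n_perm:
            block = min(_CHUNK, n_perm - done)
            mat = rng.permuted(np.tile(pool, (block, 1)), axis=1)
            null = np.abs(mat[:, :n_a].mean(axis=1) - mat[:, n_a:].mean(axis=1))
            exceed += int(np.sum(null >= observed - 1e-12))
            done += block
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(float(p), float(observed), n_perm, "pooled")


def paired_permutation_fraction_test(
    before: np.ndarray,
    after: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    force: bool = False,
) -> PermutationTestResult:
    """Two-sided paired permutation test for tracked units.

    The statistic is |fraction(before) - fraction(after)|; the null is
    built by independently swapping each unit's before/after labels with
    probability 1/2 (equivalently, flipping the sign of its paired
    difference), which respects the within-unit pairing.
    """
    _check_n_perm(n_perm, force)
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired flag vectors must have equal length")
    if before.size == 0:
        raise ValueError("empty unit set")
    diff = before - after
    observed = abs(diff.mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        block = min(_CHUNK, n_perm - done)
        signs = rng.integers(0, 2, size=(block, diff.size)) * 2 - 1
        null = np.abs((signs * diff).mean(axis=1))
        exceed += int(np.sum(null >= observed - 1e-12))
        done += block
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(float(p), float(observed), n_perm, "paired")


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided sign-flip p-value of the Wilcoxon signed-rank
    statistic, valid with tied magnitudes.

    Midranks are doubled to integers and the null distribution of
    W+ = sum of positive ranks is built by convolution over the 2^n
    equiprobable sign patterns.
    """
    ranks = stats.rankdata(np.abs(diffs))
    r2 = np.round(ranks * 2).astype(int)
    w_obs = int(np.round((r2 * (diffs > 0)).sum()))
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total - r + 1]
        dist = dist + shifted
    dist /= dist.sum()
    cdf = np.cumsum(dist)
    p_le = cdf[w_obs]
    p_ge = dist[w_obs:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def paired_strength_test(
    before: np.ndarray,
    after: np.ndarray,
    min_pairs: int = 5,
    exact_max_n: int = 25,
) -> float:
    """Two-sided Wilcoxon signed-rank test on (after - before).

    Zero differences are dropped (Wilcoxon convention); all-zero input
    returns p = 1.  The exact sign-flip distribution is used for up to
    ``exact_max_n`` non-zero pairs, the tie-corrected normal
    approximation above that.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired strength vectors must have equal length")
    if before.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs, got {before.size}")
    diffs = after - before
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    if diffs.size <= exact_max_n:
        return _exact_signed_rank_p(diffs)
    return float(
        stats.wilcoxon(
            diffs, zero_method="wilcox", correction=True, method="approx"
        ).pvalue
    )


def category_shift_table(
    profiles_before: pd.DataFrame,
    profiles_after: pd.DataFrame,
    categories: tuple[str, ...] = ("female", "male", "predator"),
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-category fractions before/after a manipulation with paired
    permutation p-values.

    Both inputs are unit-profile tables (from
    :func:`meaphys.ephys.profile_units`); only units present in both
    epochs are kept (exclusions are logged), matching the analysis of
    units maintained across an injection.
    """
    cat_before = profiles_before.groupby("unit_id")["category"].first()
    cat_after = profiles_after.groupby("unit_id")["category"].first()
    maintained = cat_before.index.intersection(cat_after.index)
    dropped = len(set(cat_before.index) ^ set(cat_after.index))
    if dropped:
        logger.info("excluded %d units present in only one epoch", dropped)
    if maintained.empty:
        raise ValueError("no units maintained across both epochs")
    rows = []
    for i, cat in enumerate(categories):
        flags_before = (cat_before.loc[maintained] == cat).to_numpy()
        flags_after = (cat_after.loc[maintained] == cat).to_numpy()
        res = paired_permutation_fraction_test(
            flags_before,
            flags_after,
            n_perm=n_perm,
            seed=None if seed is None else seed + i,
        )
        rows.append(
            {
                "category": cat,
                "frac_before": flags_before.mean(),
                "frac_after": flags_after.mean(),
                "n_units": len(maintained),
                "p_value": res.p_value,
                "n_perm": n_perm,
                "test_mode": res.mode,
            }
        )
    return pd.DataFrame(rows)
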