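"""Presentation of run results: fraction bars, ternary selectivity,
pre/post strength scatter, and raster + PSTH panels.

Purely presentational — no statistic is computed here that the result
tables do not already contain, except the PSTH, which is a direct
histogram of the plotted spikes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import CATEGORY_ORDER

logger = logging.getLogger(__name__)

_SQRT3_2 = np.sqrt(3) / 2


def ternary_xy(coords: np.ndarray) -> np.ndarray:
    """Map simplex coordinates (f, m, p) to 2-D plotting positions with
    vertices female=(0,0), male=(1,0), predator=(1/2, sqrt(3)/2)."""
    coords = np.asarray(coords, dtype=float)
    x = coords[:, 1] + 0.5 * coords[:, 2]
    y = _SQRT3_2 * coords[:, 2]
    return np.column_stack([x, y])


def category_fraction_bars(profiles: pd.DataFrame, path: Path) -> None:
    per_unit = profiles.groupby("unit_id")["category"].first()
    fracs = [
        (per_unit == cat).mean() * 100 for cat in CATEGORY_ORDER
    ]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(CATEGORY_ORDER, fracs, color=["tab:red", "tab:blue", "tab:green"])
    ax.set_ylabel("units categorized (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def selectivity_ternary(coords: np.ndarray, path: Path) -> None:
    xy = ternary_xy(coords)
    fig, ax = plt.subplots(figsize=(4, 3.6))
    tri = np.array([[0, 0], [1, 0], [0.5, _SQRT3_2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=0.8)
    ax.scatter(xy[:, 0], xy[:, 1], s=12, alpha=0.7)
    for label, (x, y) in zip(
        ("female", "male", "predator"), ((0, 0), (1, 0), (0.5, _SQRT3_2))
    ):
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(0, 4),
                    ha="center", fontsize=8)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def strength_scatter(shift: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.scatter(shift["strength_before"], shift["strength_after"], s=12,
               alpha=0.7)
    ax.plot([-1, 1], [-1, 1], color="grey", lw=0.8)
    ax.set_xlabel("strength before")
    ax.set_ylabel("strength after")
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def raster_psth(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    path: Path,
    pre_s: float = 20.0,
    post_s: float = 40.0,
    bin_s: float = 2.0,
) -> None:
    """Stimulus-aligned raster and peri-stimulus time histogram."""
    aligned = [
        spike_times[(spike_times >= o - pre_s) & (spike_times < o + post_s)] - o
        for o in onsets
    ]
    fig, (ax_r, ax_h) = plt.subplots(
        2, 1, sharex=True, figsize=(4.5, 4), height_ratios=[2, 1]
    )
    for i, trial in enumerate(aligned):
        ax_r.vlines(trial, i + 0.5, i + 1.5, color="k", lw=0.5)
    ax_r.axvspan(0, post_s, color="gold", alpha=0.15)
    ax_r.set_ylabel("trial")
    edges = np.arange(-pre_s, post_s + bin_s, bin_s)
    counts = np.zeros(len(edges) - 1)
    for trial in aligned:
        counts += np.histogram(trial, bins=edges)[0]
    rate = counts / (len(onsets) * bin_s)
    ax_h.stairs(rate, edges, fill=True, color="tab:orange")
    ax_h.set_xlabel("time from stimulus onset (s)")
    ax_h.set_ylabel("rate (spikes/s)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def make_figures(report_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Render all figures a report directory's tables support.

    Missing tables skip the corresponding plot with a warning; an empty
    unit set produces no electrophysiology plots and succeeds.
    """
    report_dir = Path(report_dir)
    out_dir = Path(out_dir) if out_dir is not None else report_dir / "figures"
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    prof_path = report_dir / "unit_profiles.csv"
    if prof_path.exists():
        profiles = pd.read_csv(prof_path)
        if len(profiles):
            if "epoch" in profiles.columns:
                profiles = profiles[profiles["epoch"] == "pre"]
            path = out_dir / "category_fractions.png"
            category_fraction_bars(profiles, path)
            written.append(path)
            resp = profiles[profiles["significant"]]
            if len(resp):
                wide = profiles.pivot_table(
                    index="unit_id", columns="stimulus", values="strength"
                )
                keep = wide.index.isin(resp["unit_id"])
                rect = wide.loc[keep].clip(lower=0)
                cols = [c for c in CATEGORY_ORDER if c in rect.columns]
                coords = rect[cols].to_numpy()
                total = coords.sum(axis=1, keepdims=True)
                ok = total[:, 0] > 0
                coords = coords[ok] / total[ok]
                if len(coords):
                    path = out_dir / "selectivity_ternary.png"
                    selectivity_ternary(coords, path)
                    written.append(path)
    else:
        logger.warning("unit_profiles.csv missing; skipping ephys plots")

    spikes_path = report_dir / "spikes.csv"
    events_path = report_dir / "events.csv"
    if spikes_path.exists() and events_path.exists():
        spikes = pd.read_csv(spikes_path)
        events = pd.read_csv(events_path)
        if len(spikes) and len(events):
            uid = spikes["unit_id"].iloc[0]
            stim = events["stimulus"].iloc[0]
            path = out_dir / f"raster_psth_{uid}_{stim}.png"
            raster_psth(
                spikes.loc[spikes["unit_id"] == uid, "spike_time_s"].to_numpy(),
                events.loc[events["stimulus"] == stim, "onset_s"].to_numpy(),
                path,
            )
            written.append(path)
    return written
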