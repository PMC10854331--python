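"""Headless-safe figures: raw variance distributions with cutoffs, threshold-vs-MCS."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .instability import InstabilitySeries, ThresholdSet
from .proms import Participant

_GROUP_COLORS = {"BD": "#c0392b", "PC": "#e67e22", "HC": "#2980b9"}


def plot_variance_distribution(
    series: Sequence[InstabilitySeries],
    thresholds: ThresholdSet,
    participants: dict[str, Participant],
    path: str | Path,
) -> None:
    """Raw rolling-variance distributions by group with moderate/high cutoff lines."""
    fig, ax = plt.subplots(figsize=(7, 4))
    by_group: dict[str, list[float]] = {}
    for s in series:
        g = participants[s.participant_id].group.value
        by_group.setdefault(g, []).extend(s.raw())
    for g in ("BD", "PC", "HC"):
        if g in by_group:
            ax.hist(
                by_group[g], bins=60, density=True, histtype="step",
                label=g, color=_GROUP_COLORS[g],
            )
    ax.axvline(thresholds.low_cutoff, color="k", ls="-", lw=1,
               label="moderate cutoff (60th pct)")
    ax.axvline(thresholds.high_cutoff, color="k", ls="--", lw=1,
               label="high cutoff (95th pct)")
    ax.set_xlabel(f"raw rolling variance ({thresholds.scale})")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_threshold_vs_mcs(
    categories: dict[str, str],
    mcs_means: dict[str, float],
    path: str | Path,
    scale: str = "",
) -> None:
    """Mean MCS T-score per instability category (low / moderate / high)."""
    order = ["low", "moderate", "high"]
    pids = [p for p in categories if p in mcs_means]
    fig, ax = plt.subplots(figsize=(5, 4))
    means, errs = [], []
    for cat in order:
        vals = [mcs_means[p] for p in pids if categories[p] == cat]
        means.append(np.mean(vals) if vals else np.nan)
        errs.append(np.std(vals) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
    ax.errorbar(order, means, yerr=errs, marker="o", color="#34495e")
    ax.set_ylabel("mean SF-12 MCS (T-score)")
    ax.set_xlabel(f"instability threshold{' (' + scale + ')' if scale else ''}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
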