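"""Matplotlib views of profiles, healing curves and p-value-by-depth tables."""

from __future__ import annotations

from typing import Iterable

import matplotlib.pyplot as plt
import numpy as np

from .depth_stats import DepthPValueProfile
from .kinetics import HealingCurve
from .profiler import GroupProfile

__all__ = ["plot_group_profiles", "plot_healing_curves", "plot_pvalue_profiles"]


def plot_group_profiles(groups: Iterable[GroupProfile], ax=None):
    """Mean +/- SD SAAID versus depth, one errorbar series per group/day."""
    if ax is None:
        _, ax = plt.subplots()
    for g in groups:
        label = g.group if g.day is None else f"{g.group} d{g.day}"
        ax.errorbar(g.depths_um, g.mean, yerr=g.sd, marker="o", capsize=3, label=label)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("depth (μm)")
    ax.set_ylabel("SAAID")
    ax.set_ylim(-1, 1)
    ax.legend()
    return ax


def plot_healing_curves(curves: dict[str, HealingCurve], ax=None):
    """Percent wound closure versus day per group."""
    if ax is None:
        _, ax = plt.subplots()
    for curve in curves.values():
        ax.errorbar(
            curve.days,
            curve.closure_mean,
            yerr=curve.closure_sd,
            marker="s",
            capsize=3,
            label=curve.group,
        )
    ax.set_xlabel("day")
    ax.set_ylabel("wound closure (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    return ax


def plot_pvalue_profiles(profiles: Iterable[DepthPValueProfile], ax=None):
    """Two-sided p versus depth (log scale) with the significance level."""
    if ax is None:
        _, ax = plt.subplots()
    alpha = 0.05
    for pr in profiles:
        alpha = pr.alpha
        tested = pr.tested.astype(bool)
        label = " vs ".join(pr.groups) + ("" if pr.day is None else f" d{pr.day}")
        ax.plot(pr.depths_um[tested], pr.p[tested], marker="o", label=label)
    ax.axhline(alpha, color="r", ls="--", lw=0.8, label=f"α = {alpha:g}")
    ax.set_yscale("log")
    ax.set_xlabel("depth (μm)")
    ax.set_ylabel("two-sided p")
    ax.legend()
    return ax
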