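"""Matplotlib figures for projections and lifetime risk."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_prevalence_trajectories(
    series_by_scenario: dict[str, pd.DataFrame],
    indicator: str = "obesity",
    ax=None,
):
    """Prevalence of one indicator over time, one line per scenario."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for name, series in series_by_scenario.items():
        ax.plot(series.index, 100 * series[indicator], marker="o", label=name)
    ax.set_xlabel("year")
    ax.set_ylabel(f"{indicator} prevalence (%)")
    ax.legend()
    ax.grid(alpha=0.3)
    return ax


def plot_lifetime_risk(risks: dict[str, dict[str, float]], ax=None):
    """Grouped bars of lifetime diabetes risk by sex and scenario."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sexes = list(risks)
    scenarios = list(next(iter(risks.values())))
    width = 0.8 / len(scenarios)
    for i, sc in enumerate(scenarios):
        xs = [j + i * width for j in range(len(sexes))]
        ax.bar(xs, [100 * risks[s][sc] for s in sexes], width=width, label=sc)
    ax.set_xticks([j + 0.4 - width / 2 for j in range(len(sexes))])
    ax.set_xticklabels(sexes)
    ax.set_ylabel("lifetime risk of type 2 diabetes (%)")
    ax.legend()
    return ax


def plot_goodness_of_fit(tables: dict[str, pd.DataFrame], axes=None):
    """Observed vs predicted prevalence diagnostics from a fit."""
    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(14, 4))
    t = tables["by_year"]
    axes[0].plot(t.index, 100 * t["obs_obesity"], "o", label="observed")
    axes[0].plot(t.index, 100 * t["pred_obesity"], "-", label="model")
    axes[0].set_title("obesity by survey year")
    t = tables["by_age"]
    x = range(len(t))
    axes[1].plot(x, 100 * t["obs_obesity"], "o", label="observed")
    axes[1].plot(x, 100 * t["pred_obesity"], "-", label="model")
    axes[1].set_xticks(list(x))
    axes[1].set_xticklabels(t.index, rotation=45, ha="right", fontsize=7)
    axes[1].set_title("obesity by age group")
    t = tables["diabetes_by_bmi"]
    x = range(len(t))
    axes[2].plot(x, 100 * t["obs_diabetes"], "o", label="observed")
    axes[2].plot(x, 100 * t["pred_diabetes"], "-", label="model")
    axes[2].set_xticks(list(x))
    axes[2].set_xticklabels(t.index)
    axes[2].set_title("diabetes by BMI class")
    for ax in axes:
        ax.set_ylabel("prevalence (%)")
        ax.legend(fontsize=8)
        ax.grid(alpha=0.3)
    return axes
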