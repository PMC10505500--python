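"""Headless plots of chemical metrics.

Two views mirror how community chemical metrics are usually inspected:
each metric against a sample variable (one facet per metric, shared x
axis), and two metrics against each other colored by a grouping variable.
Rendering uses the Agg backend so plots work on servers with no display;
figures are returned so tests can read the plotted coordinates back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["PlotSpec", "plot_metrics_vs_variable", "plot_metric_pair"]


@dataclass
class PlotSpec:
    """What to plot: metrics, x variable, optional grouping, optional file."""

    metrics: Sequence[str]
    x: str
    group: str | None = None
    path: str | None = None


def _require_columns(mt: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in mt.columns and c != mt.index.name]
    if missing:
        raise ValueError(f"columns not in the metrics table: {missing}")


def _column(mt: pd.DataFrame, name: str) -> pd.Series:
    if name in mt.columns:
        return mt[name]
    return pd.Series(mt.index, index=mt.index, name=name)


def plot_metrics_vs_variable(mt: pd.DataFrame, spec: PlotSpec):
    """One scatter facet per metric against a shared x variable.

    Returns the matplotlib figure; ``fig.axes`` has one axes per metric and
    each axes' first collection holds the plotted points.
    """
    if not spec.metrics:
        raise ValueError("at least one metric must be requested")
    _require_columns(mt, list(spec.metrics) + [spec.x])
    x = _column(mt, spec.x)
    numeric_x = pd.api.types.is_numeric_dtype(x)
    xvals = x.to_numpy() if numeric_x else np.arange(len(x))

    fig, axes = plt.subplots(
        1, len(spec.metrics), figsize=(3.2 * len(spec.metrics), 3.0),
        sharex=True, squeeze=False,
    )
    for ax, metric in zip(axes[0], spec.metrics):
        ax.scatter(xvals, mt[metric].to_numpy())
        ax.set_ylabel(metric)
        ax.set_xlabel(spec.x)
        if not numeric_x:
            ax.set_xticks(np.arange(len(x)), labels=[str(v) for v in x])
    fig.tight_layout()
    if spec.path:
        fig.savefig(spec.path)
    return fig


def plot_metric_pair(
    mt: pd.DataFrame,
    x_metric: str,
    y_metric: str,
    group: str | None = None,
    path: str | None = None,
):
    """Scatter of one metric against another, colored by an optional group.

    Returns the figure; the plotted points are the union of the axes'
    collections' offsets, and the legend has one entry per group level.
    """
    cols = [x_metric, y_metric] + ([group] if group else [])
    _require_columns(mt, cols)
    fig, ax = plt.subplots(figsize=(4.0, 3.5))
    if group:
        for level, sub in mt.groupby(_column(mt, group), sort=True):
            ax.scatter(sub[x_metric].to_numpy(), sub[y_metric].to_numpy(), label=str(level))
        ax.legend(title=group)
    else:
        ax.scatter(mt[x_metric].to_numpy(), mt[y_metric].to_numpy())
    ax.set_xlabel(x_metric)
    ax.set_ylabel(y_metric)
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig
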