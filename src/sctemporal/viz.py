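"""Visualization of cell-population evolution and embeddings.

Two plot families: fish plots (stacked, smoothly interpolated bands showing
cell-type proportions over time) and 2-d embedding scatter plots colored
either by cell-type label or by a continuous per-cell quantity such as the
centroid correlation used in novel-type detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io import TimepointDataset, ValidationError


@dataclass
class ProportionTrajectory:
    """Per-type proportions at each ordered timepoint."""

    timepoints: list[str]
    proportions: pd.DataFrame  # index: type names; columns: timepoints

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("proportions at each timepoint must sum to 1")

    def l1_distance(self, other: "ProportionTrajectory") -> float:
        """Total absolute difference between two trajectories (same timepoints)."""
        a, b = self.proportions.align(other.proportions, fill_value=0.0)
        return float(np.abs(a.to_numpy() - b.to_numpy()).sum())


def proportion_trajectory(datasets: list[TimepointDataset]) -> ProportionTrajectory:
    """Type fractions per timepoint over the union of observed type names."""
    if len(datasets) < 2:
        raise ValidationError("need at least 2 timepoints")
    for ds in datasets:
        if ds.labels is None:
            raise ValidationError("all datasets must be labeled")
    timepoints = [str(ds.meta.timepoint[0]) for ds in datasets]
    all_types = sorted({str(l) for ds in datasets for l in ds.labels})
    table = pd.DataFrame(0.0, index=all_types, columns=timepoints)
    for tp, ds in zip(timepoints, datasets):
        labels = pd.Series([str(l) for l in ds.labels])
        frac = labels.value_counts(normalize=True)
        for name, p in frac.items():
            table.loc[name, tp] = p
    return ProportionTrajectory(timepoints, table)


def trajectory_from_labels(timepoints, label_lists) -> ProportionTrajectory:
    """Build a trajectory directly from per-timepoint label lists."""
    all_types = sorted({str(l) for labels in label_lists for l in labels})
    table = pd.DataFrame(0.0, index=all_types, columns=[str(t) for t in timepoints])
    for tp, labels in zip(timepoints, label_lists):
        frac = pd.Series([str(l) for l in labels]).value_counts(normalize=True)
        for name, p in frac.items():
            table.loc[name, str(tp)] = p
    return ProportionTrajectory([str(t) for t in timepoints], table)


def fish_plot(pt: ProportionTrajectory, out_path, title: str | None = None) -> None:
    """Stacked band chart of type proportions with smooth interpolation.

    Cumulative proportions are interpolated with a monotone cubic spline, so
    band widths remain nonnegative and stack to full height everywhere.
    """
    x = np.arange(len(pt.timepoints), dtype=float)
    dense_x = np.linspace(x[0], x[-1], 200)
    cum = np.vstack(
        [np.zeros(len(x)), np.cumsum(pt.proportions.to_numpy(), axis=0)]
    )
    if len(x) >= 2:
        curves = [PchipInterpolator(x, row)(dense_x) for row in cum]
    else:
        curves = [np.full_like(dense_x, row[0]) for row in cum]
    fig, ax = plt.subplots(figsize=(7, 4))
    cmap = plt.get_cmap("tab10")
    for i, name in enumerate(pt.proportions.index):
        ax.fill_between(dense_x, curves[i], curves[i + 1], label=str(name),
                        color=cmap(i % 10), lw=0)
    ax.set_xticks(x)
    ax.set_xticklabels(pt.timepoints)
    ax.set_ylim(0, 1)
    ax.set_ylabel("proportion of cells")
    if title:
        ax.set_title(title)
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def embedding_plot(coords: np.ndarray, color_by, out_path, title: str | None = None) -> None:
    """2-d scatter colored by labels (categorical) or by values (continuous)."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValidationError("empty embedding")
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValidationError("coords must be cells x 2")
    color_by = np.asarray(color_by)
    if len(color_by) != coords.shape[0]:
        raise ValidationError("colors and coordinates differ in length")
    fig, ax = plt.subplots(figsize=(6, 5))
    if np.issubdtype(color_by.dtype, np.number):
        sc = ax.scatter(coords[:, 0], coords[:, 1], c=color_by.astype(float),
                        s=6, cmap="viridis")
        fig.colorbar(sc, ax=ax, label="value")
    else:
        cmap = plt.get_cmap("tab10")
        for i, name in enumerate(sorted(set(map(str, color_by)))):
            mask = np.asarray([str(v) == name for v in color_by])
            ax.scatter(coords[mask, 0], coords[mask, 1], s=6, color=cmap(i % 10),
                       label=name)
        ax.legend(markerscale=2, fontsize=8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
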