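"""Min-max normalization and highly-variable-gene (HVG) selection.

Scaling is per gene across cells: each gene is rescaled to [0, 1] using its
own min and max, the standard feature scaling for a classifier whose input
features are genes. The per-gene statistics of the training matrix can be
reused to scale later-timepoint matrices onto the same scale (with clipping),
so that classifier inputs are comparable across timepoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MinMaxStats:
    """Per-gene min/max recorded from a (training) matrix."""

    gene_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray


@dataclass
class FeatureSet:
    """An ordered HVG selection together with the matrix it came from."""

    gene_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("FeatureSet gene_ids contain duplicates")

    def __len__(self) -> int:
        return len(self.gene_ids)


def fit_min_max(m: ExpressionMatrix) -> MinMaxStats:
    """Record per-gene min and max from a raw count matrix."""
    return MinMaxStats(
        gene_ids=list(m.gene_ids),
        mins=m.values.min(axis=1).astype(float),
        maxs=m.values.max(axis=1).astype(float),
    )


def min_max_normalize(m: ExpressionMatrix, stats: MinMaxStats | None = None) -> ExpressionMatrix:
    """Rescale each gene to [0, 1] via (x - min) / (max - min).

    Constant genes map to all-zeros (0/0 is defined as 0: an uninformative
    feature should carry no signal). When ``stats`` from a training matrix is
    given, its min/max are applied instead and the result is clipped to
    [0, 1], so test matrices share the training feature scale.
    """
    if m.normalized:
        raise ValidationError("matrix is already normalized (double normalization)")
    if stats is None:
        stats = fit_min_max(m)
    elif stats.gene_ids != m.gene_ids:
        raise ValidationError("normalization statistics were fitted on different genes")
    span = stats.maxs - stats.mins
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (m.values - stats.mins[:, None]) / span[:, None]
    scaled = np.where(span[:, None] > 0, scaled, 0.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    return ExpressionMatrix(scaled, list(m.gene_ids), list(m.cell_ids), normalized=True)


def select_hvg(m: ExpressionMatrix, n_top: int = 2000) -> FeatureSet:
    """Select the ``n_top`` genes with largest per-gene variance.

    Variance is computed on the min-max-normalized scale; ties are broken by
    input gene order so the selection is deterministic. If the matrix has
    fewer than ``n_top`` genes, all genes are returned with a warning.
    """
    if m.n_genes == 0:
        raise ValidationError("cannot select HVGs from an empty matrix")
    values = m.values if m.normalized else min_max_normalize(m).values
    variances = values.var(axis=1)
    if m.n_genes <= n_top:
        if m.n_genes < n_top:
            warnings.warn(
                f"requested {n_top} HVGs but matrix has only {m.n_genes} genes; "
                "returning all genes",
                stacklevel=2,
            )
        return FeatureSet(list(m.gene_ids), source="all")
    # stable sort on negated variance keeps input order among ties
    order = np.argsort(-variances, kind="stable")[:n_top]
    order = np.sort(order)  # preserve genomic order within the selection
    return FeatureSet([m.gene_ids[i] for i in order], source="hvg")


def align_features(
    train: ExpressionMatrix, test: ExpressionMatrix, fs: FeatureSet
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the feature set, in its order.

    Genes in ``fs`` missing from ``test`` are filled with zero rows (logged);
    more than 50% missing is treated as incompatible feature spaces.
    """
    train_sub = train.subset_genes(fs.gene_ids)
    test_idx = {g: i for i, g in enumerate(test.gene_ids)}
    missing = [g for g in fs.gene_ids if g not in test_idx]
    if len(missing) > 0.5 * len(fs):
        raise ValidationError(
            f"{len(missing)}/{len(fs)} selected genes absent from test matrix; "
            "feature spaces are incompatible"
        )
    if missing:
        logger.warning(
            "%d of %d selected genes absent from test matrix; filled with zeros",
            len(missing),
            len(fs),
        )
    out = np.zeros((len(fs), test.n_cells), dtype=test.values.dtype)
    for row, g in enumerate(fs.gene_ids):
        i = test_idx.get(g)
        if i is not None:
            out[row, :] = test.values[i, :]
    test_sub = ExpressionMatrix(out, list(fs.gene_ids), list(test.cell_ids), test.normalized)
    return train_sub, test_sub


def prepare_training_features(
    train: ExpressionMatrix, n_hvg: int = 2000
) -> tuple[ExpressionMatrix, FeatureSet, MinMaxStats]:
    """Normalize a raw training matrix, select HVGs and keep the scaler stats.

    Convenience used by the annotation and novel-detection pipelines: returns
    the normalized HVG-restricted matrix, the feature set, and the per-gene
    min/max (on the HVG subset) to apply to later timepoints.
    """
    norm = min_max_normalize(train)
    fs = select_hvg(norm, n_top=n_hvg)
    train_hvg_raw = train.subset_genes(fs.gene_ids)
    stats = fit_min_max(train_hvg_raw)
    return min_max_normalize(train_hvg_raw, stats), fs, stats


def apply_training_features(
    test: ExpressionMatrix, fs: FeatureSet, stats: MinMaxStats
) -> ExpressionMatrix:
    """Project a raw test matrix onto the training HVGs and training scale."""
    test_idx = {g: i for i, g in enumerate(test.gene_ids)}
    missing = [g for g in fs.gene_ids if g not in test_idx]
    if len(missing) > 0.5 * len(fs):
        raise ValidationError(
            f"{len(missing)}/{len(fs)} training genes absent from test matrix"
        )
    if missing:
        logger.warning("%d training genes absent from test matrix; zero-filled", len(missing))
    out = np.zeros((len(fs), test.n_cells), dtype=float)
    for row, g in enumerate(fs.gene_ids):
        i = test_idx.get(g)
        if i is not None:
            out[row, :] = test.values[i, :]
    raw = ExpressionMatrix(out.astype(np.int64), list(fs.gene_ids), list(test.cell_ids), False)
    return min_max_normalize(raw, stats)
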