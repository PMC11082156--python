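"""Detection of novel cell types emerging at later timepoints.

A closed-set classifier trained on the initial timepoint necessarily assigns
every later cell to a known type. Cells of a genuinely new type, however,
resemble their assigned reference type less than the reference's own cells
do. The detection pipeline exploits this:

1. embed the training HVG matrix into 20 dimensions with UMAP and project
   the later-timepoint cells into the same space;
2. compute each known type's centroid (mean embedding of its training cells);
3. for every later cell, the Pearson correlation between its embedding and
   the centroid of its predicted type;
4. bisect each predicted type's cells into two groups with Louvain
   clustering, sweeping the resolution until exactly two communities appear;
5. Welch two-sample t-test on the two groups' correlations; if significant,
   the group with the smaller mean correlation is flagged;
6. flagged groups across all types are pooled and relabeled with a reserved
   novel-type label.

The embedding is fitted once on all training cells (transform semantics for
the test cells) rather than per type: correlations are only comparable in a
common space, and per-type refits degenerate for small types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .annotate import AnnotationResult, _knn_graph, _louvain
from .io import ExpressionMatrix, TimepointDataset, ValidationError

logger = logging.getLogger(__name__)

RESOLUTION_GRID = np.round(np.arange(0.05, 2.0001, 0.05), 2)


@dataclass
class TypeTestResult:
    """Per-type bisection + t-test summary."""

    cell_type: str
    n_cells: int
    group_sizes: tuple[int, int]
    mean_correlations: tuple[float, float]
    t_statistic: float
    p_value: float
    flagged_group: int | None  # 0/1, or None when not significant/skipped
    skipped: str | None = None  # reason, when the type was not tested


@dataclass
class NovelDetectionReport:
    cell_ids: list[str]
    predicted_label: list[str]  # classifier labels before relabeling
    correlation: np.ndarray  # per-cell corr to its predicted type's centroid
    group: np.ndarray  # bisection group within predicted type (-1 = untested)
    novel_flag: np.ndarray  # boolean per cell
    type_tests: list[TypeTestResult]
    relabeled: AnnotationResult
    novel_label: str
    embedding_2d: np.ndarray | None = None  # test cells x 2, for plotting
    extras: dict = field(default_factory=dict)

    def per_cell_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "predicted_label": self.predicted_label,
                "correlation": self.correlation,
                "group": self.group,
                "novel_flag": self.novel_flag,
                "final_label": self.relabeled.predicted_label,
            }
        )

    def per_type_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.type_tests:
            rows.append(
                {
                    "cell_type": t.cell_type,
                    "n_cells": t.n_cells,
                    "n_group0": t.group_sizes[0],
                    "n_group1": t.group_sizes[1],
                    "mean_corr_group0": t.mean_correlations[0],
                    "mean_corr_group1": t.mean_correlations[1],
                    "t_statistic": t.t_statistic,
                    "p_value": t.p_value,
                    "flagged_group": t.flagged_group,
                    "skipped": t.skipped,
                }
            )
        return pd.DataFrame(rows)


def embed(
    train_hvg: ExpressionMatrix,
    test_hvg: ExpressionMatrix,
    dim: int = 20,
    seed: int = 0,
    n_neighbors: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """UMAP embedding fitted on training cells, test cells projected into it.

    Returns (train_embedding, test_embedding), each cells x dim. Deterministic
    for a fixed seed (UMAP runs single-threaded when seeded).
    """
    import umap

    if train_hvg.gene_ids != test_hvg.gene_ids:
        raise ValidationError("train and test matrices must share gene order")
    if dim >= train_hvg.n_cells:
        raise ValidationError(
            f"embedding dimension {dim} must be smaller than {train_hvg.n_cells} cells"
        )
    reducer = umap.UMAP(
        n_components=dim,
        n_neighbors=min(n_neighbors, train_hvg.n_cells - 1),
        random_state=seed,
        transform_seed=seed,
    )
    emb_train = reducer.fit_transform(train_hvg.values.T)
    if test_hvg.cell_ids == train_hvg.cell_ids and np.array_equal(
        test_hvg.values, train_hvg.values
    ):
        emb_test = emb_train.copy()
    else:
        emb_test = reducer.transform(test_hvg.values.T)
    return np.asarray(emb_train, dtype=float), np.asarray(emb_test, dtype=float)


def type_centroid(embedding_train: np.ndarray, labels, cell_type) -> np.ndarray:
    """Coordinate-wise mean embedding of one type's training cells."""
    labels = np.asarray(labels)
    mask = labels == cell_type
    if not mask.any():
        raise ValidationError(f"no training cells of type '{cell_type}'")
    return embedding_train[mask].mean(axis=0)


def corr_to_centroid(cell_embeddings: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Pearson correlation of each cell's embedding vector with the centroid.

    Cells (or a centroid) with zero variance across coordinates yield NaN and
    are excluded from downstream testing.
    """
    cell_embeddings = np.atleast_2d(np.asarray(cell_embeddings, dtype=float))
    centroid = np.asarray(centroid, dtype=float)
    if cell_embeddings.shape[1] != centroid.shape[0]:
        raise ValidationError("cell vectors and centroid must share dimension")
    if cell_embeddings.shape[1] < 3:
        raise ValidationError("correlation needs at least 3 embedding coordinates")
    c = centroid - centroid.mean()
    c_norm = np.sqrt((c**2).sum())
    x = cell_embeddings - cell_embeddings.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((x**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x @ c) / (x_norm * c_norm)
    r = np.where((x_norm > 0) & (c_norm > 0), r, np.nan)
    n_missing = int(np.isnan(r).sum())
    if n_missing:
        logger.warning("%d cells with zero-variance embeddings excluded", n_missing)
    return np.clip(r, -1.0, 1.0)


def louvain_bisect(
    cell_vectors: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    resolution_grid: np.ndarray = RESOLUTION_GRID,
) -> tuple[np.ndarray, float]:
    """Split one predicted type's cells into exactly two Louvain communities.

    ``cell_vectors`` is cells x features — the cells' normalized HVG
    expression (re-clustering happens in gene space, where an admixed novel
    population stays separable even when the transform-projected embedding
    compresses it onto the reference types). The resolution parameter is
    swept over an increasing grid until the community count is exactly 2.
    If no grid value produces 2 communities, the smallest resolution
    yielding >=2 is taken and all but the largest community are merged into
    one group (logged).
    """
    embedding = np.asarray(cell_vectors, dtype=float)
    n = embedding.shape[0]
    k = min(n_neighbors, n - 1)
    graph = _knn_graph(embedding, k)
    fallback = None
    for res in resolution_grid:
        communities = _louvain(graph, seed, float(res))
        sizes = [len(c) for c in communities]
        if len(sizes) == 2:
            return np.asarray(communities.membership), float(res)
        if len(sizes) > 2 and fallback is None:
            fallback = (communities, float(res))
    if fallback is None:
        raise ValidationError("no resolution produced two or more communities")
    communities, res = fallback
    logger.warning(
        "no resolution yielded exactly 2 communities; merging all but the "
        "largest of %d communities at resolution %.2f",
        len(communities),
        res,
    )
    membership = np.asarray(communities.membership)
    largest = np.argmax([len(c) for c in communities])
    return (membership != largest).astype(int), res


def flag_novel_for_type(
    groups: np.ndarray,
    correlations: np.ndarray,
    alpha: float = 0.05,
    max_flag_fraction: float = 0.5,
) -> tuple[float, float, int | None]:
    """Welch t-test of the two groups' correlations.

    Returns (t_statistic, p_value, flagged_group). The flagged group is the
    one with the smaller mean correlation when p < alpha, else None. Novel
    cells misassigned into a known type form a minority of that type's
    cells, so a significant group is only flagged when it holds at most
    ``max_flag_fraction`` of the type (a majority with marginally lower
    correlation is within-type structure, not an emerging type). Cells with
    missing correlations are dropped; a group left with fewer than two
    usable values, or two zero-variance groups, skips the test (p = NaN).
    """
    groups = np.asarray(groups)
    correlations = np.asarray(correlations, dtype=float)
    usable = ~np.isnan(correlations)
    g0 = correlations[(groups == 0) & usable]
    g1 = correlations[(groups == 1) & usable]
    if len(g0) < 2 or len(g1) < 2:
        return np.nan, np.nan, None
    if g0.std() == 0 and g1.std() == 0:
        return np.nan, np.nan, None
    t_stat, p = scipy.stats.ttest_ind(g0, g1, equal_var=False)
    if np.isnan(p) or p >= alpha:
        return float(t_stat), float(p), None
    flagged = 0 if g0.mean() < g1.mean() else 1
    n_total = (groups == 0).sum() + (groups == 1).sum()
    n_flagged = (groups == flagged).sum()
    if n_flagged > max_flag_fraction * n_total:
        return float(t_stat), float(p), None
    return float(t_stat), float(p), flagged


def detect_novel(
    train: TimepointDataset,
    test: TimepointDataset,
    ann: AnnotationResult,
    alpha: float = 0.05,
    embed_dim: int = 20,
    min_cells: int = 20,
    n_hvg: int = 2000,
    seed: int = 0,
    novel_label: str = "novel",
    compute_2d: bool = True,
) -> NovelDetectionReport:
    """Run the full six-step novel-type detection on an annotated timepoint.

    ``ann`` must cover all cells of ``test``; ``train`` must be labeled.
    Types with fewer than ``min_cells`` predicted cells are never flagged.
    """
    from .preprocess import apply_training_features, prepare_training_features

    if train.labels is None:
        raise ValidationError("training dataset must be labeled")
    if test.n_cells == 0:
        raise ValidationError("empty test dataset")
    if list(ann.cell_ids) != list(test.matrix.cell_ids):
        raise ValidationError("annotation does not cover the test cells in order")

    known_types = set(map(str, train.labels))
    while novel_label in known_types:
        novel_label += "_1"

    x0_hvg, fs, stats = prepare_training_features(train.matrix, n_hvg=n_hvg)
    x1_hvg = apply_training_features(test.matrix, fs, stats)
    emb_train, emb_test = embed(x0_hvg, x1_hvg, dim=embed_dim, seed=seed)

    train_labels = np.asarray([str(v) for v in train.labels])
    pred = np.asarray(ann.predicted_label)
    n_test = test.n_cells
    correlation = np.full(n_test, np.nan)
    group = np.full(n_test, -1, dtype=int)
    novel_flag = np.zeros(n_test, dtype=bool)
    tests: list[TypeTestResult] = []

    for cell_type in sorted(set(pred)):
        members = np.flatnonzero(pred == cell_type)
        if cell_type not in known_types:
            tests.append(
                TypeTestResult(cell_type, len(members), (0, 0), (np.nan, np.nan),
                               np.nan, np.nan, None, skipped="unknown reference type")
            )
            continue
        centroid = type_centroid(emb_train, train_labels, cell_type)
        r = corr_to_centroid(emb_test[members], centroid)
        correlation[members] = r
        if len(members) < min_cells:
            tests.append(
                TypeTestResult(cell_type, len(members), (0, 0), (np.nan, np.nan),
                               np.nan, np.nan, None, skipped="fewer than min_cells")
            )
            continue
        membership, _res = louvain_bisect(x1_hvg.values.T[members], seed=seed)
        group[members] = membership
        t_stat, p, flagged = flag_novel_for_type(membership, r, alpha)
        sizes = (int((membership == 0).sum()), int((membership == 1).sum()))
        means = (
            float(np.nanmean(r[membership == 0])) if sizes[0] else np.nan,
            float(np.nanmean(r[membership == 1])) if sizes[1] else np.nan,
        )
        skipped = "degenerate t-test" if np.isnan(p) else None
        tests.append(
            TypeTestResult(cell_type, len(members), sizes, means, t_stat, p, flagged,
                           skipped=skipped)
        )
        if flagged is not None:
            novel_flag[members[membership == flagged]] = True

    final_labels = [novel_label if f else l for f, l in zip(novel_flag, pred)]
    class_names = list(ann.class_names)
    if novel_label not in class_names:
        class_names.append(novel_label)
    # extend the probability matrix with a column for the reserved label;
    # flagged cells get probability 1 on it (the detection is a hard decision)
    probs = np.zeros((n_test, len(class_names)))
    probs[:, : ann.probabilities.shape[1]] = ann.probabilities
    probs[novel_flag, :] = 0.0
    probs[novel_flag, class_names.index(novel_label)] = 1.0
    relabeled = AnnotationResult(list(ann.cell_ids), final_labels, probs, class_names)

    embedding_2d = None
    if compute_2d:
        _, embedding_2d = embed(x0_hvg, x1_hvg, dim=2, seed=seed)

    return NovelDetectionReport(
        cell_ids=list(ann.cell_ids),
        predicted_label=list(pred),
        correlation=correlation,
        group=group,
        novel_flag=novel_flag,
        type_tests=tests,
        relabeled=relabeled,
        novel_label=novel_label,
        embedding_2d=embedding_2d,
    )
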