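"""Supervised cross-timepoint cell annotation.

A compact feed-forward network is trained on the labeled initial timepoint
and used to assign cell-type labels (with class probabilities) to cells from
later timepoints. The architecture follows the pipeline's stated design:
three ReLU hidden layers of 256/128/64 units, softmax output over the K cell
types, mean-squared-error loss against one-hot targets, Adam optimization
with mini-batches, dropout 0.4 on each hidden layer, and early stopping on a
held-out validation split with best-weight restoration.

When the initial timepoint carries no labels, :func:`unsupervised_t0_labels`
produces Louvain community labels on a kNN graph of a low-dimensional
embedding, which then serve as training classes.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import numpy as np

from .io import CellMetadata, ExpressionMatrix, TimepointDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClassifierSpec:
    """Hyperparameters of the annotation network."""

    n_features: int = 2000
    n_classes: int = 0  # filled from the training labels
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    dropout_rate: float = 0.4
    activation: str = "relu"
    output_activation: str = "softmax"
    loss: str = "mse"  # "mse" (one-hot targets) or "cross_entropy"
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValidationError("hidden layer sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValidationError(f"unknown loss '{self.loss}'")


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    class_names: list[str]
    history: dict = field(default_factory=dict)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.history["val_loss"]))


@dataclass
class AnnotationResult:
    cell_ids: list[str]
    predicted_label: list[str]
    probabilities: np.ndarray  # cells x K
    class_names: list[str]

    def __post_init__(self) -> None:
        sums = self.probabilities.sum(axis=1)
        if self.probabilities.size and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("probability rows must sum to 1")

    @property
    def max_probability(self) -> np.ndarray:
        return self.probabilities.max(axis=1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, biases, x, dropout_rate=0.0, rng=None):
    """Forward pass; returns activations per layer and dropout masks."""
    acts = [x]
    masks = []
    a = x
    n_hidden = len(weights) - 1
    for layer in range(n_hidden):
        z = a @ weights[layer] + biases[layer]
        a = np.maximum(z, 0.0)
        if dropout_rate > 0 and rng is not None:
            mask = (rng.random(a.shape) >= dropout_rate) / (1.0 - dropout_rate)
            a = a * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(a)
    probs = _softmax(a @ weights[-1] + biases[-1])
    acts.append(probs)
    return acts, masks


def _loss_and_output_grad(probs, onehot, loss):
    b = probs.shape[0]
    if loss == "mse":
        value = float(np.sum((probs - onehot) ** 2) / b)
        dprobs = 2.0 * (probs - onehot) / b
        # back through softmax jacobian
        dz = probs * (dprobs - np.sum(dprobs * probs, axis=1, keepdims=True))
    else:  # cross-entropy with softmax: the usual simplification
        value = float(-np.sum(onehot * np.log(probs + 1e-12)) / b)
        dz = (probs - onehot) / b
    return value, dz


def _stratified_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Indices of a stratified validation split; every class keeps >=1 train cell."""
    val_idx = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < 2:
            raise ValidationError(
                f"class '{cls}' has a single cell; cannot stratify a validation split"
            )
        members = rng.permutation(members)
        n_val = max(1, int(round(fraction * len(members))))
        n_val = min(n_val, len(members) - 1)
        val_idx.extend(members[:n_val])
    val_mask = np.zeros(len(labels), dtype=bool)
    val_mask[val_idx] = True
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def train_classifier(
    x0: ExpressionMatrix, y0, spec: ClassifierSpec | None = None
) -> TrainedClassifier:
    """Train the annotation network on a normalized, HVG-restricted matrix.

    ``x0`` is genes x cells on the [0, 1] scale; ``y0`` gives one label per
    cell. All stochastic components (weight initialization, validation split,
    batch shuffling, dropout) derive from ``spec.seed``.
    """
    spec = spec or ClassifierSpec()
    y0 = np.asarray([str(v) for v in y0])
    if x0.n_cells != len(y0):
        raise ValidationError("number of cells does not match number of labels")
    class_names = sorted(set(y0))
    k = len(class_names)
    if k < 2:
        raise ValidationError("training requires at least 2 distinct classes")
    counts = {c: int(np.sum(y0 == c)) for c in class_names}
    rarest = min(counts.values())
    if rarest < max(1, int(0.01 * len(y0))):
        logger.warning("rarest class has %d cells (<1%% of %d)", rarest, len(y0))

    spec.n_features = x0.n_genes
    spec.n_classes = k
    rng = np.random.default_rng(spec.seed)

    x = x0.values.T.astype(np.float64)  # cells x features
    label_to_col = {c: i for i, c in enumerate(class_names)}
    onehot = np.zeros((len(y0), k))
    onehot[np.arange(len(y0)), [label_to_col[v] for v in y0]] = 1.0

    train_idx, val_idx = _stratified_split(y0, spec.validation_fraction, rng)
    x_tr, y_tr = x[train_idx], onehot[train_idx]
    x_va, y_va = x[val_idx], onehot[val_idx]

    sizes = [spec.n_features, *spec.hidden_sizes, k]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = [w.copy() for w in weights]
    best_biases = [b.copy() for b in biases]
    stale = 0

    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            acts, masks = _forward(weights, biases, xb, spec.dropout_rate, rng)
            loss, dz = _loss_and_output_grad(acts[-1], yb, spec.loss)
            if not np.isfinite(loss):
                raise ValidationError("non-finite training loss; training failed")
            epoch_loss += loss
            n_batches += 1
            # backprop
            grad_w = [None] * len(weights)
            grad_b = [None] * len(biases)
            delta = dz
            for layer in range(len(weights) - 1, -1, -1):
                a_prev = acts[layer]
                grad_w[layer] = a_prev.T @ delta
                grad_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ weights[layer].T
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (acts[layer] > 0)
            step += 1
            for layer in range(len(weights)):
                for g, m_, v_, p in (
                    (grad_w[layer], m_w, v_w, weights),
                    (grad_b[layer], m_b, v_b, biases),
                ):
                    m_[layer] = beta1 * m_[layer] + (1 - beta1) * g
                    v_[layer] = beta2 * v_[layer] + (1 - beta2) * g * g
                    m_hat = m_[layer] / (1 - beta1**step)
                    v_hat = v_[layer] / (1 - beta2**step)
                    p[layer] -= spec.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        val_acts, _ = _forward(weights, biases, x_va)
        val_loss, _ = _loss_and_output_grad(val_acts[-1], y_va, spec.loss)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = [w.copy() for w in weights]
            best_biases = [b.copy() for b in biases]
            stale = 0
        else:
            stale += 1
            if stale >= spec.patience:
                break

    return TrainedClassifier(
        spec=spec,
        weights=best_weights,
        biases=best_biases,
        class_names=class_names,
        history=history,
    )


def predict(clf: TrainedClassifier, x1: ExpressionMatrix) -> AnnotationResult:
    """Predict labels and class probabilities for aligned later-timepoint cells."""
    if x1.n_genes != clf.spec.n_features:
        raise ValidationError(
            f"matrix has {x1.n_genes} features but classifier expects {clf.spec.n_features}"
        )
    acts, _ = _forward(clf.weights, clf.biases, x1.values.T.astype(np.float64))
    probs = acts[-1]
    labels = [clf.class_names[i] for i in probs.argmax(axis=1)]
    return AnnotationResult(list(x1.cell_ids), labels, probs, list(clf.class_names))


def _knn_graph(embedding: np.ndarray, n_neighbors: int):
    """Undirected kNN graph (igraph) from a cells x dim embedding."""
    import igraph
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    if n <= n_neighbors:
        raise ValidationError(
            f"{n} cells is too few for a {n_neighbors}-nearest-neighbor graph"
        )
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def _louvain(graph, seed: int, resolution: float = 1.0):
    import igraph

    igraph.set_random_number_generator(_random.Random(seed))
    return graph.community_multilevel(resolution=resolution)


def unsupervised_t0_labels(
    x0: ExpressionMatrix,
    n_neighbors: int = 15,
    embed_dim: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
) -> list[str]:
    """Louvain community labels for an unlabeled initial timepoint.

    The normalized HVG matrix is embedded into ``embed_dim`` dimensions with
    UMAP, a kNN graph is built on the embedding, and Louvain communities
    become labels "cluster_1" ... "cluster_K". The default resolution is
    deliberately coarse: these labels stand in for cell *types*, and
    modularity at resolution 1 fragments small homogeneous populations.
    """
    from .novel import embed

    emb, _ = embed(x0, x0, dim=embed_dim, seed=seed)
    graph = _knn_graph(emb, n_neighbors)
    communities = _louvain(graph, seed, resolution)
    return [f"cluster_{m + 1}" for m in communities.membership]


def stepwise_merge(t0: TimepointDataset, t1_annotated: TimepointDataset) -> TimepointDataset:
    """Concatenate labeled t0 and labeled t1 data for the t1->t2 transition.

    The merged matrix lives on the intersection of the two gene sets;
    overlapping barcodes are suffix-disambiguated.
    """
    if t0.labels is None or t1_annotated.labels is None:
        raise ValidationError("both datasets must be labeled before merging")
    genes = [g for g in t0.matrix.gene_ids if g in set(t1_annotated.matrix.gene_ids)]
    if not genes:
        raise ValidationError("gene sets of the two datasets do not overlap")
    m0 = t0.matrix.subset_genes(genes)
    m1 = t1_annotated.matrix.subset_genes(genes)
    cells0 = list(m0.cell_ids)
    overlap = set(cells0) & set(m1.cell_ids)
    cells1 = [f"{c}_t1" if c in overlap else c for c in m1.cell_ids]
    if overlap:
        logger.warning("%d overlapping barcodes suffix-disambiguated", len(overlap))
    merged = ExpressionMatrix(
        np.concatenate([m0.values, m1.values], axis=1),
        genes,
        cells0 + cells1,
        normalized=m0.normalized,
    )
    meta = CellMetadata(
        cell_ids=cells0 + cells1,
        timepoint=list(t0.meta.timepoint) + list(t1_annotated.meta.timepoint),
        strata=(
            list(t0.meta.strata) + list(t1_annotated.meta.strata)
            if t0.meta.strata is not None and t1_annotated.meta.strata is not None
            else None
        ),
        labels=list(t0.labels) + list(t1_annotated.labels),
    )
    return TimepointDataset(merged, meta)


def annotate_dataset(
    t0: TimepointDataset,
    later: TimepointDataset,
    n_hvg: int = 2000,
    spec: ClassifierSpec | None = None,
) -> tuple[AnnotationResult, TrainedClassifier]:
    """End-to-end annotation: HVGs + scaling from t0, train, predict on ``later``.

    If t0 carries no labels, Louvain clusters of t0 are used as classes.
    """
    from .preprocess import apply_training_features, prepare_training_features

    spec = spec or ClassifierSpec()
    x0_hvg, fs, stats = prepare_training_features(t0.matrix, n_hvg=n_hvg)
    labels = t0.labels
    if labels is None:
        logger.info("t0 unlabeled; falling back to unsupervised clustering")
        labels = unsupervised_t0_labels(x0_hvg, seed=spec.seed)
    clf = train_classifier(x0_hvg, labels, spec)
    x1_hvg = apply_training_features(later.matrix, fs, stats)
    return predict(clf, x1_hvg), clf
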