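"""Evaluation metrics: annotation accuracy, adjusted Rand index, and TDR."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io import ValidationError


def accuracy(truth, prediction) -> float:
    """Fraction of cells whose predicted label string equals the true one.

    The reserved novel-type label therefore counts as correct only against
    cells whose ground truth carries that same label.
    """
    truth = list(map(str, truth))
    prediction = list(map(str, prediction))
    if len(truth) != len(prediction):
        raise ValidationError("label lists differ in length")
    if not truth:
        raise ValidationError("empty label lists")
    return float(np.mean([t == p for t, p in zip(truth, prediction)]))


def adjusted_rand_index(truth, prediction) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    truth = list(truth)
    prediction = list(prediction)
    if len(truth) != len(prediction):
        raise ValidationError("label lists differ in length")
    if len(truth) < 2:
        raise ValidationError("ARI requires at least 2 items")
    return float(adjusted_rand_score(truth, prediction))


def true_discovery_rate(called, truth) -> float:
    """|called ∩ truth| / |called| — one minus the false discovery rate."""
    called = set(called)
    truth = set(truth)
    if not called:
        raise ValidationError("TDR is undefined for an empty call set")
    return len(called & truth) / len(called)
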