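"""Synthetic multi-timepoint scRNA-seq data with known ground truth.

The generator produces a parametric negative-binomial world with
marker-block structure: every cell type up-shifts its own disjoint block of
marker genes, so types are separable but share most of the transcriptome.
Two designs are covered:

* three cell-composition scenarios across timepoints t0/t1/t2 —
  (1) the same types with shifted proportions, (2) a type that disappears
  after t0, (3) a novel type absent from t0 that appears at t1/t2; and
* a tDEG spike-in design in which a subset of genes drifts over time in
  opposite directions in two strata (time x strata interaction), at weak,
  medium, or strong effect levels.

Ground truth (per-cell types, novel indicators, per-gene tDEG indicators and
true coefficients) is emitted alongside the data so every pipeline stage can
be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellMetadata, ExpressionMatrix, TimepointDataset, ValidationError

DEFAULT_COMPOSITIONS = {
    1: {
        "t0": (0.20, 0.20, 0.20, 0.20, 0.20),
        "t1": (0.35, 0.25, 0.20, 0.10, 0.10),
        "t2": (0.10, 0.10, 0.20, 0.25, 0.35),
    },
    2: {
        "t0": (0.20, 0.20, 0.20, 0.20, 0.20),
        "t1": (0.30, 0.25, 0.25, 0.20, 0.00),
        "t2": (0.30, 0.25, 0.25, 0.20, 0.00),
    },
    3: {
        "t0": (0.25, 0.25, 0.25, 0.25, 0.00),
        "t1": (0.20, 0.20, 0.20, 0.20, 0.20),
        "t2": (0.20, 0.15, 0.20, 0.15, 0.30),
    },
}

EFFECT_LEVELS = {"weak": 0.1, "medium": 0.25, "strong": 0.5}


@dataclass
class ScenarioConfig:
    """Configuration of a cell-composition scenario.

    ``effect_size`` is the log-fold up-shift of each type's marker block;
    the scenario-3 novel type receives ``novel_type_shift`` on top, making
    it transcriptomically distinct from every reference type.
    """

    scenario: int = 1
    n_genes: int = 2000
    cells_per_timepoint: int = 1500
    cell_types: tuple[str, ...] = ("type_1", "type_2", "type_3", "type_4", "type_5")
    type_compositions: dict | None = None
    marker_fraction: float = 0.10
    effect_size: float = 1.0
    novel_type_shift: float = 0.5
    base_mean_shape: float = 2.0
    base_mean_scale: float = 0.5
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValidationError("scenario must be 1, 2 or 3")
        if self.type_compositions is None:
            self.type_compositions = {
                tp: dict(zip(self.cell_types, props))
                for tp, props in DEFAULT_COMPOSITIONS[self.scenario].items()
            }
        for tp, comp in self.type_compositions.items():
            total = sum(comp.values())
            if any(v < 0 for v in comp.values()) or abs(total - 1.0) > 1e-9:
                raise ValidationError(f"composition at {tp} is not a distribution")

    @property
    def novel_type(self) -> str | None:
        if self.scenario != 3:
            return None
        t0 = self.type_compositions["t0"]
        for name in self.cell_types:
            if t0.get(name, 0.0) == 0.0:
                return name
        return None


@dataclass
class TDEGSimConfig:
    """Configuration of the tDEG spike-in design."""

    n_genes: int = 2000
    n_cells: int = 900
    n_tdegs: int = 300
    effect_level: str = "medium"
    n_timepoints: int = 3
    strata_proportion: float = 0.5
    base_mean_shape: float = 2.0
    base_mean_scale: float = 0.5
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tdegs > self.n_genes:
            raise ValidationError("n_tdegs cannot exceed n_genes")
        if self.effect_level not in EFFECT_LEVELS:
            raise ValidationError(
                f"effect_level must be one of {sorted(EFFECT_LEVELS)}"
            )

    @property
    def delta(self) -> float:
        return EFFECT_LEVELS[self.effect_level]


@dataclass
class SimTruth:
    """Ground truth emitted by the generator."""

    labels: dict = field(default_factory=dict)  # timepoint -> per-cell true type
    novel: dict = field(default_factory=dict)  # timepoint -> per-cell novel flag
    tdeg_genes: list[str] = field(default_factory=list)
    tdeg_delta: float | None = None
    true_coefficients: dict = field(default_factory=dict)  # gene -> (b0,b1,b2,b3)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, omega: float) -> np.ndarray:
    """NB2 draw with mean ``mean`` and dispersion ``omega`` (gamma-Poisson)."""
    p = omega / (omega + mean)
    return rng.negative_binomial(omega, p)


def _base_means(rng: np.random.Generator, cfg) -> np.ndarray:
    means = rng.gamma(cfg.base_mean_shape, cfg.base_mean_scale, size=cfg.n_genes)
    return np.maximum(means, 0.05)  # keep every gene expressible


def simulate_scenario(cfg: ScenarioConfig) -> tuple[dict[str, TimepointDataset], SimTruth]:
    """Generate t0/t1/t2 datasets for one composition scenario.

    Returns a dict keyed "t0"/"t1"/"t2" and the ground truth. t0 carries its
    labels in the metadata; t1/t2 labels are only in the truth, mimicking
    the annotation task.
    """
    rng = np.random.default_rng(cfg.seed)
    base = _base_means(rng, cfg)
    n_markers = int(round(cfg.marker_fraction * cfg.n_genes))
    if n_markers * len(cfg.cell_types) > cfg.n_genes:
        raise ValidationError("marker blocks exceed the gene count")
    marker_blocks = {
        name: np.arange(k * n_markers, (k + 1) * n_markers)
        for k, name in enumerate(cfg.cell_types)
    }
    gene_ids = [f"g{i}" for i in range(cfg.n_genes)]
    novel = cfg.novel_type

    type_means = {}
    for name in cfg.cell_types:
        mu = base.copy()
        shift = cfg.effect_size + (cfg.novel_type_shift if name == novel else 0.0)
        mu[marker_blocks[name]] *= np.exp(shift)
        type_means[name] = mu

    truth = SimTruth()
    datasets = {}
    for tp in ("t0", "t1", "t2"):
        comp = cfg.type_compositions[tp]
        props = np.array([comp.get(name, 0.0) for name in cfg.cell_types])
        counts_per_type = rng.multinomial(cfg.cells_per_timepoint, props)
        labels = []
        columns = []
        for name, n_cells in zip(cfg.cell_types, counts_per_type):
            if n_cells == 0:
                continue
            mu = np.tile(type_means[name][:, None], (1, n_cells))
            columns.append(_nb_draw(rng, mu, cfg.dispersion))
            labels.extend([name] * n_cells)
        values = np.concatenate(columns, axis=1)
        order = rng.permutation(values.shape[1])  # shuffle so types interleave
        values = values[:, order]
        labels = [labels[i] for i in order]
        cell_ids = [f"{tp}_cell_{i}" for i in range(values.shape[1])]
        truth.labels[tp] = labels
        truth.novel[tp] = np.array([l == novel for l in labels])
        meta = CellMetadata(
            cell_ids=cell_ids,
            timepoint=[tp] * len(cell_ids),
            labels=list(labels) if tp == "t0" else None,
        )
        datasets[tp] = TimepointDataset(
            ExpressionMatrix(values, gene_ids, cell_ids, normalized=False), meta
        )
    return datasets, truth


def simulate_tdeg(cfg: TDEGSimConfig) -> tuple[TimepointDataset, SimTruth]:
    """Generate the tDEG spike-in dataset.

    Cells are split evenly across ``n_timepoints`` (time = 0, 1, ...) and into
    two strata (A/B). For each spiked gene the log-mean drifts by +delta per
    unit time in stratum A and -delta in stratum B — opposite temporal trends,
    i.e. a pure time x strata interaction with true coefficients
    beta1 = delta, beta3 = -2 delta under A = 0 coding.
    """
    rng = np.random.default_rng(cfg.seed)
    base = _base_means(rng, cfg)
    gene_ids = [f"g{i}" for i in range(cfg.n_genes)]
    tdeg_idx = rng.choice(cfg.n_genes, size=cfg.n_tdegs, replace=False)
    is_tdeg = np.zeros(cfg.n_genes, dtype=bool)
    is_tdeg[tdeg_idx] = True

    time = np.arange(cfg.n_cells) % cfg.n_timepoints
    strata = (rng.random(cfg.n_cells) < cfg.strata_proportion).astype(int)
    # ensure both strata present at every timepoint
    for t in range(cfg.n_timepoints):
        members = np.flatnonzero(time == t)
        if len(np.unique(strata[members])) < 2 and len(members) >= 2:
            strata[members[0]] = 0
            strata[members[1]] = 1

    delta = cfg.delta
    sign = np.where(strata == 0, 1.0, -1.0)  # A drifts up, B drifts down
    log_mu = np.log(base)[:, None] + is_tdeg[:, None] * delta * sign[None, :] * time[None, :]
    values = _nb_draw(rng, np.exp(log_mu), cfg.dispersion)

    cell_ids = [f"cell_{i}" for i in range(cfg.n_cells)]
    meta = CellMetadata(
        cell_ids=cell_ids,
        timepoint=[int(t) for t in time],
        strata=["A" if s == 0 else "B" for s in strata],
    )
    data = TimepointDataset(
        ExpressionMatrix(values, gene_ids, cell_ids, normalized=False), meta
    )
    truth = SimTruth(
        tdeg_genes=[gene_ids[i] for i in np.flatnonzero(is_tdeg)],
        tdeg_delta=delta,
        true_coefficients={
            gene_ids[i]: (float(np.log(base[i])), delta, 0.0, -2.0 * delta)
            for i in np.flatnonzero(is_tdeg)
        },
    )
    return data, truth


def nb_glm_counts(
    time, strata, beta, omega: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one gene's counts from the NB GLM with known coefficients.

    ``beta`` is (intercept, time, strata, interaction); used for
    parameter-recovery experiments.
    """
    time = np.asarray(time, dtype=float)
    strata = np.asarray(strata, dtype=float)
    b0, b1, b2, b3 = beta
    mu = np.exp(b0 + b1 * time + b2 * strata + b3 * time * strata)
    return _nb_draw(rng, mu, omega)
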