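"""Synthetic data with planted ground truth.

Three generators mirror the data model the method assumes:

* ``simulate_atlas`` — a multi-study purified-cell expression atlas on the
  log2 scale with planted marker genes (high in their own cell type, at
  background elsewhere), per-gene-per-study batch offsets and per-sample
  noise.
* ``simulate_bulk`` — bulk tissue mixtures: per-sample cell-type
  proportions drawn from a Dirichlet distribution, expression mixed on the
  LINEAR scale (transcripts add in tissue, log intensities do not) and
  log2-transformed with additive noise.  Optionally some marker genes are
  simulated as transcriptionally regulated: their association with their
  cell type's proportion is inverted by swapping their profile with
  another cell type's.
* ``simulate_single_cells`` — binarized detection matrices where detection
  probability follows a logistic function of expression, with optional
  planted co-detection modules driven by a shared per-cell latent state.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import LOG2_INTENSITY, ExpressionMatrix, SampleAnnotation
from .preprocess import CellTypeSummary

__all__ = [
    "SimConfig",
    "SimGroundTruth",
    "simulate_atlas",
    "simulate_bulk",
    "simulate_single_cells",
]

DEFAULT_CELL_TYPES = {f"type{i + 1}": 10 for i in range(6)}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults describe a small but realistic multi-study atlas: 6 cell
    types x 3 studies x 4 replicates, 1000 genes with 10 planted markers
    per type, marker on-level 11 vs off-level 6 on the log2 scale (a 32-fold
    gap, comfortably above the 10-fold selection rule), replicate noise SD
    0.3 and study batch SD 0.2 — magnitudes typical of RMA-normalized
    purified-cell microarray data.
    """

    n_genes: int = 1000
    cell_types: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPES)
    )
    n_studies: int = 3
    samples_per_study_per_type: int = 4
    mu_marker_on: float = 11.0
    mu_marker_off: float = 6.0
    baseline_range: tuple[float, float] = (4.0, 9.0)
    sigma_within: float = 0.3
    sigma_study: float = 0.2
    region: str = "cortex"
    # bulk mixtures
    bulk_n_samples: int = 50
    bulk_concentration: float = 1.0
    sigma_bulk: float = 0.3
    # single-cell detection
    sc_cells_per_type: int = 100
    detection_midpoint: float = 7.0
    detection_steepness: float = 1.0
    seed: int | None = None


@dataclass
class SimGroundTruth:
    planted_markers: dict[str, list[str]]
    true_proportions: pd.DataFrame | None = None
    study_offsets: pd.DataFrame | None = None
    regulated_genes: dict[str, str] = field(default_factory=dict)


def simulate_atlas(
    config: SimConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SimGroundTruth]:
    """Multi-study purified-cell atlas with planted markers."""
    rng = np.random.default_rng(config.seed)
    types = list(config.cell_types)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    total_markers = sum(config.cell_types.values())
    if total_markers > config.n_genes:
        raise ValueError("marker count exceeds n_genes")

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    planted: dict[str, list[str]] = {}
    cursor = 0
    for ct in types:
        k = config.cell_types[ct]
        planted[ct] = genes[cursor:cursor + k]
        cursor += k

    studies = [f"study{j + 1}" for j in range(config.n_studies)]
    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    # per-gene per-study batch offsets
    offsets = rng.normal(0.0, config.sigma_study,
                         size=(config.n_genes, config.n_studies))

    marker_of = np.full(config.n_genes, -1)
    for t_idx, ct in enumerate(types):
        for g in planted[ct]:
            marker_of[genes.index(g)] = t_idx

    columns, annotations = [], []
    values = []
    for t_idx, ct in enumerate(types):
        mean = np.where(
            marker_of == -1, baseline,
            np.where(marker_of == t_idx, config.mu_marker_on,
                     config.mu_marker_off),
        )
        for s_idx, study in enumerate(studies):
            for r in range(config.samples_per_study_per_type):
                sid = f"{ct}_{study}_r{r + 1}"
                col = (mean + offsets[:, s_idx]
                       + rng.normal(0.0, config.sigma_within, config.n_genes))
                values.append(col)
                columns.append(sid)
                annotations.append(
                    SampleAnnotation(sid, ct, config.region, study, "microarray")
                )
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(values), index=genes, columns=columns),
        LOG2_INTENSITY,
    )
    truth = SimGroundTruth(
        planted_markers=planted,
        study_offsets=pd.DataFrame(offsets, index=genes, columns=studies),
    )
    return matrix, annotations, truth


def simulate_bulk(
    summary: CellTypeSummary,
    config: SimConfig,
    proportions: pd.DataFrame | None = None,
    regulated_genes: dict[str, str] | None = None,
) -> tuple[ExpressionMatrix, SimGroundTruth]:
    """Bulk mixtures of the per-cell-type profiles in ``summary``.

    ``regulated_genes`` maps gene -> the cell type whose marker it is;
    each such gene's per-type profile is swapped between that type and the
    most abundant other type, so its bulk expression no longer tracks its
    own type's proportion (an inverted, "transcriptionally regulated"
    association used to test MGP pruning).
    """
    rng = np.random.default_rng(config.seed)
    types = summary.cell_types
    E = summary.values.to_numpy(dtype=float)  # genes x types, log2 scale
    if proportions is None:
        P = rng.dirichlet(
            np.full(len(types), config.bulk_concentration),
            size=config.bulk_n_samples,
        )
        proportions = pd.DataFrame(
            P, columns=types,
            index=[f"bulk{i + 1}" for i in range(config.bulk_n_samples)],
        )
    else:
        if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("proportion rows must sum to 1")
        proportions = proportions[types]

    E = E.copy()
    regulated = dict(regulated_genes or {})
    mean_props = proportions.mean(axis=0)
    for gene, own_type in regulated.items():
        gi = summary.values.index.get_loc(gene)
        ti = types.index(own_type)
        other = mean_props.drop(labels=[own_type]).idxmax()
        oi = types.index(other)
        E[gi, ti], E[gi, oi] = E[gi, oi], E[gi, ti]

    linear = np.power(2.0, E)  # genes x types
    mix = linear @ proportions.to_numpy().T  # genes x samples
    bulk = np.log2(mix) + rng.normal(0.0, config.sigma_bulk, size=mix.shape)
    matrix = ExpressionMatrix(
        pd.DataFrame(bulk, index=summary.values.index,
                     columns=proportions.index),
        LOG2_INTENSITY,
    )
    truth = SimGroundTruth(
        planted_markers={}, true_proportions=proportions,
        regulated_genes=regulated,
    )
    return matrix, truth


def simulate_single_cells(
    summary: CellTypeSummary,
    config: SimConfig,
    planted_modules: dict[str, dict] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Binary detection matrix (genes x cells) plus per-cell type labels.

    Detection probability of gene g in a cell of type c is
    ``logistic((E_gc - midpoint) / steepness)``; ``steepness`` -> 0 gives a
    hard detection threshold.  A planted module is
    ``{"genes": [...], "prevalence": q, "fidelity": f}``: per cell a shared
    latent state z ~ Bernoulli(q); each module gene copies z with
    probability f and otherwise draws an independent Bernoulli(q), giving
    pairwise detection correlation ~ f^2 within the module.
    """
    rng = np.random.default_rng(config.seed)
    types = summary.cell_types
    E = summary.values.to_numpy(dtype=float)
    genes = summary.values.index
    n_cells = config.sc_cells_per_type

    cols, labels, blocks = [], [], []
    for ti, ct in enumerate(types):
        if config.detection_steepness <= 0:
            prob = (E[:, ti] > config.detection_midpoint).astype(float)
            prob[E[:, ti] == config.detection_midpoint] = 0.5
        else:
            z = (E[:, ti] - config.detection_midpoint) / config.detection_steepness
            prob = 1.0 / (1.0 + np.exp(-z))
        block = rng.random((len(genes), n_cells)) < prob[:, None]
        blocks.append(block)
        cols.extend(f"{ct}_cell{j + 1}" for j in range(n_cells))
        labels.extend([ct] * n_cells)
    detection = np.concatenate(blocks, axis=1)

    for module in (planted_modules or {}).values():
        idx = [genes.get_loc(g) for g in module["genes"]]
        q = float(module.get("prevalence", 0.3))
        f = float(module.get("fidelity", 1.0))
        total = detection.shape[1]
        latent = rng.random(total) < q
        for gi in idx:
            copy = rng.random(total) < f
            independent = rng.random(total) < q
            detection[gi] = np.where(copy, latent, independent)

    df = pd.DataFrame(detection.astype(np.int8), index=genes, columns=cols)
    return df, pd.Series(labels, index=cols, name="cell_type")
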