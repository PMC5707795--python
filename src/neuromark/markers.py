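"""Cell-type marker gene selection.

A gene is a marker of a cell type within a brain region when, across a
multi-study atlas of purified-cell expression profiles, it is

1. detectably expressed in that cell type (per-sample median at or above a
   platform threshold: 8 on the log2 microarray scale, 2.5 RPKM),
2. strongly enriched: at least a ``fold`` (default 10x) difference from the
   median of the remaining cell types' cross-study summaries — or, when the
   target summary sits too close to the platform background for a 10-fold
   gap to be meaningful, simply higher than every other cell type,
3. cleanly separating: in one dimension, with |expression difference| as
   the distance, the mean silhouette of target-vs-rest exceeds 0.5 and the
   minimum pairwise target silhouette is positive, and
4. unique: no other cell type in the region satisfies 1-3 for it.

Robustness is enforced by rerunning the criteria over random permutations
(a third of the samples dropped each time; large microarray studies
subsampled down to the smallest study per cell type) and keeping genes that
qualify in more than ``pass_rate`` (default 95%) of permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    LOG2_INTENSITY,
    RPKM,
    ExpressionMatrix,
    RegionHierarchy,
    SampleAnnotation,
    assign_samples_to_region,
)
from .preprocess import CellTypeSummary

__all__ = [
    "MarkerSelectionConfig",
    "SilhouetteResult",
    "GeneProvenance",
    "MarkerGeneSet",
    "Verdict",
    "silhouette_scores",
    "evaluate_gene",
    "select_markers",
    "select_from_pass_rates",
    "soft_intersect",
    "apply_exclusion_filter",
    "apply_inclusion_filter",
    "refine_by_external_ranking",
    "write_marker_sets",
    "read_marker_sets",
]


@dataclass
class MarkerSelectionConfig:
    """Thresholds and randomization settings for marker selection.

    ``background`` and ``expr_threshold`` are per-scale: log2-intensity
    values for microarray, linear RPKM for RNA-seq (transformed internally
    via log2(x + rpkm_pseudocount)).
    """

    background: dict = field(
        default_factory=lambda: {LOG2_INTENSITY: 6.0, RPKM: 0.1}
    )
    expr_threshold: dict = field(
        default_factory=lambda: {LOG2_INTENSITY: 8.0, RPKM: 2.5}
    )
    fold: float = 10.0
    mean_sil_min: float = 0.5
    min_sil_min: float = 0.0
    n_permutations: int = 500
    drop_fraction: float = 1.0 / 3.0
    pass_rate: float = 0.95
    rpkm_pseudocount: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in [0, 1)")
        if not (0 < self.pass_rate <= 1):
            raise ValueError("pass_rate must be in (0, 1]")
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")

    def log2_constants(self, scale: str) -> tuple[float, float]:
        """(background, expression threshold) on the log2 comparison scale."""
        if scale == LOG2_INTENSITY:
            return float(self.background[scale]), float(self.expr_threshold[scale])
        pc = self.rpkm_pseudocount
        return (
            float(np.log2(self.background[scale] + pc)),
            float(np.log2(self.expr_threshold[scale] + pc)),
        )

    def to_log2(self, values: np.ndarray, scale: str) -> np.ndarray:
        if scale == LOG2_INTENSITY:
            return np.asarray(values, dtype=float)
        return np.log2(np.asarray(values, dtype=float) + self.rpkm_pseudocount)


@dataclass
class SilhouetteResult:
    gene_id: str
    cell_type: str
    mean_sil: float
    min_sil: float
    degenerate: bool = False


@dataclass
class GeneProvenance:
    platforms: list[str] = field(default_factory=list)
    soft_intersection: bool = False
    filter_labels: list[str] = field(default_factory=list)
    pass_rate: float | None = None


@dataclass
class MarkerGeneSet:
    """Marker genes for one (cell type, region), with per-gene provenance
    and a record of genes removed by refinement filters."""

    cell_type: str
    region: str
    genes: list[str]
    provenance: dict[str, GeneProvenance] = field(default_factory=dict)
    removed: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in marker set")
        for g in self.genes:
            self.provenance.setdefault(g, GeneProvenance())


# ---------------------------------------------------------------------------
# silhouettes

def _safe_sil(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m = np.maximum(a, b)
    return np.where(m > 0, (b - a) / np.where(m > 0, m, 1.0), 0.0)


def _silhouettes_vectorized(
    X: np.ndarray, type_indices: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """mean/min silhouette per gene for every cell type.

    ``X`` is (genes x samples); distances are |x_i - x_j| per gene.  For
    each target type: mean_sil is the mean silhouette width of ALL samples
    in the target-vs-pooled-rest two-cluster configuration; min_sil the
    minimum over other types of the mean width of TARGET samples in the
    target-vs-that-type configuration.  Singleton clusters contribute
    width 0.
    """
    types = list(type_indices)
    n = X.shape[1]
    D = np.abs(X[:, :, None] - X[:, None, :])
    # block row-sums: S[t1][t2][g, i] = sum_{j in t2} D[g, idx_t1[i], j]
    S: dict[str, dict[str, np.ndarray]] = {}
    for t1 in types:
        block = D[:, type_indices[t1], :]
        S[t1] = {t2: block[:, :, type_indices[t2]].sum(axis=2) for t2 in types}
    sizes = {t: len(type_indices[t]) for t in types}

    mean_sil: dict[str, np.ndarray] = {}
    min_sil: dict[str, np.ndarray] = {}
    for target in types:
        nt = sizes[target]
        nr = n - nt
        if nr == 0:
            continue
        total = np.zeros(X.shape[0])
        # target members in target-vs-rest
        b_rest = sum(S[target][t] for t in types if t != target) / nr
        if nt > 1:
            a_own = S[target][target] / (nt - 1)
            total += _safe_sil(a_own, b_rest).sum(axis=1)
        # else: singleton target contributes width 0
        # rest members: their cluster is the pooled rest
        for t in types:
            if t == target:
                continue
            if nr > 1:
                a_r = sum(S[t][t2] for t2 in types if t2 != target) / (nr - 1)
                b_r = S[t][target] / nt
                total += _safe_sil(a_r, b_r).sum(axis=1)
        mean_sil[target] = total / n
        # pairwise target-vs-single-other configurations
        per_type = []
        for t in types:
            if t == target or sizes[t] == 0:
                continue
            if nt > 1:
                a_own = S[target][target] / (nt - 1)
                b_t = S[target][t] / sizes[t]
                per_type.append(_safe_sil(a_own, b_t).mean(axis=1))
            else:
                per_type.append(np.zeros(X.shape[0]))
        min_sil[target] = np.min(per_type, axis=0)
    return mean_sil, min_sil


def silhouette_scores(
    values: "pd.Series | dict[str, float]",
    target_samples: list[str],
    other_samples_by_type: dict[str, list[str]],
    gene_id: str = "",
    cell_type: str = "",
) -> SilhouetteResult:
    """Silhouette separability of one gene's expression for one cell type.

    ``values`` maps sample id -> expression.  Distance between samples is
    the absolute expression difference.
    """
    values = dict(values)
    if not target_samples:
        raise ValueError("target cell type has no samples")
    if not any(other_samples_by_type.values()):
        raise ValueError("no other cell type has samples")
    ordering = list(target_samples)
    type_indices = {"__target__": np.arange(len(target_samples))}
    for t, members in other_samples_by_type.items():
        if not members:
            continue
        start = len(ordering)
        ordering.extend(members)
        type_indices[t] = np.arange(start, len(ordering))
    X = np.array([[values[s] for s in ordering]], dtype=float)
    mean_sil, min_sil = _silhouettes_vectorized(X, type_indices)
    ms = float(mean_sil["__target__"][0])
    mn = float(min_sil["__target__"][0])
    degenerate = bool(np.ptp(X) == 0)
    return SilhouetteResult(gene_id, cell_type, ms, mn, degenerate)


# ---------------------------------------------------------------------------
# criteria

@dataclass
class Verdict:
    qualifies: bool
    c1_expression: bool
    c2_fold: bool
    c3_silhouette: bool


def evaluate_gene(
    gene: str,
    cell_type: str,
    summary: CellTypeSummary,
    silhouette: SilhouetteResult,
    sample_values: np.ndarray,
    config: MarkerSelectionConfig,
) -> Verdict:
    """Apply the expression, fold-change and silhouette criteria to one gene.

    ``sample_values`` are the target cell type's per-sample expression
    values on the matrix's native scale.
    """
    bg, thr = config.log2_constants(summary.scale)
    log2fold = float(np.log2(config.fold))
    vals = config.to_log2(np.asarray(sample_values, dtype=float), summary.scale)
    c1 = bool(np.median(vals) >= thr)

    row = config.to_log2(summary.values.loc[gene].to_numpy(), summary.scale)
    cols = list(summary.values.columns)
    if cell_type not in cols:
        raise KeyError(f"cell type {cell_type!r} not in summary")
    ti = cols.index(cell_type)
    target = float(row[ti])
    others = np.delete(row, ti)
    if len(others) == 0:
        raise ValueError("summary must contain at least 2 cell types")
    if target > bg + log2fold:
        c2 = bool(target - np.median(others) >= log2fold)
    else:
        c2 = bool(target > others.max())
    c3 = bool(
        silhouette.mean_sil > config.mean_sil_min
        and silhouette.min_sil > config.min_sil_min
    )
    return Verdict(c1 and c2 and c3, c1, c2, c3)


# ---------------------------------------------------------------------------
# full selection with robustness permutations

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_from_pass_rates(
    rates: pd.DataFrame, pass_rate: float
) -> pd.DataFrame:
    """Final selection decision from per-(gene, cell type) pass rates.

    A gene is selected for a cell type iff its rate STRICTLY exceeds
    ``pass_rate`` ("more than"); genes passing for two or more cell types
    violate uniqueness and are dropped everywhere.
    """
    selected = rates > pass_rate
    multi = selected.sum(axis=1) > 1
    selected.loc[multi, :] = False
    return selected


def select_markers(
    matrix: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    hierarchy: RegionHierarchy,
    region: str,
    config: MarkerSelectionConfig,
) -> list[MarkerGeneSet]:
    """Select marker gene sets for every cell type in a brain region.

    Each permutation drops a third (rounded) of the region's samples at
    random; within microarray cell types represented by several studies the
    remaining samples are further subsampled to the smallest per-study
    count, so no study dominates.  Criteria are recomputed per permutation;
    a gene is selected for a cell type when its qualification rate over the
    permutations in which the cell type was still represented strictly
    exceeds ``pass_rate``, and no other cell type achieves the same (such
    genes are dropped everywhere: criterion of uniqueness).
    """
    ann = {a.sample_id: a for a in annotations}
    sample_ids = [
        s for s in assign_samples_to_region(annotations, hierarchy, region)
        if s in set(matrix.sample_ids)
    ]
    if not sample_ids:
        raise ValueError(f"no annotated samples in region {region!r}")
    cell_types = sorted({ann[s].cell_type for s in sample_ids})
    if len(cell_types) < 2:
        raise ValueError(f"region {region!r} has fewer than 2 cell types")

    X_all = config.to_log2(matrix.data[sample_ids].to_numpy(), matrix.scale)
    genes = np.array(matrix.gene_ids)
    bg, thr = config.log2_constants(matrix.scale)
    log2fold = float(np.log2(config.fold))

    pos = {s: i for i, s in enumerate(sample_ids)}
    # per cell type: study -> column positions; microarray flag
    by_type: dict[str, dict[str, list[int]]] = {c: {} for c in cell_types}
    is_microarray: dict[str, bool] = {}
    for s in sample_ids:
        a = ann[s]
        by_type[a.cell_type].setdefault(a.study, []).append(pos[s])
        is_microarray.setdefault(a.cell_type, a.platform == "microarray")

    n = len(sample_ids)
    n_drop = _round_half_up(config.drop_fraction * n)
    rng = np.random.default_rng(config.seed)
    G = len(genes)
    T = len(cell_types)
    pass_counts = np.zeros((G, T))
    denoms = np.zeros(T)

    for _ in range(max(1, config.n_permutations)):
        keep = set(rng.choice(n, size=n - n_drop, replace=False).tolist())
        type_cols: dict[str, list[int]] = {}
        study_cols: dict[str, dict[str, list[int]]] = {}
        for c in cell_types:
            surviving = {
                st: [i for i in idx if i in keep]
                for st, idx in sorted(by_type[c].items())
            }
            surviving = {st: idx for st, idx in surviving.items() if idx}
            if not surviving:
                continue
            if is_microarray[c] and len(surviving) > 1:
                nmin = min(len(idx) for idx in surviving.values())
                surviving = {
                    st: sorted(
                        rng.choice(idx, size=nmin, replace=False).tolist()
                    )
                    for st, idx in surviving.items()
                }
            study_cols[c] = surviving
            type_cols[c] = sorted(i for idx in surviving.values() for i in idx)

        present = [c for c in cell_types if c in type_cols]
        if len(present) < 2:
            continue
        cols = sorted(i for c in present for i in type_cols[c])
        remap = {i: j for j, i in enumerate(cols)}
        X = X_all[:, cols]
        type_indices = {
            c: np.array([remap[i] for i in type_cols[c]]) for c in present
        }
        # two-stage summaries and per-type sample medians
        summaries = np.empty((G, len(present)))
        medians = np.empty((G, len(present)))
        for j, c in enumerate(present):
            study_means = [
                X[:, [remap[i] for i in idx]].mean(axis=1)
                for idx in study_cols[c].values()
            ]
            summaries[:, j] = np.mean(study_means, axis=0)
            medians[:, j] = np.median(X[:, type_indices[c]], axis=1)

        mean_sil, min_sil = _silhouettes_vectorized(X, type_indices)

        for j, c in enumerate(present):
            others = np.delete(summaries, j, axis=1)
            target = summaries[:, j]
            high = target > bg + log2fold
            c2 = np.where(
                high,
                target - np.median(others, axis=1) >= log2fold,
                target > others.max(axis=1),
            )
            c1 = medians[:, j] >= thr
            c3 = (mean_sil[c] > config.mean_sil_min) & (
                min_sil[c] > config.min_sil_min
            )
            tj = cell_types.index(c)
            pass_counts[:, tj] += c1 & c2 & c3
            denoms[tj] += 1

    absent = [c for c, d in zip(cell_types, denoms) if d == 0]
    if absent:
        raise ValueError(f"cell types absent from every permutation: {absent}")
    rates = pd.DataFrame(pass_counts / denoms, index=genes, columns=cell_types)
    selected = select_from_pass_rates(rates, config.pass_rate).to_numpy()

    platform = "microarray" if all(is_microarray.values()) else "rnaseq"
    out = []
    for j, c in enumerate(cell_types):
        gene_list = [str(g) for g in genes[selected[:, j]]]
        prov = {
            g: GeneProvenance(
                platforms=[platform],
                pass_rate=float(rates.loc[g, c]),
            )
            for g in gene_list
        }
        out.append(MarkerGeneSet(c, region, gene_list, prov))
    return out


# ---------------------------------------------------------------------------
# cross-platform merge and refinement filters

def _top_in_cell_type(summary: CellTypeSummary, gene: str, cell_type: str) -> bool:
    row = summary.values.loc[gene]
    others = row.drop(labels=[cell_type])
    return bool(len(others) == 0 or row[cell_type] > others.max())


def soft_intersect(
    mgs_a: MarkerGeneSet,
    summary_b: CellTypeSummary,
    mgs_b: MarkerGeneSet,
    summary_a: CellTypeSummary,
) -> MarkerGeneSet:
    """Merge marker sets from two platforms for the same cell type.

    A gene is admitted when selected on both platforms; or selected on one
    platform and top-expressed in the target cell type on the other; or
    selected on a platform that is the only one measuring it.
    """
    if mgs_a.cell_type != mgs_b.cell_type:
        raise ValueError("marker sets describe different cell types")
    ct = mgs_a.cell_type
    set_a, set_b = set(mgs_a.genes), set(mgs_b.genes)
    genes, prov = [], {}

    def admit(g: str, platforms: list[str], soft: bool) -> None:
        genes.append(g)
        prov[g] = GeneProvenance(platforms=platforms, soft_intersection=soft)

    for g in sorted(set_a | set_b):
        plat_a = mgs_a.provenance.get(g, GeneProvenance()).platforms or ["a"]
        plat_b = mgs_b.provenance.get(g, GeneProvenance()).platforms or ["b"]
        if g in set_a and g in set_b:
            admit(g, plat_a + plat_b, False)
        elif g in set_a:
            if g not in summary_b.values.index:
                admit(g, plat_a, False)
            elif _top_in_cell_type(summary_b, g, ct):
                admit(g, plat_a, True)
        else:
            if g not in summary_a.values.index:
                admit(g, plat_b, False)
            elif _top_in_cell_type(summary_a, g, ct):
                admit(g, plat_b, True)
    return MarkerGeneSet(ct, mgs_a.region, genes, prov)


def apply_exclusion_filter(
    mgs: MarkerGeneSet, excluded: list[str], label: str
) -> MarkerGeneSet:
    """Remove listed genes from the set, recording them under ``label``."""
    excluded = set(excluded)
    kept = [g for g in mgs.genes if g not in excluded]
    dropped = [g for g in mgs.genes if g in excluded]
    removed = {k: list(v) for k, v in mgs.removed.items()}
    removed.setdefault(label, []).extend(dropped)
    prov = {g: mgs.provenance[g] for g in kept}
    return MarkerGeneSet(mgs.cell_type, mgs.region, kept, prov, removed)


def apply_inclusion_filter(
    mgs: MarkerGeneSet, allowed: list[str], also_drop: list[str] = ()
) -> MarkerGeneSet:
    """Retain only genes on an allow-list, then drop an explicit list."""
    allowed, also_drop = set(allowed), set(also_drop)
    kept = [g for g in mgs.genes if g in allowed and g not in also_drop]
    dropped = [g for g in mgs.genes if g not in kept]
    if not kept:
        warnings.warn(
            f"inclusion filter left no genes for {mgs.cell_type}", stacklevel=2
        )
    removed = {k: list(v) for k, v in mgs.removed.items()}
    removed.setdefault("inclusion_filter", []).extend(dropped)
    prov = {g: mgs.provenance[g] for g in kept}
    return MarkerGeneSet(mgs.cell_type, mgs.region, kept, prov, removed)


def refine_by_external_ranking(
    mgs: MarkerGeneSet,
    external: CellTypeSummary,
    target_columns: list[str],
    linear_input: bool = False,
    pseudocount: float = 0.1,
) -> MarkerGeneSet:
    """Drop genes ranked below other cell types in an external dataset.

    The target expression is the mean over ``target_columns``; a gene is
    removed iff it is strictly lower than the best remaining column.
    Genes the external summary does not cover pass through with a warning.
    """
    values = external.values
    if linear_input:
        values = np.log2(values + pseudocount)
    other_cols = [c for c in values.columns if c not in target_columns]
    if not other_cols:
        return mgs
    kept, dropped = [], []
    uncovered = [g for g in mgs.genes if g not in values.index]
    if uncovered:
        warnings.warn(
            f"external summary does not cover {len(uncovered)} genes; kept",
            stacklevel=2,
        )
    for g in mgs.genes:
        if g not in values.index:
            kept.append(g)
            continue
        target = values.loc[g, target_columns].mean()
        if target < values.loc[g, other_cols].max():
            dropped.append(g)
        else:
            kept.append(g)
    removed = {k: list(v) for k, v in mgs.removed.items()}
    removed.setdefault("external_ranking", []).extend(dropped)
    prov = {g: mgs.provenance[g] for g in kept}
    return MarkerGeneSet(mgs.cell_type, mgs.region, kept, prov, removed)


# ---------------------------------------------------------------------------
# persistence

def write_marker_sets(marker_sets: list[MarkerGeneSet], path) -> None:
    rows = []
    for mgs in marker_sets:
        for g in mgs.genes:
            p = mgs.provenance[g]
            rows.append(
                {
                    "cell_type": mgs.cell_type,
                    "region": mgs.region,
                    "gene_id": g,
                    "platforms": ",".join(p.platforms),
                    "soft_intersection": int(p.soft_intersection),
                    "filter_labels": ",".join(p.filter_labels),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "cell_type", "region", "gene_id",
            "platforms", "soft_intersection", "filter_labels",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_marker_sets(path) -> list[MarkerGeneSet]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for (ct, region), sub in df.groupby(["cell_type", "region"], sort=True):
        genes = list(sub["gene_id"])
        prov = {}
        for _, row in sub.iterrows():
            prov[row["gene_id"]] = GeneProvenance(
                platforms=[p for p in row["platforms"].split(",") if p],
                soft_intersection=row["soft_intersection"] in ("1", "True", "true"),
                filter_labels=[l for l in row["filter_labels"].split(",") if l],
            )
        out.append(MarkerGeneSet(ct, region, genes, prov))
    return out
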