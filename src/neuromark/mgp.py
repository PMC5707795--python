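"""Marker gene profile (MGP) estimation in bulk tissue.

The MGP of a cell type in a bulk expression dataset is the first principal
component of its marker genes' expression (genes standardized to zero mean,
unit variance, i.e. correlation-scale PCA), used as a surrogate for the
cell type's relative abundance across samples.  Marker genes whose PC1
loading opposes the majority sign — genes likely under condition-specific
transcriptional regulation rather than tracking cell abundance — are pruned
iteratively until all loadings share one sign; scores are then oriented so
that loadings are positive and min-max scaled to [0, 1] for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix
from .markers import MarkerGeneSet

__all__ = [
    "MGPResult",
    "GroupComparison",
    "estimate_mgp",
    "compare_groups",
    "adjust_benjamini_hochberg",
]


@dataclass
class MGPResult:
    cell_type: str
    region: str
    scores: pd.Series
    normalized_scores: pd.Series
    used_genes: list[str]
    removed_genes: dict[str, int]  # gene -> iteration at which it was pruned
    loadings: pd.Series
    variance_explained: float
    n_iterations: int


@dataclass
class GroupComparison:
    cell_type: str
    group: str
    reference: str
    statistic: float
    p_value: float
    adjusted_p: float | None
    group_mean: float
    group_sd: float
    reference_mean: float
    reference_sd: float


def _pc1(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of samples x genes standardized data.

    Returns (scores, loadings, variance_explained); orientation is fixed
    so the loading sum is non-negative (a deterministic convention — the
    final sign is set by the caller from the majority loading sign).
    """
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[0]
    scores = Z @ loadings
    if loadings.sum() < 0:
        loadings, scores = -loadings, -scores
    total = float((s ** 2).sum())
    ve = float(s[0] ** 2 / total) if total > 0 else 0.0
    return scores, loadings, ve


def estimate_mgp(
    bulk: ExpressionMatrix,
    mgs: MarkerGeneSet,
    prune_all_minority: bool = True,
) -> MGPResult:
    """Estimate the marker gene profile of ``mgs`` across bulk samples.

    ``prune_all_minority`` removes every minority-sign gene per iteration
    (default); when False only the minority gene with the largest absolute
    loading is removed per iteration.
    """
    present = [g for g in mgs.genes if g in bulk.data.index]
    n_missing = len(mgs.genes) - len(present)
    if n_missing:
        warnings.warn(
            f"{n_missing} marker genes absent from the bulk matrix; dropped",
            stacklevel=2,
        )
    data = bulk.data.loc[present]
    constant = data.index[data.std(axis=1, ddof=1) == 0]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant-expression marker genes dropped",
            stacklevel=2,
        )
        data = data.drop(index=constant)
    if data.shape[0] == 0:
        raise ValueError("no usable marker genes in the bulk matrix")

    samples = data.columns
    removed: dict[str, int] = {}

    if data.shape[0] == 1:
        # single-gene degenerate case: the MGP is the standardized gene
        warnings.warn("single usable marker gene; MGP equals that gene",
                      stacklevel=2)
        vals = data.iloc[0].to_numpy(dtype=float)
        scores = (vals - vals.mean()) / vals.std(ddof=1)
        loadings = pd.Series([1.0], index=data.index)
        return _finalize(mgs, samples, scores, data.index.tolist(), removed,
                         loadings, 1.0, 1)

    genes = data.index.tolist()
    iteration = 0
    while True:
        iteration += 1
        sub = data.loc[genes].to_numpy(dtype=float)
        Z = ((sub - sub.mean(axis=1, keepdims=True))
             / sub.std(axis=1, ddof=1, keepdims=True)).T
        scores, loadings, ve = _pc1(Z)
        pos = loadings > 0
        neg = loadings < 0
        # zero loadings carry no directional conflict: treat as majority
        if not (pos.any() and neg.any()):
            break
        if pos.sum() > neg.sum():
            minority = neg
        elif neg.sum() > pos.sum():
            minority = pos
        else:  # tie: keep the sign group with the larger |loading| mass
            minority = pos if (np.abs(loadings[pos]).sum()
                               < np.abs(loadings[neg]).sum()) else neg
        if not prune_all_minority:
            keep_one = np.zeros_like(minority)
            idx = np.where(minority)[0]
            keep_one[idx[np.argmax(np.abs(loadings[idx]))]] = True
            minority = keep_one
        for g in np.array(genes)[minority]:
            removed[str(g)] = iteration
        genes = [g for g, m in zip(genes, minority) if not m]
        if len(genes) < 2:
            # re-fit the survivor as the degenerate single-gene profile
            sub = data.loc[genes].to_numpy(dtype=float)
            z = (sub[0] - sub[0].mean()) / sub[0].std(ddof=1)
            loadings = pd.Series([1.0], index=genes)
            return _finalize(mgs, samples, z, genes, removed, loadings, 1.0,
                             iteration + 1)

    # orient: flip so loadings are positive (majority sign is positive
    # already by the _pc1 convention unless all loadings are negative)
    if (loadings <= 0).all() and (loadings < 0).any():
        loadings, scores = -loadings, -scores
    return _finalize(mgs, samples, scores, genes, removed,
                     pd.Series(loadings, index=genes), ve, iteration)


def _finalize(mgs, samples, scores, genes, removed, loadings, ve, n_iter):
    scores = pd.Series(np.asarray(scores, dtype=float), index=samples)
    rng_ = scores.max() - scores.min()
    if rng_ > 0:
        normalized = (scores - scores.min()) / rng_
    else:
        normalized = scores * 0.0
    return MGPResult(
        cell_type=mgs.cell_type,
        region=mgs.region,
        scores=scores,
        normalized_scores=normalized,
        used_genes=[str(g) for g in genes],
        removed_genes=removed,
        loadings=loadings,
        variance_explained=ve,
        n_iterations=n_iter,
    )


def compare_groups(
    result: MGPResult,
    groups: dict[str, str],
    reference: str,
    adjust: bool = False,
) -> list[GroupComparison]:
    """Two-sided Wilcoxon rank-sum comparison of each group's normalized
    MGP scores against the reference group.

    The statistic is the Mann-Whitney U of the non-reference group (its
    rank sum minus the minimum possible).  The exact null distribution is
    used for small tie-free groups, otherwise a tie- and
    continuity-corrected normal approximation.
    """
    scores = result.normalized_scores
    labels = sorted(set(groups.values()))
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} absent; have {labels}")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {
        g: scores[[s for s in scores.index if groups.get(s) == g]].to_numpy()
        for g in labels
    }
    for g, vals in by_group.items():
        if len(vals) == 0:
            raise ValueError(f"group {g!r} has no samples with scores")
    ref_vals = by_group[reference]
    out = []
    for g in labels:
        if g == reference:
            continue
        res = stats.mannwhitneyu(by_group[g], ref_vals,
                                 alternative="two-sided", method="auto")
        out.append(
            GroupComparison(
                cell_type=result.cell_type,
                group=g,
                reference=reference,
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                adjusted_p=None,
                group_mean=float(by_group[g].mean()),
                group_sd=float(by_group[g].std(ddof=1)) if len(by_group[g]) > 1 else 0.0,
                reference_mean=float(ref_vals.mean()),
                reference_sd=float(ref_vals.std(ddof=1)) if len(ref_vals) > 1 else 0.0,
            )
        )
    if adjust and out:
        adjusted = adjust_benjamini_hochberg([c.p_value for c in out])
        for c, ap in zip(out, adjusted):
            c.adjusted_p = float(ap)
    return out


def adjust_benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()
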