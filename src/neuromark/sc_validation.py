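"""Validation of marker gene sets by co-detection in single-cell data.

If a marker gene set (MGS) is truly cell-type specific and the cell type
is present in an independent single-cell RNA-seq dataset, its genes should
tend to be detected in the same cells.  Expression is binarized (detected
= any nonzero value), internal coherence is the set of pairwise Spearman
correlations of detection patterns across cells, and significance comes
from comparing those correlations against the internal correlations of
randomly drawn gene groups matched on detection prevalence (±2.5% of each
marker's prevalence) with a one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix
from .markers import MarkerGeneSet

__all__ = [
    "SCValidationResult",
    "binarize_matrix",
    "gene_prevalence",
    "internal_correlation",
    "sample_matched_null",
    "validate_mgs",
]

logger = logging.getLogger(__name__)


@dataclass
class SCValidationResult:
    cell_type: str
    n_genes_used: int
    mgs_correlations: np.ndarray
    null_correlations: np.ndarray
    p_value: float
    n_null_groups: int
    mode: str


def binarize_matrix(sc: ExpressionMatrix) -> pd.DataFrame:
    """Genes x cells detection matrix: 1 iff the input entry is > 0."""
    values = sc.data.to_numpy()
    if (values < 0).any():
        raise ValueError("negative expression values; counts/RPKM expected")
    return (sc.data > 0).astype(np.int8)


def gene_prevalence(binary: pd.DataFrame) -> pd.Series:
    """Number of cells in which each gene is detected."""
    return binary.sum(axis=1).astype(int)


def _rank_rows(binary: pd.DataFrame, genes: list[str]) -> np.ndarray:
    ranks = stats.rankdata(binary.loc[genes].to_numpy(), axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    return ranks


def _pairwise_corr(centered_ranks: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(centered_ranks, axis=1)
    C = (centered_ranks @ centered_ranks.T) / np.outer(norms, norms)
    iu = np.triu_indices(C.shape[0], k=1)
    return C[iu]


def internal_correlation(binary: pd.DataFrame, genes: list[str]) -> np.ndarray:
    """Spearman correlation over cells for every unordered gene pair.

    Constant detection rows are dropped with a warning; fewer than two
    usable genes is an error.
    """
    present = [g for g in genes if g in binary.index]
    sub = binary.loc[present]
    usable = [g for g in present if sub.loc[g].nunique() > 1]
    if len(usable) < len(present):
        warnings.warn(
            f"{len(present) - len(usable)} constant detection rows dropped",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError("need at least 2 non-constant genes")
    return _pairwise_corr(_rank_rows(binary, usable))


def sample_matched_null(
    binary: pd.DataFrame,
    genes: list[str],
    n_groups: int,
    window: float = 0.025,
    seed: int | None = None,
    widen_step: float = 0.025,
    max_window: float = 0.25,
) -> list[list[str]]:
    """Random prevalence-matched gene groups.

    For each marker gene, candidates are non-marker genes whose prevalence
    lies within ``window`` (relative, inclusive) of the marker's.  If a
    marker has no candidate, its window is widened by ``widen_step`` at a
    time (logged) up to ``max_window``; beyond that an error is raised.
    Groups are sampled with replacement across groups, without replacement
    within a group.
    """
    prevalence = gene_prevalence(binary)
    n_cells = binary.shape[1]
    marker_set = set(genes)
    # pool excludes the markers themselves and never-/always-detected genes
    pool = prevalence[
        (~prevalence.index.isin(marker_set))
        & (prevalence > 0)
        & (prevalence < n_cells)
    ]
    pool_genes = pool.index.to_numpy()
    pool_prev = pool.to_numpy()

    def eligible_at(p: float, w: float) -> np.ndarray:
        lo, hi = (1 - w) * p, (1 + w) * p
        return pool_genes[(pool_prev >= lo) & (pool_prev <= hi)]

    def eligible_min(g: str, n_needed: int = 1) -> tuple[np.ndarray, float]:
        """Smallest window (>= the configured one) with n_needed candidates."""
        p = float(prevalence[g])
        w = window
        while True:
            cand = eligible_at(p, w)
            if len(cand) >= n_needed:
                return cand, w
            if w >= max_window:
                raise ValueError(
                    f"no prevalence match for gene {g!r} within ±{max_window:.0%}"
                )
            w = min(w + widen_step, max_window)
            logger.info("widened prevalence window for %s to ±%.1f%%", g, 100 * w)

    candidates = [eligible_min(g)[0] for g in genes]

    rng = np.random.default_rng(seed)
    groups: list[list[str]] = []
    for _ in range(n_groups):
        chosen: list[str] = []
        taken: set[str] = set()
        for g, eligible in zip(genes, candidates):
            free = eligible[~np.isin(eligible, list(taken))] if taken else eligible
            if len(free) == 0:
                # window exhausted by within-group uniqueness: widen further
                eligible, _ = eligible_min(g, n_needed=len(taken) + 1)
                free = eligible[~np.isin(eligible, list(taken))]
                if len(free) == 0:
                    raise ValueError(
                        f"cannot draw a unique prevalence match for {g!r}"
                    )
            pick = str(rng.choice(free))
            chosen.append(pick)
            taken.add(pick)
        groups.append(chosen)
    return groups


def validate_mgs(
    sc: ExpressionMatrix,
    mgs: MarkerGeneSet,
    n_groups: int = 1000,
    window: float = 0.025,
    seed: int | None = None,
    mode: str = "pooled",
) -> SCValidationResult:
    """Test whether an MGS is more co-detected than prevalence-matched
    random gene groups.

    ``mode='pooled'`` (default) pools every null group's pairwise
    correlations into one null sample; ``mode='group_means'`` uses one
    mean correlation per group.  The p-value is a one-sided (greater)
    Wilcoxon rank-sum test of the MGS pairwise correlations against the
    null sample.
    """
    if mode not in ("pooled", "group_means"):
        raise ValueError("mode must be 'pooled' or 'group_means'")
    binary = binarize_matrix(sc)
    present = [g for g in mgs.genes if g in binary.index]
    usable = [g for g in present if binary.loc[g].nunique() > 1]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable (non-constant) marker genes")
    mgs_corr = _pairwise_corr(_rank_rows(binary, usable))

    groups = sample_matched_null(binary, usable, n_groups, window, seed)
    null_values = []
    for grp in groups:
        corr = _pairwise_corr(_rank_rows(binary, grp))
        null_values.append(corr.mean() if mode == "group_means" else corr)
    null_corr = (
        np.array(null_values)
        if mode == "group_means"
        else np.concatenate(null_values)
    )
    res = stats.mannwhitneyu(mgs_corr, null_corr, alternative="greater",
                             method="asymptotic")
    return SCValidationResult(
        cell_type=mgs.cell_type,
        n_genes_used=len(usable),
        mgs_correlations=mgs_corr,
        null_correlations=null_corr,
        p_value=float(res.pvalue),
        n_null_groups=n_groups,
        mode=mode,
    )
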