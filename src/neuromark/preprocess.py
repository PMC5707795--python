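"""Platform-side preparation of expression matrices.

Microarray pipeline: drop probesets whose maximal signal never clears the
global median, quantile-normalize samples a second time (the first pass
happens inside RMA, upstream of this package), then collapse probesets to
genes keeping the highest-variance probeset.  Single-cell RNA-seq enters as
cluster pseudo-samples (mean RPKM over the cluster's cells).  Both platforms
feed the same two-stage per-cell-type expression summary: mean over
replicates within a study, then unweighted mean across studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import RPKM, ExpressionMatrix, SampleAnnotation

__all__ = [
    "ProbesetMap",
    "CellTypeSummary",
    "read_probeset_map",
    "filter_low_signal_probesets",
    "collapse_probesets",
    "quantile_normalize",
    "summarize_cluster_profiles",
    "summarize_celltype_expression",
]


@dataclass
class ProbesetMap:
    """probeset_id -> gene_id mapping; a probeset maps to at most one gene."""

    mapping: dict[str, str]


def read_probeset_map(path) -> ProbesetMap:
    df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                     names=["probeset_id", "gene_id"])
    if df["probeset_id"].duplicated().any():
        dups = sorted(set(df["probeset_id"][df["probeset_id"].duplicated()]))
        raise ValueError(f"probeset mapped twice: {dups}")
    return ProbesetMap(dict(zip(df["probeset_id"], df["gene_id"])))


@dataclass
class CellTypeSummary:
    """Genes x cell-types matrix of two-stage mean expression.

    Each column is the unweighted mean over contributing studies of the
    within-study replicate means.  ``provenance`` maps cell type ->
    {study: n_samples}.
    """

    values: pd.DataFrame
    scale: str
    provenance: dict[str, dict[str, int]]

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def filter_low_signal_probesets(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep rows whose maximum across samples reaches the median of all
    matrix entries (inclusive boundary)."""
    if matrix.data.empty:
        raise ValueError("empty expression matrix")
    median = float(np.median(matrix.data.to_numpy()))
    keep = matrix.data.max(axis=1) >= median
    if not keep.any():
        raise ValueError("no probesets survive the low-signal filter")
    return ExpressionMatrix(matrix.data.loc[keep].copy(), matrix.scale)


def collapse_probesets(matrix: ExpressionMatrix, pmap: ProbesetMap) -> ExpressionMatrix:
    """One row per gene: the probeset with the largest sample variance
    (ddof=1); ties go to the lexicographically smallest probeset id.
    Probesets without a gene mapping are dropped.
    """
    mapped = [p for p in matrix.gene_ids if p in pmap.mapping]
    sub = matrix.data.loc[mapped]
    var = sub.var(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probeset in sorted(mapped):
        gene = pmap.mapping[probeset]
        if gene not in best or var[probeset] > var[best[gene]]:
            best[gene] = probeset
    genes = sorted(best)
    out = sub.loc[[best[g] for g in genes]]
    out.index = pd.Index(genes, name=matrix.data.index.name)
    return ExpressionMatrix(out, matrix.scale)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common rank-wise mean distribution.

    Tied values within a sample receive the mean of the rank-values their
    ranks span (average-ties convention).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.data.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average reference values over tie groups
        ser = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ser.to_numpy()
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(df, matrix.scale)


def summarize_cluster_profiles(
    cell_matrix: ExpressionMatrix, cluster_labels: dict[str, str]
) -> ExpressionMatrix:
    """Collapse single cells into one pseudo-sample per cluster (mean RPKM)."""
    if cell_matrix.scale != RPKM:
        raise ValueError("cluster summarization expects RPKM-scale input")
    unlabeled = [c for c in cell_matrix.sample_ids if c not in cluster_labels]
    if unlabeled:
        raise ValueError(f"cells without a cluster label: {unlabeled}")
    clusters = sorted(set(cluster_labels[c] for c in cell_matrix.sample_ids))
    cols = {}
    for cl in clusters:
        members = [c for c in cell_matrix.sample_ids if cluster_labels[c] == cl]
        if not members:
            raise ValueError(f"cluster {cl!r} has no cells")
        cols[cl] = cell_matrix.data[members].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols, index=cell_matrix.data.index), RPKM)


def summarize_celltype_expression(
    matrix: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    samples: list[str],
) -> CellTypeSummary:
    """Two-stage mean per cell type: replicate mean within each study,
    then unweighted mean across the studies representing the cell type."""
    if not samples:
        raise ValueError("no samples to summarize")
    ann = {a.sample_id: a for a in annotations}
    missing = [s for s in samples if s not in ann]
    if missing:
        raise ValueError(f"samples without annotation: {missing}")
    by_type: dict[str, dict[str, list[str]]] = {}
    for s in samples:
        a = ann[s]
        by_type.setdefault(a.cell_type, {}).setdefault(a.study, []).append(s)
    cols = {}
    provenance: dict[str, dict[str, int]] = {}
    for cell_type in sorted(by_type):
        study_means = [
            matrix.data[members].mean(axis=1)
            for members in by_type[cell_type].values()
        ]
        cols[cell_type] = pd.concat(study_means, axis=1).mean(axis=1)
        provenance[cell_type] = {
            st: len(members) for st, members in sorted(by_type[cell_type].items())
        }
    values = pd.DataFrame(cols, index=matrix.data.index)
    return CellTypeSummary(values=values, scale=matrix.scale, provenance=provenance)
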