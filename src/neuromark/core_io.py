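"""Data model and file I/O shared by every stage.

Expression values live in a genes-by-samples table tagged with their scale
(log2 microarray intensity or linear RPKM), samples carry annotations
(cell type, brain region, study, platform), and brain regions form a
hierarchy used to decide which purified-cell samples participate in a
regional marker-selection run.  Mouse-to-human gene mapping goes through
NCBI HomoloGene groups.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LOG2_INTENSITY",
    "RPKM",
    "ExpressionMatrix",
    "SampleAnnotation",
    "RegionHierarchy",
    "HomologyTable",
    "read_expression_table",
    "write_expression_table",
    "read_annotations",
    "write_annotations",
    "assign_samples_to_region",
    "read_homologene_table",
    "map_homologs",
    "default_region_hierarchy",
]

LOG2_INTENSITY = "log2_intensity"
RPKM = "rpkm"
_SCALES = (LOG2_INTENSITY, RPKM)

_PLATFORMS = ("microarray", "rnaseq_pooled", "rnaseq_single_cell_cluster")

#: override_regions keyword meaning "member of every region"
ALL_REGIONS = "all"


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with a scale tag.

    ``data`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  Values must be finite; identifiers must be unique.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise LoadError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = sorted(set(self.data.columns[self.data.columns.duplicated()]))
            raise LoadError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise LoadError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)].copy(), self.scale)


@dataclass
class SampleAnnotation:
    sample_id: str
    cell_type: str
    region: str
    study: str
    platform: str
    override_regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.platform not in _PLATFORMS:
            raise LoadError(
                f"sample {self.sample_id!r}: unknown platform {self.platform!r}; "
                f"expected one of {_PLATFORMS}"
            )


class RegionHierarchy:
    """Tree of brain regions; membership queries walk the ancestry.

    A sample annotated at a node is a member of that node and of every
    ancestor.  Per-sample ``override_regions`` add explicit extra
    memberships (the keyword ``all`` means every region) — this is how
    whole-brain microglia and cortex-derived glia participate in regions
    they were not isolated from.
    """

    def __init__(self, tree: dict):
        self._parent: dict[str, str | None] = {}
        self._children: dict[str, list[str]] = {}
        self._walk(tree, None)
        self.root = tree["name"]

    def _walk(self, node: dict, parent: str | None) -> None:
        name = node["name"]
        if name in self._parent:
            raise ValueError(f"duplicate region name {name!r}")
        self._parent[name] = parent
        self._children[name] = []
        if parent is not None:
            self._children[parent].append(name)
        for child in node.get("children", []) or []:
            self._walk(child, name)

    @classmethod
    def from_file(cls, path) -> "RegionHierarchy":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def regions(self) -> list[str]:
        return list(self._parent)

    def __contains__(self, name: str) -> bool:
        return name in self._parent

    def ancestors(self, name: str) -> list[str]:
        out = []
        cur = self._parent[name]
        while cur is not None:
            out.append(cur)
            cur = self._parent[cur]
        return out

    def is_within(self, region: str, ancestor: str) -> bool:
        """True if ``region`` equals ``ancestor`` or descends from it."""
        return region == ancestor or ancestor in self.ancestors(region)

    def membership(self, annotation: SampleAnnotation, region: str) -> bool:
        if region not in self._parent:
            raise KeyError(
                f"unknown region {region!r}; valid regions: {sorted(self._parent)}"
            )
        if ALL_REGIONS in annotation.override_regions:
            return True
        if region in annotation.override_regions:
            return True
        if annotation.region not in self._parent:
            return False
        return self.is_within(annotation.region, region)


def default_region_hierarchy() -> RegionHierarchy:
    """The packaged default brain-region hierarchy."""
    ref = importlib.resources.files("neuromark.data") / "brain_region_hierarchy.yaml"
    return RegionHierarchy(yaml.safe_load(ref.read_text()))


def read_expression_table(path, scale: str) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise LoadError(f"non-numeric value at gene {row!r}, sample {col!r}")
    return ExpressionMatrix(df.astype(float), scale)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read per-sample annotations from TSV.

    Columns: sample_id, cell_type, region, study, platform and an optional
    comma-separated override_regions column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["sample_id", "cell_type", "region", "study", "platform"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"annotation file missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df["sample_id"][df["sample_id"].duplicated()]))
        raise LoadError(f"duplicate sample ids in annotations: {dups}")
    out = []
    for _, row in df.iterrows():
        overrides = []
        if "override_regions" in df.columns and row["override_regions"]:
            overrides = [r.strip() for r in row["override_regions"].split(",") if r.strip()]
        out.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                cell_type=row["cell_type"],
                region=row["region"],
                study=row["study"],
                platform=row["platform"],
                override_regions=overrides,
            )
        )
    return out


def write_annotations(annotations: list[SampleAnnotation], path) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "cell_type": a.cell_type,
            "region": a.region,
            "study": a.study,
            "platform": a.platform,
            "override_regions": ",".join(a.override_regions),
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def assign_samples_to_region(
    annotations: list[SampleAnnotation],
    hierarchy: RegionHierarchy,
    region: str,
) -> list[str]:
    """Sample ids belonging to ``region``: annotated there or in a
    descendant, or carrying an explicit override for it."""
    if region not in hierarchy:
        raise KeyError(
            f"unknown region {region!r}; valid regions: {sorted(hierarchy.regions)}"
        )
    return [a.sample_id for a in annotations if hierarchy.membership(a, region)]


@dataclass
class HomologyTable:
    """Records of (homology_group_id, taxon_id, gene_id, gene_symbol)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        pair = self.records[["taxon_id", "gene_id"]]
        if pair.duplicated().any():
            dup = pair[pair.duplicated()].iloc[0]
            raise LoadError(
                f"(taxon, gene) pair mapped twice: ({dup['taxon_id']}, {dup['gene_id']})"
            )


def read_homologene_table(path) -> HomologyTable:
    """Parse the NCBI homologene.data tab-delimited dialect.

    Six columns (group, taxon, gene id, symbol, protein gi, accession);
    only the first four are retained.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise LoadError(
                    f"{path}: line {lineno}: expected >=4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            rows.append(
                {
                    "group_id": fields[0],
                    "taxon_id": fields[1],
                    "gene_id": fields[2],
                    "gene_symbol": fields[3],
                }
            )
    df = pd.DataFrame(rows, columns=["group_id", "taxon_id", "gene_id", "gene_symbol"])
    return HomologyTable(df)


def map_homologs(
    genes: list[str],
    table: HomologyTable,
    from_taxon: str,
    to_taxon: str,
) -> dict[str, list[str]]:
    """Map gene symbols across taxa through shared homology groups.

    Every target-taxon symbol in the query gene's group is returned
    (sorted); many-to-many pairs are preserved.  Genes without a group
    map to an empty list.  Symbols are case-sensitive.
    """
    rec = table.records
    from_taxon, to_taxon = str(from_taxon), str(to_taxon)
    src = rec[rec["taxon_id"] == from_taxon]
    dst = rec[rec["taxon_id"] == to_taxon]
    group_of = dict(zip(src["gene_symbol"], src["group_id"]))
    targets: dict[str, list[str]] = {}
    for gid, sub in dst.groupby("group_id"):
        targets[gid] = sorted(sub["gene_symbol"])
    return {g: targets.get(group_of.get(g), []) for g in genes}
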