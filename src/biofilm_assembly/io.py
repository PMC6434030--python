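"""Domain types and text I/O: community count tables, metadata, distance matrices.

File dialects (all plain text, tab-separated):

* dense count matrix — taxa x samples when the first header token is the
  reserved keyword ``taxon_id``, otherwise samples x taxa;
* sparse triplet list — header ``sample_id  taxon_id  count``, one row per
  non-zero cell;
* sample metadata — columns ``sample_id`` and ``group``;
* distance matrix — square labelled matrix, row index in the first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DENSE_TAXA_KEYWORD = "taxon_id"
_TRIPLET_COLUMNS = ("sample_id", "taxon_id", "count")

VALID_METRICS = ("sorensen", "simpson_turnover", "nestedness_component", "bray_curtis")


@dataclass(frozen=True)
class PairwiseComposition:
    """Incidence components of one sample pair: shared (a) and unique (b, c) taxa."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("incidence components must be non-negative")
        if self.a + self.b + self.c < 1:
            raise ValueError("both samples are empty (a + b + c == 0)")


class CommunityTable:
    """Sample x taxon count matrix with one group label per sample.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, rows = samples,
        columns = taxa.
    groups
        Mapping / Series sample_id -> group label covering every sample.
    drop_empty_taxa
        Drop all-zero taxon columns with a logged warning (default True).
    """

    def __init__(self, counts: pd.DataFrame, groups, drop_empty_taxa: bool = True,
                 quiet: bool = False):
        counts = pd.DataFrame(counts).copy()
        if counts.index.duplicated().any():
            raise ValueError("duplicate sample ids in count table")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate taxon ids in count table")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        bad = ~(np.isfinite(values) & (values >= 0) & (values == np.floor(values)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"negative or non-integer count at sample "
                f"{counts.index[i]!r}, taxon {counts.columns[j]!r}: {values[i, j]!r}"
            )
        counts = counts.astype(np.int64)

        empty_taxa = counts.columns[counts.sum(axis=0) == 0]
        if len(empty_taxa):
            if not drop_empty_taxa:
                raise ValueError(f"taxa with zero total count: {list(empty_taxa)}")
            (logger.debug if quiet else logger.warning)(
                "dropping %d taxa observed in zero samples: %s",
                len(empty_taxa),
                list(empty_taxa[:10]),
            )
            counts = counts.drop(columns=empty_taxa)

        empty_samples = counts.index[counts.sum(axis=1) == 0]
        if len(empty_samples):
            raise ValueError(f"samples with zero total count: {list(empty_samples)}")

        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        missing = counts.index.difference(groups.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {list(missing)}")
        self.counts = counts
        self.groups = groups.reindex(counts.index).astype(str)

    # ------------------------------------------------------------------ views
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def incidence(self) -> np.ndarray:
        """Binary presence/absence matrix (samples x taxa, dtype int8)."""
        return (self.counts.to_numpy() > 0).astype(np.int8)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def subset_group(self, group: str) -> "CommunityTable":
        """Restrict to one group's samples, dropping taxa absent from the group."""
        keep = self.groups.index[self.groups == group]
        if not len(keep):
            raise KeyError(f"no samples in group {group!r}")
        return CommunityTable(self.counts.loc[keep], self.groups.loc[keep], quiet=True)

    def min_count_filter(self, min_count: int) -> "CommunityTable":
        """Drop taxa whose total count across all samples is below ``min_count``."""
        keep = self.counts.columns[self.counts.sum(axis=0) >= min_count]
        return CommunityTable(self.counts[keep], self.groups)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CommunityTable)
            and self.counts.equals(other.counts)
            and self.groups.equals(other.groups)
        )

    def __repr__(self) -> str:
        return (
            f"CommunityTable({self.n_samples} samples x {self.n_taxa} taxa, "
            f"groups={self.group_labels()})"
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix tagged with the index it holds."""

    sample_ids: list[str]
    values: np.ndarray
    metric_name: str = "sorensen"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if self.metric_name not in VALID_METRICS:
            raise ValueError(f"metric_name must be one of {VALID_METRICS}")
        if self.metric_name in ("sorensen", "simpson_turnover", "bray_curtis"):
            if (self.values > 1 + 1e-12).any():
                raise ValueError(f"{self.metric_name} dissimilarities must be <= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy ``squareform`` order."""
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


# --------------------------------------------------------------------- readers

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_community_table(path, metadata_path, drop_empty_taxa: bool = True) -> CommunityTable:
    """Read a dense or sparse-triplet count table plus sample metadata.

    The dense orientation is auto-detected: a first header token equal to
    ``taxon_id`` marks rows as taxa; anything else marks rows as samples.
    A three-column header ``sample_id/taxon_id/count`` marks the sparse
    triplet dialect.
    """
    raw = _read_tsv(path)
    cols = [c.strip() for c in raw.columns]
    if tuple(cols) == _TRIPLET_COLUMNS:
        counts = _triplet_to_dense(raw)
    else:
        frame = raw.set_index(raw.columns[0])
        try:
            frame = frame.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric count in {path}: {exc}") from exc
        if cols[0] == _DENSE_TAXA_KEYWORD:
            frame = frame.T  # rows were taxa
        if frame.index.duplicated().any():
            raise ValueError("duplicate sample ids in count table")
        if frame.columns.duplicated().any():
            raise ValueError("duplicate taxon ids in count table")
        counts = frame

    meta = _read_tsv(metadata_path)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata must have columns 'sample_id' and 'group'")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    groups = meta.set_index("sample_id")["group"]
    return CommunityTable(counts, groups, drop_empty_taxa=drop_empty_taxa)


def _triplet_to_dense(raw: pd.DataFrame) -> pd.DataFrame:
    trip = raw.copy()
    trip.columns = list(_TRIPLET_COLUMNS)
    try:
        trip["count"] = trip["count"].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in triplet file: {exc}") from exc
    dup = trip.duplicated(subset=["sample_id", "taxon_id"])
    if dup.any():
        raise ValueError("duplicate (sample, taxon) cell in triplet file")
    dense = trip.pivot(index="sample_id", columns="taxon_id", values="count").fillna(0.0)
    dense.index.name = None
    dense.columns.name = None
    return dense


def write_community_table(table: CommunityTable, path, metadata_path=None) -> None:
    """Write a dense samples x taxa TSV (and optionally the metadata TSV)."""
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        meta = pd.DataFrame({"sample_id": table.sample_ids, "group": table.groups.values})
        meta.to_csv(metadata_path, sep="\t", index=False)


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    """Write a square labelled TSV; round-trips through :func:`read_distance_matrix`."""
    frame = d.to_frame()
    frame.index.name = d.metric_name
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_distance_matrix(path, metric_name: str | None = None) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    name = metric_name or frame.index.name
    if name not in VALID_METRICS:
        name = "sorensen"
    return DistanceMatrix(list(frame.index.astype(str)), frame.to_numpy(dtype=float), name)
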