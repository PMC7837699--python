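"""Core community-matrix data model, normalization, dissimilarity and clustering.

The central object is :class:`CommunityTable`, a sample x taxon abundance
matrix with per-taxon kingdom/group annotations. Downstream stages
(co-occurrence, biogeography, indicator screening, function linkage) all
consume this type or the :class:`DistanceMatrix` derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

KINGDOMS = ("bacteria", "fungi")
GROUPS = ("LAB", "AAB", "yeast", "other")

__all__ = [
    "CommunityTable",
    "DistanceMatrix",
    "Dendrogram",
    "rarefy",
    "to_relative_abundance",
    "bray_curtis",
    "combine_kingdoms",
    "hierarchical_cluster",
]


@dataclass
class CommunityTable:
    """Sample x taxon abundance matrix with taxon annotations.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative matrix, samples as rows, taxa as columns.
    annotations : pandas.DataFrame
        Indexed by taxon id with ``kingdom`` (bacteria/fungi) and
        ``group`` (LAB/AAB/yeast/other) columns. Every taxon in
        ``data`` must be annotated.
    relative : bool
        Whether rows are declared to be relative abundances (each row
        summing to 1).
    """

    data: pd.DataFrame
    annotations: pd.DataFrame
    relative: bool = False

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("abundance matrix contains negative values")
        missing = set(self.data.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(f"taxa lacking annotations: {sorted(missing)}")
        for col in ("kingdom", "group"):
            if col not in self.annotations.columns:
                raise ValueError(f"annotations missing column {col!r}")
        bad_k = set(self.annotations["kingdom"]) - set(KINGDOMS)
        if bad_k:
            raise ValueError(f"unknown kingdoms: {sorted(bad_k)}")
        bad_g = set(self.annotations["group"]) - set(GROUPS)
        if bad_g:
            raise ValueError(f"unknown groups: {sorted(bad_g)}")
        if self.relative:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                off = self.data.index[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
                raise ValueError(f"relative rows must sum to 1; offending samples: {off}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def kingdom_of(self, taxon: str) -> str:
        return str(self.annotations.loc[taxon, "kingdom"])

    def group_of(self, taxon: str) -> str:
        return str(self.annotations.loc[taxon, "group"])

    def taxa_in_group(self, group: str) -> list[str]:
        sel = self.annotations.loc[list(self.data.columns)]
        return list(sel.index[sel["group"] == group])

    def group_fraction(self, group: str) -> pd.Series:
        """Per-sample summed abundance of all taxa annotated with ``group``."""
        taxa = self.taxa_in_group(group)
        return self.data[taxa].sum(axis=1) if taxa else pd.Series(0.0, index=self.data.index)

    def subset_samples(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(sample_ids)], self.annotations, self.relative)

    def subset_taxa(self, taxon_ids) -> "CommunityTable":
        return CommunityTable(self.data[list(taxon_ids)], self.annotations, relative=False)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    ids: list
    d: np.ndarray
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        # exact symmetry/diagonal for downstream numerics
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def align(self, ids) -> "DistanceMatrix":
        """Reorder/subset to the given ids."""
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges[k] = (i, j)`` joins clusters ``i`` and ``j`` at
    ``heights[k]``; leaves are numbered ``0..n-1`` and the k-th merge
    creates cluster ``n + k`` (same convention as scipy linkage rows).
    """

    merges: list[tuple[int, int]]
    heights: list[float]
    leaf_ids: list
    linkage_name: str
    sizes: list[int] = field(default_factory=list)

    def to_linkage(self) -> np.ndarray:
        """Return a scipy-style (n-1) x 4 linkage matrix."""
        out = np.zeros((len(self.merges), 4))
        for k, ((i, j), h) in enumerate(zip(self.merges, self.heights)):
            out[k] = (i, j, h, self.sizes[k] if self.sizes else 0)
        return out


def rarefy(counts: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and
    reported via a warning. Input must be integer counts.
    """
    values = counts.data.to_numpy()
    frac = values - np.floor(values)
    if (frac != 0).any():
        r, c = np.argwhere(frac != 0)[0]
        raise ValueError(
            "rarefy requires integer counts; non-integer value "
            f"{values[r, c]!r} at sample {counts.data.index[r]!r}, "
            f"taxon {counts.data.columns[c]!r}"
        )
    values = values.astype(np.int64)
    if depth <= 0:
        raise ValueError("depth must be a positive integer")

    totals = values.sum(axis=1)
    keep = totals >= depth
    dropped = list(counts.data.index[~keep])
    if dropped:
        warnings.warn(f"{len(dropped)} sample(s) below depth {depth} dropped: {dropped}")

    rng = np.random.default_rng(seed)
    n_taxa = values.shape[1]
    rows = []
    for row in values[keep]:
        reads = np.repeat(np.arange(n_taxa), row)
        chosen = rng.choice(reads.size, size=depth, replace=False)
        rows.append(np.bincount(reads[chosen], minlength=n_taxa))
    data = pd.DataFrame(
        np.array(rows, dtype=np.int64) if rows else np.empty((0, n_taxa), dtype=np.int64),
        index=counts.data.index[keep],
        columns=counts.data.columns,
    )
    return CommunityTable(data, counts.annotations, relative=False)


def to_relative_abundance(counts: CommunityTable) -> CommunityTable:
    """Row-normalize to relative abundances; zeros are preserved."""
    values = counts.values
    sums = values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        bad = list(counts.data.index[zero])
        raise ValueError(f"cannot normalize all-zero sample(s): {bad}")
    data = pd.DataFrame(
        values / sums[:, None], index=counts.data.index, columns=counts.data.columns
    )
    return CommunityTable(data, counts.annotations, relative=True)


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    values = table.values
    zero_rows = values.sum(axis=1) == 0
    if zero_rows.sum() >= 2:
        bad = list(table.data.index[zero_rows])
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    diffs = np.abs(values[:, None, :] - values[None, :, :]).sum(axis=2)
    sums = (values[:, None, :] + values[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(sums > 0, diffs / np.where(sums > 0, sums, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d, "braycurtis")


def combine_kingdoms(
    bacteria: CommunityTable,
    fungi: CommunityTable,
    weights: tuple[float, float] = (0.5, 0.5),
) -> CommunityTable:
    """Merge bacterial and fungal tables into one weighted relative table.

    The fungal table is restricted to taxa annotated group=yeast, each
    kingdom block is row-renormalized to its weight, and the blocks are
    concatenated so each output row sums to 1 (for the default equal
    weights, each block contributes 0.5).
    """
    wb, wf = weights
    if wb < 0 or wf < 0 or not np.isclose(wb + wf, 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    if set(bacteria.sample_ids) != set(fungi.sample_ids):
        only_b = sorted(set(bacteria.sample_ids) - set(fungi.sample_ids))
        only_f = sorted(set(fungi.sample_ids) - set(bacteria.sample_ids))
        raise ValueError(
            f"sample sets differ; only in bacteria: {only_b}, only in fungi: {only_f}"
        )
    yeast_taxa = fungi.taxa_in_group("yeast")
    fungi_data = fungi.data[yeast_taxa].loc[bacteria.data.index]

    blocks = []
    for block, w in ((bacteria.data, wb), (fungi_data, wf)):
        if w == 0:
            continue
        sums = block.sum(axis=1)
        if (sums == 0).any():
            bad = list(block.index[sums == 0])
            raise ValueError(f"all-zero block row(s) prevent renormalization: {bad}")
        blocks.append(block.div(sums, axis=0) * w)
    merged = pd.concat(blocks, axis=1)
    annotations = pd.concat([bacteria.annotations, fungi.annotations])
    annotations = annotations[~annotations.index.duplicated()]
    return CommunityTable(merged, annotations, relative=True)


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "ward.d2") -> Dendrogram:
    """Agglomerative clustering with the Ward.D2 squared-distance update.

    Implements the Lance-Williams recurrence on squared dissimilarities
    (merge heights are the square roots), which reproduces standard
    Ward.D2 merge heights. Ties are broken by the smallest (i, j)
    cluster-index pair.
    """
    if linkage.lower() not in ("ward.d2", "ward"):
        raise ValueError(f"unsupported linkage: {linkage}")
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    # S holds squared inter-cluster dissimilarities over active clusters
    big = np.inf
    S = np.full((2 * n - 1, 2 * n - 1), big)
    S[:n, :n] = d.d**2
    np.fill_diagonal(S, big)
    active = np.zeros(2 * n - 1, dtype=bool)
    active[:n] = True
    sizes = np.zeros(2 * n - 1, dtype=np.int64)
    sizes[:n] = 1

    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    out_sizes: list[int] = []
    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = S[np.ix_(idx, idx)]
        flat = int(np.argmin(sub))  # row-major scan -> smallest (i, j) among ties
        a, b = divmod(flat, len(idx))
        if a > b:
            a, b = b, a
        i, j = int(idx[a]), int(idx[b])
        h = float(np.sqrt(S[i, j]))
        new = n + step
        merges.append((i, j))
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        sizes[new] = ni + nj
        out_sizes.append(int(ni + nj))

        others = idx[(idx != i) & (idx != j)]
        if others.size:
            nk = sizes[others]
            upd = ((ni + nk) * S[i, others] + (nj + nk) * S[j, others] - nk * S[i, j]) / (
                ni + nj + nk
            )
            S[new, others] = upd
            S[others, new] = upd
        active[i] = active[j] = False
        active[new] = True

    return Dendrogram(merges, heights, list(d.ids), "ward.d2", out_sizes)
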