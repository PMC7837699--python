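"""VOC table preprocessing and community-to-function linkage statistics.

Blank-based background filtering, Kovats retention indices, per-compound
z-scores, and the combined report tying VOC composition to community
structure (Mantel tests), ordination axes (per-taxon Spearman screens),
dough-rise rates and dominant sensory notes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_fdr, spearman
from .community import CommunityTable, DistanceMatrix, bray_curtis
from .multivariate import KruskalDunnResult, MantelResult, kruskal_dunn, mantel, nmds

__all__ = [
    "VOCTable",
    "FunctionLinkReport",
    "background_filter",
    "kovats_ri",
    "zscore_matrix",
    "average_replicates",
    "link_function",
]


@dataclass
class VOCTable:
    """Sample x compound relative peak areas (analyte / internal standard)."""

    data: pd.DataFrame
    retention_times: dict[str, float] = field(default_factory=dict)
    retention_indices: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("peak areas must be non-negative")
        for cid, ri in self.retention_indices.items():
            if not np.isfinite(ri) or ri < 700:
                raise ValueError(f"retention index for {cid!r} must be finite and >= 700")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class FunctionLinkReport:
    mantel_voc_community: MantelResult | None = None
    mantel_voc_aab: MantelResult | None = None
    taxon_nmds_correlations: pd.DataFrame | None = None
    aab_rise_spearman: tuple[float, float] | None = None
    sensory_kruskal: KruskalDunnResult | None = None
    nmds_stress: float | None = None
    warnings: list = field(default_factory=list)


def background_filter(voc: VOCTable, blanks: VOCTable) -> VOCTable:
    """Drop compounds whose signal does not exceed the blank background.

    A compound is eliminated from the whole table when its maximum area
    across samples is less than or equal to its maximum area across blank
    samples. Compounds absent from the blanks are retained.
    """
    if blanks is None or blanks.data.empty or len(blanks.sample_ids) == 0:
        raise ValueError("background_filter requires at least one blank sample")
    keep = []
    for compound in voc.compound_ids:
        if compound in blanks.data.columns:
            blank_max = float(blanks.data[compound].max())
            if float(voc.data[compound].max()) <= blank_max:
                continue
        keep.append(compound)
    return VOCTable(
        voc.data[keep].copy(),
        {c: v for c, v in voc.retention_times.items() if c in keep},
        {c: v for c, v in voc.retention_indices.items() if c in keep},
    )


def kovats_ri(rt: float, alkane_rts: dict[int, float]) -> float:
    """Kovats retention index by linear interpolation between n-alkanes.

    RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n)) for the bracketing
    alkane carbon numbers n and n+1 (temperature-programmed convention).
    """
    carbons = sorted(alkane_rts)
    if len(carbons) < 2:
        raise ValueError("need at least two alkane standards")
    rts = [alkane_rts[c] for c in carbons]
    if any(b <= a for a, b in zip(rts, rts[1:])):
        raise ValueError("alkane retention times must increase with carbon number")
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(
            f"retention time {rt} outside the alkane range [{rts[0]}, {rts[-1]}]"
        )
    idx = int(np.searchsorted(rts, rt, side="right")) - 1
    idx = min(idx, len(carbons) - 2)
    n, rt_n = carbons[idx], rts[idx]
    n_next, rt_next = carbons[idx + 1], rts[idx + 1]
    return 100.0 * (n + (n_next - n) * (rt - rt_n) / (rt_next - rt_n))


def zscore_matrix(voc: VOCTable) -> pd.DataFrame:
    """Standardize each compound to mean 0, SD 1 (population SD).

    Compounds with zero variance become all-NaN columns.
    """
    if len(voc.sample_ids) < 2:
        raise ValueError("need at least 2 samples to standardize")
    x = voc.data.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    z = (x - mu) / sd.replace(0.0, np.nan)
    return z


def average_replicates(df: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Average replicate rows into one row per inoculum/starter."""
    mapping = mapping.loc[df.index]
    return df.groupby(mapping).mean().sort_index()


def link_function(
    voc: VOCTable,
    community: CommunityTable,
    rise: pd.Series | None = None,
    sensory: pd.Series | None = None,
    n_perm: int = 999,
    seed: int = 0,
    min_note_n: int = 5,
) -> FunctionLinkReport:
    """Compute the community->function linkage report.

    All inputs must already be averaged to one row per starter and share
    a sample namespace. Sub-analyses with missing inputs are skipped with
    a warning recorded on the report.
    """
    report = FunctionLinkReport()
    samples = [s for s in voc.sample_ids if s in set(community.sample_ids)]
    if len(samples) < 4:
        raise ValueError("need at least 4 shared samples between VOC and community tables")
    voc_sub = VOCTable(voc.data.loc[samples])
    comm_sub = community.subset_samples(samples)

    voc_rel = voc_sub.data.div(voc_sub.data.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    voc_bc = DistanceMatrix(samples, _safe_braycurtis(voc_rel.to_numpy()), "braycurtis")

    comm_bc = bray_curtis(comm_sub)
    report.mantel_voc_community = mantel(voc_bc, comm_bc, n_perm=n_perm, seed=seed)

    aab = comm_sub.group_fraction("AAB").to_numpy()
    aab_d = DistanceMatrix(samples, np.abs(aab[:, None] - aab[None, :]), "euclidean_pct_aab")
    report.mantel_voc_aab = mantel(voc_bc, aab_d, n_perm=n_perm, seed=seed + 1)

    ord_res = nmds(voc_bc, k=2, seed=seed)
    report.nmds_stress = ord_res.stress
    rows = []
    for taxon in comm_sub.taxon_ids:
        abund = comm_sub.data[taxon].to_numpy(dtype=float)
        for axis in (0, 1):
            coords = ord_res.coordinates[:, axis]
            if abund.std() == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = spearman(abund, coords)
            rows.append({"taxon": taxon, "axis": axis + 1, "rho": rho, "p_raw": p})
    tax = pd.DataFrame(rows)
    tax["p_fdr"] = bh_fdr(tax["p_raw"].to_numpy())
    report.taxon_nmds_correlations = tax

    if rise is not None:
        shared = [s for s in samples if s in rise.index]
        if len(shared) >= 4:
            report.aab_rise_spearman = spearman(
                comm_sub.group_fraction("AAB").loc[shared].to_numpy(),
                rise.loc[shared].to_numpy(dtype=float),
            )
        else:
            report.warnings.append("too few samples with rise rates; Spearman skipped")
    else:
        report.warnings.append("no rise rates provided; %AAB-rise Spearman skipped")

    if sensory is not None:
        shared = [s for s in samples if s in sensory.index]
        try:
            report.sensory_kruskal = kruskal_dunn(
                comm_sub.group_fraction("AAB").loc[shared].to_numpy(),
                sensory.loc[shared].to_numpy(dtype=object),
                min_group_n=min_note_n,
            )
        except ValueError as exc:
            report.warnings.append(f"sensory analysis skipped: {exc}")
    else:
        report.warnings.append("no sensory notes provided; Kruskal-Wallis skipped")

    for msg in report.warnings:
        warnings.warn(msg)
    return report


def _safe_braycurtis(values: np.ndarray) -> np.ndarray:
    diffs = np.abs(values[:, None, :] - values[None, :, :]).sum(axis=2)
    sums = (values[:, None, :] + values[None, :, :]).sum(axis=2)
    d = np.where(sums > 0, diffs / np.where(sums > 0, sums, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return d
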