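"""Indicator-taxon detection for categorical and continuous metadata.

Categorical variables use the point-biserial correlation index r (the
correlation-type indicator statistic) with a permutation p-value;
continuous variables use Spearman rank correlation. A prevalence filter
and per-variable Benjamini-Hochberg FDR control precede reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_fdr, spearman
from .community import CommunityTable

__all__ = [
    "IndicatorResult",
    "indicator_r",
    "indicator_indval",
    "indicator_continuous",
    "indicator_screen",
]


@dataclass
class IndicatorResult:
    taxon_id: str
    variable: str
    kind: str  # categorical | continuous
    statistic: float
    p_raw: float
    p_fdr: float
    n_samples: int
    best_level: str | None = None
    reason: str | None = None


def _point_biserial(abund: np.ndarray, member: np.ndarray) -> float:
    sa, sm = abund.std(), member.std()
    if sa == 0 or sm == 0:
        return float("nan")
    return float(np.corrcoef(abund, member)[0, 1])


def indicator_r(
    abundance,
    groups,
    target_level,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation indicator index for one taxon against one group level.

    r is the point-biserial correlation between abundance and the 0/1
    membership vector of ``target_level``; p comes from one-sided label
    permutations with the add-one rule, so it is never reported as 0.
    Returns (nan, nan) for a constant abundance vector.
    """
    abundance = np.asarray(abundance, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 group levels")
    if (abundance < 0).any():
        raise ValueError("abundances must be non-negative")
    member = (groups == target_level).astype(float)
    r = _point_biserial(abundance, member)
    if np.isnan(r):
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    eps = 1e-12
    hits = 0
    for _ in range(n_perm):
        rp = _point_biserial(abundance, member[rng.permutation(member.size)])
        hits += rp >= r - eps
    return r, (hits + 1) / (n_perm + 1)


def indicator_indval(
    abundance,
    groups,
    target_level,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Group-equalized IndVal statistic (sqrt of A*B) with permutation p.

    A = mean abundance in the target group divided by the sum of
    per-group mean abundances (group-equalized specificity); B = fraction
    of target-group samples where the taxon occurs. Provided as an
    alternative to :func:`indicator_r` for region-style analyses.
    """
    abundance = np.asarray(abundance, dtype=float)
    groups = np.asarray(groups, dtype=object)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")

    def stat(ab, gl):
        means = np.array([ab[gl == lv].mean() for lv in levels])
        total = means.sum()
        if total == 0:
            return float("nan")
        a = means[list(levels).index(target_level)] / total
        mask = gl == target_level
        b = (ab[mask] > 0).mean()
        return float(np.sqrt(a * b))

    obs = stat(abundance, groups)
    if np.isnan(obs):
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    eps = 1e-12
    hits = 0
    for _ in range(n_perm):
        sp = stat(abundance, groups[rng.permutation(groups.size)])
        hits += (not np.isnan(sp)) and sp >= obs - eps
    return obs, (hits + 1) / (n_perm + 1)


def indicator_continuous(abundance, variable) -> tuple[float, float]:
    """Spearman correlation of taxon abundance with a continuous variable.

    Midrank ties; exact permutation p for n <= 9, t-approximation above.
    """
    abundance = np.asarray(abundance, dtype=float)
    variable = np.asarray(variable, dtype=float)
    if not (np.isfinite(abundance).all() and np.isfinite(variable).all()):
        raise ValueError("inputs must be finite")
    return spearman(abundance, variable)


def _max_level_r(abund: np.ndarray, dummies: np.ndarray):
    """Best point-biserial r over group levels; returns (r, level index)."""
    ac = abund - abund.mean()
    sa = ac.std()
    if sa == 0:
        return float("nan"), -1
    dc = dummies - dummies.mean(axis=0)
    sd = dc.std(axis=0)
    with np.errstate(invalid="ignore"):
        rs = (ac @ dc) / (abund.size * sa * np.where(sd > 0, sd, np.nan))
    if np.all(np.isnan(rs)):
        return float("nan"), -1
    best = int(np.nanargmax(rs))
    return float(rs[best]), best


def indicator_screen(
    table: CommunityTable,
    metadata: pd.DataFrame,
    types: dict[str, str],
    prevalence_min: float = 0.10,
    fdr_alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    detection_threshold: float = 0.01,
    statistic: str = "r",
) -> list[IndicatorResult]:
    """Screen every taxon against every metadata variable.

    Taxa detected (abundance > ``detection_threshold``) in fewer than
    ``prevalence_min`` of samples are excluded. For categorical variables
    the statistic is the maximum point-biserial r over levels with a
    permutation p on that maximum; continuous variables use Spearman
    correlation. FDR (Benjamini-Hochberg) is applied within each
    variable; rows are sorted by adjusted p then taxon id.
    """
    untyped = [c for c in metadata.columns if c not in types]
    if untyped:
        raise ValueError(f"variables missing a categorical/continuous type: {untyped}")
    bad = {v: t for v, t in types.items() if t not in ("categorical", "continuous")}
    if bad:
        raise ValueError(f"unknown variable types: {bad}")

    meta = metadata.loc[table.sample_ids]
    values = table.values
    prevalence = (values > detection_threshold).mean(axis=0)
    kept = [t for t, p in zip(table.taxon_ids, prevalence) if p >= prevalence_min]
    rng = np.random.default_rng(seed)

    results: list[IndicatorResult] = []
    for variable in metadata.columns:
        kind = types[variable]
        col = meta[variable]
        var_results: list[IndicatorResult] = []
        if kind == "categorical":
            labels = col.to_numpy(dtype=object)
            levels = sorted(pd.unique(labels))
            dummies = np.column_stack([(labels == lv).astype(float) for lv in levels])
            perms = np.array([rng.permutation(len(labels)) for _ in range(n_perm)])
            for taxon in kept:
                abund = table.data[taxon].to_numpy(dtype=float)
                if statistic == "indval":
                    best_lv = None
                    obs, p = float("nan"), float("nan")
                    # best level by observed statistic, then permute that max
                    stats_by_level = [
                        indicator_indval(abund, labels, lv, n_perm=n_perm,
                                         seed=int(rng.integers(2**31)))
                        for lv in levels
                    ]
                    vals = [s[0] for s in stats_by_level]
                    if not np.all(np.isnan(vals)):
                        bi = int(np.nanargmax(vals))
                        obs, p = stats_by_level[bi]
                        best_lv = levels[bi]
                    var_results.append(IndicatorResult(
                        taxon, variable, kind, obs, p, np.nan, len(labels), best_lv,
                        None if not np.isnan(obs) else "constant abundance"))
                    continue
                obs, best_idx = _max_level_r(abund, dummies)
                if np.isnan(obs):
                    var_results.append(IndicatorResult(
                        taxon, variable, kind, np.nan, np.nan, np.nan,
                        len(labels), None, "constant abundance"))
                    continue
                eps = 1e-12
                hits = 0
                for perm in perms:
                    rp, _ = _max_level_r(abund, dummies[perm])
                    hits += (not np.isnan(rp)) and rp >= obs - eps
                p = (hits + 1) / (n_perm + 1)
                var_results.append(IndicatorResult(
                    taxon, variable, kind, obs, p, np.nan, len(labels),
                    levels[best_idx]))
        else:
            var = col.to_numpy(dtype=float)
            for taxon in kept:
                abund = table.data[taxon].to_numpy(dtype=float)
                if abund.std() == 0 or np.std(var) == 0:
                    var_results.append(IndicatorResult(
                        taxon, variable, kind, np.nan, np.nan, np.nan,
                        var.size, None, "constant vector"))
                    continue
                rho, p = indicator_continuous(abund, var)
                var_results.append(IndicatorResult(
                    taxon, variable, kind, rho, p, np.nan, var.size))
        adj = bh_fdr([r.p_raw for r in var_results])
        for r, a in zip(var_results, adj):
            r.p_fdr = float(a)
        results.extend(var_results)

    results.sort(key=lambda r: (np.inf if np.isnan(r.p_fdr) else r.p_fdr, r.taxon_id, r.variable))
    return results
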