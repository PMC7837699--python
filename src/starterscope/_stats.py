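"""Shared rank-statistics helpers used by several analysis modules."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

__all__ = ["spearman", "bh_fdr", "rankdata"]

rankdata = stats.rankdata  # midrank ties throughout


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x, y, *, exact_max: int = 9, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p for small n.

    Ties receive midranks. For n <= ``exact_max`` the p-value is computed
    by enumerating all n! permutations of one rank vector; above that the
    usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if np.isnan(rho):
        return float("nan"), float("nan")

    if n <= exact_max:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / denom
        eps = 1e-12
        if alternative == "two-sided":
            p = float(np.mean(np.abs(rhos) >= abs(rho) - eps))
        elif alternative == "greater":
            p = float(np.mean(rhos >= rho - eps))
        elif alternative == "less":
            p = float(np.mean(rhos <= rho + eps))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return rho, p

    res = stats.spearmanr(x, y, alternative=alternative)
    return rho, float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out
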