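"""Permutation-based multivariate statistics on distance matrices.

Mantel correlation, sequential (Type-I) PERMANOVA via the Gower-centered
inner-product partition, non-metric multidimensional scaling, and
Kruskal-Wallis with Dunn post-hoc comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from ._stats import bh_fdr, rankdata
from .community import DistanceMatrix

__all__ = [
    "MantelResult",
    "PermanovaResult",
    "NmdsResult",
    "KruskalDunnResult",
    "mantel",
    "permanova",
    "nmds",
    "kruskal_dunn",
]


@dataclass
class MantelResult:
    rho: float
    p: float
    n_perm: int
    method: str
    alternative: str = "greater"
    reason: str | None = None


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, ss, df, pseudo_f, r2, p
    residual_ss: float
    residual_df: int
    total_ss: float
    n_perm: int
    dropped_samples: list = field(default_factory=list)


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    converged: bool
    n_starts: int
    ids: list = field(default_factory=list)
    stress_history: list = field(default_factory=list)


@dataclass
class KruskalDunnResult:
    h: float
    p: float
    groups: list
    dunn: pd.DataFrame  # group_a, group_b, z, p_raw, p_fdr
    dropped_groups: list = field(default_factory=list)


def _offdiag(d: np.ndarray) -> np.ndarray:
    return squareform(d, checks=False)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test between two distance matrices.

    The statistic is the rank (Spearman) or linear (Pearson) correlation
    over the n(n-1)/2 off-diagonal pairs; the null distribution permutes
    rows and columns of ``d2`` simultaneously. The default one-sided p
    tests for positive association with the add-one rule
    (#{rho_perm >= rho_obs} + 1) / (n_perm + 1). With ``exact=True`` all
    n! permutations are enumerated instead (small n only) and p is the
    exact null fraction.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different sample sets")
    d2 = d2.align(d1.ids)
    n = len(d1)
    if n < 4:
        raise ValueError(f"need at least 4 samples for a Mantel test, got {n}")
    if method not in ("spearman", "pearson", "rank", "linear"):
        raise ValueError(f"unknown method {method!r}")
    use_rank = method in ("spearman", "rank")

    v1 = _offdiag(d1.d)
    x = rankdata(v1) if use_rank else v1
    x = x - x.mean()
    sx = np.sqrt((x**2).sum())

    def corr_with(mat: np.ndarray) -> float:
        v2 = _offdiag(mat)
        y = rankdata(v2) if use_rank else v2
        y = y - y.mean()
        sy = np.sqrt((y**2).sum())
        if sx == 0 or sy == 0:
            return float("nan")
        return float((x @ y) / (sx * sy))

    rho = corr_with(d2.d)
    if np.isnan(rho):
        return MantelResult(
            float("nan"), float("nan"), n_perm, method, alternative,
            reason="constant distances: correlation undefined",
        )

    eps = 1e-12

    def tail_hit(rp: float) -> bool:
        if alternative == "greater":
            return rp >= rho - eps
        if alternative == "less":
            return rp <= rho + eps
        if alternative == "two-sided":
            return abs(rp) >= abs(rho) - eps
        raise ValueError(f"unknown alternative {alternative!r}")

    if exact:
        import itertools

        perms = list(itertools.permutations(range(n)))
        hits = sum(tail_hit(corr_with(d2.d[np.ix_(p_, p_)])) for p_ in perms)
        return MantelResult(rho, hits / len(perms), len(perms), method, alternative)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += tail_hit(corr_with(d2.d[np.ix_(perm, perm)]))
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(rho, p, n_perm, method, alternative)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_columns(values: np.ndarray, kind: str) -> np.ndarray:
    """Encode one predictor as design-matrix columns (no intercept)."""
    if kind == "continuous":
        v = values.astype(float)
        return (v - v.mean())[:, None]
    # categorical: dummy-code dropping the first level
    levels = sorted(pd.unique(values))
    cols = [(values == lv).astype(float) for lv in levels[1:]]
    if not cols:
        return np.empty((len(values), 0))
    return np.column_stack(cols)


def permanova(
    d: DistanceMatrix,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    types: dict[str, str] | None = None,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a distance matrix.

    Terms are added in the order of ``predictors`` columns
    (McArdle-Anderson partition of the Gower-centered matrix); the order
    matters for correlated predictors. Samples with missing predictor
    values are dropped and reported. P-values come from free permutation
    of sample labels.

    ``types`` optionally maps column name to "categorical"/"continuous";
    by default numeric columns are treated as continuous and everything
    else as categorical.
    """
    pred = predictors.loc[list(d.ids)]
    missing = pred.isna().any(axis=1)
    dropped = list(pred.index[missing])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) with missing predictors: {dropped}")
        keep_ids = [i for i in d.ids if i not in set(dropped)]
        d = d.align(keep_ids)
        pred = pred.loc[keep_ids]
    n = len(d)
    g = _gower_center(d.d)
    total_ss = float(np.trace(g))

    # sequential hat matrices
    ones = np.ones((n, 1))
    x = ones
    hats = []
    dfs = []
    prev_rank = 1
    for term in pred.columns:
        if types and term in types:
            kind = types[term]
        else:
            kind = "continuous" if pd.api.types.is_numeric_dtype(pred[term]) else "categorical"
        cols = _design_columns(pred[term].to_numpy(), kind)
        x = np.column_stack([x, cols])
        rank = np.linalg.matrix_rank(x)
        df = rank - prev_rank
        if df == 0:
            raise ValueError(f"term {term!r} is degenerate (zero df after earlier terms)")
        prev_rank = rank
        h = x @ np.linalg.pinv(x)
        hats.append(h)
        dfs.append(df)
    resid_df = n - prev_rank
    if resid_df <= 0:
        raise ValueError("model saturates the samples; no residual df")

    h0 = ones @ ones.T / n
    deltas = []
    prev = h0
    for h in hats:
        deltas.append(h - prev)
        prev = h
    resid_proj = np.eye(n) - prev

    def term_stats(gmat: np.ndarray):
        ss = np.array([float((dh * gmat).sum()) for dh in deltas])
        ss_res = float((resid_proj * gmat).sum())
        f = (ss / np.array(dfs)) / (ss_res / resid_df)
        return ss, ss_res, f

    ss, ss_res, f_obs = term_stats(g)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(deltas))
    eps = 1e-12
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, f_perm = term_stats(g[np.ix_(perm, perm)])
        hits += f_perm >= f_obs - eps
    pvals = (hits + 1) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "term": list(pred.columns),
            "ss": ss,
            "df": dfs,
            "pseudo_f": f_obs,
            "r2": ss / total_ss,
            "p": pvals,
        }
    )
    return PermanovaResult(table, ss_res, resid_df, total_ss, n_perm, dropped)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    g = _gower_center(d)
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w)


def _stress1(d_emb: np.ndarray, d_hat: np.ndarray) -> float:
    denom = (d_emb**2).sum()
    if denom == 0:
        return float("inf")
    return float(np.sqrt(((d_emb - d_hat) ** 2).sum() / denom))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-7,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Iterates monotone (isotonic) regression of configuration distances on
    the observed dissimilarity order with Guttman-transform updates. Runs
    a classical-scaling start plus ``n_starts - 1`` random starts and
    keeps the lowest-stress solution. The final configuration is centered
    and rotated to its principal axes with a deterministic sign
    convention, so downstream axis correlations are reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(d)
    delta = _offdiag(d.d)
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    rng = np.random.default_rng(seed)

    def run(x0: np.ndarray):
        x = x0.copy()
        d_emb = pdist(x)
        history = []
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            fit = np.empty_like(d_emb)
            fit[order] = iso.fit_transform(np.arange(order.size), d_emb[order])
            s = _stress1(d_emb, fit)
            history.append(s)
            if prev - s < tol:
                converged = True
                break
            prev = s
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_emb > 0, fit / d_emb, 0.0)
            b = -squareform(ratio, checks=False)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = b @ x / n
            d_emb = pdist(x)
        return x, history[-1], converged, history

    starts = [_classical_mds(d.d, k)]
    scale = delta.max() if delta.size and delta.max() > 0 else 1.0
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(scale=scale, size=(n, k)))

    best = None
    for x0 in starts:
        x, s, conv, hist = run(x0)
        if best is None or s < best[1]:
            best = (x, s, conv, hist)
    x, s, conv, hist = best

    # deterministic orientation: center, principal axes, sign fix
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for col in range(x.shape[1]):
        if x[np.argmax(np.abs(x[:, col])), col] < 0:
            x[:, col] = -x[:, col]
    return NmdsResult(x, s, conv, n_starts, list(d.ids), hist)


def kruskal_dunn(
    values,
    groups,
    min_group_n: int = 5,
    fdr: bool = True,
) -> KruskalDunnResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn pairwise z-tests.

    Groups with fewer than ``min_group_n`` observations are dropped
    before testing. Dunn p-values are two-sided normal tails, reported
    raw with an optional BH-adjusted column alongside.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    level_counts = pd.Series(groups).value_counts()
    eligible = sorted(level_counts.index[level_counts >= min_group_n])
    dropped = sorted(set(level_counts.index) - set(eligible))
    if len(eligible) < 2:
        raise ValueError(
            f"fewer than 2 groups with n >= {min_group_n} (eligible: {eligible})"
        )
    mask = np.isin(groups, eligible)
    v, glab = values[mask], groups[mask]
    samples = [v[glab == lv] for lv in eligible]

    if np.all(v == v[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)

    # Dunn post-hoc on the pooled midranks
    r = rankdata(v)
    big_n = v.size
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (big_n - 1)))
    var_base = big_n * (big_n + 1) / 12 - tie_term
    mean_ranks = {lv: r[glab == lv].mean() for lv in eligible}
    ns = {lv: int((glab == lv).sum()) for lv in eligible}
    rows = []
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            a, b = eligible[i], eligible[j]
            se = np.sqrt(var_base * (1 / ns[a] + 1 / ns[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p_raw": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan})
    dunn = pd.DataFrame(rows)
    if fdr and len(dunn):
        dunn["p_fdr"] = bh_fdr(dunn["p_raw"].to_numpy())
    return KruskalDunnResult(float(h), float(p), eligible, dunn, dropped)
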