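"""Probabilistic pairwise co-occurrence analysis on presence/absence data.

For each taxon pair the joint-occurrence count under random placement
follows a hypergeometric distribution; the two tail probabilities
(P(J <= j_obs) and P(J >= j_obs), both including the observed value)
classify pairs as positive, negative or random associates. Pairs whose
expected co-occurrence is too small are filtered before Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .community import CommunityTable

__all__ = [
    "IncidenceMatrix",
    "CooccurrencePair",
    "CooccurrenceResult",
    "presence_absence",
    "pair_distribution",
    "cooccur_analysis",
    "results_to_frame",
]


@dataclass
class IncidenceMatrix:
    """Binary sample x taxon presence matrix plus the binarization threshold."""

    sample_ids: list
    taxon_ids: list
    presence: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        vals = set(np.unique(self.presence).tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"presence entries must be 0/1, got {sorted(vals)}")
        if self.presence.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("presence shape does not match ids")


@dataclass
class CooccurrencePair:
    taxon_a: str
    taxon_b: str
    N: int
    N1: int
    N2: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float


@dataclass
class CooccurrenceResult:
    pair: CooccurrencePair
    sign: str  # positive | negative | random
    p_raw: float
    p_bonferroni: float
    passed_expected_filter: bool


def presence_absence(table: CommunityTable, threshold: float = 0.01) -> IncidenceMatrix:
    """Binarize a relative-abundance table: present iff abundance > threshold.

    The inequality is strict, so an abundance exactly at the threshold
    counts as absent.
    """
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    presence = (table.values > threshold).astype(np.int8)
    return IncidenceMatrix(table.sample_ids, table.taxon_ids, presence, threshold)


def pair_distribution(N: int, N1: int, N2: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the joint-occurrence count J for two taxa.

    Given N samples with taxon 1 present in N1 and taxon 2 in N2, under
    random placement J is hypergeometric:
    P(J=j) = C(N1, j) C(N-N1, N2-j) / C(N, N2) on
    max(0, N1+N2-N) <= j <= min(N1, N2). Returns (support, probabilities).
    """
    if N < 0 or not (0 <= N1 <= N) or not (0 <= N2 <= N):
        raise ValueError(f"require 0 <= N1, N2 <= N; got N={N}, N1={N1}, N2={N2}")
    lo = max(0, N1 + N2 - N)
    hi = min(N1, N2)
    j = np.arange(lo, hi + 1)
    # hypergeom evaluates in log space internally (rational-safe for large N)
    probs = hypergeom.pmf(j, N, N1, N2)
    return j, probs


def _pair_tails(N: int, N1: int, N2: int, j_obs: int) -> tuple[float, float]:
    dist = hypergeom(N, N1, N2)
    p_lt = float(dist.cdf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))
    return min(p_lt, 1.0), min(p_gt, 1.0)


def cooccur_analysis(
    inc: IncidenceMatrix,
    alpha: float = 0.05,
    min_expected: float = 1.0,
) -> list[CooccurrenceResult]:
    """Classify every taxon pair as positive / negative / random.

    Pairs whose expected joint count ``N1*N2/N`` is <= ``min_expected``
    are excluded before Bonferroni correction (they cannot be informative)
    but still appear in the output with ``passed_expected_filter=False``
    and sign ``random``. The Bonferroni factor m counts only pairs that
    pass the filter. Output is ordered by (taxon_a, taxon_b).
    """
    taxa = list(inc.taxon_ids)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    P = inc.presence.astype(np.int64)  # int8 would overflow in the matmul
    N = len(inc.sample_ids)
    counts = P.sum(axis=0)
    joint = P.T @ P

    order = np.argsort(np.array(taxa, dtype=object))
    raw: list[CooccurrencePair] = []
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            ia, ib = order[ai], order[bi]
            N1, N2 = int(counts[ia]), int(counts[ib])
            j_obs = int(joint[ia, ib])
            p_lt, p_gt = _pair_tails(N, N1, N2, j_obs)
            raw.append(
                CooccurrencePair(
                    taxa[ia], taxa[ib], N, N1, N2, j_obs, N1 * N2 / N, p_lt, p_gt
                )
            )

    m = sum(1 for p in raw if p.expected > min_expected)
    results = []
    for p in raw:
        passed = p.expected > min_expected
        p_raw = min(p.p_lt, p.p_gt)
        p_bonf = min(1.0, m * p_raw) if passed else 1.0
        sign = "random"
        if passed and p_bonf <= alpha:
            sign = "negative" if p.p_lt < p.p_gt else "positive"
        results.append(CooccurrenceResult(p, sign, p_raw, p_bonf, passed))
    return results


def results_to_frame(results: list[CooccurrenceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        p = r.pair
        rows.append(
            {
                "taxon_a": p.taxon_a,
                "taxon_b": p.taxon_b,
                "N": p.N,
                "N1": p.N1,
                "N2": p.N2,
                "j_obs": p.j_obs,
                "expected": p.expected,
                "p_lt": p.p_lt,
                "p_gt": p.p_gt,
                "sign": r.sign,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "passed_expected_filter": r.passed_expected_filter,
            }
        )
    return pd.DataFrame(rows)
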