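"""Serial-transfer competition outcomes and the in-situ/in-vitro concordance test.

CFU counts per pair x replicate x transfer become per-species relative
abundances, persistence calls against a detection limit, per-species
persistence indices, and finally a Monte-Carlo test of whether the
experimentally observed outcomes match the signs of the survey
co-occurrence analysis more often than chance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._stats import spearman

__all__ = [
    "CompetitionDataset",
    "PersistenceCall",
    "ConcordanceReport",
    "pairwise_design",
    "relative_abundances",
    "classify_persistence",
    "persistence_index",
    "growth_persistence_correlation",
    "concordance_test",
]

CO_PERSISTENCE = "co-persistence"
EXCLUSION_A = "exclusion_of_a"
EXCLUSION_B = "exclusion_of_b"
MUTUAL_COLLAPSE = "mutual_collapse"


@dataclass
class CompetitionDataset:
    """Long-format CFU records plus species kingdom annotations.

    ``records`` columns: pair, species_a, species_b, replicate, transfer,
    species, cfu. Every pair x replicate x transfer must carry a CFU
    count for both member species.
    """

    records: pd.DataFrame
    kingdoms: dict[str, str] = field(default_factory=dict)

    REQUIRED = ("pair", "species_a", "species_b", "replicate", "transfer", "species", "cfu")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        if (self.records["cfu"] < 0).any():
            raise ValueError("CFU counts must be non-negative")
        grouped = self.records.groupby(["pair", "replicate", "transfer"])
        for key, grp in grouped:
            members = {grp["species_a"].iloc[0], grp["species_b"].iloc[0]}
            if set(grp["species"]) != members:
                raise ValueError(f"pair x replicate x transfer {key} lacks both species")

    @property
    def transfers(self) -> list[int]:
        return sorted(self.records["transfer"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(set(self.records["species_a"]) | set(self.records["species_b"]))


@dataclass
class PersistenceCall:
    pair: str
    species_a: str
    species_b: str
    mean_fraction_a: float
    mean_fraction_b: float
    persisted_a: bool
    persisted_b: bool
    outcome: str
    transfer: int
    limit: float


@dataclass
class ConcordanceReport:
    pairs: pd.DataFrame  # pair, sign, outcome, match
    n_match: int
    n_tested: int
    mc_p: float
    exact_p: float
    n_draws: int
    seed: int
    pool_positive: int = 8
    pool_total: int = 16


def pairwise_design(kingdoms: dict[str, str]) -> pd.DataFrame:
    """Enumerate all unordered species pairs of a fully factorial design.

    Returns one row per pair with a ``cross_kingdom`` flag (members from
    different kingdoms).
    """
    species = sorted(kingdoms)
    rows = []
    for a, b in itertools.combinations(species, 2):
        rows.append(
            {
                "pair": f"{a}__{b}",
                "species_a": a,
                "species_b": b,
                "cross_kingdom": kingdoms[a] != kingdoms[b],
            }
        )
    return pd.DataFrame(rows)


def relative_abundances(data: CompetitionDataset) -> pd.DataFrame:
    """Within-pair fractions CFU_species / (CFU_a + CFU_b).

    Fractions sum to 1 within each pair x replicate x transfer; a unit
    with both CFUs zero yields NaN fractions and a warning.
    """
    df = data.records.copy()
    totals = df.groupby(["pair", "replicate", "transfer"])["cfu"].transform("sum")
    zero = totals == 0
    if zero.any():
        bad = df.loc[zero, ["pair", "replicate", "transfer"]].drop_duplicates()
        warnings.warn(f"both CFUs zero in {len(bad)} unit(s); fractions undefined:\n{bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["fraction"] = np.where(totals > 0, df["cfu"] / totals.where(totals > 0, 1), np.nan)
    return df[["pair", "species_a", "species_b", "replicate", "transfer", "species", "fraction"]]


def classify_persistence(
    data: CompetitionDataset,
    limit: float = 0.01,
    transfer: int = 6,
) -> list[PersistenceCall]:
    """Call persistence per pair at a focal transfer.

    A species persisted if its mean relative abundance across replicates
    (means of per-replicate fractions, not pooled CFUs) is strictly
    above ``limit``. Co-persistence requires both species to persist.
    """
    fracs = relative_abundances(data)
    fracs = fracs[fracs["transfer"] == transfer]
    if fracs.empty:
        raise ValueError(f"no records at transfer {transfer}")
    calls = []
    for pair, grp in fracs.groupby("pair", sort=True):
        a = grp["species_a"].iloc[0]
        b = grp["species_b"].iloc[0]
        n_reps = grp["replicate"].nunique()
        if n_reps < 1:
            raise ValueError(f"pair {pair} has no replicates at transfer {transfer}")
        mean_a = float(grp.loc[grp["species"] == a, "fraction"].mean())
        mean_b = float(grp.loc[grp["species"] == b, "fraction"].mean())
        pa = mean_a > limit
        pb = mean_b > limit
        if pa and pb:
            outcome = CO_PERSISTENCE
        elif pa:
            outcome = EXCLUSION_B
        elif pb:
            outcome = EXCLUSION_A
        else:
            outcome = MUTUAL_COLLAPSE
        calls.append(PersistenceCall(pair, a, b, mean_a, mean_b, pa, pb, outcome, transfer, limit))
    return calls


def persistence_index(calls: list[PersistenceCall]) -> dict[str, int]:
    """Number of competitions in which each species persisted."""
    index: dict[str, int] = {}
    for call in calls:
        index.setdefault(call.species_a, 0)
        index.setdefault(call.species_b, 0)
        if call.persisted_a:
            index[call.species_a] += 1
        if call.persisted_b:
            index[call.species_b] += 1
    return index


def growth_persistence_correlation(
    growth: dict[str, float],
    index: dict[str, int],
) -> tuple[float, float]:
    """Spearman correlation between solo growth and the persistence index.

    Exact permutation p for up to 9 species, two-sided.
    """
    if set(growth) != set(index):
        only_g = sorted(set(growth) - set(index))
        only_i = sorted(set(index) - set(growth))
        raise ValueError(f"species mismatch; growth-only: {only_g}, index-only: {only_i}")
    species = sorted(growth)
    if len(species) < 4:
        raise ValueError("need at least 4 species")
    g = [growth[s] for s in species]
    ix = [index[s] for s in species]
    return spearman(g, ix)


def _match(sign: str, outcome: str) -> bool:
    # positive sign predicts co-persistence; negative predicts that at
    # least one member is excluded (either direction).
    if sign == "positive":
        return outcome == CO_PERSISTENCE
    if sign == "negative":
        return outcome in (EXCLUSION_A, EXCLUSION_B, MUTUAL_COLLAPSE)
    raise ValueError(f"sign must be positive/negative, got {sign!r}")


def concordance_test(
    signs: dict[str, str],
    outcomes: dict[str, str] | list[PersistenceCall],
    n_draws: int = 10_000,
    seed: int = 0,
    pool: tuple[int, int] = (8, 16),
    replace: bool = True,
) -> ConcordanceReport:
    """Monte-Carlo concordance of co-occurrence signs with competition outcomes.

    Each tested pair has a significant co-occurrence sign and an
    experimental outcome; ``n_match`` counts pairs where the sign
    predicted the outcome. The null draws random sign vectors from a
    pool with ``pool = (n_positive, n_total)`` (default 8 of 16, i.e.
    P(+) = 0.5), with replacement by default; ``mc_p`` is the fraction of
    draws achieving >= n_match matches. The closed-form binomial tail at
    match probability 1/2 is reported alongside as ``exact_p``.
    """
    if isinstance(outcomes, list):
        outcomes = {c.pair: c.outcome for c in outcomes}
    missing_o = sorted(set(signs) - set(outcomes))
    if missing_o:
        raise ValueError(f"pairs lacking an experimental outcome: {missing_o}")

    pairs = sorted(signs)
    matches = np.array([_match(signs[p], outcomes[p]) for p in pairs])
    n_tested = len(pairs)
    n_match = int(matches.sum())

    pool_pos, pool_total = pool
    if not (0 <= pool_pos <= pool_total) or pool_total <= 0:
        raise ValueError(f"invalid sign pool {pool}")
    pool_signs = np.array([1] * pool_pos + [0] * (pool_total - pool_pos))
    target = np.array([outcomes[p] == CO_PERSISTENCE for p in pairs]).astype(int)

    rng = np.random.default_rng(seed)
    if replace:
        draws = rng.choice(pool_signs, size=(n_draws, n_tested), replace=True)
    else:
        if n_tested > pool_total:
            raise ValueError("cannot draw without replacement: pool smaller than tested set")
        draws = np.empty((n_draws, n_tested), dtype=int)
        for i in range(n_draws):
            draws[i] = rng.permutation(pool_signs)[:n_tested]
    # a drawn positive sign matches iff the outcome is co-persistence
    match_counts = (draws == target[None, :]).sum(axis=1)
    mc_p = float(np.mean(match_counts >= n_match))

    exact_p = float(binom.sf(n_match - 1, n_tested, 0.5))

    table = pd.DataFrame(
        {
            "pair": pairs,
            "sign": [signs[p] for p in pairs],
            "outcome": [outcomes[p] for p in pairs],
            "match": matches,
        }
    )
    return ConcordanceReport(
        table, n_match, n_tested, mc_p, exact_p, n_draws, seed, pool_pos, pool_total
    )
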