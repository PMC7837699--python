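import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starterscope.competition import (
    CO_PERSISTENCE,
    EXCLUSION_A,
    EXCLUSION_B,
    CompetitionDataset,
    classify_persistence,
    concordance_test,
    growth_persistence_correlation,
    pairwise_design,
    persistence_index,
    relative_abundances,
)
from starterscope.synthetic_data import (
    example_competition_design,
    generate_competitions,
)


def simple_dataset(frac_a=0.6, n_reps=3, transfer=6):
    rows = []
    for rep in range(1, n_reps + 1):
        rows.append({"pair": "p1", "species_a": "A", "species_b": "B",
                     "replicate": rep, "transfer": transfer, "species": "A",
                     "cfu": 1000 * frac_a})
        rows.append({"pair": "p1", "species_a": "A", "species_b": "B",
                     "replicate": rep, "transfer": transfer, "species": "B",
                     "cfu": 1000 * (1 - frac_a)})
    return CompetitionDataset(pd.DataFrame(rows))


class TestRelativeAbundances:
    def test_even_split(self):
        data = simple_dataset(0.5)
        fr = relative_abundances(data)
        assert set(fr["fraction"].round(9)) == {0.5}

    def test_ninety_nine_to_one(self):
        fr = relative_abundances(simple_dataset(0.99))
        a = fr[fr["species"] == "A"]["fraction"].iloc[0]
        assert a == pytest.approx(0.99)

    def test_fractions_sum_to_one(self, rng):
        rows = []
        for pair in ["x", "y"]:
            for rep in [1, 2]:
                ca, cb = rng.integers(1, 1000, 2)
                for sp, c in (("A", ca), ("B", cb)):
                    rows.append({"pair": pair, "species_a": "A", "species_b": "B",
                                 "replicate": rep, "transfer": 6,
                                 "species": sp, "cfu": float(c)})
        fr = relative_abundances(CompetitionDataset(pd.DataFrame(rows)))
        sums = fr.groupby(["pair", "replicate"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_both_zero_flagged(self):
        df = simple_dataset().records.copy()
        df["cfu"] = 0.0
        with pytest.warns(UserWarning, match="both CFUs zero"):
            fr = relative_abundances(CompetitionDataset(df))
        assert fr["fraction"].isna().all()


class TestClassifyPersistence:
    def test_co_persistence(self):
        calls = classify_persistence(simple_dataset(0.6))
        assert calls[0].outcome == CO_PERSISTENCE

    def test_minor_species_excluded(self):
        calls = classify_persistence(simple_dataset(0.995))
        assert calls[0].outcome == EXCLUSION_B
        assert not calls[0].persisted_b

    def test_boundary_is_strict(self):
        rows = []
        for rep in (1, 2):
            rows.append({"pair": "p1", "species_a": "A", "species_b": "B",
                         "replicate": rep, "transfer": 6, "species": "A",
                         "cfu": 990.0})
            rows.append({"pair": "p1", "species_a": "A", "species_b": "B",
                         "replicate": rep, "transfer": 6, "species": "B",
                         "cfu": 10.0})
        calls = classify_persistence(CompetitionDataset(pd.DataFrame(rows)), limit=0.01)
        # species B sits exactly at 1%: not persisted (strict inequality)
        assert calls[0].mean_fraction_b == pytest.approx(0.01)
        assert not calls[0].persisted_b
        assert calls[0].outcome == EXCLUSION_B

    def test_replicate_order_invariance(self):
        data = simple_dataset(0.7, n_reps=4)
        shuffled = CompetitionDataset(
            data.records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        c1 = classify_persistence(data)
        c2 = classify_persistence(shuffled)
        assert c1[0].outcome == c2[0].outcome
        assert c1[0].mean_fraction_a == pytest.approx(c2[0].mean_fraction_a)

    def test_missing_transfer_errors(self):
        with pytest.raises(ValueError, match="transfer 3"):
            classify_persistence(simple_dataset(transfer=6), transfer=3)


class TestPairwiseDesign:
    def test_eight_species_design_counts(self):
        kingdoms, _, _ = example_competition_design()
        design = pairwise_design(kingdoms)
        assert len(design) == 28
        assert int(design["cross_kingdom"].sum()) == 16
        assert int((~design["cross_kingdom"]).sum()) == 12

    def test_each_species_in_seven_pairs(self):
        kingdoms, _, _ = example_competition_design()
        design = pairwise_design(kingdoms)
        counts = design["species_a"].value_counts().add(
            design["species_b"].value_counts(), fill_value=0
        )
        assert set(counts) == {7.0}


class TestPersistenceIndex:
    def test_full_persistence_index_seven(self):
        kingdoms, winners, _ = example_competition_design()
        winners = {p: CO_PERSISTENCE for p in winners}
        data = generate_competitions(winners, kingdoms)
        index = persistence_index(classify_persistence(data))
        assert set(index.values()) == {7}

    def test_order_invariance(self):
        kingdoms, winners, _ = example_competition_design()
        data = generate_competitions(winners, kingdoms)
        calls = classify_persistence(data)
        assert persistence_index(calls) == persistence_index(calls[::-1])


class TestGrowthPersistenceCorrelation:
    def test_concordant_ranks(self):
        growth = {f"s{i}": float(i) for i in range(8)}
        index = {f"s{i}": i for i in range(8)}
        rho, p = growth_persistence_correlation(growth, index)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(8) * 1, abs=1e-6)

    def test_exact_p_matches_enumeration(self, rng):
        growth = {f"s{i}": float(v) for i, v in enumerate(rng.random(5))}
        index = {f"s{i}": int(v) for i, v in enumerate(rng.integers(0, 7, 5))}
        rho, p = growth_persistence_correlation(growth, index)
        species = sorted(growth)
        rx = stats.rankdata([growth[s] for s in species])
        ry = stats.rankdata([index[s] for s in species])
        obs = np.corrcoef(rx, ry)[0, 1]
        hits = 0
        perms = list(itertools.permutations(ry))
        for perm in perms:
            hits += abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12
        assert p == pytest.approx(hits / len(perms), abs=1e-12)

    def test_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            growth_persistence_correlation({"a": 1.0}, {"b": 2})

    def test_recovery_of_planted_correlation(self):
        # ranks generated with agreement tuned near rho ~ 0.8
        rhos = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=8)
            noisy = base + rng.normal(0, 0.55, 8)
            growth = {f"s{i}": float(b) for i, b in enumerate(base)}
            index = {f"s{i}": int(r) for i, r in enumerate(stats.rankdata(noisy))}
            rhos.append(growth_persistence_correlation(growth, index)[0])
        assert abs(np.median(rhos) - 0.8) < 0.15


class TestConcordance:
    def test_exact_binomial_seven_of_eight(self):
        signs = {f"p{i}": "positive" for i in range(7)} | {"p7": "negative"}
        outcomes = {f"p{i}": CO_PERSISTENCE for i in range(7)} | {"p7": CO_PERSISTENCE}
        rep = concordance_test(signs, outcomes, n_draws=10_000, seed=1)
        assert rep.n_match == 7
        assert rep.exact_p == pytest.approx(9 / 256)
        assert rep.mc_p < 0.05

    def test_significant_at_005(self):
        _, winners, signs = example_competition_design()
        kingdoms = example_competition_design()[0]
        data = generate_competitions(winners, kingdoms)
        calls = classify_persistence(data)
        rep = concordance_test(signs, calls, n_draws=10_000, seed=0)
        assert rep.n_match == 7 and rep.n_tested == 8
        assert rep.mc_p < 0.05

    def test_zero_matches_p_near_one(self):
        signs = {f"p{i}": "positive" for i in range(8)}
        outcomes = {f"p{i}": EXCLUSION_A for i in range(8)}
        rep = concordance_test(signs, outcomes, n_draws=5000, seed=2)
        assert rep.n_match == 0
        assert rep.mc_p == pytest.approx(1.0)

    def test_mc_converges_to_exact(self):
        signs = {f"p{i}": "positive" for i in range(7)} | {"p7": "negative"}
        outcomes = {f"p{i}": CO_PERSISTENCE for i in range(7)} | {"p7": CO_PERSISTENCE}
        rep = concordance_test(signs, outcomes, n_draws=100_000, seed=3)
        assert abs(rep.mc_p - rep.exact_p) < 0.005

    def test_missing_outcome_errors(self):
        with pytest.raises(ValueError, match="lacking an experimental outcome"):
            concordance_test({"p0": "positive"}, {})

    def test_without_replacement_supported(self):
        # all-co-persistence outcomes: 8 matches need all 8 drawn signs
        # positive, probability C(8,8)/C(16,8) = 1/12870 per draw
        signs = {f"p{i}": "positive" for i in range(8)}
        outcomes = {f"p{i}": CO_PERSISTENCE for i in range(8)}
        rep = concordance_test(signs, outcomes, n_draws=20_000, seed=4, replace=False)
        assert rep.n_match == 8
        assert rep.mc_p <= 0.01


class TestGeneratedRoundTrip:
    def test_noiseless_outcomes_match_prescription(self):
        kingdoms, winners, _ = example_competition_design()
        data = generate_competitions(winners, kingdoms, dispersion=None)
        calls = classify_persistence(data)
        observed = {c.pair: c.outcome for c in calls}
        assert observed == winners

    def test_noisy_outcomes_still_match(self):
        kingdoms, winners, _ = example_competition_design()
        data = generate_competitions(winners, kingdoms, dispersion=50.0, seed=11)
        calls = classify_persistence(data)
        observed = {c.pair: c.outcome for c in calls}
        assert observed == winners

    def test_conflicting_prescription_errors(self):
        kingdoms, winners, _ = example_competition_design()
        with pytest.raises(ValueError, match="detection limit"):
            generate_competitions(winners, kingdoms, co_fractions=(0.995, 0.005))
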