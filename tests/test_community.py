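import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from starterscope.community import (
    CommunityTable,
    DistanceMatrix,
    bray_curtis,
    combine_kingdoms,
    hierarchical_cluster,
    rarefy,
    to_relative_abundance,
)

from conftest import make_table


class TestCommunityTable:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_table([[1.0, -0.1]])

    def test_relative_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            make_table([[0.5, 0.4]], relative=True)

    def test_missing_annotation_rejected(self):
        ann = pd.DataFrame({"kingdom": ["bacteria"], "group": ["LAB"]}, index=["t0"])
        with pytest.raises(ValueError, match="lacking annotations"):
            make_table([[1.0, 2.0]], annotations=ann)

    def test_unknown_group_rejected(self):
        ann = pd.DataFrame({"kingdom": ["bacteria"], "group": ["mold"]}, index=["t0"])
        with pytest.raises(ValueError, match="unknown groups"):
            make_table([[1.0]], annotations=ann)

    def test_group_fraction(self, small_relative_table):
        frac = small_relative_table.group_fraction("AAB")
        assert frac.tolist() == [0.3, 0.7, 0.5]


class TestRarefy:
    def test_depth_equals_row_total_is_identity(self):
        t = make_table([[3, 4, 5]])
        out = rarefy(t, 12, seed=0)
        assert out.data.iloc[0].tolist() == [3, 4, 5]

    def test_single_taxon_sample(self):
        t = make_table([[10, 0]])
        out = rarefy(t, 5, seed=0)
        assert out.data.iloc[0].tolist() == [5, 0]

    def test_rows_sum_to_depth(self, rng):
        t = make_table(rng.integers(0, 50, size=(6, 5)) + 1)
        out = rarefy(t, 20, seed=3)
        assert (out.data.sum(axis=1) == 20).all()

    def test_shallow_samples_dropped_with_warning(self):
        t = make_table([[100, 100], [2, 1]])
        with pytest.warns(UserWarning, match="below depth"):
            out = rarefy(t, 50, seed=0)
        assert out.sample_ids == ["s0"]

    def test_non_integer_input_names_cell(self):
        t = make_table([[1.5, 2.0]])
        with pytest.raises(ValueError, match=r"s0.*t0|t0.*s0"):
            rarefy(t, 1, seed=0)

    def test_reproducible_given_seed(self, rng):
        t = make_table(rng.integers(1, 30, size=(4, 6)))
        a = rarefy(t, 15, seed=42).data
        b = rarefy(t, 15, seed=42).data
        pd.testing.assert_frame_equal(a, b)

    def test_expected_proportion_preserved(self):
        # taxon proportion after rarefaction is unbiased: check the mean
        # over 1000 draws against the source proportion within 3 MC SEs
        t = make_table([[30, 70]])
        depth = 40
        props = []
        for seed in range(1000):
            out = rarefy(t, depth, seed=seed)
            props.append(out.data.iloc[0, 0] / depth)
        props = np.array(props)
        se = props.std(ddof=1) / np.sqrt(len(props))
        assert abs(props.mean() - 0.3) <= 3 * se + 1e-12


class TestRelativeAbundance:
    def test_simple(self):
        out = to_relative_abundance(make_table([[2, 2]]))
        assert out.data.iloc[0].tolist() == [0.5, 0.5]

    def test_preserves_zeros(self):
        out = to_relative_abundance(make_table([[1260, 0, 0]]))
        assert out.data.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_idempotent(self, rng):
        vals = rng.random((5, 4))
        once = to_relative_abundance(make_table(vals))
        twice = to_relative_abundance(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_all_zero_row_errors(self):
        with pytest.raises(ValueError, match="s1"):
            to_relative_abundance(make_table([[1, 2], [0, 0]]))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(make_table([[0.5, 0.5], [0.5, 0.5]], relative=True))
        assert d.d[0, 1] == 0

    def test_disjoint_supports_one(self):
        d = bray_curtis(make_table([[1, 0], [0, 1]]))
        assert d.d[0, 1] == 1

    def test_hand_computed_value(self):
        d = bray_curtis(make_table([[0.7, 0.3], [0.3, 0.7]], relative=True))
        assert d.d[0, 1] == pytest.approx(0.4)

    def test_two_zero_rows_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(make_table([[0, 0], [0, 0], [1, 1]]))

    def test_min_identity_on_relative_rows(self, rng):
        # BC == 1 - 2*sum(min)/sum(x+y) algebraically
        vals = rng.dirichlet(np.ones(5), size=6)
        d = bray_curtis(make_table(vals, relative=True))
        for i in range(6):
            for j in range(6):
                mins = np.minimum(vals[i], vals[j]).sum()
                expected = 1 - 2 * mins / (vals[i] + vals[j]).sum()
                assert d.d[i, j] == pytest.approx(expected)

    def test_range_and_symmetry(self, rng):
        d = bray_curtis(make_table(rng.random((8, 4))))
        assert (d.d >= 0).all() and (d.d <= 1).all()
        np.testing.assert_allclose(d.d, d.d.T)


class TestCombineKingdoms:
    @staticmethod
    def _pair(bvals, fvals):
        bact = make_table(
            bvals,
            taxa=[f"b{j}" for j in range(np.shape(bvals)[1])],
            annotations=pd.DataFrame(
                {"kingdom": "bacteria", "group": "LAB"},
                index=[f"b{j}" for j in range(np.shape(bvals)[1])],
            ),
        )
        fung = make_table(
            fvals,
            taxa=[f"f{j}" for j in range(np.shape(fvals)[1])],
            annotations=pd.DataFrame(
                {"kingdom": "fungi", "group": "yeast"},
                index=[f"f{j}" for j in range(np.shape(fvals)[1])],
            ),
        )
        return bact, fung

    def test_equal_weights_example(self):
        bact, fung = self._pair([[1, 0]], [[1]])
        out = combine_kingdoms(bact, fung)
        assert out.data.iloc[0].tolist() == [0.5, 0.0, 0.5]

    def test_degenerate_weight_keeps_bacteria_only(self):
        bact, fung = self._pair([[2, 2]], [[1]])
        out = combine_kingdoms(bact, fung, weights=(1.0, 0.0))
        assert out.data.iloc[0].tolist() == [0.5, 0.5]

    def test_rows_sum_to_one_random_blocks(self, rng):
        bact, fung = self._pair(rng.random((5, 3)) + 0.1, rng.random((5, 2)) + 0.1)
        out = combine_kingdoms(bact, fung)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0)

    def test_sample_mismatch_errors(self):
        bact, fung = self._pair([[1, 0], [1, 1]], [[1]])
        with pytest.raises(ValueError, match="sample sets differ"):
            combine_kingdoms(bact, fung)

    def test_nonyeast_fungi_excluded(self):
        bact, fung = self._pair([[1, 1]], [[1, 1]])
        fung.annotations.loc["f1", "group"] = "other"
        out = combine_kingdoms(bact, fung)
        assert "f1" not in out.taxon_ids
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0)

    def test_column_order_invariance_of_braycurtis(self, rng):
        bact, fung = self._pair(rng.random((4, 3)) + 0.1, rng.random((4, 2)) + 0.1)
        d1 = bray_curtis(combine_kingdoms(bact, fung))
        shuffled = CommunityTable(
            bact.data[["b2", "b0", "b1"]], bact.annotations, bact.relative
        )
        d2 = bray_curtis(combine_kingdoms(shuffled, fung))
        np.testing.assert_allclose(d1.d, d2.d)


class TestHierarchicalCluster:
    def test_two_samples_merge_at_distance(self):
        d = DistanceMatrix(["a", "b"], [[0, 3.0], [3.0, 0]])
        dend = hierarchical_cluster(d)
        assert dend.merges == [(0, 1)]
        assert dend.heights[0] == pytest.approx(3.0)

    def test_equidistant_tie_broken_by_lowest_pair(self):
        d = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        dend = hierarchical_cluster(d)
        assert dend.merges[0] == (0, 1)

    def test_matches_scipy_ward_on_random_matrices(self, rng):
        # scipy's nearest-neighbor-chain ward is the independent oracle
        for _ in range(5):
            pts = rng.random((10, 3))
            cond = squareform(
                np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)), checks=False
            )
            ours = hierarchical_cluster(
                DistanceMatrix(list(range(10)), squareform(cond))
            )
            theirs = linkage(cond, method="ward")
            np.testing.assert_allclose(sorted(ours.heights), sorted(theirs[:, 2]),
                                       rtol=1e-8)

    def test_heights_nondecreasing(self, rng):
        pts = rng.random((12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dend = hierarchical_cluster(DistanceMatrix(list(range(12)), d))
        assert all(a <= b + 1e-12 for a, b in zip(dend.heights, dend.heights[1:]))

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(DistanceMatrix(["a"], [[0.0]]))
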