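import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_lance_williams
from echinodiv.cluster import cut_dendrogram, cut_dendrogram_k
from echinodiv.errors import ValidationError
from echinodiv.io import TRAIT_COLUMNS, TraitTable
from echinodiv.traits import (
    assign_levels,
    cluster_profiles,
    cv_percent,
    diversity_table,
    level_frequencies,
    shannon_index,
    standardize,
    summarize_trait,
    ward_cluster,
)


class TestSummarize:
    def test_hand_computed_pair(self):
        row = summarize_trait([1.0, 3.0])
        assert row["Mean"] == pytest.approx(2.0)
        assert row["S"] == pytest.approx(np.sqrt(2), rel=1e-9)  # n-1 SD
        assert row["CV"] == pytest.approx(100 * np.sqrt(2) / 2, rel=1e-9)

    def test_constant_vector(self):
        row = summarize_trait([5.0, 5.0, 5.0])
        assert row["S"] == 0 and row["CV"] == 0 and row["Range"] == 0

    def test_published_plant_height_cv(self):
        # plant height: printed mean 64.62 cm, SD 16.34 -> CV 25.29%
        assert cv_percent(64.62, 16.34) == pytest.approx(25.29, abs=0.005)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            summarize_trait([1.0])


class TestLevels:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (5.0, 1),     # below X - 2s
            (5.999, 1),
            (6.0, 2),     # lower edge of level 2
            (10.0, 6),    # edges at 6,7,...,14: 10 falls in [10, 11)
            (13.999, 9),
            (14.0, 10),   # >= X + 2s
            (14.1, 10),
            (50.0, 10),
        ],
    )
    def test_bin_edges(self, value, expected):
        assert assign_levels([value], mean=10.0, sd=2.0)[0] == expected

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValidationError, match="sd"):
            assign_levels([1.0], mean=1.0, sd=0.0)


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon_index([0.1] * 10) == pytest.approx(np.log(10), rel=1e-12)

    def test_single_level_zero(self):
        assert shannon_index([1.0] + [0.0] * 9) == 0.0

    def test_invariant_under_permutation(self):
        p = np.array([0.5, 0.2, 0.2, 0.1, 0, 0, 0, 0, 0, 0])
        rng = np.random.default_rng(3)
        assert shannon_index(p) == pytest.approx(
            shannon_index(rng.permutation(p)), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [[0.5, 0.4], [-0.1, 1.1]])
    def test_invalid_frequencies(self, bad):
        with pytest.raises(ValidationError):
            shannon_index(bad)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10).map(
            lambda xs: np.array(xs) / np.sum(xs)
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds(self, p):
        h = shannon_index(p)
        assert -1e-12 <= h <= np.log(10) + 1e-12


class TestDiversityTable:
    def test_frequencies_sum_to_one(self, small_trait_table):
        summary, dist = diversity_table(small_trait_table)
        np.testing.assert_allclose(dist.frequencies.sum(axis=1), 1.0, atol=1e-12)
        assert ((dist.levels >= 1) & (dist.levels <= 10)).all().all()

    def test_two_populations_half_frequencies(self):
        data = pd.DataFrame(
            [[1, 1, 1, 1, 1, 1, 0.4, 1, 1], [2, 2, 2, 2, 2, 2, 0.6, 2, 2]],
            columns=TRAIT_COLUMNS, index=["A", "B"],
        )
        _, dist = diversity_table(TraitTable(data.astype(float)))
        assert set(np.unique(dist.frequencies.to_numpy())) <= {0.0, 0.5}

    def test_h_matches_histogram_oracle(self):
        # independent recomputation: explicit histogram over the bin edges
        rng = np.random.default_rng(42)
        v = rng.normal(50, 5, size=1000)
        mean, sd = v.mean(), v.std(ddof=1)
        edges = [-np.inf] + [mean - 2 * sd + k * 0.5 * sd for k in range(9)] + [np.inf]
        counts, _ = np.histogram(v, bins=edges)
        p = counts / counts.sum()
        h_oracle = -(p[p > 0] * np.log(p[p > 0])).sum()
        h = shannon_index(level_frequencies(assign_levels(v, mean, sd)))
        assert h == pytest.approx(h_oracle, abs=0.1)

    def test_relabeling_invariance(self, small_trait_table):
        summary, _ = diversity_table(small_trait_table)
        shuffled = TraitTable(
            small_trait_table.data.sample(frac=1, random_state=5)
        )
        summary2, _ = diversity_table(shuffled)
        pd.testing.assert_frame_equal(summary, summary2)


class TestStandardize:
    def test_zero_mean_unit_sd(self, small_trait_table):
        z = standardize(small_trait_table)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_hand_z_scores(self):
        data = pd.DataFrame(
            {c: [1.0, 2.0, 3.0] for c in TRAIT_COLUMNS}, index=list("abc")
        )
        data["M7"] = [0.2, 0.4, 0.6]
        z = standardize(TraitTable(data))
        np.testing.assert_allclose(z["M1"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_column_rejected(self, small_trait_table):
        t = small_trait_table
        t.data["M3"] = 7.0
        with pytest.raises(ValidationError, match="M3"):
            standardize(TraitTable(t.data))


class TestWard:
    def test_duplicate_rows_merge_at_zero(self):
        z = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=list("abc"))
        d = ward_cluster(z)
        assert d.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_line_points_first_merge(self):
        # points at 0, 1, 10: Ward joins {0, 1} first
        z = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        d = ward_cluster(z)
        assert sorted(d.merges[0, :2].astype(int).tolist()) == [0, 1]
        # Ward merge cost of {0},{1} on squared distances is 1.0
        assert d.heights[0] == pytest.approx(1.0)

    def test_two_blobs_recovered_at_mid_cut(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=(5, 3))
        b = rng.normal(10, 1, size=(5, 3))
        z = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(10)])
        d = ward_cluster(z)
        cut = cut_dendrogram(d, float(np.mean([d.heights[-2], d.heights[-1]])))
        assert cut.n_clusters == 2
        assert len(set(cut.labels[:5])) == 1 and len(set(cut.labels[5:])) == 1

    def test_heights_non_decreasing_and_nan_rejected(self, small_trait_table):
        z = standardize(small_trait_table)
        d = ward_cluster(z)
        assert (np.diff(d.heights) >= -1e-9).all()
        z.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            ward_cluster(z)

    def test_matches_naive_lance_williams(self):
        # exhaustive oracle at small n: Ward heights from the LW recurrence
        rng = np.random.default_rng(19)
        for n in (4, 6, 8):
            x = rng.normal(size=(n, 3))
            d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
            expected = naive_lance_williams(d2, "ward")
            got = sorted(ward_cluster(pd.DataFrame(x)).heights.tolist())
            np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_spss_rescaling_monotone(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table), rescale_spss=True)
        assert d.heights.max() == pytest.approx(25.0)
        assert (np.diff(d.heights) >= -1e-9).all()


class TestCut:
    def test_threshold_zero_singletons(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table))
        assert cut_dendrogram(d, 0.0).n_clusters == d.n_leaves

    def test_above_root_single_cluster(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table))
        assert cut_dendrogram(d, d.heights[-1] * 1.01).n_clusters == 1

    def test_monotone_in_threshold(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table))
        ks = [
            cut_dendrogram(d, t).n_clusters
            for t in np.linspace(0, d.heights[-1] * 1.1, 25)
        ]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_partition_covers_everything(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table))
        cut = cut_dendrogram(d, float(np.median(d.heights)))
        assert len(cut.labels) == d.n_leaves
        assert set(cut.labels) == set(range(1, cut.n_clusters + 1))

    def test_cut_k_exact(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table))
        for k in range(1, d.n_leaves + 1):
            assert cut_dendrogram_k(d, k).n_clusters == k


class TestProfiles:
    def test_single_cluster_equals_global_means(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table))
        cut = cut_dendrogram(d, d.heights[-1] * 1.01)
        prof = cluster_profiles(cut, small_trait_table)
        np.testing.assert_allclose(
            prof.loc[1, TRAIT_COLUMNS], small_trait_table.data.mean(), rtol=1e-12
        )

    def test_singletons_equal_rows(self, small_trait_table):
        d = ward_cluster(standardize(small_trait_table))
        cut = cut_dendrogram(d, 0.0)
        prof = cluster_profiles(cut, small_trait_table)
        for pop, label in zip(cut.ids, cut.labels):
            np.testing.assert_allclose(
                prof.loc[label, TRAIT_COLUMNS],
                small_trait_table.data.loc[pop],
                rtol=1e-12,
            )

    def test_recovers_group_means(self, study):
        truth = study.truth.groups
        cut = cut_dendrogram_k(
            ward_cluster(standardize(study.trait_table)), 5
        )
        prof = cluster_profiles(cut, study.trait_table)
        assert (prof["n"].sum()) == 46
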