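import itertools
import math

import numpy as np
import pytest
from scipy import stats

from phageome.data_io import CountMatrix
from phageome.ecology_stats import (
    DistanceMatrix,
    chao1,
    group_test,
    pcoa,
    permanova,
    recruitment_rate,
    relative_abundance,
    shannon,
    spearman_distance,
    within_between_distances,
)
from phageome.synthetic_data import CommunitySpec, generate_community


def matrix_from_counts(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        sample_ids=[f"s{i}" for i in range(counts.shape[0])],
        feature_ids=[f"f{j}" for j in range(counts.shape[1])],
        counts=counts,
        feature_lengths=np.full(counts.shape[1], 1000),
    )


def dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(sample_ids=ids, values=values)


class TestRelativeAbundance:
    def test_proportions(self):
        props = relative_abundance(matrix_from_counts([[10, 30, 60]]))
        np.testing.assert_allclose(props, [[0.1, 0.3, 0.6]])

    def test_rows_sum_to_one(self, rng):
        counts = rng.integers(0, 100, (5, 20)) + 1
        props = relative_abundance(matrix_from_counts(counts))
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named(self):
        with pytest.raises(ValueError, match="s1"):
            relative_abundance(matrix_from_counts([[1, 2], [0, 0]]))


class TestAlphaDiversity:
    def test_shannon_uniform_is_log_richness(self):
        assert shannon(np.full(4, 0.25)) == pytest.approx(math.log(4))

    def test_shannon_single_feature_is_zero(self):
        assert shannon(np.array([1.0])) == 0.0

    def test_shannon_hand_arithmetic(self):
        h = shannon(np.array([0.5, 0.25, 0.25]))
        assert h == pytest.approx(0.5 * math.log(2) + 0.5 * math.log(4))
        assert h == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_base_option(self):
        assert shannon(np.full(4, 0.25), base=2) == pytest.approx(2.0)

    def test_shannon_rejects_negatives(self):
        with pytest.raises(ValueError):
            shannon(np.array([1.2, -0.2]))

    def test_chao1_formula(self):
        counts = [3] * 4 + [1] * 4 + [2] * 2  # S_obs=10, F1=4, F2=2
        assert chao1(np.array(counts)) == pytest.approx(14.0)

    def test_chao1_no_singletons_equals_observed(self):
        assert chao1(np.array([5, 3, 2, 7])) == 4.0

    def test_chao1_bias_corrected_branch(self):
        counts = [4] * 7 + [1] * 3  # S_obs=10, F1=3, F2=0
        assert chao1(np.array(counts)) == pytest.approx(13.0)

    def test_chao1_rejects_non_integer(self):
        with pytest.raises(ValueError):
            chao1(np.array([1.5, 2.0]))


class TestSpearmanDistance:
    def test_identical_profiles_distance_zero(self):
        d = spearman_distance(np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]]))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_distance_two(self):
        d = spearman_distance(np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        data = rng.uniform(size=(6, 10))
        d = spearman_distance(data)
        for i in range(6):
            for j in range(6):
                ri = stats.rankdata(data[i])
                rj = stats.rankdata(data[j])
                rho = np.corrcoef(ri, rj)[0, 1]
                expected = 0.0 if i == j else 1 - rho
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        data = rng.uniform(size=(4, 15))
        d1 = spearman_distance(data)
        d2 = spearman_distance(np.exp(3 * data))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_constant_profile_named_in_error(self):
        with pytest.raises(ValueError, match="s1"):
            spearman_distance(np.array([[1.0, 2, 3], [5.0, 5, 5]]))

    def test_range_and_symmetry(self, rng):
        d = spearman_distance(rng.uniform(size=(8, 12)))
        assert (d.values >= -1e-12).all() and (d.values <= 2 + 1e-12).all()
        np.testing.assert_allclose(d.values, d.values.T, atol=1e-15)


class TestPcoa:
    def test_three_equidistant_samples(self):
        d = dm([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        res = pcoa(d)
        assert res.coordinates.shape[1] == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)
        assert abs(res.eigenvalues[2]) < 1e-12

    def test_points_on_line_recover_distances(self):
        x = np.array([0.0, 1.0, 3.5, 7.0])
        d = dm(np.abs(x[:, None] - x[None, :]))
        res = pcoa(d)
        assert res.coordinates.shape[1] == 1
        rec = np.abs(res.coordinates[:, 0][:, None] - res.coordinates[:, 0][None, :])
        np.testing.assert_allclose(rec, d.values, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        d = dm([[0, 0, 1], [0, 0, 1], [1, 1, 0]])
        res = pcoa(d)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_euclidean_reconstruction_property(self, rng):
        points = rng.normal(size=(7, 3))
        diff = points[:, None, :] - points[None, :, :]
        d = dm(np.sqrt((diff**2).sum(-1)) * (1 - np.eye(7)))
        res = pcoa(d)
        coords = res.coordinates
        rec = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(rec, d.values, atol=1e-9)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        data = rng.uniform(size=(6, 12))
        d = spearman_distance(data)
        res = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=list(d.sample_ids))
        )
        ref_eigs = np.sort(ref.eigvals.to_numpy())[::-1]
        np.testing.assert_allclose(
            res.eigenvalues[:4], ref_eigs[:4], atol=1e-8
        )


def anderson_one_way_f(d, labels):
    """Independent one-way pseudo-F via Anderson's group sum-of-squares
    formula (no hat matrices): SS_total = sum d^2 / n over all pairs,
    SS_within = per-group pairwise d^2 / group size."""
    n = len(labels)
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(set(labels))
    return (ss_among / (a - 1)) / (ss_within / (n - a)), ss_among / ss_total


class TestPermanova:
    def test_perfect_separation_r_squared_one(self):
        values = np.ones((4, 4)) - np.eye(4)
        values[0, 1] = values[1, 0] = 0.0
        values[2, 3] = values[3, 2] = 0.0
        d = dm(values)
        res = permanova(d, {"group": ["a", "a", "b", "b"]}, n_permutations=0)
        assert res.r_squared("group") == pytest.approx(1.0)

    def test_matches_anderson_formula(self, rng):
        data = rng.uniform(size=(9, 15))
        d = spearman_distance(data)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(d, {"group": labels}, n_permutations=0)
        f_ref, r2_ref = anderson_one_way_f(d.values, labels)
        assert res.factors[0].pseudo_f == pytest.approx(f_ref, rel=1e-10)
        assert res.r_squared("group") == pytest.approx(r2_ref, rel=1e-10)

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        """n=6, one 2-level factor: exact p equals brute-force enumeration of
        all label permutations through an independent F computation."""
        data = rng.uniform(size=(6, 10))
        d = spearman_distance(data)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, {"group": labels}, n_permutations="exact")
        f_obs, _ = anderson_one_way_f(d.values, labels)
        assert res.factors[0].pseudo_f == pytest.approx(f_obs, rel=1e-10)
        count = total = 0
        for perm in itertools.permutations(range(6)):
            shuffled = [labels[i] for i in perm]
            f_perm, _ = anderson_one_way_f(d.values, shuffled)
            if f_perm >= f_obs - 1e-12:
                count += 1
            total += 1
        assert res.factors[0].p_value == pytest.approx(count / total, abs=1e-12)

    def test_sequential_r_squared_sums_to_one(self, rng):
        spec = CommunitySpec(n_donors=3, samples_per_donor=4, n_features=40,
                             reads_per_sample=5000, seed=5)
        matrix, _, truth = generate_community(spec)
        d = spearman_distance(matrix)
        res = permanova(
            d,
            {"donor": truth.donor_of_sample, "treatment": truth.treatment_of_sample},
            n_permutations=0,
        )
        total = sum(f.r_squared for f in res.factors) + res.residual_r_squared
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_skbio_one_way(self, rng):
        skbio = pytest.importorskip("skbio")
        data = rng.uniform(size=(8, 12))
        d = spearman_distance(data)
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(d, {"group": labels}, n_permutations=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, ids=list(d.sample_ids)),
            grouping=labels, permutations=0,
        )
        assert res.factors[0].pseudo_f == pytest.approx(
            float(ref["test statistic"]), rel=1e-9
        )

    def test_p_reproducible_from_seed_and_r2_invariant(self, rng):
        data = rng.uniform(size=(10, 12))
        d = spearman_distance(data)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permanova(d, {"g": labels}, n_permutations=199, seed=11)
        r2 = permanova(d, {"g": labels}, n_permutations=199, seed=11)
        r3 = permanova(d, {"g": labels}, n_permutations=499, seed=4)
        assert r1.factors[0].p_value == r2.factors[0].p_value
        assert r1.r_squared("g") == r3.r_squared("g")

    def test_confounded_factor_is_error(self):
        d = dm(1 - np.eye(3))
        with pytest.raises(ValueError, match="confounded"):
            permanova(d, {"id": ["a", "b", "c"]}, n_permutations=0)

    def test_donor_structure_dominates_treatment(self):
        """Parameter recovery: donor R^2 exceeds treatment R^2 under the
        default donor-dominant generative conditions (20 seeded replicates
        here; the full 100-replicate check runs in the acceptance suite)."""
        wins = 0
        for seed in range(20):
            spec = CommunitySpec(seed=seed)
            matrix, _, truth = generate_community(spec)
            d = spearman_distance(matrix)
            res = permanova(
                d,
                {"donor": truth.donor_of_sample,
                 "treatment": truth.treatment_of_sample},
                n_permutations=0,
            )
            if res.r_squared("donor") > res.r_squared("treatment"):
                wins += 1
        assert wins >= 19


def mann_whitney_exact_oracle(x, y):
    """Exhaustive two-sided rank-sum enumeration for tiny samples."""
    pooled = np.concatenate([x, y])
    n_x = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    u_obs = min(u_obs, n_x * len(y) - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        u = ranks[list(combo)].sum() - n_x * (n_x + 1) / 2
        u = min(u, n_x * len(y) - u)
        if u <= u_obs + 1e-12:
            count += 1
        total += 1
    return count / total


class TestWithinBetween:
    def make_distance(self, values, subjects):
        ids = [f"s{i}" for i in range(len(subjects))]
        return dm(values, ids), {f"s{i}": s for i, s in enumerate(subjects)}

    def test_extreme_separation_minimal_p(self, rng):
        # two subjects, two samples each: within 0, between 1
        values = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        ) - np.diag([0.0] * 4)
        np.fill_diagonal(values, 0)
        d, grouping = self.make_distance(values, ["a", "a", "b", "b"])
        res = within_between_distances(d, grouping)
        assert set(res.within) == {0.0} and set(res.between) == {1.0}
        assert res.p_value < 0.1  # smallest attainable with 2 vs 4 values

    def test_exchangeable_sets_p_near_one(self, rng):
        data = rng.uniform(size=(6, 30))
        d = spearman_distance(data)
        grouping = {s: g for s, g in zip(d.sample_ids, ["a", "a", "a", "b", "b", "b"])}
        res = within_between_distances(d, grouping)
        assert res.p_value > 0.2  # no real structure

    def test_matches_exhaustive_rank_sum_oracle(self, rng):
        data = rng.uniform(size=(5, 20))
        d = spearman_distance(data)
        grouping = {s: g for s, g in zip(d.sample_ids, ["a", "a", "a", "b", "b"])}
        res = within_between_distances(d, grouping)
        oracle_p = mann_whitney_exact_oracle(res.within, res.between)
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_no_within_pairs_is_error(self):
        d = dm(1 - np.eye(3))
        with pytest.raises(ValueError, match="within"):
            within_between_distances(d, {"s0": "a", "s1": "b", "s2": "c"})


class TestRecruitmentRate:
    def test_pooled_arithmetic(self):
        per_sample, pooled = recruitment_rate([10_000], [4_966])
        assert pooled == pytest.approx(0.4966)
        assert per_sample[0] == pytest.approx(0.4966)

    def test_zero_recruited(self):
        _, pooled = recruitment_rate([100, 200], [0, 0])
        assert pooled == 0.0

    def test_pooled_is_count_weighted_mean(self, rng):
        totals = rng.integers(1000, 50_000, 6)
        recruited = (totals * rng.uniform(0.2, 0.8, 6)).astype(int)
        per_sample, pooled = recruitment_rate(totals, recruited)
        assert pooled == pytest.approx(np.average(per_sample, weights=totals))

    def test_recruited_above_total_is_error(self):
        with pytest.raises(ValueError):
            recruitment_rate([100], [101])


class TestGroupTest:
    def test_two_groups_delegate_to_mann_whitney(self, rng):
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(0, 1, 8)])
        groups = ["a"] * 8 + ["b"] * 8
        res = group_test(values, groups)
        assert res.test == "mann-whitney"
        ref = stats.mannwhitneyu(values[:8], values[8:], alternative="two-sided")
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_shifted_group_detected(self, rng):
        values = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(8, 1, 10)]
        )
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = group_test(values, groups)
        assert res.test == "kruskal-wallis"
        assert res.p_value < 0.01

    def test_all_equal_is_flagged_degenerate(self):
        res = group_test([1.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            group_test([1.0, 2.0], ["a", "a"])

    def test_null_calibration_uniform_p(self, rng):
        """Permuted labels on exchangeable data give uniform p-values."""
        pvals = []
        for _ in range(300):
            values = rng.normal(size=15)
            groups = rng.permutation(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
            pvals.append(group_test(values, groups).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
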