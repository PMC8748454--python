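import itertools
import math

import numpy as np
import pytest
from scipy import stats

from tfap.robustness import (
    KSResult,
    ProfileSet,
    build_tf_feature_vectors,
    knn_label_purity,
    ks_two_sample,
    max_feasible_perplexity,
    randomize_profiles,
    robustness_report,
    same_drug_distances,
    tsne_embed,
)


def ks_d_oracle(a, b):
    """sup |ECDF difference| evaluated at every sample point."""
    pts = sorted(set(a) | set(b))
    best = 0.0
    for x in pts:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


def perm_p_oracle(a, b):
    """Exact permutation p by full enumeration of group splits."""
    pooled = list(a) + list(b)
    d_obs = ks_d_oracle(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(a)):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        count += ks_d_oracle(ga, gb) >= d_obs - 1e-12
        total += 1
    return count / total


class TestProfileSet:
    def test_labels_must_be_unique_pairs(self):
        with pytest.raises(ValueError, match="duplicate"):
            ProfileSet(
                features=np.zeros((2, 3)),
                labels=[("d", "cl"), ("d", "cl")],
                space="expression",
            )

    def test_tf_feature_vectors_shape_and_feature_flag(self):
        vals = {
            ("d1", "c1"): {"A": 1, "B": 0},
            ("d1", "c2"): {"A": -1, "B": 2},  # 2 = excluded
            ("d2", "c1"): {"A": 0, "B": 1},
        }
        ps_state = build_tf_feature_vectors(vals, feature="state")
        assert ps_state.features.shape == (3, 2)
        # excluded maps to 0 in state features
        row = ps_state.features[ps_state.labels.index(("d1", "c2"))]
        assert list(row) == [-1.0, 0.0]
        ranks = {k: {"A": 1.5, "B": 3.0} for k in vals}
        ps_rank = build_tf_feature_vectors(ranks, feature="rank")
        assert ps_rank.features.shape == (3, 2)
        assert list(ps_rank.features[0]) == [-1.5, -3.0]

    def test_misaligned_tf_axis_errors(self):
        with pytest.raises(ValueError, match="TF axis"):
            build_tf_feature_vectors(
                {("d1", "c1"): {"A": 1}, ("d2", "c1"): {"B": 1}}
            )


class TestDistances:
    def test_identical_points_distance_zero(self):
        emb = np.zeros((2, 2))
        d = same_drug_distances(emb, [("d", "c1"), ("d", "c2")])
        assert list(d) == [0.0]

    def test_three_four_five_triangle(self):
        emb = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = same_drug_distances(emb, [("d", "c1"), ("d", "c2")])
        assert list(d) == [5.0]

    def test_pair_count_combinatorics(self):
        # 4 drugs x 3 cell lines -> 4 * C(3,2) = 12 cross-line pairs
        labels = [
            (f"d{i}", f"c{j}") for i in range(4) for j in range(3)
        ]
        emb = np.random.default_rng(0).normal(size=(12, 2))
        d = same_drug_distances(emb, labels)
        assert len(d) == 12

    def test_same_cell_line_pairs_not_counted(self):
        labels = [("d", "c1"), ("d", "c1.b"), ("e", "c1")]
        # replicate-style duplicate cell line labels differ -> counted;
        # but a drug present only once has no pair
        emb = np.zeros((3, 2))
        assert len(same_drug_distances(emb, labels)) == 1

    def test_no_shared_drug_errors(self):
        with pytest.raises(ValueError, match="no drug"):
            same_drug_distances(
                np.zeros((2, 2)), [("d1", "c1"), ("d2", "c2")]
            )

    def test_normalized_distances_scale_free(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(8, 2))
        labels = [(f"d{i % 4}", f"c{i // 4}") for i in range(8)]
        d1 = same_drug_distances(emb, labels, normalize=True)
        d2 = same_drug_distances(emb * 37.0, labels, normalize=True)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(10, 2))
        labels = [(f"d{i % 5}", f"c{i // 5}") for i in range(10)]
        theta = 1.234
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = emb @ rot.T + np.array([11.0, -3.0])
        np.testing.assert_allclose(
            same_drug_distances(emb, labels),
            same_drug_distances(moved, labels),
            atol=1e-9,
        )


class TestRandomize:
    def test_single_feature_profiles_unchanged(self):
        ps = ProfileSet(
            features=np.array([[1.0], [2.0]]),
            labels=[("d", "c1"), ("d", "c2")],
            space="expression",
        )
        out = randomize_profiles(ps, seed=3)
        np.testing.assert_array_equal(out.features, ps.features)

    def test_per_profile_multiset_preserved(self):
        rng = np.random.default_rng(4)
        ps = ProfileSet(
            features=rng.normal(size=(5, 20)),
            labels=[(f"d{i}", "c") for i in range(5)],
            space="expression",
        )
        out = randomize_profiles(ps, seed=9)
        np.testing.assert_allclose(
            np.sort(out.features, axis=1), np.sort(ps.features, axis=1)
        )
        assert out.labels == ps.labels

    def test_seed_determinism(self):
        ps = ProfileSet(
            features=np.arange(30.0).reshape(3, 10),
            labels=[(f"d{i}", "c") for i in range(3)],
            space="expression",
        )
        a = randomize_profiles(ps, seed=5).features
        b = randomize_profiles(ps, seed=5).features
        np.testing.assert_array_equal(a, b)


class TestKS:
    def test_identical_multisets_d_zero(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert r.D == 0.0

    def test_interleaved_example(self):
        r = ks_two_sample([0.0, 1.0], [0.5, 1.5])
        assert r.D == pytest.approx(0.5)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=40), rng.normal(0.5, 1, size=25)
        r = ks_two_sample(a, b, method="asymp")
        ref = stats.ks_2samp(a, b, method="asymp")
        assert r.D == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_permutation_p_matches_full_enumeration_3v3(self):
        a, b = [0.1, 0.9, 1.7], [0.5, 1.1, 2.3]
        r = ks_two_sample(a, b, method="permutation")
        assert r.D == pytest.approx(ks_d_oracle(a, b))
        assert r.p == pytest.approx(perm_p_oracle(a, b))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


@pytest.fixture(scope="module")
def clusters():
    rng = np.random.default_rng(8)
    centers = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
    feats, labels = [], []
    for c, center in enumerate(centers):
        for i in range(8):
            feats.append(center + rng.normal(0, 0.01, 3))
            labels.append((f"d{i}", f"cluster{c}"))
    return ProfileSet(np.array(feats), labels, "expression")


class TestTSNE:

    def test_output_shape_and_determinism(self, clusters):
        e1 = tsne_embed(clusters, seed=13)
        e2 = tsne_embed(clusters, seed=13)
        assert e1.shape == (24, 2)
        np.testing.assert_array_equal(e1, e2)

    def test_well_separated_clusters_stay_pure(self, clusters):
        emb = tsne_embed(clusters, seed=13)
        purity = knn_label_purity(emb, [l[1] for l in clusters.labels], k=3)
        assert purity >= 0.9

    def test_infeasible_perplexity_suggests_limit(self, clusters):
        with pytest.raises(ValueError, match="must be <"):
            tsne_embed(clusters, perplexity=10.0, seed=0)
        assert max_feasible_perplexity(24) == pytest.approx(23 / 3)

    def test_too_few_profiles(self):
        ps = ProfileSet(np.zeros((3, 2)), [("d", "a"), ("d", "b"), ("e", "a")], "expression")
        with pytest.raises(ValueError, match="at least 4"):
            tsne_embed(ps, seed=0)


class TestReport:
    def test_identical_inputs_identical_paired_results(self):
        rng = np.random.default_rng(10)
        feats = rng.normal(size=(12, 6))
        labels = [(f"d{i % 6}", f"c{i // 6}") for i in range(12)]
        a = ProfileSet(feats, labels, "expression")
        b = ProfileSet(feats.copy(), list(labels), "tf_activation")
        rep = robustness_report(a, b, seed=21)
        assert rep["expression"]["ks"].D == rep["tf_activation"]["ks"].D
        np.testing.assert_allclose(
            rep["expression"]["observed"], rep["tf_activation"]["observed"]
        )

    def test_label_mismatch_lists_difference(self):
        a = ProfileSet(np.zeros((2, 2)), [("d1", "c1"), ("d1", "c2")], "expression")
        b = ProfileSet(np.zeros((2, 2)), [("d2", "c1"), ("d2", "c2")], "tf_activation")
        with pytest.raises(ValueError, match="d2"):
            robustness_report(a, b, seed=0)

    def test_seed_recorded_in_report(self):
        rng = np.random.default_rng(12)
        feats = rng.normal(size=(8, 5))
        labels = [(f"d{i % 4}", f"c{i // 4}") for i in range(8)]
        a = ProfileSet(feats, labels, "expression")
        b = ProfileSet(feats * 2, list(labels), "tf_activation")
        rep = robustness_report(a, b, seed=33)
        assert rep["seed"] == 33
        assert rep["expression"]["seed"] == 33


def test_permutation_ks_p_uniform_on_independent_null_samples():
    """On independent same-distribution samples the permutation p is uniform."""
    rng = np.random.default_rng(99)
    n_rep, alpha, hits = 200, 0.05, 0
    for rep in range(n_rep):
        a, b = rng.normal(size=12), rng.normal(size=12)
        res = ks_two_sample(
            a, b, method="permutation", seed=rep, n_permutations=199, max_exact=0
        )
        hits += res.p < alpha
    lo = stats.binom.ppf(0.005, n_rep, alpha)
    hi = stats.binom.ppf(0.995, n_rep, alpha)
    assert lo <= hits <= hi


def test_pipeline_null_comparison_controls_type_one_error():
    """Observed data that are themselves randomized reject at most at alpha.

    The within-profile randomization preserves each profile's value
    multiset, so a null "observed" sample and its re-randomization are
    positively dependent: the comparison is valid but conservative.  The
    check is therefore one-sided — no excess rejections.
    """
    rng = np.random.default_rng(7)
    n_rep, alpha, hits = 200, 0.05, 0
    for rep in range(n_rep):
        feats = rng.normal(size=(24, 15))
        labels = [(f"d{i % 12}", f"c{i // 12}") for i in range(24)]
        null_obs = randomize_profiles(
            ProfileSet(feats, labels, "expression"), seed=1000 + rep
        )
        rerand = randomize_profiles(null_obs, seed=5000 + rep)
        d1 = same_drug_distances(null_obs.features, labels)
        d2 = same_drug_distances(rerand.features, labels)
        res = ks_two_sample(
            d1, d2, method="permutation", seed=rep, n_permutations=199, max_exact=0
        )
        hits += res.p < alpha
    assert hits <= stats.binom.ppf(0.995, n_rep, alpha)
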