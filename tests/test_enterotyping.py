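import numpy as np
import pandas as pd
import pytest

from conftest import (
    brute_force_medoids,
    euclidean_distance_matrix,
    partitions_agree,
)
from enteronet.enterotypes import (
    DistanceMatrix,
    calinski_harabasz,
    driver_taxa,
    jensen_shannon_distance,
    jsd_matrix,
    pam_cluster,
    pcoa,
    select_enterotypes,
)
from enteronet.io_tables import AbundanceTable
from enteronet.simulate import SimConfig, generate_cohort


def dm_from_points(points):
    d = euclidean_distance_matrix(np.asarray(points, dtype=float))
    return DistanceMatrix([f"s{i}" for i in range(len(points))], d)


def random_simplex(rng, n, k):
    x = rng.dirichlet(np.ones(k), size=n)
    return x


class TestJensenShannon:
    def test_identical_distributions_are_zero(self):
        p = [0.2, 0.3, 0.5]
        assert jensen_shannon_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_sqrt_ln2(self):
        d = jensen_shannon_distance([1.0, 0.0], [0.0, 1.0], pseudocount=0.0)
        assert d == pytest.approx(np.sqrt(np.log(2)), abs=1e-12)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for p, q in zip(random_simplex(rng, 20, 6), random_simplex(rng, 20, 6)):
            assert jensen_shannon_distance(p, q) == pytest.approx(
                jensen_shannon_distance(q, p), abs=1e-12
            )

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        pts = random_simplex(rng, 300, 5)
        for a, b, c in pts.reshape(100, 3, 5):
            dab = jensen_shannon_distance(a, b)
            dbc = jensen_shannon_distance(b, c)
            dac = jensen_shannon_distance(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_length_mismatch_and_negatives_rejected(self):
        with pytest.raises(ValueError):
            jensen_shannon_distance([1.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            jensen_shannon_distance([1.5, -0.5], [0.5, 0.5])

    def test_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(2)
        rows = random_simplex(rng, 3, 4)
        table = AbundanceTable(
            pd.DataFrame(rows, index=["a", "b", "c"], columns=list("wxyz"))
        )
        pc = 1e-6
        D = jsd_matrix(table, pseudocount=pc)
        for i in range(3):
            for j in range(3):
                expected = jensen_shannon_distance(rows[i], rows[j], pc)
                assert D.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_identical_samples_at_zero_distance(self):
        rows = np.tile([0.25, 0.25, 0.5], (2, 1))
        table = AbundanceTable(pd.DataFrame(rows, index=["a", "b"], columns=list("xyz")))
        assert jsd_matrix(table).values[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestPam:
    def test_perfectly_separated_pairs(self):
        d = np.zeros((4, 4))
        d[np.ix_([0, 1], [2, 3])] = 10.0
        d[np.ix_([2, 3], [0, 1])] = 10.0
        D = DistanceMatrix(list("abcd"), d)
        assignment, medoids = pam_cluster(D, 2)
        assert partitions_agree(assignment.values, [0, 0, 1, 1])
        cost = sum(
            D.values[i, D.ids.index(medoids[c])]
            for i, c in enumerate(assignment.values)
        )
        assert cost == pytest.approx(0.0)

    def test_matches_exhaustive_search_on_clustered_instances(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(2, 4))
            n = int(rng.integers(k + 2, 9))
            centers = rng.uniform(-10, 10, size=(k, 2))
            pts = centers[rng.integers(0, k, n)] + rng.normal(size=(n, 2))
            D = dm_from_points(pts)
            assignment, medoids = pam_cluster(D, k)
            cost_opt, meds_opt = brute_force_medoids(D.values, k)
            med_idx = [D.ids.index(m) for m in medoids]
            cost_pam = D.values[:, med_idx].min(axis=1).sum()
            assert cost_pam == pytest.approx(cost_opt, abs=1e-9)

    def test_never_better_than_exhaustive_and_locally_optimal(self):
        # uniform instances may trap PAM on a swap plateau; it must still be
        # a valid single-swap local optimum and never beat the true optimum
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, k = 8, 3
            D = dm_from_points(rng.normal(size=(n, 2)))
            assignment, medoids = pam_cluster(D, k)
            med_idx = sorted(D.ids.index(m) for m in medoids)
            cost_pam = D.values[:, med_idx].min(axis=1).sum()
            cost_opt, _ = brute_force_medoids(D.values, k)
            assert cost_pam >= cost_opt - 1e-9
            for m in med_idx:
                for h in set(range(n)) - set(med_idx):
                    trial = sorted(set(med_idx) - {m} | {h})
                    cost_trial = D.values[:, trial].min(axis=1).sum()
                    assert cost_trial >= cost_pam - 1e-9

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal(0, 1, (5, 2)), rng.normal(8, 1, (5, 2))]
        )
        D = dm_from_points(pts)
        a1, _ = pam_cluster(D, 2)
        perm = rng.permutation(10)
        D2 = DistanceMatrix(
            [D.ids[i] for i in perm], D.values[np.ix_(perm, perm)]
        )
        a2, _ = pam_cluster(D2, 2)
        aligned = a2.loc[D.ids]
        assert partitions_agree(a1.values, aligned.values)

    def test_k_out_of_range(self):
        D = dm_from_points([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            pam_cluster(D, 1)
        with pytest.raises(ValueError):
            pam_cluster(D, 3)


class TestCalinskiHarabasz:
    def test_hand_computed_four_points(self):
        # line positions 0,1,10,11; clusters {0,1},{2,3}
        # medoids 0 and 2 (lowest-index ties), overall medoid 1:
        # W = 1+1 = 2, B = 2*d(0,1)^2 + 2*d(2,1)^2 = 2 + 162 = 164
        # CH = (164/1)/(2/2) = 164
        D = dm_from_points([[0.0], [1.0], [10.0], [11.0]])
        assert calinski_harabasz(D, [0, 0, 1, 1]) == pytest.approx(164.0)

    def test_prefers_true_k_on_separated_clusters(self):
        rng = np.random.default_rng(4)
        pts = np.vstack(
            [rng.normal(0, 0.1, (6, 2)), rng.normal(10, 0.1, (6, 2))]
        )
        D = dm_from_points(pts)
        a2, _ = pam_cluster(D, 2)
        a3, _ = pam_cluster(D, 3)
        assert calinski_harabasz(D, a2) > calinski_harabasz(D, a3)

    def test_equidistant_simplex_finite_and_symmetric(self):
        d = np.ones((4, 4)) - np.eye(4)
        D = DistanceMatrix(list("abcd"), d)
        ch1 = calinski_harabasz(D, [0, 0, 1, 1])
        ch2 = calinski_harabasz(D, [1, 1, 0, 0])
        assert np.isfinite(ch1) and ch1 == pytest.approx(ch2)

    def test_zero_within_dispersion_returns_infinity(self):
        D = dm_from_points([[0.0], [0.0], [5.0], [5.0]])
        assert calinski_harabasz(D, [0, 0, 1, 1]) == np.inf


class TestSelectEnterotypes:
    def test_recovers_planted_two_enterotypes(self):
        from sklearn.metrics import adjusted_rand_score

        ab, _, truth = generate_cohort(SimConfig(seed=42))
        res = select_enterotypes(ab)
        assert res.k_selected == 2
        ari = adjusted_rand_score(truth.enterotype_label.values, res.assignment.values)
        assert ari >= 0.9
        assert sorted(res.cluster_sizes.values()) == [43, 91]

    def test_single_cluster_data_reports_full_curve(self):
        ab, _, _ = generate_cohort(SimConfig(n_samples=40, driver_effect=1.0, seed=9))
        res = select_enterotypes(ab, k_range=range(2, 6))
        assert sorted(res.ch_scores) == [2, 3, 4, 5]
        assert np.isfinite(list(res.ch_scores.values())).all()

    def test_forced_k_range_of_two(self):
        ab, _, _ = generate_cohort(SimConfig(n_samples=30, seed=10))
        res = select_enterotypes(ab, k_range=[2])
        assert res.k_selected == 2
        D = jsd_matrix(ab, pseudocount=1e-6)
        direct, _ = pam_cluster(D, 2)
        assert (res.assignment == direct).all()

    def test_taxon_order_invariance(self):
        ab, _, _ = generate_cohort(SimConfig(n_samples=40, seed=12))
        res1 = select_enterotypes(ab, k_range=[2, 3])
        shuffled = AbundanceTable(
            ab.data[list(reversed(ab.taxon_ids))], rank=ab.rank
        )
        res2 = select_enterotypes(shuffled, k_range=[2, 3])
        assert res1.k_selected == res2.k_selected
        assert partitions_agree(res1.assignment.values, res2.assignment.values)


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        positions = np.array([0.0, 1.0, 2.0, 4.0])
        D = dm_from_points(positions[:, None])
        res = pcoa(D, n_axes=3)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(axis1)
        expected = np.diff(positions - positions.mean())
        assert np.allclose(np.abs(gaps), np.abs(expected), atol=1e-8)
        assert res.eigenvalues[1:] == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_distances_give_zero_coordinates(self):
        D = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        res = pcoa(D, n_axes=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_distances_reconstructed_from_full_rank_coordinates(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 3))
        D = dm_from_points(pts)
        res = pcoa(D, n_axes=6)
        coords = res.coordinates.to_numpy()
        rebuilt = euclidean_distance_matrix(coords)
        assert np.allclose(rebuilt, D.values, atol=1e-8)

    def test_matches_skbio_on_euclidean_input(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 3))
        D = dm_from_points(pts)
        ours = pcoa(D, n_axes=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, ids=D.ids), number_of_dimensions=3
        )
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()),
            atol=1e-6,
        )

    def test_eigenvalues_non_increasing_and_proportions_bounded(self):
        rng = np.random.default_rng(7)
        D = dm_from_points(rng.normal(size=(10, 4)))
        res = pcoa(D, n_axes=5)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9


class TestDriverTaxa:
    def test_hand_ranking_two_taxa(self):
        rows = np.array([[0.8, 0.2], [0.8, 0.2], [0.3, 0.7], [0.3, 0.7]])
        table = AbundanceTable(
            pd.DataFrame(rows, index=list("abcd"), columns=["t1", "t2"])
        )
        out = driver_taxa(table, [0, 0, 1, 1], top_n=2)
        assert out[0].index[0] == "t1"
        assert out[0].loc["t1", "difference"] == pytest.approx(0.5)
        assert out[1].index[0] == "t2"

    def test_planted_drivers_top_ranked(self):
        hits = 0
        for seed in range(10):
            ab, _, truth = generate_cohort(SimConfig(seed=seed))
            ranked = driver_taxa(ab, truth.enterotype_label, top_n=1)
            ok = all(
                ranked[c].index[0] in truth.driver_taxa[c] for c in truth.driver_taxa
            )
            hits += ok
        assert hits >= 9

    def test_identical_clusters_have_vanishing_differences(self):
        rows = np.tile([0.25, 0.25, 0.5], (6, 1))
        table = AbundanceTable(
            pd.DataFrame(rows, index=[f"s{i}" for i in range(6)], columns=list("xyz"))
        )
        out = driver_taxa(table, [0, 0, 0, 1, 1, 1], top_n=3)
        for df in out.values():
            assert np.allclose(df["difference"], 0.0)
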