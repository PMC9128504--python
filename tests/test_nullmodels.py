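import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from phylonull.io import patristic_distances
from phylonull.nullmodels import (NullPool, beta_mntd, beta_mpd,
                                  beta_nti_matrix, bray_curtis,
                                  bray_curtis_matrix, build_pools,
                                  discretize_counts, mntd, mpd,
                                  raup_crick_bray, ses_metric, ses_pool,
                                  taxa_shuffle)
from phylonull.simulate import simulate_tree

from .oracles import (beta_mntd_naive, beta_nti_naive, mntd_naive, mpd_naive,
                      nonempty_subsets, ses_naive)


class TestMPD:
    def test_single_pair_both_weightings(self, balanced_dist):
        a = [1, 1, 0, 0]
        assert mpd(a, balanced_dist, weighted=False) == 2.0
        assert mpd(a, balanced_dist, weighted=True) == 2.0

    def test_balanced_tree_unweighted(self, balanced_dist):
        # brute force over 6 pairs: (2+2+4+4+4+4)/6
        assert mpd([1, 1, 1, 1], balanced_dist,
                   weighted=False) == pytest.approx(10 / 3)

    def test_absent_taxa_ignored(self, balanced_dist):
        assert mpd([1, 1, 0, 0], balanced_dist) == 2.0

    def test_fewer_than_two_taxa_undefined(self, balanced_dist):
        assert math.isnan(mpd([0, 5, 0, 0], balanced_dist))


class TestMNTD:
    def test_balanced_tree_each_tip_has_sister_at_two(self, balanced_dist):
        assert mntd([1, 1, 1, 1], balanced_dist, weighted=False) == 2.0

    def test_two_taxa(self, balanced_dist):
        assert mntd([1, 0, 0, 1], balanced_dist) == 4.0

    def test_weighted_identical_minima(self, balanced_dist):
        assert mntd([3, 1, 0, 0], balanced_dist, weighted=True) == 2.0


class TestBetaMNTD:
    def test_identical_samples_zero(self, balanced_dist):
        assert beta_mntd([1, 2, 0, 3], [1, 2, 0, 3], balanced_dist) == 0.0

    def test_disjoint_clades(self, balanced_dist):
        assert beta_mntd([1, 1, 0, 0], [0, 0, 1, 1], balanced_dist) == 4.0

    def test_nested_samples(self, balanced_dist):
        # a={A}, b={A,B}: directional means 0 and mean(0, 2) -> 0.5
        assert beta_mntd([1, 0, 0, 0], [1, 1, 0, 0], balanced_dist,
                         weighted=False) == 0.5

    def test_beta_mpd_cross_pairs(self, balanced_dist):
        assert beta_mpd([1, 1, 0, 0], [0, 0, 1, 1], balanced_dist) == 4.0


@pytest.mark.parametrize("weighted", [False, True])
def test_alpha_beta_metrics_match_bruteforce_on_subsets(weighted, rng):
    """mpd/mntd/beta_mntd equal exhaustive loops on all nonempty subsets
    of random small trees (abundances drawn randomly per subset)."""
    for t in range(5):
        n = int(rng.integers(3, 7))
        tree = simulate_tree(n, seed=rng)
        dist = patristic_distances(tree)
        D = dist.data.tolist()
        subsets = list(nonempty_subsets(n))
        abunds = [[x * float(rng.integers(1, 9)) for x in s] for s in subsets]
        for a in abunds:
            assert mpd(a, dist, weighted) == pytest.approx(
                mpd_naive(a, D, weighted), abs=1e-12, nan_ok=True)
            assert mntd(a, dist, weighted) == pytest.approx(
                mntd_naive(a, D, weighted), abs=1e-12, nan_ok=True)
        pair_idx = rng.integers(0, len(abunds), size=(40, 2))
        for i, j in pair_idx:
            assert beta_mntd(abunds[i], abunds[j], dist, weighted) == \
                pytest.approx(beta_mntd_naive(abunds[i], abunds[j], D,
                                              weighted), abs=1e-12)


class TestTaxaShuffle:
    def test_distance_multiset_preserved(self, balanced_dist, rng):
        shuffled = taxa_shuffle(balanced_dist, rng)
        assert sorted(shuffled.data.ravel()) == \
            sorted(balanced_dist.data.ravel())
        assert shuffled.taxa == balanced_dist.taxa

    def test_star_tree_invariant(self, rng):
        # equal-distance star: every shuffle yields the same matrix
        from phylonull.io import PatristicMatrix
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        star = PatristicMatrix(("a", "b", "c", "d"), d)
        assert np.array_equal(taxa_shuffle(star, rng).data, star.data)


class TestSES:
    def test_star_tree_degenerate_null(self, rng):
        from phylonull.io import PatristicMatrix
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        star = PatristicMatrix(("a", "b", "c", "d"), d)
        with pytest.warns(UserWarning, match="degenerate"):
            res = ses_metric([1, 1, 0, 0], star, metric="mpd", n_iter=19,
                             rng=rng)
        assert math.isnan(res.ses) and math.isnan(res.index)
        assert res.observed == 2.0

    def test_index_negates_ses(self, balanced_dist, rng):
        res = ses_metric([3, 1, 1, 0], balanced_dist, metric="mntd",
                         n_iter=99, rng=rng)
        assert res.index == -res.ses

    @pytest.mark.parametrize("metric", ["mpd", "mntd"])
    def test_matches_naive_shuffled_matrix_loop(self, metric):
        """Same seed, same permutation stream: fast path equals the
        literal shuffled-matrix re-implementation to 1e-12."""
        tree = simulate_tree(5, seed=np.random.default_rng(55))
        dist = patristic_distances(tree)
        a = [3.0, 0.0, 1.0, 2.0, 1.0]
        res = ses_metric(a, dist, metric=metric, n_iter=99,
                         rng=np.random.default_rng(123))
        obs, mean, sd, ses = ses_naive(a, dist.data.tolist(), metric, True,
                                       99, np.random.default_rng(123))
        assert res.observed == pytest.approx(obs, abs=1e-12)
        assert res.null_mean == pytest.approx(mean, abs=1e-12)
        assert res.null_sd == pytest.approx(sd, abs=1e-12)
        assert res.ses == pytest.approx(ses, abs=1e-12)

    def test_pool_shares_permutation_stream(self, balanced_dist):
        table = pd.DataFrame([[1, 1, 0, 1], [0, 2, 1, 1]],
                             index=["x", "y"], columns=balanced_dist.taxa)
        out1 = ses_pool(table, balanced_dist, metric="mntd", n_iter=49,
                        rng=np.random.default_rng(7))
        out2 = ses_pool(table, balanced_dist, metric="mntd", n_iter=49,
                        rng=np.random.default_rng(7))
        pd.testing.assert_frame_equal(out1, out2)


class TestBetaNTI:
    @pytest.fixture
    def pool(self):
        tree = simulate_tree(12, seed=np.random.default_rng(3))
        dist = patristic_distances(tree)
        rng = np.random.default_rng(4)
        A = rng.integers(0, 6, size=(4, 12)).astype(float)
        A[A.sum(axis=1) == 0, 0] = 1.0
        table = pd.DataFrame(A, index=[f"s{i}" for i in range(4)],
                             columns=dist.taxa)
        return table, dist

    def test_matches_naive_oracle(self, pool):
        table, dist = pool
        _, bnti = beta_nti_matrix(table, dist, n_iter=49,
                                  rng=np.random.default_rng(11))
        _, expected = beta_nti_naive(table.to_numpy().tolist(),
                                     dist.data.tolist(), 49,
                                     np.random.default_rng(11))
        np.testing.assert_allclose(bnti.to_numpy(), expected, atol=1e-12)

    def test_symmetric_with_nan_diagonal(self, pool):
        table, dist = pool
        _, bnti = beta_nti_matrix(table, dist, n_iter=49,
                                  rng=np.random.default_rng(1))
        m = bnti.to_numpy()
        assert np.isnan(np.diag(m)).all()
        np.testing.assert_array_equal(m, m.T)

    def test_same_seed_bitwise_identical(self, pool):
        table, dist = pool
        runs = [beta_nti_matrix(table, dist, n_iter=99,
                                rng=np.random.default_rng(42))[1]
                for _ in range(2)]
        assert runs[0].equals(runs[1])

    def test_identical_samples_degenerate(self, balanced_dist):
        table = pd.DataFrame([[1, 2, 3, 4]] * 3, index=["a", "b", "c"],
                             columns=balanced_dist.taxa, dtype=float)
        with pytest.warns(UserWarning, match="degenerate"):
            obs, bnti = beta_nti_matrix(table, balanced_dist, n_iter=19,
                                        rng=np.random.default_rng(0))
        assert (obs.to_numpy() == 0).all()
        assert np.isnan(bnti.to_numpy()[np.triu_indices(3, 1)]).all()


class TestBrayCurtis:
    @pytest.mark.parametrize("a, b, expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 1, 0], [0, 0, 2], 1.0),
        ([2, 2, 0], [0, 2, 2], 0.5),
    ])
    def test_examples(self, a, b, expected):
        assert bray_curtis(a, b) == pytest.approx(expected)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            a = rng.integers(0, 20, size=8).astype(float)
            b = rng.integers(0, 20, size=8).astype(float)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert bray_curtis(a, b) == pytest.approx(
                scipy_braycurtis(a, b), abs=1e-12)

    def test_common_rescaling_invariance(self, rng):
        a = rng.integers(0, 9, size=6).astype(float) + 1
        b = rng.integers(0, 9, size=6).astype(float) + 1
        assert bray_curtis(3.7 * a, 3.7 * b) == pytest.approx(
            bray_curtis(a, b))

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_shape_and_symmetry(self, toy_table):
        m = bray_curtis_matrix(toy_table)
        assert (m.to_numpy() == m.to_numpy().T).all()
        assert np.all(np.diag(m.to_numpy()) == 0)


def _rc_pool(rng, n_taxa=20, n_samples=8, total=200):
    """Random integer pool plus one identical and one disjoint pair."""
    profile = np.sort(rng.lognormal(0, 1, n_taxa))[::-1]
    profile /= profile.sum()
    rows = [rng.multinomial(total, profile) for _ in range(n_samples)]
    rows.append(rows[0].copy())                      # identical to sample 0
    left = np.zeros(n_taxa, dtype=int)
    right = np.zeros(n_taxa, dtype=int)
    left[: n_taxa // 2] = 20
    right[n_taxa // 2:] = 20
    rows += [left, right]                            # fully disjoint pair
    ids = [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids, columns=[f"t{i}"
                                                  for i in range(n_taxa)])


class TestRaupCrick:
    def test_bounds_and_tails(self, rng):
        table = _rc_pool(rng)
        rc = raup_crick_bray(table, n_iter=199, rng=np.random.default_rng(9))
        vals = rc.to_numpy()[np.triu_indices(len(table), 1)]
        assert (vals >= -1).all() and (vals <= 1).all()
        # identical pair far less dissimilar than the null expects
        assert rc.loc["s0", "s8"] <= -0.9
        # disjoint constructed pair more dissimilar than the null expects
        assert rc.loc["s9", "s10"] >= 0.9

    def test_reproducible(self, rng):
        table = _rc_pool(rng)
        a = raup_crick_bray(table, n_iter=49, rng=np.random.default_rng(5))
        b = raup_crick_bray(table, n_iter=49, rng=np.random.default_rng(5))
        assert a.equals(b)

    def test_non_integer_rejected(self):
        t = pd.DataFrame([[0.5, 1.2], [1.0, 2.0]], index=["a", "b"],
                         columns=["x", "y"])
        with pytest.raises(ValueError, match="integer"):
            raup_crick_bray(t, n_iter=9)

    def test_single_taxon_pool_rejected(self):
        t = pd.DataFrame([[5, 0], [3, 0]], index=["a", "b"],
                         columns=["x", "y"])
        with pytest.raises(ValueError, match="degenerate"):
            raup_crick_bray(t, n_iter=9)

    def test_occupancy_abundance_variant_runs(self, rng):
        table = _rc_pool(rng)
        rc = raup_crick_bray(table, n_iter=49, rng=np.random.default_rng(2),
                             species_weight="occupancy_abundance")
        vals = rc.to_numpy()[np.triu_indices(len(table), 1)]
        assert np.isfinite(vals).all()


class TestDiscretize:
    def test_integer_table_above_floor_unchanged(self):
        t = pd.DataFrame([[600, 500], [700, 400]], index=["a", "b"],
                         columns=["x", "y"], dtype=float)
        pd.testing.assert_frame_equal(discretize_counts(t, floor=1000), t)

    def test_normalized_table_rescaled_to_floor(self):
        t = pd.DataFrame([[0.2, 0.3], [0.1, 0.4]], index=["a", "b"],
                         columns=["x", "y"])
        out = discretize_counts(t, floor=1000)
        assert (out.to_numpy() == np.round(out.to_numpy())).all()
        assert out.sum(axis=1).min() >= 990  # rounding slack only

    def test_preserves_proportions_approximately(self):
        t = pd.DataFrame([[0.2, 0.6]], index=["a"], columns=["x", "y"])
        out = discretize_counts(t, floor=1000)
        assert out.loc["a", "y"] / out.loc["a", "x"] == pytest.approx(3.0,
                                                                      rel=0.01)


class TestNullPools:
    def test_grouping(self, toy_metadata):
        pools = build_pools(toy_metadata, seed=1)
        keys = {p.key: p.sample_ids for p in pools}
        assert keys == {("leaf", 4): ("s3",), ("root", 3): ("s1", "s2")}

    def test_rng_streams_independent_and_deterministic(self, toy_metadata):
        pools = build_pools(toy_metadata, seed=1)
        again = build_pools(toy_metadata, seed=1)
        p, q = pools[0], again[0]
        assert p.rng("bnti").random() == q.rng("bnti").random()
        assert p.rng("bnti").random() != p.rng("rc").random()
        other = pools[1]
        assert p.rng("bnti").random() != other.rng("bnti").random()
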