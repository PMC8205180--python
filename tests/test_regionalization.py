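"""WPGMA against a naive oracle, tree cutting, district consolidation and
MRPP."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from phytoreg import regionalization as reg


def dm_from(D, ids=None):
    D = np.asarray(D, dtype=float)
    ids = ids or [f"L{i}" for i in range(D.shape[0])]
    return DistanceMatrix((D + D.T) / 2, ids=ids)


def random_dm(rng, n):
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    return dm_from(D)


def naive_wpgma(D):
    """Dict-of-dicts WPGMA: merge the closest pair, average the two merged
    clusters' distances. Tie-break by smallest (i, j) cluster-id pair."""
    n = D.shape[0]
    dist = {
        i: {j: float(D[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    size = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(dist) > 1:
        best = min(
            (
                (dist[i][j], (min(i, j), max(i, j)))
                for i in dist
                for j in dist[i]
                if i < j
            ),
        )
        d_min, (a, b) = best
        new = {}
        for k in dist:
            if k in (a, b):
                continue
            new[k] = 0.5 * (dist[a][k] + dist[b][k])
        del dist[a], dist[b]
        for k in dist:
            del dist[k][a], dist[k][b]
            dist[k][next_id] = new[k]
        dist[next_id] = new
        merges.append((a, b, d_min, size[a] + size[b]))
        size[next_id] = size[a] + size[b]
        next_id += 1
    return merges


class TestWpgma:
    def test_two_leaves(self):
        dendro = reg.wpgma(dm_from([[0, 0.4], [0.4, 0]]))
        assert dendro.linkage.shape == (1, 4)
        assert dendro.linkage[0, 2] == pytest.approx(0.4)

    def test_three_leaf_hand_update(self):
        # d(1,2)=0.2, d(1,3)=0.6, d(2,3)=0.8: merge (1,2)@0.2 then
        # d({1,2},3) = (0.6+0.8)/2 = 0.7
        D = [[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]
        dendro = reg.wpgma(dm_from(D))
        np.testing.assert_allclose(dendro.linkage[:, 2], [0.2, 0.7])
        assert set(dendro.linkage[0, :2]) == {0, 1}

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        dm = random_dm(rng, n)
        dendro = reg.wpgma(dm)
        oracle = naive_wpgma(dm.data)
        for row, (a, b, h, s) in zip(dendro.linkage, oracle):
            assert {int(row[0]), int(row[1])} == {a, b}
            assert row[2] == pytest.approx(h, abs=1e-12)
            assert row[3] == s

    def test_matches_scipy_weighted_cophenetics(self):
        """Independent cross-check: scipy's 'weighted' (McQuitty) linkage
        yields the same cophenetic distances on a tie-free matrix."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(7)
        dm = random_dm(rng, 12)
        ours = reg.wpgma(dm)
        theirs = linkage(squareform(dm.data, checks=False), method="weighted")
        np.testing.assert_allclose(
            cophenet(ours.linkage), cophenet(theirs), atol=1e-10
        )

    def test_nan_rejected(self):
        class FakeDM:  # skbio itself refuses NaN at construction
            data = np.array([[0.0, np.nan], [np.nan, 0.0]])
            ids = ("a", "b")

        with pytest.raises(ValueError, match="NaN"):
            reg.wpgma(FakeDM())


class TestCutTree:
    def test_k_extremes(self):
        rng = np.random.default_rng(1)
        dm = random_dm(rng, 6)
        dendro = reg.wpgma(dm)
        assert reg.cut_tree(dendro, 1).nunique() == 1
        assert reg.cut_tree(dendro, 6).nunique() == 6

    def test_three_leaf_cut(self):
        D = [[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]
        dendro = reg.wpgma(dm_from(D, ids=["x", "y", "z"]))
        labels = reg.cut_tree(dendro, 2)
        assert labels["x"] == labels["y"] != labels["z"]

    @pytest.mark.parametrize("seed", range(5))
    def test_hierarchical_nesting(self, seed):
        """cut(k) refines cut(k-1): cells sharing a group at k share one at
        k-1."""
        rng = np.random.default_rng(seed)
        dm = random_dm(rng, 9)
        dendro = reg.wpgma(dm)
        for k in range(2, 9):
            fine = reg.cut_tree(dendro, k)
            coarse = reg.cut_tree(dendro, k - 1)
            mapping = {}
            for cid in fine.index:
                g = fine[cid]
                assert mapping.setdefault(g, coarse[cid]) == coarse[cid]


class TestConsolidate:
    def test_identity_when_groups_equal_k_final(self):
        D = [[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]
        dendro = reg.wpgma(dm_from(D, ids=["x", "y", "z"]))
        labels = reg.cut_tree(dendro, 2)
        out = reg.consolidate_districts(labels, dendro, k_final=2)
        assert (out.assignment["provenance"] == "cluster").all()
        assert out.districts.nunique() == 2
        # largest group is named A
        assert out.districts.value_counts().idxmax() == "A"

    def test_minor_groups_rejoin_by_cophenetic_proximity(self):
        # two tight blocks plus one outlier leaf; cutting at k=3 isolates
        # the outlier, consolidation must glue it to its nearest block
        D = np.full((7, 7), 0.9)
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    D[i, j] = 0.1 if i != j else 0.0
        D[6, :] = D[:, 6] = 0.95
        D[6, 3] = D[3, 6] = 0.5  # outlier closest to second block
        np.fill_diagonal(D, 0)
        dm = dm_from(D)
        dendro = reg.wpgma(dm)
        labels = reg.cut_tree(dendro, 3)
        out = reg.consolidate_districts(labels, dendro, k_final=2)
        assert out.assignment.loc["L6", "provenance"] == "reassigned"
        assert out.districts["L6"] == out.districts["L3"]

    def test_too_few_groups_raises(self):
        D = [[0, 0.2], [0.2, 0]]
        dendro = reg.wpgma(dm_from(D))
        labels = reg.cut_tree(dendro, 1)
        with pytest.raises(ValueError, match="groups"):
            reg.consolidate_districts(labels, dendro, k_final=2)


def hand_matrix():
    """6 points, two planted groups of 3 with small within / large between."""
    D = np.array(
        [
            [0.0, 0.1, 0.2, 0.9, 0.8, 0.7],
            [0.1, 0.0, 0.3, 0.6, 0.9, 0.8],
            [0.2, 0.3, 0.0, 0.7, 0.6, 0.9],
            [0.9, 0.6, 0.7, 0.0, 0.2, 0.1],
            [0.8, 0.9, 0.6, 0.2, 0.0, 0.3],
            [0.7, 0.8, 0.9, 0.1, 0.3, 0.0],
        ]
    )
    return dm_from(D, ids=[f"p{i}" for i in range(6)])


def exhaustive_mrpp_p(dm, labels):
    """Exact permutation p over all distinct label splits."""
    ids = list(dm.ids)
    arr = labels.reindex(ids).to_numpy()
    D = dm.data
    groups = sorted(set(arr))

    def delta(lab):
        total = 0.0
        for g in groups:
            idx = [i for i, v in enumerate(lab) if v == g]
            m = len(idx)
            s = sum(D[i, j] for i in idx for j in idx if i != j)
            total += (m / len(lab)) * s / (m * (m - 1))
        return total

    obs = delta(arr)
    n = len(ids)
    g0 = groups[0]
    k = sum(1 for v in arr if v == g0)
    deltas = []
    for combo in itertools.combinations(range(n), k):
        lab = [groups[1]] * n
        for i in combo:
            lab[i] = g0
        deltas.append(delta(lab))
    count = sum(1 for d in deltas if d <= obs + 1e-12)
    return obs, count / len(deltas)


class TestMrpp:
    def test_perfect_separation(self):
        # groups big enough that no permutation re-creates the split
        D = np.ones((20, 20))
        D[:10, :10] = 0
        D[10:, 10:] = 0
        np.fill_diagonal(D, 0)
        dm = dm_from(D)
        labels = pd.Series(["g1"] * 10 + ["g2"] * 10, index=dm.ids)
        res = reg.mrpp(dm, labels, permutations=99, seed=0)
        assert res.observed_delta == 0.0
        assert res.p_value == pytest.approx(1 / 100)
        assert res.a_statistic > 0

    def test_hand_delta_and_exhaustive_p(self):
        dm = hand_matrix()
        labels = pd.Series(["u"] * 3 + ["v"] * 3, index=dm.ids)
        # hand arithmetic: xi_u = (0.1+0.2+0.3)/3, xi_v = (0.2+0.1+0.3)/3
        assert reg.mrpp(dm, labels, permutations=9, seed=0).observed_delta == pytest.approx(
            0.5 * (0.6 / 3) + 0.5 * (0.6 / 3)
        )
        obs, p_exact = exhaustive_mrpp_p(dm, labels)
        res = reg.mrpp(dm, labels, permutations=1999, seed=1)
        assert res.observed_delta == pytest.approx(obs)
        # all 20 splits: Monte-Carlo p within sampling error of the exact p
        se = np.sqrt(p_exact * (1 - p_exact) / 1999)
        assert abs(res.p_value - p_exact) < max(4 * se, 0.02)

    def test_label_name_invariance(self):
        dm = hand_matrix()
        l1 = pd.Series(["u"] * 3 + ["v"] * 3, index=dm.ids)
        l2 = pd.Series(["north"] * 3 + ["south"] * 3, index=dm.ids)
        r1 = reg.mrpp(dm, l1, permutations=199, seed=5)
        r2 = reg.mrpp(dm, l2, permutations=199, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.observed_delta == r2.observed_delta

    def test_a_positive_iff_delta_below_expectation(self):
        dm = hand_matrix()
        labels = pd.Series(["u"] * 3 + ["v"] * 3, index=dm.ids)
        res = reg.mrpp(dm, labels, permutations=199, seed=2)
        assert (res.a_statistic > 0) == (res.observed_delta < res.expected_delta)

    def test_small_group_rejected(self):
        dm = hand_matrix()
        labels = pd.Series(["u"] * 5 + ["v"], index=dm.ids)
        with pytest.raises(ValueError, match="fewer than two"):
            reg.mrpp(dm, labels, permutations=9)

    def test_newick_export_parses(self, tmp_path):
        import dendropy

        dm = hand_matrix()
        dendro = reg.wpgma(dm)
        path = tmp_path / "t.nwk"
        dendro.write_newick(path)
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(dm.ids)
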