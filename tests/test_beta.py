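import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from sargasso import beta
from sargasso.simulate import generate_source_pool
from sargasso.table import OtuTable


def brute_force_weighted_unifrac(table, tree, normalized=True):
    """Independent per-branch accumulation: for every non-root node, gather its
    descendant tip set and weight the branch by |A − B| (and A + B)."""
    totals = table.sample_totals().astype(float)
    idx = {o: k for k, o in enumerate(table.otu_ids)}
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    denom = np.zeros((n, n))
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        cols = [idx[t] for t in tips if t in idx]
        frac = table.counts[:, cols].sum(axis=1) / totals  # per-sample proportion
        d += node.length * np.abs(frac[:, None] - frac[None, :])
        denom += node.length * (frac[:, None] + frac[None, :])
    if normalized:
        with np.errstate(invalid="ignore"):
            d = np.where(denom > 0, d / denom, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


class TestBrayCurtis:
    def test_identical_zero(self):
        t = OtuTable([[3, 1], [6, 2]], ["a", "b"], ["x", "y"])
        assert beta.bray_curtis(t)["a", "b"] == pytest.approx(0.0)

    def test_disjoint_one(self):
        t = OtuTable([[3, 0], [0, 9]], ["a", "b"], ["x", "y"])
        assert beta.bray_curtis(t)["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        # (0.6, 0.4) vs (0.2, 0.8) -> 0.4
        t = OtuTable([[6, 4], [2, 8]], ["a", "b"], ["x", "y"])
        assert beta.bray_curtis(t)["a", "b"] == pytest.approx(0.4)

    def test_empty_sample_rejected(self):
        t = OtuTable([[0, 0], [1, 1]], ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            beta.bray_curtis(t)


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        tree = TreeNode.read(io.StringIO("((a:1,b:2):1,c:1);"))
        t = OtuTable([[4, 2, 2], [8, 4, 4]], ["s1", "s2"], ["a", "b", "c"])
        assert beta.weighted_unifrac(t, tree)["s1", "s2"] == pytest.approx(0.0)

    def test_two_tip_opposite_samples(self):
        tree = TreeNode.read(io.StringIO("(a:1,b:1);"))
        t = OtuTable([[5, 0], [0, 5]], ["s1", "s2"], ["a", "b"])
        norm = beta.weighted_unifrac(t, tree, normalized=True)
        raw = beta.weighted_unifrac(t, tree, normalized=False)
        assert norm["s1", "s2"] == pytest.approx(1.0)
        assert raw["s1", "s2"] == pytest.approx(2.0)

    def test_missing_tip_reported(self):
        tree = TreeNode.read(io.StringIO("(a:1,b:1);"))
        t = OtuTable([[5, 1]], ["s1"], ["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            beta.weighted_unifrac(t, tree)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_brute_force_oracle(self, rng, normalized):
        for rep in range(10):
            pool = generate_source_pool(8, 1.0, seed=int(rng.integers(2 ** 31)))
            counts = rng.integers(0, 40, size=(5, 8))
            counts[counts.sum(axis=1) == 0, 0] = 1
            t = OtuTable(counts, [f"s{i}" for i in range(5)], pool.taxon_ids)
            got = beta.weighted_unifrac(t, pool.tree, normalized=normalized)
            expect = brute_force_weighted_unifrac(t, pool.tree, normalized)
            np.testing.assert_allclose(got.data, expect, atol=1e-12)

    def test_normalized_bounds(self, transect_dataset):
        dm = beta.weighted_unifrac(
            transect_dataset.table.drop_empty_otus(), transect_dataset.tree
        )
        assert dm.data.min() >= 0 and dm.data.max() <= 1 + 1e-12


class TestPcoa:
    def test_equilateral_eigenvalues(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            list("abc"))
        res = beta.pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(8, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(8)])
        res = beta.pcoa(dm)
        recon = squareform(pdist(res.coordinates[:, :2]))
        np.testing.assert_allclose(recon, dm.data, atol=1e-9)

    def test_agrees_with_skbio(self, rng):
        pts = rng.normal(size=(7, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(7)])
        ours = beta.pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9])[::-1][:3],
            ref.eigvals.to_numpy()[:3],
            atol=1e-9,
        )

    def test_proportions_sum_to_one_over_positive(self, transect_dataset):
        dm = beta.bray_curtis(transect_dataset.table)
        res = beta.pcoa(dm)
        assert res.proportion_explained.sum() == pytest.approx(1.0)


class TestPermanova:
    @staticmethod
    def _brute_force(d, labels):
        # direct evaluation of the sums-of-squares formulas
        n = len(labels)
        ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in set(labels):
            idx = [i for i, l in enumerate(labels) if l == g]
            ss_within += sum(
                d[i, j] ** 2 for ii, i in enumerate(idx) for j in idx[ii + 1:]
            ) / len(idx)
        a = len(set(labels))
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    def test_hand_built_matrix(self):
        d = np.array(
            [[0, 1, 4, 5], [1, 0, 4.5, 5.5], [4, 4.5, 0, 1.5], [5, 5.5, 1.5, 0]]
        )
        dm = DistanceMatrix(d, list("abcd"))
        g = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        res = beta.permanova(dm, g, n_perm=99, seed=0)
        assert res.pseudo_F == pytest.approx(
            self._brute_force(d, ["g1", "g1", "g2", "g2"]), abs=1e-12
        )
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total)

    def test_matches_skbio_statistic(self, rng):
        pts = rng.normal(size=(12, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(12)])
        g = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.ids)
        ours = beta.permanova(dm, g, n_perm=9, seed=0)
        ref = skbio_permanova(dm, list(g), permutations=9)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_perfect_separation(self):
        # two groups of clones, all between-group distances 1: only label
        # permutations recreating the split can match the observed F
        d = np.zeros((10, 10))
        d[:5, 5:] = 1.0
        d[5:, :5] = 1.0
        ids = [f"s{i}" for i in range(10)]
        g = {s: ("g1" if i < 5 else "g2") for i, s in enumerate(ids)}
        res = beta.permanova(DistanceMatrix(d, ids), g, n_perm=199, seed=1)
        assert res.ss_within == pytest.approx(0.0)
        assert res.p <= 0.05

    def test_single_group_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), list("ab"))
        with pytest.raises(ValueError):
            beta.permanova(dm, {"a": "g", "b": "g"}, n_perm=9)

    def test_pairwise_three_groups(self, rng):
        pts = rng.normal(size=(9, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(9)])
        g = {f"s{i}": ["x", "y", "z"][i // 3] for i in range(9)}
        out = beta.pairwise_permanova(dm, g, n_perm=49, seed=0, bonferroni=True)
        assert len(out) == 3
        assert (out["p_bonferroni"] >= out["p"]).all()


class TestPermdisp:
    def test_euclidean_distance_to_centroid(self, rng):
        # Euclidean geometry: z must equal the plain distance to the centroid
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(10)])
        g = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.ids)
        res = beta.permdisp(dm, g, n_perm=99, seed=0)
        for lab in ("a", "b"):
            idx = np.flatnonzero(np.asarray(g == lab))
            centroid = pts[idx].mean(axis=0)
            expect = np.linalg.norm(pts[idx] - centroid, axis=1)
            np.testing.assert_allclose(
                res.distances.iloc[idx].to_numpy(), expect, atol=1e-9
            )

    def test_mirror_groups_no_difference(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]], float)
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(6)])
        g = pd.Series(["a"] * 3 + ["b"] * 3, index=dm.ids)
        res = beta.permdisp(dm, g, n_perm=199, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.5

    def test_tight_vs_diffuse(self, rng):
        tight = rng.normal(0, 0.05, size=(8, 2))
        diffuse = rng.normal(0, 3.0, size=(8, 2))
        pts = np.vstack([tight, diffuse])
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(16)])
        g = pd.Series(["t"] * 8 + ["d"] * 8, index=dm.ids)
        res = beta.permdisp(dm, g, n_perm=199, seed=0)
        assert res.F > 10 and res.p < 0.05

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(squareform(pdist(np.eye(3))), list("abc"))
        with pytest.raises(ValueError):
            beta.permdisp(dm, {"a": "g1", "b": "g2", "c": "g2"}, n_perm=9)


class TestAnosim:
    def test_perfect_separation(self):
        d = np.array(
            [[0, 0.1, 0.9, 0.8], [0.1, 0, 0.85, 0.95],
             [0.9, 0.85, 0, 0.05], [0.8, 0.95, 0.05, 0]]
        )
        dm = DistanceMatrix(d, list("abcd"))
        r, p = beta.anosim(dm, {"a": "x", "b": "x", "c": "y", "d": "y"},
                           n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_skbio(self, rng):
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(10)])
        g = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.ids)
        ours, _ = beta.anosim(dm, g, n_perm=9, seed=0)
        ref = skbio_anosim(dm, list(g), permutations=9)
        assert ours == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_null_expectation_near_zero(self, rng):
        rs = []
        for s in range(200):
            pts = rng.normal(size=(10, 3))
            dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(10)])
            g = pd.Series(rng.permutation(["a"] * 5 + ["b"] * 5), index=dm.ids)
            rs.append(beta.anosim(dm, g, n_perm=1, seed=s)[0])
        assert abs(np.mean(rs)) < 0.05


class TestSimper:
    def test_conservation(self, transect_dataset):
        g = transect_dataset.metadata["region"]
        bc = beta.bray_curtis(transect_dataset.table)
        for res in beta.simper(transect_dataset.table, g):
            i_idx = [k for k, s in enumerate(transect_dataset.table.sample_ids)
                     if g.loc[s] == res.group_1]
            j_idx = [k for k, s in enumerate(transect_dataset.table.sample_ids)
                     if g.loc[s] == res.group_2]
            mean_bc = np.mean([bc.data[i, j] for i in i_idx for j in j_idx])
            assert res.overall_dissimilarity == pytest.approx(100 * mean_bc)
            assert res.contributions.sum() == pytest.approx(
                res.overall_dissimilarity
            )

    def test_hand_pair_contributions(self):
        t = OtuTable([[8, 2], [2, 8]], ["s1", "s2"], ["a", "b"])
        res = beta.simper(t, {"s1": "g1", "s2": "g2"})[0]
        # |0.8−0.2|/2 ·100 = 30 per taxon
        assert res.contributions["a"] == pytest.approx(30.0)
        assert res.contributions["b"] == pytest.approx(30.0)

    def test_two_way_restricts_pairs(self):
        t = OtuTable([[8, 2], [2, 8], [5, 5], [9, 1]],
                     ["s1", "s2", "s3", "s4"], ["a", "b"])
        g = {"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"}
        crossed = {"s1": "u", "s2": "v", "s3": "u", "s4": "v"}
        res = beta.simper(t, g, crossed)[0]
        assert res.n_pairs == 2  # (s1,s3) and (s2,s4) only


class TestDistanceDecay:
    @pytest.mark.parametrize("n,df_resid", [(39, 1480), (17, 270), (22, 460)])
    def test_ordered_pair_degrees_of_freedom(self, rng, n, df_resid):
        pts = rng.normal(size=(n, 2))
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(squareform(pdist(pts)) / 10, ids)
        geo = DistanceMatrix(squareform(pdist(rng.normal(size=(n, 2)))), ids)
        res = beta.distance_decay(dm, geo)
        assert res.df == (1, df_resid)
        assert res.n_points == n * (n - 1)

    def test_constant_similarity(self):
        d = np.array([[0, .5, .5], [.5, 0, .5], [.5, .5, 0]])
        dm = DistanceMatrix(d, list("abc"))
        geo = DistanceMatrix(
            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float), list("abc"))
        res = beta.distance_decay(dm, geo)
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_perfect_decay_slope(self):
        ids = list("abcd")
        g = np.abs(np.arange(4)[:, None] - np.arange(4)[None, :]).astype(float)
        geo = DistanceMatrix(g, ids)
        dm = DistanceMatrix(g * 0.1, ids)  # similarity = 1 − 0.1·geo
        res = beta.distance_decay(dm, geo)
        assert res.slope == pytest.approx(-0.1)
        assert res.r_squared == pytest.approx(1.0)
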