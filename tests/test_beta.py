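"""Distances, PCoA and matrix permutation tests, with independent oracles
(exhaustive branch enumeration; scikit-bio cross-checks)."""

import io
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from dysbiome import (AbundanceTable, DistanceMatrix, SampleMetadata, anosim,
                      bray_curtis, covariate_mantel, mantel, pcoa, unifrac)
from dysbiome.tables import PhyloTree, read_tree
from skbio import TreeNode
from skbio.diversity import beta_diversity


def _tree(newick: str) -> PhyloTree:
    t = TreeNode.read(io.StringIO(newick))
    for n in t.traverse(include_self=False):
        if n.length is None:
            n.length = 0.0
    return PhyloTree(t)


def _table(counts, samples, taxa):
    return AbundanceTable(pd.DataFrame(counts, index=samples, columns=taxa))


def _meta(groups):
    return SampleMetadata(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(groups))],
        "group": groups}))


def unifrac_by_enumeration(tree: PhyloTree, counts: pd.DataFrame,
                           a: str, b: str) -> float:
    """Independent unweighted UniFrac oracle: walk every branch and classify
    its length as shared or unique from raw leaf-descendant sets."""
    taxa_a = {t for t in counts.columns if counts.loc[a, t] > 0}
    taxa_b = {t for t in counts.columns if counts.loc[b, t] > 0}
    unique = shared = 0.0
    for node in tree.tree.postorder(include_self=False):
        leaves = {tip.name for tip in node.tips(include_self=True)}
        in_a, in_b = bool(leaves & taxa_a), bool(leaves & taxa_b)
        if in_a and in_b:
            shared += node.length
        elif in_a or in_b:
            unique += node.length
    return unique / (unique + shared)


class TestBrayCurtis:
    def test_closed_forms(self):
        rel = _table([[50, 50, 0], [25, 25, 50], [50, 50, 0]],
                     ["s0", "s1", "s2"], list("abc")).to_relative()
        dm = bray_curtis(rel)
        assert dm.values[0, 2] == pytest.approx(0.0)
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_disjoint_supports(self):
        rel = _table([[1, 0], [0, 1]], ["s0", "s1"], list("ab")).to_relative()
        assert bray_curtis(rel).values[0, 1] == pytest.approx(1.0)


class TestUniFrac:
    FOUR_LEAF = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_identical_samples_zero(self):
        tree = _tree(self.FOUR_LEAF)
        t = _table([[1, 2, 0, 0], [1, 2, 0, 0]], ["s0", "s1"], list("ABCD"))
        assert unifrac(t, tree.tree and tree, weighted=False).values[0, 1] == 0
        assert unifrac(t, tree, weighted=True).values[0, 1] == 0

    def test_fully_disjoint_paths(self):
        tree = _tree(self.FOUR_LEAF)
        t = _table([[1, 0, 0, 0], [0, 0, 1, 0]], ["s0", "s1"], list("ABCD"))
        assert unifrac(t, tree, weighted=False).values[0, 1] == pytest.approx(1.0)

    def test_worked_example_matches_enumeration_oracle(self):
        """{A,B} vs {A,C}: unique = B, C and the {C,D} stem; shared = A and
        the {A,B} stem -> 3/5 (verified by exhaustive branch enumeration)."""
        tree = _tree(self.FOUR_LEAF)
        t = _table([[1, 1, 0, 0], [1, 0, 1, 0]], ["s0", "s1"], list("ABCD"))
        d = unifrac(t, tree, weighted=False).values[0, 1]
        assert d == pytest.approx(3 / 5)
        assert d == pytest.approx(
            unifrac_by_enumeration(tree, t.data, "s0", "s1"))

    def test_star_tree_equals_jaccard(self, rng):
        taxa = [f"t{i}" for i in range(12)]
        star = _tree("(" + ",".join(f"{t}:1" for t in taxa) + ");")
        counts = rng.integers(0, 3, size=(6, 12))
        counts[:, 0] += 1
        t = _table(counts, [f"s{i}" for i in range(6)], taxa)
        dm = unifrac(t, star, weighted=False)
        presence = counts > 0
        for i, j in combinations(range(6), 2):
            inter = (presence[i] & presence[j]).sum()
            union = (presence[i] | presence[j]).sum()
            jaccard = 1 - inter / union
            assert dm.values[i, j] == pytest.approx(jaccard, abs=1e-12)

    def test_matches_skbio_on_random_data(self, default_cohort):
        table = default_cohort.table.drop_zero_taxa()
        sub = AbundanceTable(table.data.iloc[:8], table.lineages)
        tree = default_cohort.tree
        for weighted in (False, True):
            ours = unifrac(sub, tree, weighted=weighted)
            metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
            ref = beta_diversity(
                metric, sub.data.to_numpy(), ids=sub.sample_ids,
                tree=tree.tree, taxa=sub.taxon_ids,
                **({"normalized": True} if weighted else {}))
            np.testing.assert_allclose(
                ours.values, ref.data, atol=1e-10,
                err_msg=f"weighted={weighted}")

    def test_bounds(self, default_cohort):
        sub = AbundanceTable(default_cohort.table.drop_zero_taxa().data.iloc[:6],
                             default_cohort.table.lineages)
        for weighted in (False, True):
            dm = unifrac(sub, default_cohort.tree, weighted=weighted)
            assert (dm.values >= 0).all() and (dm.values <= 1 + 1e-12).all()

    def test_missing_taxon_listed(self):
        tree = _tree(self.FOUR_LEAF)
        t = _table([[1, 1], [1, 0]], ["s0", "s1"], ["A", "ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            unifrac(t, tree)


class TestPcoa:
    def test_collinear_points_recovered(self):
        x = np.array([0.0, 1.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        coords = res.coordinates.iloc[:, 0].to_numpy()
        rec = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(rec, d, atol=1e-9)
        assert np.all(np.abs(res.eigenvalues[1:]) < 1e-9)

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d))
        assert res.proportion_explained[:2].sum() == pytest.approx(1.0, abs=1e-9)
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-9)
        assert not res.has_negative_eigenvalues

    def test_negative_eigenvalues_flagged(self):
        # a non-Euclidean dissimilarity (violates triangle-embedding)
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1.95],
                      [1, 1, 1.95, 0]])
        res = pcoa(DistanceMatrix(list("abcd"), d))
        assert res.has_negative_eigenvalues
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_matches_skbio(self, rng):
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
        from skbio.stats.ordination import pcoa as sk_pcoa
        from skbio import DistanceMatrix as SkDM
        ref = sk_pcoa(SkDM(d, [f"s{i}" for i in range(7)]))
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9])[::-1],
            np.sort(ref.eigvals[ref.eigvals > 1e-9].to_numpy())[::-1],
            rtol=1e-8)


class TestAnosim:
    def test_all_equal_distances_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = anosim(DistanceMatrix([f"s{i}" for i in range(6)], d),
                     _meta(["PN"] * 3 + ["T"] * 3))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_exact_p(self):
        """3+3 design with every between-distance above every within-distance:
        R = 1 and exact p = 2/20 = 1/10 (10 distinct bipartitions)."""
        within, between = 0.1, 0.9
        d = np.full((6, 6), between)
        for block in (slice(0, 3), slice(3, 6)):
            d[block, block] = within
        np.fill_diagonal(d, 0)
        res = anosim(DistanceMatrix([f"s{i}" for i in range(6)], d),
                     _meta(["PN"] * 3 + ["T"] * 3))
        assert res.exact
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 10)

    def test_rank_invariance_under_monotone_transform(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        meta = _meta(["PN"] * 4 + ["T"] * 4)
        ids = [f"s{i}" for i in range(8)]
        r1 = anosim(DistanceMatrix(ids, d), meta)
        r2 = anosim(DistanceMatrix(ids, d ** 2), meta)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_skbio_statistic(self, rng):
        pts = rng.normal(size=(9, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(9)]
        groups = ["PN"] * 4 + ["T"] * 5
        ours = anosim(DistanceMatrix(ids, d), _meta(groups))
        from skbio.stats.distance import anosim as sk_anosim
        from skbio import DistanceMatrix as SkDM
        ref = sk_anosim(SkDM(d, ids), list(groups), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_single_group_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            anosim(DistanceMatrix([f"s{i}" for i in range(4)], d),
                   _meta(["PN"] * 4))


class TestMantel:
    def _random_dm(self, rng, n=5):
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_identity_r_one(self, rng):
        d = self._random_dm(rng)
        assert mantel(d, d).statistic == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        d = self._random_dm(rng)
        d3 = DistanceMatrix(d.ids, 3 * d.values)
        assert mantel(d, d3, method="pearson").statistic == pytest.approx(1.0)

    def test_equals_direct_pearson_of_upper_triangle(self, rng):
        d1, d2 = self._random_dm(rng), self._random_dm(rng)
        iu = np.triu_indices(5, k=1)
        expected = np.corrcoef(d1.values[iu], d2.values[iu])[0, 1]
        assert mantel(d1, d2).statistic == pytest.approx(expected, abs=1e-12)

    def test_matches_skbio(self, rng):
        d1, d2 = self._random_dm(rng, 8), self._random_dm(rng, 8)
        from skbio.stats.distance import mantel as sk_mantel
        from skbio import DistanceMatrix as SkDM
        ref = sk_mantel(SkDM(d1.values, d1.ids), SkDM(d2.values, d2.ids),
                        permutations=0)
        assert mantel(d1, d2).statistic == pytest.approx(ref[0], abs=1e-12)

    def test_mismatched_ids_rejected(self, rng):
        d1 = self._random_dm(rng)
        d2 = DistanceMatrix([f"x{i}" for i in range(5)], d1.values)
        with pytest.raises(ValueError):
            mantel(d1, d2)


class TestCovariateMantel:
    def test_constant_covariate_degenerate(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        x = pd.Series(2.0, index=dm.ids)
        res = covariate_mantel(dm, x)
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_first_axis_positive_control(self, rng):
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(12)], d)
        axis = pcoa(dm).coordinates.iloc[:, 0]
        res = covariate_mantel(dm, axis, seed=5)
        assert res.statistic > 0

    def test_missing_covariate_rejected(self, rng):
        pts = rng.normal(size=(4, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(4)], d)
        with pytest.raises(ValueError):
            covariate_mantel(dm, pd.Series([1.0], index=["s0"]))
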