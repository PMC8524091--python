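"""Distances, Neighbor-Joining and PCA with marker contributions."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from hybriqc.relatedness import (DistanceMatrix, PCAResult, encode_numeric,
                                 flag_related_pairs, marker_contributions,
                                 neighbor_joining, pairwise_distance, pca,
                                 tree_to_newick)

from conftest import make_panel, matrix_from_strings


def _dm(labels, values):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(sample_ids=list(labels), values=v,
                          n_shared=np.full_like(v, 17, dtype=int))


def _patristic(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[frozenset({t1.label, t2.label})] = pdm.patristic_distance(t1, t2)
    return out


class TestEncoding:
    def test_dosage_values(self):
        m = matrix_from_strings({"s1": "AHB-"})
        num = encode_numeric(m)
        assert list(num.iloc[0, :3]) == [0.0, 0.5, 1.0]
        assert np.isnan(num.iloc[0, 3])


class TestDistances:
    def test_identity_and_single_difference(self):
        m = matrix_from_strings({"a": "AAAA", "b": "AAAA", "c": "HAAA"})
        d = pairwise_distance(encode_numeric(m))
        frame = d.to_frame()
        assert frame.loc["a", "b"] == 0.0
        assert frame.loc["a", "c"] == pytest.approx(0.5)  # HOM1 vs HET, one locus

    def test_fourteen_homozygous_differences(self, qc_panel):
        """14 opposite-homozygote loci out of 17 give sqrt(14) ~ 3.742,
        inside the sqrt(17) bound of the encoding."""
        m = matrix_from_strings({"a": "A" * 14 + "AAA", "b": "B" * 14 + "AAA"},
                                panel=qc_panel)
        d = pairwise_distance(encode_numeric(m))
        assert d.to_frame().loc["a", "b"] == pytest.approx(np.sqrt(14))
        assert d.to_frame().loc["a", "b"] <= np.sqrt(17)

    def test_missing_loci_are_pairwise_deleted(self):
        m = matrix_from_strings({"a": "A-B", "b": "BAB"})
        d = pairwise_distance(encode_numeric(m))
        # only loci 1 and 3 are shared; they differ at locus 1 only
        assert d.to_frame().loc["a", "b"] == pytest.approx(1.0)
        assert d.n_shared[0, 1] == 2

    def test_no_shared_loci_flagged(self):
        m = matrix_from_strings({"a": "A-", "b": "-B"})
        d = pairwise_distance(encode_numeric(m))
        assert np.isnan(d.to_frame().loc["a", "b"])
        assert d.undefined_pairs == [("a", "b")]

    def test_metric_axioms_on_complete_data(self):
        rng = np.random.default_rng(21)
        calls = rng.choice([0, 1, 2], size=(8, 6)).astype(np.int8)
        m = matrix_from_strings({f"s{i}": "A" * 6 for i in range(8)})
        m.calls = calls
        d = pairwise_distance(encode_numeric(m)).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()
        for i in range(8):          # triangle inequality (Euclidean)
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = _dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = neighbor_joining(d)
        # three-point formulas: vA=1, vB=2, vC=3; patristic = input exactly
        pat = _patristic(tree)
        assert pat[frozenset("AB")] == pytest.approx(3.0)
        assert pat[frozenset("AC")] == pytest.approx(4.0)
        assert pat[frozenset("BC")] == pytest.approx(5.0)

    def test_additive_quartet_topology_and_lengths(self):
        # AB=2, CD=2, all cross distances 4 -> AB|CD, leaves 1, internal 2
        d = _dm("ABCD", [[0, 2, 4, 4], [2, 0, 4, 4],
                         [4, 4, 0, 2], [4, 4, 2, 0]])
        tree = neighbor_joining(d)
        pat = _patristic(tree)
        for pair, expected in [("AB", 2), ("CD", 2), ("AC", 4),
                               ("AD", 4), ("BC", 4), ("BD", 4)]:
            assert pat[frozenset(pair)] == pytest.approx(expected)
        leaf_lengths = {leaf.taxon.label: leaf.edge.length
                        for leaf in tree.leaf_node_iter()}
        assert all(v == pytest.approx(1.0) for v in leaf_lengths.values())
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.length and e.head_node.taxon is None]
        assert internal == [pytest.approx(2.0)]

    def test_additive_five_taxon_recovery(self):
        """NJ reproduces the path lengths of the generating tree exactly."""
        src = dendropy.Tree.get(
            data="((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);", schema="newick")
        pdm = src.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in src.taxon_namespace}
        labels = sorted(taxa)
        n = len(labels)
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a],
                                                           taxa[labels[j]])
        tree = neighbor_joining(_dm(labels, d))
        pat = _patristic(tree)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert pat[frozenset({a, b})] == pytest.approx(
                    d[i, labels.index(b)], abs=1e-9)

    def test_topology_agrees_with_dendropy_oracle(self):
        """On an additive matrix, the in-package NJ and dendropy's NJ
        recover the same unrooted topology (RF distance 0)."""
        import random
        rng = np.random.default_rng(17)
        src = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
            rng=random.Random(17))
        for e in src.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.1, 2.0))
        pdm = src.phylogenetic_distance_matrix()
        taxa = list(src.taxon_namespace)
        labels = [t.label for t in taxa]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        mine = neighbor_joining(_dm(labels, d))
        oracle = pdm.nj_tree()
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=tree_to_newick(mine), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=oracle.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions(); t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_newick_round_trip(self):
        d = _dm("ABCDE", np.array([[0, 2, 4, 4, 6], [2, 0, 4, 4, 6],
                                   [4, 4, 0, 2, 6], [4, 4, 2, 0, 6],
                                   [6, 6, 6, 6, 0]], dtype=float))
        tree = neighbor_joining(d)
        pat1 = _patristic(tree)
        back = dendropy.Tree.get(data=tree_to_newick(tree), schema="newick")
        pat2 = _patristic(back)
        assert set(pat1) == set(pat2)
        for k in pat1:
            assert pat1[k] == pytest.approx(pat2[k], abs=1e-9)

    def test_two_samples_single_edge(self):
        tree = neighbor_joining(_dm("AB", [[0, 3], [3, 0]]))
        assert _patristic(tree)[frozenset("AB")] == pytest.approx(3.0)

    def test_incomplete_matrix_rejected(self):
        v = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="incomplete"):
            neighbor_joining(_dm("ABC", v))

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(33)
        x = rng.random((6, 4))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        tree = neighbor_joining(_dm("ABCDEF", d))
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0.0


class TestRelatedPairs:
    def test_sister_lines_flagged_at_zero(self):
        m = matrix_from_strings({"sis1": "AABB", "sis2": "AABB", "far": "BBAA"})
        d = pairwise_distance(encode_numeric(m))
        pairs = flag_related_pairs(d, threshold=2.0)
        assert pairs.iloc[0].tolist() == ["sis1", "sis2", 0.0]

    def test_strict_inequality_and_empty_results(self):
        m = matrix_from_strings({"a": "AAAA", "b": "BBBB"})
        d = pairwise_distance(encode_numeric(m))  # distance 2.0
        assert flag_related_pairs(d, threshold=2.0).empty
        assert flag_related_pairs(d, threshold=0.0).empty

    def test_restricted_to_designed_pairs(self):
        m = matrix_from_strings({"f1": "AAAA", "f2": "AAAA", "m1": "AABB"})
        d = pairwise_distance(encode_numeric(m))
        pairs = flag_related_pairs(d, threshold=2.0,
                                   restrict_to=[("f1", "m1"), ("f2", "m1")])
        assert set(map(tuple, pairs[["sample_a", "sample_b"]].values)) == {
            ("f1", "m1"), ("f2", "m1")}


class TestPCA:
    def _numeric(self, seed=0, n=20, k=6, missing=0.1):
        rng = np.random.default_rng(seed)
        x = rng.choice([0.0, 0.5, 1.0], size=(n, k))
        x[rng.random((n, k)) < missing] = np.nan
        return pd.DataFrame(x, index=[f"s{i}" for i in range(n)],
                            columns=[f"m{j}" for j in range(k)])

    def test_reconstruction_identity(self):
        num = self._numeric()
        res = pca(num)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T \
            + res.imputed.mean(axis=0).to_numpy()
        assert np.allclose(recon, res.imputed.to_numpy(), atol=1e-9)

    def test_variance_explained_sums_to_100(self):
        res = pca(self._numeric(seed=3))
        assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-9)

    def test_duplicate_samples_get_equal_scores(self):
        num = self._numeric(missing=0.0)
        num.loc["s1"] = num.loc["s0"]
        res = pca(num)
        assert np.allclose(res.scores.loc["s0"], res.scores.loc["s1"],
                           atol=1e-9)

    def test_rank_one_matrix(self):
        v = np.array([0.0, 0.5, 1.0, 0.5])
        num = pd.DataFrame(np.outer([0, 1, 2, 3.0], v),
                           index=list("abcd"), columns=[f"m{j}" for j in range(4)])
        res = pca(num)
        assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        num = pd.DataFrame(np.ones((4, 3)), columns=list("xyz"))
        with pytest.raises(ValueError, match="zero-variance"):
            pca(num)

    def test_deterministic_signs(self):
        res1, res2 = pca(self._numeric(seed=5)), pca(self._numeric(seed=5))
        assert np.allclose(res1.scores, res2.scores)
        for k in range(res1.loadings.shape[1]):
            col = res1.loadings.iloc[:, k]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0


class TestContributions:
    def _manual_result(self, loadings, eigenvalues):
        L = np.asarray(loadings, dtype=float)
        idx = [f"m{j}" for j in range(L.shape[0])]
        cols = [f"PC{k + 1}" for k in range(L.shape[1])]
        return PCAResult(
            scores=pd.DataFrame(np.zeros((2, L.shape[1])), columns=cols),
            loadings=pd.DataFrame(L, index=idx, columns=cols),
            eigenvalues=np.asarray(eigenvalues, dtype=float),
            variance_explained=np.zeros(L.shape[1]),
            column_means=pd.Series(np.zeros(L.shape[0]), index=idx),
            imputed=pd.DataFrame())

    def test_single_component_examples(self):
        res = self._manual_result([[1.0], [0.0], [0.0]], [2.0])
        contrib = marker_contributions(res, dims=1)
        assert contrib["PC1"].tolist() == [100.0, 0.0, 0.0]
        equal = self._manual_result([[0.5], [0.5], [0.5], [0.5]], [1.0])
        assert marker_contributions(equal, dims=1)["PC1"].tolist() == [25.0] * 4

    def test_combined_contribution_sums_to_100(self):
        rng = np.random.default_rng(11)
        num = pd.DataFrame(rng.random((15, 7)),
                           columns=[f"m{j}" for j in range(7)])
        res = pca(num)
        for dims in (1, 2, 4):
            contrib = marker_contributions(res, dims=dims)
            for col in contrib.columns:
                assert contrib[col].sum() == pytest.approx(100.0, abs=1e-9)

    def test_dims_bounded_by_components(self):
        res = pca(self._numeric_for_bounds())
        with pytest.raises(ValueError, match="dims"):
            marker_contributions(res, dims=99)

    def _numeric_for_bounds(self):
        rng = np.random.default_rng(2)
        return pd.DataFrame(rng.random((5, 3)), columns=list("abc"))
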