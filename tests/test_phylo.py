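"""Variant matrix coding, distances, BME tree, PCA, Moran's I, subclones."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from barcodewga.phylo import (
    VariantMatrix,
    append_diploid_root,
    bme_tree,
    build_variant_matrix,
    consolidate_subclones,
    morans_i,
    profile_pca,
    variant_distances,
)
from barcodewga.simulate import CloneConfig, GenomeConfig, make_clone_tree

NA = np.nan


class TestVariantMatrix:
    @pytest.mark.parametrize("detected,cov,expected", [
        (True, 3, 1.0),     # detection dominates low coverage
        (False, 4, NA),     # unassessable
        (False, 5, 0.0),    # boundary: coverage 5 is assessable
    ])
    def test_coding_rule(self, detected, cov, expected):
        geno = pd.DataFrame([[detected]], index=["s1"], columns=["v1"])
        coverage = pd.DataFrame([[cov]], index=["s1"], columns=["v1"])
        vm = build_variant_matrix(geno, coverage)
        value = vm.data[0, 0]
        if np.isnan(expected):
            assert np.isnan(value)
        else:
            assert value == expected

    def test_shape_mismatch_error(self):
        geno = pd.DataFrame([[True]], index=["s1"], columns=["v1"])
        cov = pd.DataFrame([[1, 2]], index=["s1"], columns=["v1", "v2"])
        with pytest.raises(ValueError):
            build_variant_matrix(geno, cov)

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            VariantMatrix(["s1"], ["v1"], np.array([[2.0]]))


class TestDistances:
    def test_identical_rows_zero(self):
        vm = VariantMatrix(["a", "b"], list("xyz"),
                           np.array([[1, 1, 0], [1, 1, 0]], dtype=float))
        D = variant_distances(vm)
        assert D.loc["a", "b"] == 0

    def test_single_differing_site(self):
        vm = VariantMatrix(["a", "b"], list("xyz"),
                           np.array([[1, 1, 0], [0, 1, 0]], dtype=float))
        assert variant_distances(vm).loc["a", "b"] == 1

    def test_na_rescaling_convention(self):
        """(1,NA,0,1) vs (0,1,0,1): one mismatch over 3 usable sites,
        rescaled by 4/3."""
        vm = VariantMatrix(["a", "b"], list("wxyz"),
                           np.array([[1, NA, 0, 1], [0, 1, 0, 1]]))
        assert variant_distances(vm).loc["a", "b"] == pytest.approx(4 / 3)

    def test_no_shared_sites_error(self):
        vm = VariantMatrix(["a", "b"], list("xy"),
                           np.array([[1, NA], [NA, 0]]))
        with pytest.raises(ValueError, match="share"):
            variant_distances(vm)

    def test_symmetric_nonnegative_zero_diagonal(self, rng):
        data = rng.choice([0.0, 1.0, NA], size=(6, 40), p=[0.45, 0.45, 0.1])
        data[:, 0] = 1.0  # guarantee joint coverage
        vm = VariantMatrix([f"s{i}" for i in range(6)], list(range(40)), data)
        D = variant_distances(vm).to_numpy()
        assert np.allclose(D, D.T)
        assert (D >= 0).all()
        assert np.allclose(np.diag(D), 0)

    def test_diploid_root_distance_is_rescaled_row_sum(self):
        vm = VariantMatrix(["a"], list("wxyz"), np.array([[1, 1, NA, 0]]))
        D = variant_distances(append_diploid_root(vm))
        assert D.loc["a", "diploid"] == pytest.approx(2 * 4 / 3)


def rf_distance(newick1: str, newick2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestBmeTree:
    def test_additive_four_taxon_recovery(self):
        # tree ((a,b),(c,d)) with internal edge 3: additive distances
        D = pd.DataFrame(
            [[0, 3, 8, 9],
             [3, 0, 9, 10],
             [8, 9, 0, 5],
             [9, 10, 5, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        tree = bme_tree(D, root_label="a")
        assert rf_distance(tree.newick(), "((a,b),(c,d));") == 0

    def test_three_taxon_closed_form(self):
        D = pd.DataFrame([[0, 5, 9], [5, 0, 8], [9, 8, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        tree = bme_tree(D, root_label="a")
        # three-point formulas: la = (5+9-8)/2 = 3, lb = 2, lc = 6
        inner = next(n for n in tree.adjacency if not isinstance(n, str))
        assert tree.adjacency[inner]["a"] == pytest.approx(3)
        assert tree.adjacency[inner]["b"] == pytest.approx(2)
        assert tree.adjacency[inner]["c"] == pytest.approx(6)

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1], [2, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            bme_tree(D)

    def test_clonal_hierarchy_recovered_under_dropout(self):
        """12-sample genealogy (4 subclones, truncal+private variants),
        detection dropout 0.1: Robinson-Foulds 0 to truth in >= 90% of 50
        replicates."""
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            tree_truth = make_clone_tree(CloneConfig(), GenomeConfig(), r)
            sites = sorted(set().union(
                *[tree_truth.sample_sites(s) for s in tree_truth.samples]))
            idx = {site: j for j, site in enumerate(sites)}
            data = np.zeros((12, len(sites)))
            for i, s in enumerate(tree_truth.samples):
                for site in sorted(tree_truth.sample_sites(s)):
                    if r.random() > 0.10:  # allelic dropout of the variant
                        data[i, idx[site]] = 1.0
            vm = VariantMatrix(tree_truth.samples, sites, data)
            inferred = bme_tree(variant_distances(append_diploid_root(vm)))
            hits += rf_distance(inferred.newick(), tree_truth.newick) == 0
        assert hits >= 45

    def test_negative_branch_lengths_clamped(self):
        D = pd.DataFrame([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]],
                         index=list("abcd"), columns=list("abcd"), dtype=float)
        tree = bme_tree(D)
        for node, nbrs in tree.adjacency.items():
            for length in nbrs.values():
                assert length >= 0


class TestMoransI:
    def test_gradient_positive(self):
        coords = np.column_stack([np.arange(10), np.zeros(10)])
        values = np.arange(10, dtype=float)
        assert morans_i(values, coords=coords, k=1) > 0

    def test_checkerboard_negative_rook_weights(self):
        """4x4 checkerboard with rook adjacency: direct-formula oracle gives
        I = -1 (perfect anticorrelation among neighbors)."""
        n = 16
        coords = [(i, j) for i in range(4) for j in range(4)]
        values = np.array([(i + j) % 2 for i, j in coords], dtype=float)
        W = np.zeros((n, n))
        for a, (i, j) in enumerate(coords):
            for b, (k, l) in enumerate(coords):
                if abs(i - k) + abs(j - l) == 1:
                    W[a, b] = 1.0
        W = W / W.sum(axis=1, keepdims=True)
        observed = morans_i(values, weights=W)
        # oracle: every neighbor pair has opposite parity
        z = values - values.mean()
        oracle = n / W.sum() * (z @ W @ z) / (z ** 2).sum()
        assert observed == pytest.approx(oracle)
        assert observed == pytest.approx(-1.0)

    def test_permutation_null_expectation(self, rng):
        coords = rng.uniform(0, 10, size=(20, 2))
        values = rng.normal(size=20)
        stats = [morans_i(rng.permutation(values), coords=coords, k=4)
                 for _ in range(500)]
        assert np.mean(stats) == pytest.approx(-1 / 19, abs=0.02)

    def test_bounds_with_row_standardized_weights(self, rng):
        for _ in range(20):
            coords = rng.uniform(0, 5, size=(15, 2))
            values = rng.normal(size=15)
            assert -1.001 <= morans_i(values, coords=coords, k=4) <= 1.001

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(5), coords=np.random.rand(5, 2))


class TestProfilePCA:
    def test_two_clusters_separated_on_pc1(self):
        data = np.vstack([np.tile([1, 1, 0, 0], (4, 1)),
                          np.tile([0, 0, 1, 1], (4, 1))]).astype(float)
        vm = VariantMatrix([f"s{i}" for i in range(8)], list("wxyz"), data)
        scores = profile_pca(vm)
        pc1 = scores["PC1"]
        assert (pc1[:4].to_numpy() * pc1[4:].to_numpy() < 0).all()

    def test_matches_dense_eigendecomposition(self, rng):
        data = rng.choice([0.0, 1.0], size=(10, 30))
        vm = VariantMatrix([f"s{i}" for i in range(10)], list(range(30)), data)
        scores = profile_pca(vm, n_components=2).to_numpy()
        Xc = data - data.mean(axis=0)
        cov = Xc.T @ Xc / (len(data) - 1)
        vals, vecs = np.linalg.eigh(cov)
        top = vecs[:, np.argsort(vals)[::-1][:2]]
        oracle = Xc @ top
        for c in range(2):
            assert np.allclose(np.abs(scores[:, c]), np.abs(oracle[:, c]),
                               atol=1e-8)

    def test_single_outlier_row_extreme_on_pc1(self):
        data = np.zeros((6, 10))
        data[3, :] = 1.0
        vm = VariantMatrix([f"s{i}" for i in range(6)], list(range(10)), data)
        scores = profile_pca(vm)["PC1"].to_numpy()
        assert np.argmax(np.abs(scores)) == 3


class TestConsolidate:
    def presence(self, rows):
        return pd.DataFrame(rows, index=["s1", "s2", "s3", "s4"],
                            columns=["m1"])

    def test_majority_present(self):
        df = self.presence([[1], [1], [1], [0]])
        out = consolidate_subclones(df, {s: "c1" for s in df.index})
        assert bool(out.loc["c1", "m1"])

    def test_exact_half_absent(self):
        df = self.presence([[1], [1], [0], [0]])
        out = consolidate_subclones(df, {s: "c1" for s in df.index})
        assert not bool(out.loc["c1", "m1"])

    def test_sv_bulk_rescue(self):
        df = self.presence([[1], [0], [0], [0]])
        out = consolidate_subclones(df, {s: "c1" for s in df.index},
                                    mutation_class="sv", bulk_presence={"m1"})
        assert bool(out.loc["c1", "m1"])
        out2 = consolidate_subclones(df, {s: "c1" for s in df.index},
                                     mutation_class="sv", bulk_presence=set())
        assert not bool(out2.loc["c1", "m1"])

    def test_truncal_mutations_shared_by_all_subclones_without_noise(self, rng):
        """At zero dropout, mutations shared between subclones include every
        truncal truth mutation (common-ancestor evidence)."""
        tree = make_clone_tree(CloneConfig(), GenomeConfig(), rng)
        sites = sorted(set().union(*[tree.sample_sites(s) for s in tree.samples]))
        presence = pd.DataFrame(
            [[site in tree.sample_sites(s) for site in sites]
             for s in tree.samples],
            index=tree.samples, columns=pd.Index(range(len(sites))))
        presence.columns = [str(x) for x in range(len(sites))]
        site_label = dict(zip(presence.columns, sites))
        out = consolidate_subclones(presence, tree.subclone_of)
        shared_all = set(out.columns[out.all(axis=0)])
        truncal = {c for c, s in site_label.items()
                   if s in set(tree.truncal_sites)}
        assert truncal <= shared_all

    def test_empty_subclone_error(self):
        df = self.presence([[1], [1], [1], [1]])
        with pytest.raises(ValueError):
            consolidate_subclones(df, {s: "c1" for s in df.index} | {"ghost": "c2"})
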