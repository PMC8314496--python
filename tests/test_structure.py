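import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from hypothesis import given, settings
from hypothesis import strategies as st

from radpop import simulate, structure
from radpop.datamodel import RadpopError

from conftest import independent_sites_config, make_dataset

ADDITIVE_D = np.array(
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
)


class TestGRM:
    def test_two_site_longhand_entries(self):
        # site1 dosages (0,1,1,2), site2 (0,0,2,2); p=0.5 at both ->
        # z-scores +-sqrt(2); averaging the cross-products over 2 sites:
        gd = make_dataset(np.array([[0, 0], [1, 0], [1, 2], [2, 2]]))
        G = structure.grm(gd)
        expected = np.array(
            [[2, 1, -1, -2], [1, 1, -1, -1], [-1, -1, 1, 1], [-2, -1, 1, 2]],
            dtype=float,
        )
        np.testing.assert_allclose(G, expected, atol=1e-12)

    def test_symmetry_and_fixed_site_skipped(self):
        gd = make_dataset(np.array([[0, 1, 2], [0, 1, 0], [0, 0, 1], [0, 2, 1]]))
        G = structure.grm(gd)  # first site fixed -> skipped
        np.testing.assert_allclose(G, G.T)

    def test_identical_samples_maximal_off_diagonal(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, 40)
        dos = np.vstack([base, base, rng.integers(0, 3, 40), rng.integers(0, 3, 40)])
        G = structure.grm(make_dataset(dos))
        off = G - np.diag(np.diag(G))
        assert off[0, 1] == pytest.approx(off.max())


class TestPCA:
    def test_variance_percentages_sum_to_100(self):
        cfg = independent_sites_config([10, 10], 500, 0.2, seed=5)
        gd, _, _, _ = simulate.simulate_dataset(cfg)
        pc = structure.pca(gd, k=gd.n_samples - 1)
        assert pc.variance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_pc1_separates_diverged_populations(self):
        cfg = independent_sites_config([15, 15], 2_000, 0.2, seed=5)
        gd, _, _, _ = simulate.simulate_dataset(cfg)
        pc = structure.pca(gd, k=2)
        pc1 = pc.coordinates[:, 0]
        a, b = pc1[:15], pc1[15:]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert a.max() < b.min() or b.max() < a.min()  # no overlap

    def test_k_must_be_below_sample_count(self):
        gd = make_dataset([[0, 1], [1, 0]])
        with pytest.raises(RadpopError):
            structure.pca(gd, k=2)

    def test_k1_on_two_samples_takes_positive_spectrum(self):
        gd = make_dataset([[0, 1, 2], [2, 1, 0]])
        pc = structure.pca(gd, k=1)
        assert pc.variance_pct[0] == pytest.approx(100.0, abs=1e-9)


class TestAlleleSharing:
    def test_identical_samples_distance_zero(self):
        gd = make_dataset([[0, 1, 2], [0, 1, 2]])
        D = structure.allele_sharing_distance(gd)
        assert D[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        gd = make_dataset([[0, 2, 0], [2, 0, 2]])
        assert structure.allele_sharing_distance(gd)[0, 1] == 1.0

    def test_longhand_mixed_pair(self):
        gd = make_dataset([[0, 1, 2], [2, 1, 0]])
        # per-site |diff|/2: 1, 0, 1 -> mean 2/3
        assert structure.allele_sharing_distance(gd)[0, 1] == pytest.approx(2 / 3)

    def test_no_shared_sites_rejected(self):
        gd = make_dataset([[0, -1], [-1, 2]])
        with pytest.raises(RadpopError):
            structure.allele_sharing_distance(gd)


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        njt = structure.nj_tree(ADDITIVE_D, list("ABCD"))
        paths = structure.tree_path_lengths(njt)
        expected = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        for pair, d in expected.items():
            assert paths[pair] == pytest.approx(d, abs=1e-9)
        # cherry (A,B) vs (C,D): removing the internal edge separates them
        newick = njt.as_newick()
        assert "(A:1.0,B:2.0)" in newick.replace(" ", "")

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        njt = structure.nj_tree(D, list("XYZ"))
        paths = structure.tree_path_lengths(njt)
        assert paths[("X", "Y")] == pytest.approx(2, abs=1e-9)
        assert paths[("X", "Z")] == pytest.approx(3, abs=1e-9)
        assert paths[("Y", "Z")] == pytest.approx(5, abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        n = 6
        coords = rng.random((n, 3))
        D = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        labels = [f"T{i}" for i in range(n)]
        base = structure.tree_path_lengths(structure.nj_tree(D, labels))
        perm = rng.permutation(n)
        D2 = D[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        other = structure.tree_path_lengths(structure.nj_tree(D2, labels2))
        for pair in base:
            assert other[pair] == pytest.approx(base[pair], abs=1e-9)

    def test_agreement_with_independent_nj_oracle(self):
        # dendropy's own NJ on the same matrix gives the same unrooted topology
        labels = list("ABCDEF")
        rng = np.random.default_rng(9)
        coords = rng.random((6, 4))
        D = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        njt = structure.nj_tree(D, labels)

        tns = njt.tree.taxon_namespace
        csv_rows = ["," + ",".join(labels)]
        for i, lab in enumerate(labels):
            csv_rows.append(lab + "," + ",".join(str(x) for x in D[i]))
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO("\n".join(csv_rows)), taxon_namespace=tns
        )
        oracle = pdm.nj_tree()
        for t in (njt.tree, oracle):
            t.encode_bipartitions()
        assert treecompare.symmetric_difference(njt.tree, oracle) == 0

    def test_asymmetric_matrix_rejected(self):
        D = ADDITIVE_D.copy()
        D[0, 1] = 99
        with pytest.raises(RadpopError):
            structure.nj_tree(D, list("ABCD"))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_nj_edge_lengths_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        coords = rng.random((n, 2))
        D = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        njt = structure.nj_tree(D, [f"T{i}" for i in range(n)])
        for edge in njt.tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


def test_populations_cluster_in_pca_and_tree(standard_run):
    gd, _, _, _ = standard_run
    pc = structure.pca(gd, k=2)
    # mean silhouette-like check: within-population PC spread smaller than total
    coords = pc.coordinates
    labels = np.array([gd.populations[s] for s in gd.samples])
    total_var = coords.var(axis=0).sum()
    within = np.mean(
        [coords[labels == p].var(axis=0).sum() for p in np.unique(labels)]
    )
    assert within < total_var / 2

    D = structure.allele_sharing_distance(gd)
    njt = structure.nj_tree(D, gd.samples)
    rooted = njt.midpoint_rooted()
    taxa = rooted.taxon_namespace
    n_mono = 0
    pops = sorted(set(labels))
    for p in pops:
        tips = [t for t in taxa if t.label.startswith(p + "_")]
        mrca = rooted.mrca(taxa=tips)
        if len(mrca.leaf_nodes()) == len(tips):
            n_mono += 1
    # populations form clades on the midpoint-rooted individual tree
    assert n_mono >= len(pops) - 1
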