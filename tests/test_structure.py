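"""PCA, genome-spread subsampling, neighbor joining and cluster extraction."""

import warnings
from io import StringIO

import numpy as np
import pandas as pd
import pytest

from popdiff.genotype_io import GenotypeMatrix, make_snp_map
from popdiff.popgen_stats import ibs_distance_matrix
from popdiff.simdata import SimulationConfig, simulate_panel
from popdiff.structure import (
    ascertainment_curve,
    assign_clusters,
    nj_tree,
    pca_patterson,
    subsample_snps,
)

from oracles import best_fit_topology, tree_splits


def _ari(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(list(a), list(b))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pc1_separates_two_simulated_subpopulations():
    cfg = SimulationConfig(n_subpops=2, sizes=(40, 40), n_snps=1500, n_chromosomes=3,
                           chrom_length_bp=600_000, differentiation=0.3, seed=13)
    gm, _, truth, _ = simulate_panel(cfg)
    pca = pca_patterson(gm, 2)
    pc1 = pca.scores["PC1"]
    g1 = pc1[truth.true_assignment == "P1"]
    g2 = pc1[truth.true_assignment == "P2"]
    assert g1.max() < g2.min() or g2.max() < g1.min()  # zero overlap on PC1


def test_duplicated_accessions_get_identical_scores(structured_panel):
    _, gm, _, _ = structured_panel
    sub = gm.take_accessions(np.arange(20))
    dup = GenotypeMatrix(sub.accession_ids + [a + "_copy" for a in sub.accession_ids],
                         sub.snp_ids, np.vstack([sub.dosage, sub.dosage]),
                         np.vstack([sub.missing_mask, sub.missing_mask]))
    pca = pca_patterson(dup, 3)
    np.testing.assert_allclose(pca.scores.values[:20], pca.scores.values[20:], atol=1e-8)


def test_rank_bound_returns_fewer_components_with_warning():
    dosage = np.array([[0, 0], [1, 0], [2, 0], [1, 0]], dtype=np.int8)
    gm = GenotypeMatrix(list("abcd"), ["s1", "s2"], dosage, np.zeros_like(dosage, dtype=bool))
    with pytest.warns(UserWarning, match="components"):
        pca = pca_patterson(gm, 2)
    assert pca.scores.shape[1] == 1
    assert pca.n_monomorphic_dropped == 1


def test_scores_invariant_to_snp_reordering(structured_panel):
    _, gm, _, _ = structured_panel
    rng = np.random.default_rng(1)
    perm = rng.permutation(gm.n_snps)
    a = pca_patterson(gm, 3).scores.values
    b = pca_patterson(gm.take_snps(perm), 3).scores.values
    for k in range(3):
        assert np.allclose(a[:, k], b[:, k], atol=1e-6) or np.allclose(a[:, k], -b[:, k], atol=1e-6)


def test_eigenvalues_non_increasing_and_components_orthogonal(structured_panel):
    _, gm, _, _ = structured_panel
    pca = pca_patterson(gm, 5)
    assert np.all(np.diff(pca.eigenvalues) <= 1e-9)
    gram = pca.scores.values.T @ pca.scores.values
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def test_subsample_saturation_returns_all_snps(structured_panel):
    _, gm, snp_map, _ = structured_panel
    idx = subsample_snps(snp_map, gm, gm.n_snps)
    assert len(idx) == gm.n_snps


def test_subsample_takes_one_snp_per_decile_on_uniform_map():
    """m=10 on a single-chromosome 100-SNP uniform map: one SNP per decile."""
    n = 100
    ids = [f"s{j}" for j in range(n)]
    positions = np.arange(1, n + 1) * 100  # uniform, chromosome length 10,000
    smap = make_snp_map(ids, ["chr1"] * n, positions, ["A"] * n, ["G"] * n)
    rng = np.random.default_rng(2)
    dosage = rng.integers(0, 3, size=(20, n)).astype(np.int8)
    gm = GenotypeMatrix([f"a{i}" for i in range(20)], ids, dosage,
                        np.zeros_like(dosage, dtype=bool))
    idx = subsample_snps(smap, gm, 10)
    assert len(idx) == 10
    deciles = (positions[idx] - 1) // 1000
    assert sorted(deciles) == list(range(10))  # exactly one per decile


def test_subsample_prefers_higher_gene_diversity():
    ids = ["lo", "hi"]
    smap = make_snp_map(ids, ["chr1", "chr1"], [100, 200], ["A", "A"], ["G", "G"])
    # p=0.1 (GD 0.18) vs p=0.5 (GD 0.5) in one window
    dosage = np.array([[0, 0], [0, 1], [0, 1], [0, 2], [1, 2]], dtype=np.int8)
    gm = GenotypeMatrix([f"a{i}" for i in range(5)], ids, dosage,
                        np.zeros_like(dosage, dtype=bool))
    idx = subsample_snps(smap, gm, 1)
    assert gm.snp_ids[idx[0]] == "hi"


# ---------------------------------------------------------------------------
# Ascertainment curve
# ---------------------------------------------------------------------------

def test_ascertainment_full_count_is_exactly_one(structured_panel):
    _, gm, snp_map, _ = structured_panel
    curve = ascertainment_curve(gm, snp_map, [gm.n_snps], n_replicates=2, seed=0)
    assert curve.table["mean_abs_correlation"].iloc[0] == pytest.approx(1.0)


def test_ascertainment_low_on_unstructured_panel():
    cfg = SimulationConfig(n_subpops=1, sizes=(60,), n_snps=2000, n_chromosomes=4,
                           chrom_length_bp=600_000, seed=17)
    gm, snp_map, _, _ = simulate_panel(cfg)
    curve = ascertainment_curve(gm, snp_map, [200], n_replicates=5, seed=0)
    # without structure the PCs are noise directions: subset PCs barely correlate
    assert curve.table["mean_abs_correlation"].iloc[0] < 0.5


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_four_taxon_additive_distances_recover_generating_topology():
    """((A,B),(C,D)) with leaf branches 1,2,3,4 and internal branch 5."""
    ids = list("ABCD")
    d = pd.DataFrame(
        [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
        index=ids, columns=ids, dtype=float)
    tree = nj_tree(d)
    splits = _my_tree_splits(tree)
    assert frozenset((frozenset("AB"), frozenset("CD"))) in splits
    # branch lengths are exact on additive input
    assert tree.graph.edges["A", _neighbor(tree, "A")]["length"] == pytest.approx(1.0)
    assert tree.graph.edges["B", _neighbor(tree, "B")]["length"] == pytest.approx(2.0)


def _neighbor(tree, leaf):
    return next(iter(tree.graph.neighbors(leaf)))


def _my_tree_splits(tree):
    import networkx as nx

    leaves = set(tree.leaves)
    splits = set()
    for u, v in tree.graph.edges():
        h = tree.graph.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u) if x in leaves)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset((side, frozenset(leaves - side))))
    return splits


def test_three_taxon_branch_lengths_solve_pairwise_equations():
    ids = list("ABC")
    d = pd.DataFrame([[0, 5, 7], [5, 0, 8], [7, 8, 0]], index=ids, columns=ids, dtype=float)
    tree = nj_tree(d)
    la = tree.graph.edges["A", _neighbor(tree, "A")]["length"]
    lb = tree.graph.edges["B", _neighbor(tree, "B")]["length"]
    lc = tree.graph.edges["C", _neighbor(tree, "C")]["length"]
    assert la + lb == pytest.approx(5)
    assert la + lc == pytest.approx(7)
    assert lb + lc == pytest.approx(8)


def test_identical_rows_are_joined_first():
    ids = list("ABCD")
    d = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], dtype=float)
    tree = nj_tree(pd.DataFrame(d, index=ids, columns=ids))
    assert _neighbor(tree, "A") == _neighbor(tree, "B")


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_matches_brute_force_topology_enumeration(n_taxa):
    """Random additive tree metrics: NJ recovers the same topology as the
    least-squares fit over all enumerated unrooted topologies."""
    rng = np.random.default_rng(100 + n_taxa)
    labels = [chr(ord("A") + i) for i in range(n_taxa)]
    for _ in range(3):
        # build a random additive metric from a random topology
        from oracles import enumerate_unrooted_topologies
        import networkx as nx

        topos = enumerate_unrooted_topologies(labels)
        edges = topos[rng.integers(len(topos))]
        g = nx.Graph()
        for u, v in edges:
            g.add_edge(u, v, weight=float(rng.uniform(0.5, 3.0)))
        d = [[0.0] * n_taxa for _ in range(n_taxa)]
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                d[i][j] = d[j][i] = nx.shortest_path_length(
                    g, labels[i], labels[j], weight="weight")
        tree = nj_tree(pd.DataFrame(d, index=labels, columns=labels))
        assert _my_tree_splits(tree) == best_fit_topology(d, labels)
        assert _my_tree_splits(tree) == tree_splits(edges, labels)


def test_nj_agrees_with_reference_implementation():
    """Random (non-additive) distances: same topology as scikit-bio's NJ."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix, TreeNode
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(11)
    pts = rng.random((9, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = [f"L{i}" for i in range(9)]
    mine = nj_tree(pd.DataFrame(d, index=ids, columns=ids))
    ref = skbio_nj(DistanceMatrix(d, ids))
    mine_parsed = TreeNode.read(StringIO(mine.newick))
    assert mine_parsed.compare_rfd(ref) == 0.0


def test_non_symmetric_matrix_rejected():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(d)


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------

def test_three_subpop_labels_recovered_exactly(structured_panel):
    _, gm, _, truth = structured_panel
    tree = nj_tree(ibs_distance_matrix(gm))
    clusters = assign_clusters(tree, 3)
    assert _ari(truth.true_assignment.values,
                clusters.reindex(truth.true_assignment.index).values) == 1.0


def test_two_island_bipartition_recovered(two_island_panel):
    _, gm, _, truth = two_island_panel
    sub = gm.take_accessions(np.arange(0, 200, 4))  # thin for speed
    labels = truth.true_assignment.iloc[np.arange(0, 200, 4)]
    tree = nj_tree(ibs_distance_matrix(sub))
    clusters = assign_clusters(tree, 2)
    assert _ari(labels.values, clusters.reindex(labels.index).values) == 1.0


def test_k_equal_to_leaf_count_gives_singletons(structured_panel):
    _, gm, _, _ = structured_panel
    sub = gm.take_accessions(np.arange(8))
    tree = nj_tree(ibs_distance_matrix(sub))
    clusters = assign_clusters(tree, 8)
    assert clusters.nunique() == 8


def test_invalid_k_rejected(structured_panel):
    _, gm, _, _ = structured_panel
    tree = nj_tree(ibs_distance_matrix(gm.take_accessions(np.arange(6))))
    with pytest.raises(ValueError):
        assign_clusters(tree, 1)
    with pytest.raises(ValueError):
        assign_clusters(tree, 7)
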