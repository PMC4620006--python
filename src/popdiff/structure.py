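"""Population-structure inference: Patterson-normalized PCA, neighbor-joining
trees from IBS distances, cluster extraction, and the marker-subsampling
sufficiency (ascertainment-bias) procedure.

PCA follows the Patterson/Eigenstrat normalization: each SNP column is
mean-centered and divided by the binomial standard deviation
:math:`\\sqrt{p(1-p)}` with *p* the sample allele frequency; missing calls
are imputed to the column mean before scaling.

The neighbor-joining implementation is the classic Saitou–Nei agglomeration
(Q-criterion, ties broken by lowest row/column index); negative branch
lengths are permitted and flagged.  Clusters are extracted by cutting the
K−1 longest branches (internal branches first) and taking the connected leaf
components.

The ascertainment procedure subsamples m genome-spread, high-diversity SNPs
(one per equal-physical-length window, window offsets jittered across
replicates), re-runs PCA, and reports the mean absolute correlation of the
first five principal components with the full-marker PCA after greedy
matching of components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .popgen_stats import gene_diversity

__all__ = [
    "PcaResult",
    "pca_patterson",
    "subsample_snps",
    "AscertainmentCurve",
    "ascertainment_curve",
    "NjTree",
    "nj_tree",
    "assign_clusters",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame       # accessions x components
    eigenvalues: np.ndarray    # non-increasing
    n_snps_used: int
    n_monomorphic_dropped: int


def pca_patterson(genotypes: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the dosage matrix with binomial (Patterson) SNP normalization."""
    if genotypes.n_accessions < 2:
        raise ValueError("PCA needs at least two accessions")
    d = genotypes.dosage_float()
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    n_dropped = int((~poly).sum())
    if poly.sum() < 1:
        raise ValueError("no polymorphic SNPs")
    z = (d[:, poly] - col_mean[poly]) / np.sqrt(p[poly] * (1.0 - p[poly]))
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-9))
    k = min(n_components, rank, genotypes.n_accessions - 1)
    if k < n_components:
        warnings.warn(f"only {k} informative components available (requested {n_components})")
    scores = u[:, :k] * s[:k]
    eig = (s[:k] ** 2) / (genotypes.n_accessions - 1)
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=genotypes.accession_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=eig,
        n_snps_used=int(poly.sum()),
        n_monomorphic_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Genome-spread SNP subsampling
# ---------------------------------------------------------------------------

def subsample_snps(snp_map: pd.DataFrame, genotypes: GenotypeMatrix, m: int,
                   seed=None, jitter: bool = False) -> np.ndarray:
    """Pick ~``m`` genome-spread, maximally diverse SNPs; returns column indices.

    The genome is divided into windows of length total_length/m; within each
    window the SNP maximizing gene diversity is chosen (ties: lowest missing
    rate, then lowest position).  Empty windows are skipped.  ``jitter``
    shifts the window grid by a random offset (for replicate subsamples).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m >= genotypes.n_snps:
        return np.arange(genotypes.n_snps)
    smap = snp_map.set_index("snp_id").loc[genotypes.snp_ids]
    p = genotypes.allele_frequency()
    gd = np.where(np.isnan(p), -1.0, 2.0 * p * (1.0 - p))
    miss = genotypes.missing_fraction()

    chrom_len = smap.groupby("chrom")["pos"].max()
    total_len = float(chrom_len.sum())
    win = max(total_len / m, 1.0)
    offset = 0.0
    if jitter:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        offset = float(rng.uniform(0.0, win))

    pos = smap["pos"].values.astype(float)
    chrom_codes, chrom_labels = pd.factorize(smap["chrom"])
    win_idx = np.floor((pos - 1 + offset) / win).astype(np.int64)
    key = chrom_codes.astype(np.int64) * (win_idx.max() + 2) + win_idx

    order = np.lexsort((pos, miss, -gd))  # best candidate first within ties
    chosen = {}
    for i in order:
        k = key[i]
        if k not in chosen:
            chosen[k] = i
    return np.sort(np.fromiter(chosen.values(), dtype=np.int64))


# ---------------------------------------------------------------------------
# Ascertainment curve
# ---------------------------------------------------------------------------

@dataclass
class AscertainmentCurve:
    table: pd.DataFrame  # marker_count, mean_abs_correlation, sd
    n_replicates: int


def _greedy_match_abs_corr(a: pd.DataFrame, b: pd.DataFrame, n_pc: int = 5) -> float:
    """Mean |Pearson r| over greedily matched component pairs.

    Components of the subset PCA (*b*) are matched to the full-set PCA (*a*)
    by repeatedly pairing the highest absolute correlation, which absorbs
    sign flips and component reordering.
    """
    ka = min(n_pc, a.shape[1])
    kb = min(n_pc, b.shape[1])
    if ka == 0 or kb == 0:
        return float("nan")
    av = a.values[:, :ka]
    bv = b.values[:, :kb]
    az = (av - av.mean(0)) / av.std(0)
    bz = (bv - bv.mean(0)) / bv.std(0)
    corr = np.abs(az.T @ bz / av.shape[0])
    corr = np.nan_to_num(corr)
    taken_a, taken_b, picked = set(), set(), []
    flat = [(-corr[i, j], i, j) for i in range(ka) for j in range(kb)]
    for negc, i, j in sorted(flat):
        if i in taken_a or j in taken_b:
            continue
        taken_a.add(i)
        taken_b.add(j)
        picked.append(-negc)
        if len(picked) == min(ka, kb):
            break
    if len(picked) < n_pc:
        warnings.warn(f"only {len(picked)} components recoverable; averaging over those")
    return float(np.mean(picked))


def ascertainment_curve(genotypes: GenotypeMatrix, snp_map: pd.DataFrame,
                        marker_counts, n_replicates: int = 20, seed: int = 0,
                        n_pc: int = 5) -> AscertainmentCurve:
    """Marker-number sufficiency curve for structure inference.

    For each marker count and replicate: subsample genome-spread SNPs
    (window offsets jittered per replicate), run PCA, and average the
    absolute correlations of the first five PCs against the full-set PCA.
    The full marker count gives 1.0 by construction.
    """
    if max(marker_counts) > genotypes.n_snps:
        raise ValueError("marker count exceeds available SNPs")
    full = pca_patterson(genotypes, n_components=n_pc)
    rng = np.random.default_rng(seed)
    rows = []
    for count in marker_counts:
        vals = []
        for _ in range(n_replicates):
            idx = subsample_snps(snp_map, genotypes, count, seed=rng, jitter=True)
            sub = pca_patterson(genotypes.take_snps(idx), n_components=n_pc)
            vals.append(_greedy_match_abs_corr(full.scores, sub.scores, n_pc=n_pc))
        rows.append(
            {
                "marker_count": int(count),
                "mean_abs_correlation": float(np.nanmean(vals)),
                "sd": float(np.nanstd(vals)),
            }
        )
    return AscertainmentCurve(pd.DataFrame(rows), n_replicates)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class NjTree:
    """Unrooted binary tree over accession leaves.

    ``graph`` is a networkx Graph whose edges carry ``length`` and an
    ``order`` attribute (creation order, used for deterministic tie-breaks);
    leaves are the accession-name nodes.  ``newick`` serializes the tree
    rooted arbitrarily at the last join.
    """

    graph: nx.Graph
    leaves: list
    newick: str
    has_negative_lengths: bool


def nj_tree(distance_matrix) -> NjTree:
    """Classic Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing Q_ij = (n-2) d_ij − r_i − r_j,
    breaking ties by lowest (row, column) index, computes the two branch
    lengths, and reduces the matrix.  Accepts a labeled DataFrame or a square
    array.  Negative branch lengths are retained and flagged.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        d = distance_matrix.values.astype(float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        labels = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")

    g = nx.Graph()
    order_counter = 0
    active = list(range(n))          # indices into the working matrix rows
    names = list(labels)             # node name per active index
    work = d.copy()
    next_internal = 0

    def add_edge(u, v, length):
        nonlocal order_counter
        g.add_edge(u, v, length=float(length), order=order_counter)
        order_counter += 1

    while len(active) > 2:
        k = len(active)
        sub = work[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # tie-break: lowest (row, col) among minima
        flat = np.argmin(q)
        qmin = q.flat[flat]
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        ties = [(i, j) for i, j in ties if i < j]
        i, j = min(ties)
        a, b = active[i], active[j]
        dij = work[a, b]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        new_name = f"_nj{next_internal}"
        next_internal += 1
        add_edge(names[a], new_name, li)
        add_edge(names[b], new_name, lj)
        # distances from the new node to every other active node
        grown = np.pad(work, ((0, 1), (0, 1)), mode="constant")
        for m_idx in active:
            if m_idx in (a, b):
                continue
            grown[-1, m_idx] = grown[m_idx, -1] = 0.5 * (work[a, m_idx] + work[b, m_idx] - dij)
        work = grown
        names.append(new_name)
        active = [x for x in active if x not in (a, b)] + [work.shape[0] - 1]

    a, b = active
    add_edge(names[a], names[b], work[a, b])

    has_neg = any(attrs["length"] < 0 for _, _, attrs in g.edges(data=True))
    leaves = [x for x in labels]
    root = names[-1]
    newick = _to_newick(g, root) + ";"
    return NjTree(graph=g, leaves=leaves, newick=newick, has_negative_lengths=has_neg)


def _quote(name: str) -> str:
    if any(ch in name for ch in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _to_newick(g: nx.Graph, root) -> str:
    def rec(node, parent):
        children = [nb for nb in g.neighbors(node) if nb != parent]
        if not children:
            return _quote(str(node))
        parts = [
            f"{rec(c, node)}:{g.edges[node, c]['length']:.10g}" for c in sorted(
                children, key=lambda nb: g.edges[node, nb]["order"]
            )
        ]
        label = "" if str(node).startswith("_nj") else _quote(str(node))
        return "(" + ",".join(parts) + ")" + label
    return rec(root, None)


def assign_clusters(tree: NjTree, k: int) -> pd.Series:
    """Cut the tree into K clusters by removing the K−1 longest branches.

    Internal branches are removed first (longest first, ties by creation
    order); once exhausted, external (leaf) branches follow, so K up to the
    leaf count yields singletons.  Returns accession -> cluster label
    ('C1'..'CK', ordered by each cluster's first leaf).
    """
    leaves = set(tree.leaves)
    if k < 2:
        raise ValueError("K must be >= 2 for downstream differentiation use")
    if k > len(leaves):
        raise ValueError("K exceeds the number of leaves")
    edges = list(tree.graph.edges(data=True))
    internal = [e for e in edges if e[0] not in leaves and e[1] not in leaves]
    external = [e for e in edges if e[0] in leaves or e[1] in leaves]
    rank = lambda e: (-e[2]["length"], e[2]["order"])
    candidates = sorted(internal, key=rank) + sorted(external, key=rank)

    # cut greedily; a cut only counts if it separates leaves from leaves,
    # so exactly K leaf-bearing components result
    pruned = tree.graph.copy()
    n_clusters = 1
    for u, v, _ in candidates:
        if n_clusters == k:
            break
        pruned.remove_edge(u, v)
        side_u = nx.node_connected_component(pruned, u)
        side_v = nx.node_connected_component(pruned, v)
        if side_u & leaves and side_v & leaves:
            n_clusters += 1
        else:
            pruned.add_edge(u, v)
    comps = []
    for comp in nx.connected_components(pruned):
        comp_leaves = sorted(comp & leaves)
        if comp_leaves:
            comps.append(comp_leaves)
    comps.sort(key=lambda ls: ls[0])
    mapping = {}
    for idx, comp_leaves in enumerate(comps, start=1):
        for leaf in comp_leaves:
            mapping[leaf] = f"C{idx}"
    return pd.Series(mapping, name="cluster").reindex(tree.leaves)
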