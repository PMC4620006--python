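"""Independent brute-force oracles, coded from first principles with explicit
loops and enumeration.  These deliberately share no code with the library:
they re-derive each statistic from its definition so the vectorized
implementations can be checked against them."""

import itertools
import math

MISSING = None  # genotype encoding used by the oracles: dosage int or None


def genotype_alleles(dosage):
    """The two alleles of a diploid genotype as a list, alt coded 1."""
    return [1] * dosage + [0] * (2 - dosage)


def oracle_gene_diversity(freqs):
    total = 0.0
    for p in freqs:
        total += p * p
    return 1.0 - total


def oracle_pic(freqs):
    s = 0.0
    for p in freqs:
        s += p * p
    double = 0.0
    k = len(freqs)
    for u in range(k - 1):
        for v in range(u + 1, k):
            double += 2.0 * freqs[u] ** 2 * freqs[v] ** 2
    return 1.0 - s - double


def oracle_locus_ibs(d1, d2):
    """P(random allele from genotype 1 == random allele from genotype 2),
    by enumerating the four allele draws."""
    a1 = genotype_alleles(d1)
    a2 = genotype_alleles(d2)
    matches = 0
    for x in a1:
        for y in a2:
            matches += 1 if x == y else 0
    return matches / 4.0


def oracle_pairwise_ibs(geno_i, geno_j):
    """Mean per-locus IBS over jointly non-missing loci (None = missing)."""
    total, count = 0.0, 0
    for d1, d2 in zip(geno_i, geno_j):
        if d1 is None or d2 is None:
            continue
        total += oracle_locus_ibs(d1, d2)
        count += 1
    return total / count if count else None


def oracle_kinship(genotypes):
    """Full kinship matrix from a list-of-lists genotype table (None missing)."""
    n = len(genotypes)
    q = [[oracle_pairwise_ibs(genotypes[i], genotypes[j]) for j in range(n)] for i in range(n)]
    off = [q[i][j] for i in range(n) for j in range(n) if i != j and q[i][j] is not None]
    q_m = sum(off) / len(off)
    return [
        [(q[i][j] - q_m) / (1.0 - q_m) if q[i][j] is not None else None for j in range(n)]
        for i in range(n)
    ], q_m


def oracle_dest_locus(dosages_by_subpop, literal_division=False):
    """Jost's D at one locus from per-subpopulation genotype lists (None missing).

    Returns None when any subpopulation has < 2 called genotypes.
    """
    n_subpops = len(dosages_by_subpop)
    freqs, counts = [], []
    for geno in dosages_by_subpop:
        called = [d for d in geno if d is not None]
        if len(called) < 2:
            return None
        counts.append(len(called))
        freqs.append(sum(called) / (2.0 * len(called)))
    inv_sum = 0.0
    for c in counts:
        inv_sum += 1.0 / c
    n_harm = n_subpops / inv_sum
    h_s_raw = 0.0
    for p in freqs:
        h_s_raw += 2.0 * p * (1.0 - p)
    h_s_raw /= n_subpops
    h_s = n_harm / (n_harm - 1.0) * h_s_raw
    p_bar = sum(freqs) / n_subpops
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if math.isclose(h_s, 1.0):
        return None
    core = (h_t - h_s) / (1.0 - h_s)
    factor = n_subpops / (n_subpops - 1.0)
    return core / factor if literal_division else core * factor


def oracle_population_dest(freqs_by_subpop):
    """Population-level Jost's D from known subpopulation allele frequencies."""
    n = len(freqs_by_subpop)
    h_s = sum(2.0 * p * (1.0 - p) for p in freqs_by_subpop) / n
    p_bar = sum(freqs_by_subpop) / n
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if math.isclose(h_s, 1.0):
        return None
    return (h_t - h_s) / (1.0 - h_s) * n / (n - 1.0)


def oracle_allele_reconciliation(ref_pair, other_pair):
    """Expected merge action for two reported allele pairs of one SNP.

    Enumerates the four representations of a biallelic SNP (two strands x two
    allele orders).  Returns 'same', 'flip' or None.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    representations = {
        (ref_pair[0], ref_pair[1]): "same",
        (comp[ref_pair[0]], comp[ref_pair[1]]): "same",
        (ref_pair[1], ref_pair[0]): "flip",
        (comp[ref_pair[1]], comp[ref_pair[0]]): "flip",
    }
    return representations.get(tuple(other_pair))


def enumerate_unrooted_topologies(labels):
    """All distinct unrooted binary tree topologies over the labels, as graphs.

    Built by sequential insertion of each new leaf into every edge of every
    smaller topology (3 -> 15 -> 105 ... trees).  Each topology is a list of
    edges between leaves and numbered internal nodes.
    """
    base = [("I0", labels[0]), ("I0", labels[1]), ("I0", labels[2])]
    trees = [base]
    next_internal = 1
    for leaf in labels[3:]:
        grown = []
        for tree in trees:
            for i, (u, v) in enumerate(tree):
                new_node = f"I{next_internal}"
                new_tree = tree[:i] + tree[i + 1:]
                new_tree += [(u, new_node), (new_node, v), (new_node, leaf)]
                grown.append(new_tree)
        next_internal += 1
        trees = grown
    return trees


def tree_splits(edges, labels):
    """The set of non-trivial leaf bipartitions induced by a topology."""
    import networkx as nx

    g = nx.Graph(edges)
    label_set = frozenset(labels)
    splits = set()
    for u, v in edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u) if x in label_set)
        if 1 < len(side) < len(labels) - 1:
            splits.add(frozenset((side, label_set - side)))
    return splits


def best_fit_topology(dist, labels):
    """Least-squares branch-length fit over all unrooted topologies; returns
    the split set of the best-fitting topology (the brute-force alternative
    to neighbor joining for small leaf counts)."""
    import networkx as nx
    import numpy as np

    best = None
    pairs = list(itertools.combinations(range(len(labels)), 2))
    for edges in enumerate_unrooted_topologies(labels):
        g = nx.Graph()
        g.add_edges_from(edges)
        edge_list = list(g.edges())
        a = np.zeros((len(pairs), len(edge_list)))
        y = np.zeros(len(pairs))
        for row, (i, j) in enumerate(pairs):
            path = nx.shortest_path(g, labels[i], labels[j])
            for u, v in zip(path[:-1], path[1:]):
                try:
                    col = edge_list.index((u, v))
                except ValueError:
                    col = edge_list.index((v, u))
                a[row, col] = 1.0
            y[row] = dist[i][j]
        coef, residuals, *_ = np.linalg.lstsq(a, y, rcond=None)
        rss = float(np.sum((a @ coef - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, edges)
    return tree_splits(best[1], labels)
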