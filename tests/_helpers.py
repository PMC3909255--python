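"""Shared builders for test networks."""

from __future__ import annotations

import itertools

import numpy as np

from lncnet import BipartiteAssociationNetwork, DiseaseNode, GeneNode


def net_from_edges(
    edges,
    gene_types=None,
    isolated_genes=(),
    isolated_diseases=(),
    disease_classes=None,
):
    """Build a network from (gene_id, disease_id) pairs; lncRNA by default."""
    edges = set(edges)
    gene_ids = sorted({g for g, _ in edges} | set(isolated_genes))
    disease_ids = sorted({d for _, d in edges} | set(isolated_diseases))
    gene_types = gene_types or {}
    disease_classes = disease_classes or {}
    genes = [GeneNode(g, gene_types.get(g, "lncRNA")) for g in gene_ids]
    diseases = [DiseaseNode(d, disease_class=disease_classes.get(d)) for d in disease_ids]
    return BipartiteAssociationNetwork(genes, diseases, edges)


def net_from_adjacency(A):
    """Network from a 0/1 genes x diseases array (alternating gene types)."""
    A = np.asarray(A)
    n_g, n_d = A.shape
    gene_ids = [f"g{i:02d}" for i in range(n_g)]
    disease_ids = [f"d{j:02d}" for j in range(n_d)]
    edges = {(gene_ids[i], disease_ids[j]) for i in range(n_g) for j in range(n_d) if A[i, j]}
    return net_from_edges(
        edges,
        gene_types={g: ("coding" if i % 2 else "lncRNA") for i, g in enumerate(gene_ids)},
        isolated_genes=gene_ids,
        isolated_diseases=disease_ids,
    )


def random_network(rng, max_genes=15, max_diseases=10, p=None):
    """Random bipartite network with at least one association."""
    n_g = int(rng.integers(2, max_genes + 1))
    n_d = int(rng.integers(1, max_diseases + 1))
    density = p if p is not None else float(rng.uniform(0.15, 0.6))
    A = rng.random((n_g, n_d)) < density
    if not A.any():
        A[0, 0] = True
    return net_from_adjacency(A)


def two_block_cliques(genes_per_block=5, diseases_per_block=3):
    """Two disjoint complete bipartite blocks: a perfectly recoverable net."""
    edges = set()
    for b in range(2):
        for i in range(genes_per_block):
            for j in range(diseases_per_block):
                edges.add((f"b{b}g{i}", f"b{b}d{j}"))
    return net_from_edges(edges)


def brute_force_clustering(G):
    """O(n^3) Watts-Strogatz local clustering by explicit triple enumeration."""
    values = {}
    for v in G:
        nbrs = list(G[v])
        k = len(nbrs)
        if k < 2:
            values[v] = 0.0
            continue
        closed = sum(1 for a, b in itertools.combinations(nbrs, 2) if G.has_edge(a, b))
        values[v] = 2.0 * closed / (k * (k - 1))
    return values
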