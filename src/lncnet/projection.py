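"""One-mode projections of the bipartite network.

Two products are derived from a gene-disease association network:

* unweighted co-neighbor projections — the disease projection (two diseases
  linked when they share an implicated gene; the "lncDN" view when the
  network holds only lncRNAs) and the gene projection (two genes linked when
  they are implicated in a common disease; the "DlncN" view);

* the resource-allocation weighted gene projection ``W`` that drives
  propagation scoring.  Resource allocation spreads one unit of resource
  from each gene equally over its diseases and then returns each disease's
  pool equally to its genes, so

      w_ij = (1/k(x_j)) * sum_l a_il * a_jl / k(y_l)

  is the fraction of gene *j*'s resource that ends up on gene *i*
  (``a`` the bipartite adjacency, ``k(x_j)`` gene degree, ``k(y_l)`` disease
  degree).  Columns of connected genes sum to one: ``W`` is column
  stochastic on the support of the network and conserves total resource.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import sparse

from .network import BipartiteAssociationNetwork

__all__ = [
    "OneModeProjection",
    "ProjectionWeights",
    "one_mode_projection",
    "resource_allocation_weights",
    "two_step_spread",
    "export_projection",
    "export_weights",
]


@dataclass(frozen=True)
class OneModeProjection:
    """Co-neighbor graph on one side of a bipartite network.

    ``shared_count`` maps each edge (a sorted id pair) to the number of
    common neighbors on the opposite side; it is ≥ 1 by construction and
    there are no self-loops.
    """

    side: str
    nodes: tuple[str, ...]
    shared_count: Mapping[tuple[str, str], int]

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.shared_count))

    @property
    def n_edges(self) -> int:
        return len(self.shared_count)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v in self.shared_count:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for (u, v), c in self.shared_count.items():
            G.add_edge(u, v, shared_count=int(c))
        return G


def one_mode_projection(net: BipartiteAssociationNetwork, side: str) -> OneModeProjection:
    """Project the bipartite network onto ``side`` ("gene" or "disease").

    Two nodes are connected iff they share at least one neighbor on the
    opposite side; ``shared_count`` records how many they share.
    """
    if side not in ("gene", "disease"):
        raise ValueError(f"side must be 'gene' or 'disease', got {side!r}")
    if net.n_genes == 0 and net.n_diseases == 0:
        raise ValueError("cannot project an empty network")
    if side == "disease":
        nodes = net.disease_ids
        groups = net.gene_neighbors  # each gene links a set of diseases
    else:
        nodes = net.gene_ids
        groups = net.disease_neighbors  # each disease links a set of genes
    counts: Counter[tuple[str, str]] = Counter()
    for _, members in sorted(groups.items()):
        for pair in itertools.combinations(members, 2):  # members pre-sorted
            counts[pair] += 1
    return OneModeProjection(side=side, nodes=nodes, shared_count=dict(counts))


@dataclass(frozen=True)
class ProjectionWeights:
    """Resource-allocation weight matrix over a fixed gene order.

    ``matrix[i, j]`` is the fraction of gene ``gene_order[j]``'s resource
    transferred to gene ``gene_order[i]``.  Dense ``numpy`` array for small
    gene sets, ``scipy.sparse`` CSR above ``dense_threshold`` genes; the
    contract is identical either way.
    """

    gene_order: tuple[str, ...]
    matrix: np.ndarray | sparse.csr_array = field(repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)

    @property
    def is_sparse(self) -> bool:
        return sparse.issparse(self.matrix)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray() if self.is_sparse else np.asarray(self.matrix)

    def index(self, gene_id: str) -> int:
        return self.gene_order.index(gene_id)


def _weights_from_adjacency(A: np.ndarray) -> np.ndarray:
    """Dense resource-allocation weights from a genes × diseases adjacency."""
    kx = A.sum(axis=1)
    ky = A.sum(axis=0)
    ky_safe = np.where(ky > 0, ky, 1.0)
    kx_safe = np.where(kx > 0, kx, 1.0)
    # two-step spread written as a single matrix product; degree-0 genes get
    # an all-zero row and column (their adjacency rows are zero)
    return (A / ky_safe) @ A.T / kx_safe[np.newaxis, :]


def resource_allocation_weights(
    net: BipartiteAssociationNetwork,
    *,
    dense_threshold: int = 2000,
    zero_diagonal: bool = False,
) -> ProjectionWeights:
    """Resource-allocation weighted gene projection of the network.

    Every gene appears in the matrix, including degree-0 genes (zero row and
    column), so gene indexing is stable across cross-validation folds.

    The diagonal self-return term ``w_jj`` is kept by default — the two-step
    process produces it.  ``zero_diagonal=True`` removes it for sensitivity
    analysis (note this breaks column normalization).
    """
    A, gene_order, _ = net.adjacency()
    W = _weights_from_adjacency(A)
    if zero_diagonal:
        np.fill_diagonal(W, 0.0)
    matrix: np.ndarray | sparse.csr_array = W
    if len(gene_order) > dense_threshold:
        matrix = sparse.csr_array(W)
    return ProjectionWeights(gene_order=gene_order, matrix=matrix)


def two_step_spread(net: BipartiteAssociationNetwork, f: np.ndarray) -> np.ndarray:
    """Simulate the two-step resource-allocation process explicitly.

    Step 1 divides each gene's resource equally among its diseases; step 2
    divides each disease's pooled resource equally among its genes.  The
    result equals ``W @ f`` entrywise (this function is the independent
    oracle for the merged matrix form).  Resource held by degree-0 genes is
    not moved.
    """
    A, gene_order, _ = net.adjacency()
    f = np.asarray(f, dtype=float)
    if f.shape != (len(gene_order),):
        raise ValueError(f"f must have shape ({len(gene_order)},), got {f.shape}")
    kx = A.sum(axis=1)
    ky = A.sum(axis=0)
    kx_safe = np.where(kx > 0, kx, 1.0)
    ky_safe = np.where(ky > 0, ky, 1.0)
    on_diseases = A.T @ (f / kx_safe)  # step 1: gene → its diseases, equal split
    return A @ (on_diseases / ky_safe)  # step 2: disease → its genes, equal split


def export_projection(proj: OneModeProjection, path: str | Path, format: str = "edgelist") -> None:
    """Write a projection as GraphML or a TSV edge list with ``shared_count``."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(proj.to_networkx(), path)
    elif format == "edgelist":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tshared_count\n")
            for u, v in proj.edges:
                fh.write(f"{u}\t{v}\t{proj.shared_count[(u, v)]}\n")
    else:
        raise ValueError(f"unsupported export format {format!r}")


def export_weights(weights: ProjectionWeights, path: str | Path) -> None:
    """Write W as a three-column sparse TSV (receiver, source, weight)."""
    path = Path(path)
    W = weights.toarray()
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_i\tgene_j\tweight\n")
        for i, j in zip(*np.nonzero(W)):
            fh.write(f"{weights.gene_order[i]}\t{weights.gene_order[j]}\t{W[i, j]:.12g}\n")
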