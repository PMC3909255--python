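"""Data model and I/O for bipartite gene-disease association networks.

The central object is :class:`BipartiteAssociationNetwork`: genes (either
``lncRNA`` or protein-``coding``) on one side, diseases on the other, and an
undirected association edge between a gene and a disease whenever mutation or
dysfunction of the gene is implicated in that disease.  Everything downstream
— one-mode projections, resource-allocation weighting, propagation scoring,
cross-validation — consumes this object.

Networks are read from and written to a small tab-separated dialect
(see :func:`load_associations`) and to GraphML.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

__all__ = [
    "GENE_TYPES",
    "DISEASE_CLASSES",
    "NetworkFormatError",
    "NetworkValidationError",
    "MergeConflictError",
    "GeneNode",
    "DiseaseNode",
    "ParseReport",
    "BipartiteAssociationNetwork",
    "load_associations",
    "merge_networks",
    "filter_min_degree",
    "export_graph",
    "read_graphml",
]

#: Allowed values of :attr:`GeneNode.gene_type`.
GENE_TYPES: tuple[str, str] = ("lncRNA", "coding")

#: Canonical disease-class vocabulary (physiological-system classes in the
#: style of Goh et al.'s human disease network).  Shipped for optional
#: validation and display only — class labels on nodes are free strings.
DISEASE_CLASSES: tuple[str, ...] = (
    "Bone",
    "Cancer",
    "Cardiovascular",
    "Connective tissue",
    "Dermatological",
    "Developmental",
    "Ear, Nose, Throat",
    "Endocrine",
    "Gastrointestinal",
    "Hematological",
    "Immunological",
    "Metabolic",
    "Muscular",
    "Neurological",
    "Nutritional",
    "Ophthamological",
    "Psychiatric",
    "Renal",
    "Respiratory",
    "Skeletal",
)


class NetworkFormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class NetworkValidationError(ValueError):
    """Contents violate the network data model (e.g. unknown gene type)."""


class MergeConflictError(NetworkValidationError):
    """The same gene id carries different gene types in two networks."""


@dataclass(frozen=True)
class GeneNode:
    """A gene vertex; ``gene_type`` distinguishes lncRNAs from coding genes."""

    id: str
    gene_type: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise NetworkValidationError(
                f"gene {self.id!r}: unknown gene_type {self.gene_type!r} "
                f"(expected one of {GENE_TYPES})"
            )


@dataclass(frozen=True)
class DiseaseNode:
    """A disease vertex with optional display name, MIM id and class label."""

    id: str
    name: str | None = None
    mim: str | None = None
    disease_class: str | None = None


@dataclass(frozen=True)
class ParseReport:
    """Bookkeeping from :func:`load_associations`."""

    rows_read: int
    edges_added: int
    duplicates_dropped: int
    node_only_rows: int = 0


class BipartiteAssociationNetwork:
    """Bipartite gene-disease association network.

    Parameters
    ----------
    genes, diseases
        Iterables of :class:`GeneNode` / :class:`DiseaseNode`.  Duplicate ids
        are allowed only if the nodes are identical.
    edges
        Iterable of ``(gene_id, disease_id)`` pairs.  Every endpoint must be
        registered; duplicate pairs collapse to a single edge.

    Notes
    -----
    Gene and disease ids share one namespace: an id may not appear on both
    sides.  This guards the one-mode projections against silent corruption.
    """

    def __init__(
        self,
        genes: Iterable[GeneNode] = (),
        diseases: Iterable[DiseaseNode] = (),
        edges: Iterable[tuple[str, str]] = (),
        parse_report: ParseReport | None = None,
    ) -> None:
        self._genes: dict[str, GeneNode] = {}
        for g in genes:
            prev = self._genes.get(g.id)
            if prev is not None and prev != g:
                raise NetworkValidationError(f"conflicting duplicate gene node {g.id!r}")
            self._genes[g.id] = g
        self._diseases: dict[str, DiseaseNode] = {}
        for d in diseases:
            prev_d = self._diseases.get(d.id)
            if prev_d is not None and prev_d != d:
                raise NetworkValidationError(f"conflicting duplicate disease node {d.id!r}")
            self._diseases[d.id] = d
        overlap = self._genes.keys() & self._diseases.keys()
        if overlap:
            raise NetworkValidationError(
                f"ids used on both sides of the bipartite network: {sorted(overlap)[:5]}"
            )
        self._edges: set[tuple[str, str]] = set()
        for g_id, d_id in edges:
            if g_id not in self._genes:
                raise NetworkValidationError(f"edge references unregistered gene {g_id!r}")
            if d_id not in self._diseases:
                raise NetworkValidationError(f"edge references unregistered disease {d_id!r}")
            self._edges.add((g_id, d_id))
        self.parse_report = parse_report
        self._adjacency_cache: tuple[np.ndarray, tuple[str, ...], tuple[str, ...]] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> tuple[GeneNode, ...]:
        return tuple(self._genes[i] for i in self.gene_ids)

    @property
    def diseases(self) -> tuple[DiseaseNode, ...]:
        return tuple(self._diseases[i] for i in self.disease_ids)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._genes))

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._diseases))

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    @property
    def n_diseases(self) -> int:
        return len(self._diseases)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def gene(self, gene_id: str) -> GeneNode:
        return self._genes[gene_id]

    def disease(self, disease_id: str) -> DiseaseNode:
        return self._diseases[disease_id]

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def has_disease(self, disease_id: str) -> bool:
        return disease_id in self._diseases

    def has_edge(self, gene_id: str, disease_id: str) -> bool:
        return (gene_id, disease_id) in self._edges

    def genes_of_type(self, gene_type: str) -> tuple[GeneNode, ...]:
        if gene_type not in GENE_TYPES:
            raise ValueError(f"unknown gene_type {gene_type!r}")
        return tuple(g for g in self.genes if g.gene_type == gene_type)

    def disease_class_map(self) -> dict[str, str | None]:
        """Disease id → class label (None where unlabeled)."""
        return {d.id: d.disease_class for d in self.diseases}

    # -- degrees and adjacency --------------------------------------------

    @property
    def gene_degrees(self) -> dict[str, int]:
        counts = Counter(g for g, _ in self._edges)
        return {g: counts.get(g, 0) for g in self._genes}

    @property
    def disease_degrees(self) -> dict[str, int]:
        counts = Counter(d for _, d in self._edges)
        return {d: counts.get(d, 0) for d in self._diseases}

    def gene_degree(self, gene_id: str) -> int:
        return sum(1 for g, _ in self._edges if g == gene_id)

    def disease_degree(self, disease_id: str) -> int:
        return sum(1 for _, d in self._edges if d == disease_id)

    @property
    def gene_neighbors(self) -> dict[str, tuple[str, ...]]:
        """Gene id → sorted tuple of associated disease ids."""
        nbrs: dict[str, list[str]] = {g: [] for g in self._genes}
        for g, d in self._edges:
            nbrs[g].append(d)
        return {g: tuple(sorted(v)) for g, v in nbrs.items()}

    @property
    def disease_neighbors(self) -> dict[str, tuple[str, ...]]:
        """Disease id → sorted tuple of associated gene ids."""
        nbrs: dict[str, list[str]] = {d: [] for d in self._diseases}
        for g, d in self._edges:
            nbrs[d].append(g)
        return {d: tuple(sorted(v)) for d, v in nbrs.items()}

    def adjacency(self) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
        """Dense genes × diseases 0/1 adjacency with its row/column orders.

        Orders are lexicographic in node id, which fixes the deterministic
        tie-breaking used throughout ranking.  The returned array is a copy.
        """
        if self._adjacency_cache is None:
            genes = self.gene_ids
            diseases = self.disease_ids
            g_index = {g: i for i, g in enumerate(genes)}
            d_index = {d: j for j, d in enumerate(diseases)}
            A = np.zeros((len(genes), len(diseases)))
            for g, d in self._edges:
                A[g_index[g], d_index[d]] = 1.0
            self._adjacency_cache = (A, genes, diseases)
        A, genes, diseases = self._adjacency_cache
        return A.copy(), genes, diseases

    # -- derived networks --------------------------------------------------

    def with_edges(
        self, edges: Iterable[tuple[str, str]], *, keep_all_nodes: bool = True
    ) -> "BipartiteAssociationNetwork":
        """Copy of this network with a replaced edge set.

        With ``keep_all_nodes=False`` only nodes incident to the new edges
        are retained.
        """
        edges = set(edges)
        if keep_all_nodes:
            return BipartiteAssociationNetwork(self.genes, self.diseases, edges)
        gene_ids = {g for g, _ in edges}
        disease_ids = {d for _, d in edges}
        return BipartiteAssociationNetwork(
            (self._genes[g] for g in gene_ids),
            (self._diseases[d] for d in disease_ids),
            edges,
        )

    def without_edge(self, gene_id: str, disease_id: str) -> "BipartiteAssociationNetwork":
        """Copy with one association removed; all nodes are kept."""
        if (gene_id, disease_id) not in self._edges:
            raise KeyError(f"no edge ({gene_id!r}, {disease_id!r})")
        return self.with_edges(self._edges - {(gene_id, disease_id)})

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteAssociationNetwork):
            return NotImplemented
        return (
            self._genes == other._genes
            and self._diseases == other._diseases
            and self._edges == other._edges
        )

    __hash__ = None  # type: ignore[assignment]

    def __repr__(self) -> str:
        return (
            f"<BipartiteAssociationNetwork: {self.n_genes} genes, "
            f"{self.n_diseases} diseases, {self.n_edges} associations>"
        )


# ---------------------------------------------------------------------------
# Delimited-text dialect
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("gene_id", "gene_type", "disease_id")
_OPTIONAL_COLUMNS = ("gene_label", "disease_name", "mim", "disease_class", "source")


def _iter_rows(path: Path, sep: str) -> Iterator[tuple[int, list[str]]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split(sep)


def _first_non_null(a: str | None, b: str | None) -> str | None:
    return a if a is not None else b


def _merge_disease_nodes(prev: DiseaseNode, new: DiseaseNode) -> DiseaseNode:
    return DiseaseNode(
        prev.id,
        name=_first_non_null(prev.name, new.name),
        mim=_first_non_null(prev.mim, new.mim),
        disease_class=_first_non_null(prev.disease_class, new.disease_class),
    )


def load_associations(path: str | Path, *, sep: str = "\t") -> BipartiteAssociationNetwork:
    """Read a gene-disease association table.

    Dialect: tab-separated, UTF-8, ``#`` comment lines ignored, header row
    required.  Required columns: ``gene_id``, ``gene_type``
    (``lncRNA``/``coding``), ``disease_id``.  Recognised optional columns:
    ``gene_label``, ``disease_name``, ``mim``, ``disease_class``, ``source``.

    A row with an empty ``disease_id`` declares an (isolated) gene only, and
    a row with an empty ``gene_id`` declares a disease only; rows with both
    ids add one association.  Duplicate associations are dropped and counted
    in the attached :class:`ParseReport` (``net.parse_report``).

    Raises
    ------
    NetworkFormatError
        Missing required columns, malformed rows, or an empty file.
    NetworkValidationError
        Unknown ``gene_type`` values or contradictory re-declarations; the
        message names the offending line number.
    """
    path = Path(path)
    header: list[str] | None = None
    col_idx: dict[str, int] = {}
    genes: dict[str, GeneNode] = {}
    diseases: dict[str, DiseaseNode] = {}
    edges: set[tuple[str, str]] = set()
    rows_read = duplicates = node_only = 0

    for lineno, fields in _iter_rows(path, sep):
        if header is None:
            header = [f.strip() for f in fields]
            missing = set(_REQUIRED_COLUMNS) - set(header)
            if missing:
                raise NetworkFormatError(
                    f"{path}: missing required column(s) {sorted(missing)}"
                )
            col_idx = {name: i for i, name in enumerate(header)}
            continue
        if len(fields) > len(header):
            raise NetworkFormatError(
                f"{path}, line {lineno}: {len(fields)} fields but header names {len(header)}"
            )
        row = {
            name: (fields[i].strip() if i < len(fields) else "")
            for name, i in col_idx.items()
        }
        rows_read += 1
        gid, did = row["gene_id"], row["disease_id"]
        if not gid and not did:
            raise NetworkFormatError(
                f"{path}, line {lineno}: row declares neither a gene nor a disease"
            )
        if gid:
            gtype = row["gene_type"]
            if gtype not in GENE_TYPES:
                raise NetworkValidationError(
                    f"{path}, line {lineno}: unknown gene_type {gtype!r} for gene "
                    f"{gid!r} (expected one of {GENE_TYPES})"
                )
            node = GeneNode(gid, gtype, label=row.get("gene_label") or None)
            prev = genes.get(gid)
            if prev is None:
                genes[gid] = node
            elif prev.gene_type != gtype:
                raise NetworkValidationError(
                    f"{path}, line {lineno}: gene {gid!r} re-declared as {gtype!r} "
                    f"(was {prev.gene_type!r})"
                )
            elif prev.label is None and node.label is not None:
                genes[gid] = node
        if did:
            d_node = DiseaseNode(
                did,
                name=row.get("disease_name") or None,
                mim=row.get("mim") or None,
                disease_class=row.get("disease_class") or None,
            )
            prev_d = diseases.get(did)
            diseases[did] = d_node if prev_d is None else _merge_disease_nodes(prev_d, d_node)
        if gid and did:
            if (gid, did) in edges:
                duplicates += 1
            else:
                edges.add((gid, did))
        else:
            node_only += 1

    if header is None:
        raise NetworkFormatError(f"{path}: no header row found")
    report = ParseReport(rows_read, len(edges), duplicates, node_only)
    return BipartiteAssociationNetwork(genes.values(), diseases.values(), edges, report)


def merge_networks(
    a: BipartiteAssociationNetwork, b: BipartiteAssociationNetwork
) -> BipartiteAssociationNetwork:
    """Union of two association networks (nodes and edges; shared edges once).

    Gene metadata must agree on ``gene_type``; other metadata is merged with
    the first network taking precedence.

    Raises
    ------
    MergeConflictError
        If the same gene id is lncRNA in one input and coding in the other.
    """
    genes: dict[str, GeneNode] = {g.id: g for g in a.genes}
    for g in b.genes:
        prev = genes.get(g.id)
        if prev is None:
            genes[g.id] = g
        elif prev.gene_type != g.gene_type:
            raise MergeConflictError(
                f"gene {g.id!r} is {prev.gene_type!r} in one network and "
                f"{g.gene_type!r} in the other"
            )
        elif prev.label is None and g.label is not None:
            genes[g.id] = GeneNode(g.id, prev.gene_type, label=g.label)
    diseases: dict[str, DiseaseNode] = {d.id: d for d in a.diseases}
    for d in b.diseases:
        prev_d = diseases.get(d.id)
        diseases[d.id] = d if prev_d is None else _merge_disease_nodes(prev_d, d)
    return BipartiteAssociationNetwork(
        genes.values(), diseases.values(), set(a.edges) | set(b.edges)
    )


def filter_min_degree(
    net: BipartiteAssociationNetwork, min_degree: int, *, iterative: bool = False
) -> BipartiteAssociationNetwork:
    """Keep only edges whose both endpoints have degree ≥ ``min_degree``.

    Degrees are those of the *input* network (single pass); nodes left
    without edges are dropped.  With ``iterative=True`` the pass repeats on
    its own output until no further edge is removed (fixpoint pruning).
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    while True:
        g_deg = net.gene_degrees
        d_deg = net.disease_degrees
        kept = {
            (g, d) for g, d in net.edges if g_deg[g] >= min_degree and d_deg[d] >= min_degree
        }
        filtered = net.with_edges(kept, keep_all_nodes=False)
        if not iterative or filtered.n_edges == net.n_edges:
            return filtered
        net = filtered


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def _to_networkx(net: BipartiteAssociationNetwork) -> nx.Graph:
    G = nx.Graph()
    for g in net.genes:
        attrs = {"side": "gene", "gene_type": g.gene_type}
        if g.label is not None:
            attrs["gene_label"] = g.label
        G.add_node(g.id, **attrs)
    for d in net.diseases:
        attrs = {"side": "disease"}
        if d.name is not None:
            attrs["disease_name"] = d.name
        if d.mim is not None:
            attrs["mim"] = d.mim
        if d.disease_class is not None:
            attrs["disease_class"] = d.disease_class
        G.add_node(d.id, **attrs)
    G.add_edges_from(sorted(net.edges))
    return G


def export_graph(
    net: BipartiteAssociationNetwork, path: str | Path, format: str = "edgelist"
) -> None:
    """Write the network as ``graphml`` or as a tab-separated ``edgelist``.

    Both formats round-trip: reading the file back (with
    :func:`read_graphml` or :func:`load_associations`) reproduces the node
    ids, gene types, metadata and edge set exactly, including isolated nodes.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_to_networkx(net), path)
    elif format == "edgelist":
        columns = ["gene_id", "gene_type", "gene_label", "disease_id",
                   "disease_name", "mim", "disease_class"]
        g_nbrs = net.gene_neighbors
        d_deg = net.disease_degrees
        with path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(columns) + "\n")
            for g in net.genes:
                targets = g_nbrs[g.id]
                if not targets:
                    fh.write(f"{g.id}\t{g.gene_type}\t{g.label or ''}\t\t\t\t\n")
                    continue
                for d_id in targets:
                    d = net.disease(d_id)
                    fh.write(
                        f"{g.id}\t{g.gene_type}\t{g.label or ''}\t{d.id}\t"
                        f"{d.name or ''}\t{d.mim or ''}\t{d.disease_class or ''}\n"
                    )
            for d in net.diseases:
                if d_deg[d.id] == 0:
                    fh.write(
                        f"\t\t\t{d.id}\t{d.name or ''}\t{d.mim or ''}\t"
                        f"{d.disease_class or ''}\n"
                    )
    else:
        raise ValueError(f"unsupported export format {format!r}")


def read_graphml(path: str | Path) -> BipartiteAssociationNetwork:
    """Read a network previously written by :func:`export_graph` as GraphML."""
    G = nx.read_graphml(Path(path))
    genes: list[GeneNode] = []
    diseases: list[DiseaseNode] = []
    for node, attrs in G.nodes(data=True):
        side = attrs.get("side")
        if side == "gene":
            genes.append(GeneNode(str(node), attrs["gene_type"], label=attrs.get("gene_label")))
        elif side == "disease":
            diseases.append(
                DiseaseNode(
                    str(node),
                    name=attrs.get("disease_name"),
                    mim=attrs.get("mim"),
                    disease_class=attrs.get("disease_class"),
                )
            )
        else:
            raise NetworkFormatError(f"{path}: node {node!r} lacks a gene/disease side attribute")
    gene_ids = {g.id for g in genes}
    edges = set()
    for u, v in G.edges():
        u, v = str(u), str(v)
        edges.add((u, v) if u in gene_ids else (v, u))
    return BipartiteAssociationNetwork(genes, diseases, edges)
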