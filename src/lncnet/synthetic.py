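"""Synthetic bipartite gene-disease fixtures with planted class structure.

No curated lncRNA-disease table is redistributable, so every pipeline stage
is exercised on generated networks that emulate the statistical structure
the method relies on:

* heavy-tailed degree sequences on both sides (a few hub diseases and hub
  genes, many degree-one nodes), produced by preferential attachment on a
  fixed node set;
* diseases partitioned into phenotype classes, and genes with a "home"
  class toward which their later associations are biased — the planted
  analogue of the observation that co-associated genes concentrate within
  disease classes.  This class-block signal is exactly what propagation can
  exploit, so held-out associations of biased generators are recoverable
  while degree-preserving shuffles of the same networks are not.

The default configuration is the small study condition used throughout the
tests (60 diseases, 250 genes, 500 associations); :func:`full_scale`
returns the full-size condition (214 diseases, 295 lncRNAs + 801 coding
genes, 578 + 980 = 1558 associations, 20 classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import (
    BipartiteAssociationNetwork,
    DiseaseNode,
    GeneNode,
    export_graph,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "full_scale",
    "generate_network",
    "make_paired_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    within_class_bias
        Odds multiplier for a gene's associations landing on a disease of
        its home class (1 = no planted signal).  The default plants a
        strongly class-pure signal: most of a gene's diseases fall in one
        class, matching the observation that most disease genes and
        lncRNAs act within a single phenotype class.
    degree_exponent
        Tail-heaviness control; attachment weights are
        ``(degree + 1) ** (degree_exponent - 1)``, so the default 2.0 gives
        linear preferential attachment.
    n_lncrna_edges
        Exact number of associations incident to lncRNA genes (the rest go
        to coding genes); ``None`` leaves the split to the attachment
        process.
    n_hidden
        Number of held-out "hidden true" pairs emitted for recovery tests;
        they are class-consistent but absent from the network.
    """

    n_diseases: int = 60
    n_lncrna: int = 67
    n_coding: int = 183
    n_edges: int = 500
    n_classes: int = 20
    within_class_bias: float = 100.0
    degree_exponent: float = 2.0
    n_lncrna_edges: int | None = 186
    n_hidden: int = 25
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_lncrna + self.n_coding

    def __post_init__(self) -> None:
        for name in ("n_diseases", "n_lncrna", "n_coding", "n_edges", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_edges < self.n_diseases:
            raise ValueError("n_edges must be >= n_diseases (every disease reachable)")
        if self.n_edges > self.n_genes * self.n_diseases:
            raise ValueError("n_edges exceeds the number of possible gene-disease pairs")
        if self.within_class_bias < 1.0:
            raise ValueError("within_class_bias must be >= 1")
        if self.degree_exponent <= 1.0:
            raise ValueError("degree_exponent must be > 1")
        if self.n_lncrna_edges is not None:
            if not 0 <= self.n_lncrna_edges <= self.n_edges:
                raise ValueError("n_lncrna_edges must lie in [0, n_edges]")
            if self.n_lncrna_edges > self.n_lncrna * self.n_diseases:
                raise ValueError("n_lncrna_edges exceeds possible lncRNA-disease pairs")
            if self.n_edges - self.n_lncrna_edges > self.n_coding * self.n_diseases:
                raise ValueError("coding edge quota exceeds possible coding-disease pairs")
        if self.n_hidden < 0:
            raise ValueError("n_hidden must be >= 0")


def full_scale(seed: int = 0) -> GeneratorConfig:
    """Full-size study condition: 295 lncRNAs + 801 coding genes, 214
    diseases, 578 lncRNA + 980 coding = 1558 associations, 20 classes."""
    return GeneratorConfig(
        n_diseases=214,
        n_lncrna=295,
        n_coding=801,
        n_edges=1558,
        n_classes=20,
        n_lncrna_edges=578,
        n_hidden=78,
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted with each fixture.

    ``hidden`` pairs are plausible (class-consistent) associations that are
    deliberately absent from the network; recovery tests expect them to rank
    better than random unassociated pairs.
    """

    disease_class: dict[str, str]
    gene_class: dict[str, str]
    hidden: tuple[tuple[str, str], ...]


def _weighted_choice(rng: np.random.Generator, weights: np.ndarray) -> int:
    total = weights.sum()
    if total <= 0:
        raise ValueError("no admissible choice")
    return int(rng.choice(len(weights), p=weights / total))


def generate_network(
    cfg: GeneratorConfig | None = None,
) -> tuple[BipartiteAssociationNetwork, SyntheticTruth]:
    """Generate one bipartite fixture plus its ground truth.

    Placement runs in two phases.  A seeding phase gives every disease one
    association, drawn from genes whose home class matches (so each class
    block is populated).  A growth phase then places the remaining edges:
    the gene is drawn with attachment weight ``(degree+1)**(exponent-1)``
    within its side quota, and the disease with the same kernel times
    ``within_class_bias`` on the gene's home class.  Duplicate pairs are
    rejected.  Fully deterministic under ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    width_d = max(3, len(str(cfg.n_diseases)))
    disease_ids = [f"D{i:0{width_d}d}" for i in range(cfg.n_diseases)]
    lnc_ids = [f"L{i:04d}" for i in range(cfg.n_lncrna)]
    cod_ids = [f"G{i:04d}" for i in range(cfg.n_coding)]
    gene_ids = lnc_ids + cod_ids
    gene_type = {g: ("lncRNA" if g in set(lnc_ids) else "coding") for g in gene_ids}

    class_names = [f"class{c:02d}" for c in range(cfg.n_classes)]
    # even partition of diseases over classes, order randomized
    perm = rng.permutation(cfg.n_diseases)
    disease_class_idx = np.empty(cfg.n_diseases, dtype=int)
    for pos, d in enumerate(perm):
        disease_class_idx[d] = pos % cfg.n_classes
    gene_class_idx = rng.integers(0, cfg.n_classes, size=len(gene_ids))

    class_members: list[np.ndarray] = [
        np.flatnonzero(disease_class_idx == c) for c in range(cfg.n_classes)
    ]
    gamma = cfg.degree_exponent - 1.0
    gene_deg = np.zeros(len(gene_ids), dtype=float)
    disease_deg = np.zeros(cfg.n_diseases, dtype=float)
    n_lnc = cfg.n_lncrna
    adjacency = np.zeros((len(gene_ids), cfg.n_diseases), dtype=bool)
    edges: list[tuple[int, int]] = []

    remaining = {
        "lncRNA": cfg.n_lncrna_edges if cfg.n_lncrna_edges is not None else None,
        "coding": (cfg.n_edges - cfg.n_lncrna_edges)
        if cfg.n_lncrna_edges is not None
        else None,
    }

    def side_slice(side: str) -> slice:
        return slice(0, n_lnc) if side == "lncRNA" else slice(n_lnc, len(gene_ids))

    def draw_side() -> str:
        if remaining["lncRNA"] is None:
            # unconstrained: proportional to pool sizes
            return "lncRNA" if rng.random() < n_lnc / len(gene_ids) else "coding"
        total = remaining["lncRNA"] + remaining["coding"]
        return "lncRNA" if rng.random() < remaining["lncRNA"] / total else "coding"

    def commit(gi: int, dj: int, side: str) -> None:
        adjacency[gi, dj] = True
        edges.append((gi, dj))
        gene_deg[gi] += 1
        disease_deg[dj] += 1
        if remaining[side] is not None:
            remaining[side] -= 1

    # --- seeding: one association per disease, home-class gene preferred ---
    for dj in rng.permutation(cfg.n_diseases):
        side = draw_side()
        while remaining[side] is not None and remaining[side] == 0:
            side = "lncRNA" if side == "coding" else "coding"
        sl = side_slice(side)
        offsets = np.arange(sl.start, sl.stop)
        matching = offsets[gene_class_idx[sl] == disease_class_idx[dj]]
        pool = matching if matching.size else offsets
        weights = (gene_deg[pool] + 1.0) ** gamma
        gi = int(pool[_weighted_choice(rng, weights)])
        commit(gi, int(dj), side)

    # --- growth: preferential attachment with within-class bias ------------
    attempts = 0
    max_attempts = 200 * cfg.n_edges + 1000
    while len(edges) < cfg.n_edges:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("edge placement failed to converge; config too dense")
        side = draw_side()
        sl = side_slice(side)
        offsets = np.arange(sl.start, sl.stop)
        open_mask = adjacency[sl].sum(axis=1) < cfg.n_diseases
        pool = offsets[open_mask]
        if pool.size == 0:
            continue
        gi = int(pool[_weighted_choice(rng, (gene_deg[pool] + 1.0) ** gamma)])
        w = (disease_deg + 1.0) ** gamma
        if cfg.within_class_bias > 1.0:
            home = class_members[gene_class_idx[gi]]
            w = w.copy()
            w[home] *= cfg.within_class_bias
        w[adjacency[gi]] = 0.0
        if w.sum() <= 0:
            continue
        dj = _weighted_choice(rng, w)
        commit(gi, dj, side)

    # --- hidden class-consistent pairs, absent from the network -----------
    hidden: list[tuple[int, int]] = []
    hidden_set: set[tuple[int, int]] = set()
    attempts = 0
    while len(hidden) < cfg.n_hidden and attempts < 200 * max(cfg.n_hidden, 1):
        attempts += 1
        connected = np.flatnonzero(gene_deg > 0)
        gi = int(connected[_weighted_choice(rng, gene_deg[connected])])
        home = class_members[gene_class_idx[gi]]
        free = [int(dj) for dj in home if not adjacency[gi, dj] and (gi, int(dj)) not in hidden_set]
        if not free:
            continue
        dj = free[int(rng.integers(len(free)))]
        hidden.append((gi, dj))
        hidden_set.add((gi, dj))

    genes = [GeneNode(g, gene_type[g]) for g in gene_ids]
    diseases = [
        DiseaseNode(disease_ids[j], disease_class=class_names[disease_class_idx[j]])
        for j in range(cfg.n_diseases)
    ]
    net = BipartiteAssociationNetwork(
        genes, diseases, {(gene_ids[i], disease_ids[j]) for i, j in edges}
    )
    truth = SyntheticTruth(
        disease_class={disease_ids[j]: class_names[disease_class_idx[j]] for j in range(cfg.n_diseases)},
        gene_class={gene_ids[i]: class_names[gene_class_idx[i]] for i in range(len(gene_ids))},
        hidden=tuple(sorted((gene_ids[i], disease_ids[j]) for i, j in hidden)),
    )
    return net, truth


def make_paired_fixture(
    cfg: GeneratorConfig | None = None,
) -> tuple[BipartiteAssociationNetwork, BipartiteAssociationNetwork, SyntheticTruth]:
    """(lncRNA-only network, integrated network, truth) sharing one structure.

    The integrated network is generated once; the lncRNA-only network is its
    restriction to lncRNA genes (all diseases retained).  Integrated minus
    the coding-gene associations therefore equals the lncRNA-only network
    exactly.
    """
    integrated, truth = generate_network(cfg)
    lnc_genes = integrated.genes_of_type("lncRNA")
    lnc_ids = {g.id for g in lnc_genes}
    lnc_edges = {(g, d) for g, d in integrated.edges if g in lnc_ids}
    lnc_only = BipartiteAssociationNetwork(lnc_genes, integrated.diseases, lnc_edges)
    return lnc_only, integrated, truth


def write_fixture(
    net: BipartiteAssociationNetwork, truth: SyntheticTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write associations.tsv, truth.tsv and classes.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "truth": outdir / "truth.tsv",
        "classes": outdir / "classes.tsv",
    }
    export_graph(net, paths["associations"], format="edgelist")
    with paths["truth"].open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tdisease_id\n")
        for g, d in truth.hidden:
            fh.write(f"{g}\t{d}\n")
    with paths["classes"].open("w", encoding="utf-8") as fh:
        fh.write("node_id\tside\tclass\n")
        for d, c in sorted(truth.disease_class.items()):
            fh.write(f"{d}\tdisease\t{c}\n")
        for g, c in sorted(truth.gene_class.items()):
            fh.write(f"{g}\tgene\t{c}\n")
    return paths
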