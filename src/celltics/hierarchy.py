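"""Pathway hierarchy parsing, pruning, layering and binary mask construction.

The Reactome hierarchy ships as a parent-child relation file among pathway
stable ids plus a gene-to-pathway annotation file. Top-level pathways hang
off a synthetic root. Although usually described as a tree, the relation
file can contain multi-parent pathways, so the graph is handled as a DAG.

For a network with ``l`` hidden layers, pathways are assigned to levels
1..l by their shortest-path depth from the root (top-level pathways =
level 1). Genes attach beneath level ``l``:

* a gene annotated to a pathway deeper than ``l`` is re-attached to that
  pathway's ancestors at depth exactly ``l``;
* a gene annotated to a pathway shallower than ``l`` is connected through
  a chain of single-parent artificial pad nodes (``<pathway>#pad<k>``)
  reaching down to depth ``l``.

Every gene therefore reaches level 1 in exactly ``l`` steps, which is what
lets a binary mask matrix per adjacent layer pair encode the whole graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROOT = "__root__"
MAX_LEVELS = 10

SPECIES_PREFIX = {"mouse": "R-MMU", "human": "R-HSA", "rat": "R-RNO"}

__all__ = [
    "PathwayTree",
    "LayeredPathwayGraph",
    "MaskStack",
    "load_pathway_hierarchy",
    "prune_to_genes",
    "build_layered_graph",
    "build_masks",
]


@dataclass
class PathwayTree:
    """Pathway DAG plus gene annotations, rooted at a synthetic node."""

    graph: nx.DiGraph  # edges parent -> child; pathway -> gene for annotations
    names: dict = field(default_factory=dict)  # pathway id -> display name

    @property
    def pathways(self) -> list:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "pathway"
        )

    @property
    def genes(self) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene")

    def annotations_of(self, gene: str) -> list:
        return sorted(self.graph.predecessors(gene))

    def copy(self) -> "PathwayTree":
        return PathwayTree(graph=self.graph.copy(), names=dict(self.names))


@dataclass
class LayeredPathwayGraph:
    """Depth-l layered graph: levels[1] = top pathways, levels[l] next to genes."""

    l: int
    levels: dict            # level (1..l) -> sorted list of node ids
    genes: list             # sorted gene ids feeding level l
    edges: set              # (parent, child) pairs, adjacent levels only
    artificial: set         # pad node ids
    level_of: dict          # node id -> level

    def parents_of(self, node: str) -> list:
        return sorted(p for (p, c) in self.edges if c == node)


@dataclass
class MaskStack:
    """Binary connectivity matrices child-layer x parent-layer.

    ``masks[0]`` maps genes to level-l pathways; ``masks[k]`` (k >= 1) maps
    level ``l-k+1`` to level ``l-k``. Entry (i, j) is 1 iff row entity i
    connects to column entity j in the layered graph.
    """

    masks: list             # list of uint8 arrays
    row_ids: list           # list of id lists, one per mask
    col_ids: list

    @property
    def gene_ids(self) -> list:
        return self.row_ids[0]

    @property
    def n_levels(self) -> int:
        return len(self.masks)


def load_pathway_hierarchy(relations_path, annotations_path, species: str) -> PathwayTree:
    """Parse relation and annotation TSVs into a :class:`PathwayTree`.

    ``relations_path``: two-column TSV ``parent<TAB>child`` of pathway ids.
    ``annotations_path``: TSV ``gene<TAB>pathway`` (extra columns ignored).
    ``species`` is either a known name (mouse/human/rat) or a literal
    stable-id prefix; only pathways with that prefix are kept.
    """
    prefix = SPECIES_PREFIX.get(species.lower(), species)

    try:
        rel = pd.read_csv(relations_path, sep="\t", header=None, usecols=[0, 1], dtype=str)
    except pd.errors.EmptyDataError:  # a flat hierarchy has no relations
        rel = pd.DataFrame(columns=[0, 1], dtype=str)
    rel.columns = ["parent", "child"]
    rel = rel[rel["parent"].str.startswith(prefix) & rel["child"].str.startswith(prefix)]

    ann = pd.read_csv(annotations_path, sep="\t", header=None, dtype=str)
    ann = ann.iloc[:, :2]
    ann.columns = ["gene", "pathway"]
    ann = ann[ann["pathway"].str.startswith(prefix)]
    if ann.empty:
        raise ValueError(f"no annotations left after filtering to species prefix {prefix!r}")

    g = nx.DiGraph()
    g.add_node(ROOT, kind="root")
    pathway_ids = set(rel["parent"]) | set(rel["child"]) | set(ann["pathway"])
    for p in pathway_ids:
        g.add_node(p, kind="pathway")
    for parent, child in rel.itertuples(index=False):
        g.add_edge(parent, child)

    pathway_only = g.subgraph(pathway_ids)
    if not nx.is_directed_acyclic_graph(pathway_only):
        cycle = nx.find_cycle(pathway_only)
        raise ValueError(f"pathway relations contain a cycle: {cycle}")

    # top-level pathways (no pathway parent) hang off the synthetic root
    for p in pathway_ids:
        if g.in_degree(p) == 0:
            g.add_edge(ROOT, p)

    for gene, pathway in ann.drop_duplicates().itertuples(index=False):
        gnode = f"gene:{gene}"
        g.add_node(gnode, kind="gene", symbol=gene)
        g.add_edge(pathway, gnode)

    return PathwayTree(graph=g)


def prune_to_genes(tree: PathwayTree, genes) -> PathwayTree:
    """Restrict the hierarchy to marker genes and their ancestor pathways.

    Genes absent from the annotation are dropped (their count is logged).
    Raises if no marker gene is annotated at all.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty marker gene list")
    annotated = {tree.graph.nodes[n]["symbol"]: n for n in tree.graph if tree.graph.nodes[n].get("kind") == "gene"}
    found = [annotated[g] for g in genes if g in annotated]
    missing = len(genes) - len(found)
    if missing:
        logger.info("prune: %d of %d marker genes have no pathway annotation and were dropped", missing, len(genes))
    if not found:
        raise ValueError("none of the marker genes are annotated to any pathway")

    keep: set = {ROOT}
    for gnode in found:
        keep.add(gnode)
        keep.update(nx.ancestors(tree.graph, gnode))
    sub = tree.graph.subgraph(keep).copy()
    return PathwayTree(graph=sub, names=dict(tree.names))


def build_layered_graph(tree: PathwayTree, l: int, max_levels: int = MAX_LEVELS) -> LayeredPathwayGraph:
    """Assign pathways to levels 1..l and attach genes beneath level l.

    Depth is the shortest-path distance from the root on the (pruned)
    pathway graph; only edges between adjacent levels are kept — along any
    shortest path each node retains a parent one level up, so no node is
    orphaned. Pathway nodes that end up without any input from below are
    dropped bottom-up.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if l > max_levels:
        raise ValueError(f"l={l} exceeds the configured maximum of {max_levels}")

    g = tree.graph
    pathway_nodes = [n for n, d in g.nodes(data=True) if d.get("kind") == "pathway"]
    gene_nodes = [n for n, d in g.nodes(data=True) if d.get("kind") == "gene"]
    depth = nx.single_source_shortest_path_length(g, ROOT)
    depth = {n: d for n, d in depth.items() if n in set(pathway_nodes)}

    level_of: dict = {n: d for n, d in depth.items() if d <= l}
    edges: set = set()
    for u, v in g.edges():
        if u in level_of and v in level_of and level_of[v] == level_of[u] + 1:
            edges.add((u, v))

    artificial: set = set()
    gene_edges: dict = {}  # gene -> set of level-l parents
    for gnode in gene_nodes:
        sym = g.nodes[gnode]["symbol"]
        parents: set = set()
        for p in g.predecessors(gnode):
            d = depth.get(p)
            if d is None:
                continue
            if d == l:
                parents.add(p)
            elif d > l:
                # re-attach to the annotated pathway's depth-l ancestors
                anc = nx.ancestors(g, p)
                parents.update(a for a in anc if depth.get(a) == l)
            else:
                # pad with a shared single-parent chain down to depth l
                chain_parent = p
                for k in range(1, l - d + 1):
                    pad = f"{p}#pad{k}"
                    if pad not in level_of:
                        level_of[pad] = d + k
                        artificial.add(pad)
                    edges.add((chain_parent, pad))
                    chain_parent = pad
                parents.add(chain_parent)
        if parents:
            gene_edges[sym] = parents

    if not gene_edges:
        raise ValueError("no gene could be attached at the requested depth")

    # drop pathway nodes that receive no input, bottom-up
    children: dict = {}
    for u, v in edges:
        children.setdefault(u, set()).add(v)
    fed = {p for parents in gene_edges.values() for p in parents}
    changed = True
    while changed:
        changed = False
        for node in list(level_of):
            has_input = node in fed or children.get(node, set())
            if not has_input:
                del level_of[node]
                artificial.discard(node)
                edges = {(u, v) for (u, v) in edges if v != node and u != node}
                children = {}
                for u, v in edges:
                    children.setdefault(u, set()).add(v)
                changed = True

    levels = {k: sorted(n for n, d in level_of.items() if d == k) for k in range(1, l + 1)}
    genes = sorted(gene_edges)
    all_edges = set(edges)
    for sym, parents in gene_edges.items():
        for p in parents:
            if p in level_of:
                all_edges.add((p, sym))

    return LayeredPathwayGraph(
        l=l,
        levels=levels,
        genes=genes,
        edges=all_edges,
        artificial=artificial,
        level_of=dict(level_of),
    )


def build_masks(graph: LayeredPathwayGraph) -> MaskStack:
    """Emit one binary matrix per adjacent layer pair, lexicographically ordered."""
    for k in range(1, graph.l + 1):
        if not graph.levels[k]:
            raise ValueError(f"level {k} has no nodes; reduce l or provide a deeper hierarchy")
    if not graph.genes:
        raise ValueError("layered graph has no genes")

    masks, row_ids, col_ids = [], [], []
    # genes -> level l
    layers = [graph.genes] + [graph.levels[k] for k in range(graph.l, 0, -1)]
    for child_layer, parent_layer in zip(layers[:-1], layers[1:]):
        row_index = {n: i for i, n in enumerate(child_layer)}
        col_index = {n: j for j, n in enumerate(parent_layer)}
        m = np.zeros((len(child_layer), len(parent_layer)), dtype=np.uint8)
        for parent, child in graph.edges:
            if child in row_index and parent in col_index:
                m[row_index[child], col_index[parent]] = 1
        masks.append(m)
        row_ids.append(list(child_layer))
        col_ids.append(list(parent_layer))
    return MaskStack(masks=masks, row_ids=row_ids, col_ids=col_ids)


def export_masks(stack: MaskStack, directory) -> None:
    """Write each mask as MatrixMarket plus row/column id lists."""
    import os

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(directory, exist_ok=True)
    for i, (m, rows, cols) in enumerate(zip(stack.masks, stack.row_ids, stack.col_ids)):
        mmwrite(os.path.join(directory, f"mask_{i}.mtx"), csr_matrix(m))
        with open(os.path.join(directory, f"mask_{i}_rows.txt"), "w") as fh:
            fh.write("\n".join(rows) + "\n")
        with open(os.path.join(directory, f"mask_{i}_cols.txt"), "w") as fh:
            fh.write("\n".join(cols) + "\n")
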