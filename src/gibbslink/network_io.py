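"""Reading, merging and writing protein–protein interaction networks.

Networks arrive either as KEGG KGML pathway XML (one file per pathway) or as
plain edge lists (SIF or two-column TSV).  Individual pathways are merged into
a single undirected simple graph by identifier union — the same semantics as
Cytoscape's network-union merge, with nodes matched by exact identifier
equality.  An optional two-column mapping table (e.g. Entrez -> HGNC symbol)
can relabel nodes after parsing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed."""


@dataclass
class PathwayGraph:
    """A single pathway: the unit prior to merging.

    Nodes are gene identifiers (KGML keeps the organism prefix, e.g.
    ``hsa:5925``); edges are unordered pairs.  The graph is always simple
    and undirected: self-loops are dropped at construction.
    """

    name: str
    graph: nx.Graph
    source_format: str  # one of {"kgml", "sif", "edgelist"}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}


@dataclass
class PPINetwork:
    """Merged undirected simple PPI network with pathway provenance."""

    graph: nx.Graph
    provenance: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


def _clean_graph(g: nx.Graph) -> int:
    """Drop self-loops in place; return the number dropped."""
    loops = list(nx.selfloop_edges(g))
    g.remove_edges_from(loops)
    return len(loops)


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------

def parse_kgml(kgml_document: str | bytes, name: str | None = None) -> PathwayGraph:
    """Parse a KEGG KGML pathway document into a :class:`PathwayGraph`.

    Every ``entry`` of type ``gene`` contributes all gene identifiers in its
    ``name`` attribute as nodes.  ``group`` entries expand to the union of the
    gene sets of their components.  Each ``relation`` between two entries adds
    edges between every gene of the first and every gene of the second (clique
    expansion across entry gene sets; no within-entry edges).  Non-gene
    entries (compounds, maps, orthologs) are skipped, and relation subtypes
    (activation, inhibition, binding, ...) are all flattened to undirected
    edges, since downstream scoring uses only adjacency.

    Parameters
    ----------
    kgml_document:
        KGML XML text or bytes.
    name:
        Pathway identifier; defaults to the document's ``name``/``title``
        attribute on the ``pathway`` element.

    Raises
    ------
    NetworkFormatError
        If the XML is malformed (the message names the offending line).
    """
    if isinstance(kgml_document, str):
        kgml_document = kgml_document.encode()
    try:
        # KGML documents reference the KEGG DTD; never fetch it.
        parser = etree.XMLParser(load_dtd=False, no_network=True, resolve_entities=False)
        root = etree.parse(io.BytesIO(kgml_document), parser).getroot()
    except etree.XMLSyntaxError as exc:
        raise NetworkFormatError(f"malformed KGML: {exc}") from exc

    pathway_name = name or root.get("title") or root.get("name") or "kgml-pathway"

    # entry id -> set of gene identifiers
    entry_genes: dict[str, set[str]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "gene":
            genes = {tok.strip() for tok in (entry.get("name") or "").split() if tok.strip()}
            if genes:
                entry_genes[eid] = genes
        elif etype == "group":
            groups[eid] = [c.get("id") for c in entry.iter("component")]
        # compounds, maps and other entry types are skipped

    # expand groups to the union of their components' gene sets
    for gid, comps in groups.items():
        genes: set[str] = set()
        for cid in comps:
            genes |= entry_genes.get(cid, set())
        if genes:
            entry_genes[gid] = genes

    g = nx.Graph()
    for genes in entry_genes.values():
        g.add_nodes_from(genes)

    for rel in root.iter("relation"):
        a = entry_genes.get(rel.get("entry1"))
        b = entry_genes.get(rel.get("entry2"))
        if not a or not b:
            continue  # relation touching a non-gene entry
        g.add_edges_from((u, v) for u in a for v in b if u != v)

    dropped = _clean_graph(g)
    if dropped:
        logger.info("parse_kgml(%s): dropped %d self-loop(s)", pathway_name, dropped)
    if g.number_of_nodes() == 0:
        logger.warning("parse_kgml(%s): no gene entries found; empty pathway", pathway_name)
    return PathwayGraph(name=pathway_name, graph=g, source_format="kgml")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def parse_edge_list(
    text: str,
    dialect: str = "tsv",
    name: str = "edge-list",
    header: bool = False,
) -> PathwayGraph:
    """Parse a SIF or two-column TSV edge list.

    SIF records are whitespace-delimited ``source type target [target ...]``;
    TSV records are ``source<TAB>target`` (any whitespace accepted).  Edges
    are deduplicated; self-loops are dropped with a logged count.

    Raises
    ------
    NetworkFormatError
        If a record has fewer than two identifiers (message carries the line
        number) or the dialect is unknown.
    """
    if dialect not in {"sif", "tsv", "edgelist"}:
        raise NetworkFormatError(f"unknown edge-list dialect: {dialect!r}")

    g = nx.Graph()
    n_loops = 0
    lines = text.splitlines()
    start = 1 if header and lines else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        toks = line.split()
        if dialect == "sif":
            if len(toks) < 3:
                if len(toks) == 1:
                    g.add_node(toks[0])  # SIF allows isolated-node records
                    continue
                raise NetworkFormatError(
                    f"{name}: line {lineno}: SIF record needs source, type, target"
                )
            src, targets = toks[0], toks[2:]
        else:
            if len(toks) < 2:
                raise NetworkFormatError(
                    f"{name}: line {lineno}: expected two identifiers, got {len(toks)}"
                )
            src, targets = toks[0], [toks[1]]
        for tgt in targets:
            if src == tgt:
                n_loops += 1
                g.add_node(src)
            else:
                g.add_edge(src, tgt)
    if n_loops:
        logger.info("parse_edge_list(%s): dropped %d self-loop(s)", name, n_loops)
    return PathwayGraph(name=name, graph=g, source_format="sif" if dialect == "sif" else "edgelist")


# ---------------------------------------------------------------------------
# Merging and relabeling
# ---------------------------------------------------------------------------

def merge_networks(pathways: list[PathwayGraph]) -> PPINetwork:
    """Union-merge pathways into one PPI network.

    Nodes are matched by exact identifier equality; node and edge sets are
    unions over the inputs, so merging is idempotent, commutative and
    associative.
    """
    if not pathways:
        raise ValueError("merge_networks: empty pathway list")
    g = nx.Graph()
    for p in pathways:
        g.add_nodes_from(p.graph.nodes)
        g.add_edges_from(p.graph.edges)
    _clean_graph(g)
    return PPINetwork(graph=g, provenance=[p.name for p in pathways])


def read_id_mapping(text: str) -> dict[str, str]:
    """Read a two-column TSV mapping table (source_id -> target_id).

    First mapping wins on duplicated source identifiers.
    """
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        toks = line.split()
        if len(toks) < 2:
            raise NetworkFormatError(f"id-mapping line {lineno}: expected two columns")
        mapping.setdefault(toks[0], toks[1])
    return mapping


def apply_id_mapping(network: PPINetwork, mapping: dict[str, str]) -> PPINetwork:
    """Relabel nodes through a mapping table.

    Unmapped nodes keep their original identifiers (counted in the log).  If
    the mapping collapses distinct nodes onto one identifier their
    neighborhoods are merged; any self-loop so created is dropped.
    """
    unmapped = sum(1 for n in network.graph.nodes if n not in mapping)
    if unmapped:
        logger.info("apply_id_mapping: %d node(s) kept their original identifier", unmapped)
    g = nx.relabel_nodes(network.graph, lambda n: mapping.get(n, n), copy=True)
    _clean_graph(g)
    return PPINetwork(graph=g, provenance=list(network.provenance))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_edge_list(network: PPINetwork, dialect: str = "tsv") -> str:
    """Serialize a network as a sorted edge list.

    Endpoints are written in lexicographic order within each record and
    records are sorted, so output is canonical: ``parse_edge_list`` on the
    result reproduces the network exactly.  Isolated nodes are representable
    only in SIF (single-identifier records); a two-column TSV carries edges
    only, so isolated nodes are dropped from TSV output with a logged count.
    """
    if dialect not in {"sif", "tsv", "edgelist"}:
        raise NetworkFormatError(f"unknown edge-list dialect: {dialect!r}")
    records = []
    for u, v in network.graph.edges:
        a, b = sorted((u, v))
        records.append(f"{a}\tpp\t{b}" if dialect == "sif" else f"{a}\t{b}")
    isolated = sorted(n for n in network.graph.nodes if network.graph.degree(n) == 0)
    if dialect == "sif":
        records.extend(isolated)
    elif isolated:
        logger.info("write_edge_list: %d isolated node(s) not representable in TSV", len(isolated))
    return "\n".join(sorted(records)) + ("\n" if records else "")
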