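"""Pathway networks: KGML parsing, currency-metabolite filtering, reaction graphs.

Curated pathway maps (KEGG KGML or plain edge lists) are turned into
undirected reaction-level networks: nodes are metabolic reactions (or
signaling proteins), and two reactions are joined by an edge when one
produces a metabolite that the other consumes.  Ubiquitous "currency"
metabolites (water, ATP, ...) would create biologically uninformative
edges and are removed by a degree-based policy before the graph is built.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KGMLParseError",
    "PathwayValidationError",
    "ReactionEntry",
    "PathwayDocument",
    "MetaboliteFilterPolicy",
    "PathwayNetwork",
    "parse_kgml",
    "metabolite_degrees",
    "filter_metabolites",
    "build_reaction_network",
    "connected_components",
    "read_edge_list_network",
]


class KGMLParseError(ValueError):
    """Raised when a pathway XML document cannot be parsed."""


class PathwayValidationError(ValueError):
    """Raised when a parsed document violates a structural invariant."""


@dataclass(frozen=True)
class ReactionEntry:
    """One reaction of a pathway document.

    ``gene_ids`` are the genes coding for the enzymes catalyzing the
    reaction; ``substrates``/``products`` are metabolite identifiers.
    """

    reaction_id: str
    gene_ids: frozenset[str]
    substrates: tuple[str, ...]
    products: tuple[str, ...]


@dataclass(frozen=True)
class PathwayDocument:
    """Parsed pathway definition prior to graph construction.

    ``relations`` holds signaling interactions as pairs of entity ids;
    ``entities`` maps each declared protein entity to its gene ids (used
    for signaling-mode networks).
    """

    pathway_id: str
    title: str
    reactions: tuple[ReactionEntry, ...]
    relations: tuple[tuple[str, str], ...] = ()
    entities: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PathwayValidationError(
                f"duplicate reaction ids in pathway {self.pathway_id!r}: {dupes}"
            )
        for a, b in self.relations:
            for end in (a, b):
                if end not in self.entities:
                    raise PathwayValidationError(
                        f"relation endpoint {end!r} is not a declared entity "
                        f"in pathway {self.pathway_id!r}"
                    )

    @property
    def metabolites(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out.update(r.substrates)
            out.update(r.products)
        return out


@dataclass(frozen=True)
class MetaboliteFilterPolicy:
    """Rule deciding which metabolites may form reaction-reaction edges.

    A metabolite is dropped from all substrate/product lists when it takes
    part in more than ``degree_threshold`` reactions of the whole model
    (default 8) unless whitelisted, or when it is blacklisted outright.
    """

    degree_threshold: int = 8
    whitelist: frozenset[str] = frozenset()
    blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.degree_threshold < 1:
            raise ValueError("degree_threshold must be >= 1")
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ValueError(f"whitelist and blacklist overlap: {sorted(overlap)}")

    def removes(self, metabolite: str, degree: int) -> bool:
        if metabolite in self.blacklist:
            return True
        return degree > self.degree_threshold and metabolite not in self.whitelist


@dataclass
class PathwayNetwork:
    """Undirected reaction/protein network with gene annotations.

    ``adjacency`` is the symmetric binary matrix A with A[i, j] = 1 iff
    nodes i and j (in the order of ``nodes``) are joined by an edge.
    """

    pathway_id: str
    nodes: list[str]
    node_genes: dict[str, frozenset[str]]
    adjacency: np.ndarray
    title: str = ""
    kind: str = "metabolic"  # or "signaling"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=np.uint8)
        n = len(self.nodes)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} != ({n}, {n})")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a
        missing = [v for v in self.nodes if v not in self.node_genes]
        for v in missing:  # nodes without annotation keep an empty gene set
            self.node_genes[v] = frozenset()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        idx = np.argwhere(np.triu(self.adjacency, 1))
        return [(self.nodes[i], self.nodes[j]) for i, j in idx]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def subnetwork(self, keep: list[str]) -> "PathwayNetwork":
        pos = {v: i for i, v in enumerate(self.nodes)}
        idx = [pos[v] for v in keep]
        return PathwayNetwork(
            pathway_id=self.pathway_id,
            nodes=list(keep),
            node_genes={v: self.node_genes[v] for v in keep},
            adjacency=self.adjacency[np.ix_(idx, idx)].copy(),
            title=self.title,
            kind=self.kind,
        )


_KNOWN_TAGS = {"pathway", "entry", "reaction", "relation", "substrate", "product",
               "graphics", "component", "subtype", "alt"}


def parse_kgml(xml_text: str) -> PathwayDocument:
    """Parse a KGML (KEGG Markup Language v0.7.1 subset) document.

    Reads ``entry``, ``reaction`` (with ``substrate``/``product`` children)
    and ``relation`` elements; anything else is ignored with a warning.
    Genes are attached to reactions through gene-type entries carrying a
    ``reaction`` attribute.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise KGMLParseError(f"malformed pathway XML at line {line}, column {col}: {exc}") from exc
    if root.tag != "pathway":
        raise PathwayValidationError(f"root element is {root.tag!r}, expected 'pathway'")
    pathway_id = root.get("name") or root.get("id")
    if not pathway_id:
        raise PathwayValidationError("pathway element lacks a 'name' (or 'id') attribute")
    title = root.get("title", "")

    for elem in root.iter():
        if elem.tag not in _KNOWN_TAGS:
            logger.warning("ignoring unknown KGML element <%s> in %s", elem.tag, pathway_id)

    # gene-type entries: provide gene annotations for reactions and the
    # node set for signaling pathways
    entities: dict[str, frozenset[str]] = {}
    reaction_genes: dict[str, set[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        if eid is None:
            continue
        etype = entry.get("type", "")
        genes = frozenset(entry.get("name", "").split()) if etype in ("gene", "ortholog") else frozenset()
        entities[eid] = genes
        rxn_attr = entry.get("reaction")
        if rxn_attr and etype in ("gene", "ortholog"):
            for rname in rxn_attr.split():
                reaction_genes.setdefault(rname, set()).update(genes)

    reactions = []
    for rxn in root.findall("reaction"):
        rname = rxn.get("name") or rxn.get("id")
        if rname is None:
            raise PathwayValidationError(f"reaction without name/id in pathway {pathway_id!r}")
        subs = tuple(s.get("name") or s.get("id", "") for s in rxn.findall("substrate"))
        prods = tuple(p.get("name") or p.get("id", "") for p in rxn.findall("product"))
        genes: set[str] = set()
        for part in rname.split():
            genes.update(reaction_genes.get(part, set()))
        reactions.append(
            ReactionEntry(reaction_id=rname, gene_ids=frozenset(genes),
                          substrates=subs, products=prods)
        )

    relations = []
    for rel in root.findall("relation"):
        a, b = rel.get("entry1"), rel.get("entry2")
        if a is None or b is None:
            raise PathwayValidationError(f"relation missing entry1/entry2 in {pathway_id!r}")
        relations.append((a, b))

    return PathwayDocument(
        pathway_id=pathway_id,
        title=title,
        reactions=tuple(reactions),
        relations=tuple(relations),
        entities=entities,
    )


def metabolite_degrees(docs: list[PathwayDocument]) -> dict[str, int]:
    """Number of reactions each metabolite takes part in, over the whole model.

    A metabolite is counted once per reaction, whether it appears as a
    substrate, a product, or both.
    """
    degrees: dict[str, int] = {}
    for doc in docs:
        for r in doc.reactions:
            for m in set(r.substrates) | set(r.products):
                degrees[m] = degrees.get(m, 0) + 1
    return degrees


def filter_metabolites(
    doc: PathwayDocument,
    policy: MetaboliteFilterPolicy,
    global_metabolite_degrees: dict[str, int],
) -> PathwayDocument:
    """Drop currency metabolites from all substrate/product lists.

    ``global_metabolite_degrees`` must cover every metabolite of ``doc``;
    degrees are global (whole-model), not per pathway.
    """
    missing = sorted(doc.metabolites - set(global_metabolite_degrees))
    if missing:
        raise ValueError(f"metabolites missing from the degree map: {missing}")

    def keep(m: str) -> bool:
        return not policy.removes(m, global_metabolite_degrees[m])

    reactions = tuple(
        replace(
            r,
            substrates=tuple(m for m in r.substrates if keep(m)),
            products=tuple(m for m in r.products if keep(m)),
        )
        for r in doc.reactions
    )
    return replace(doc, reactions=reactions)


def build_reaction_network(doc: PathwayDocument, mode: str = "auto") -> PathwayNetwork:
    """Build the undirected reaction (or signaling) network of a pathway.

    Metabolic mode: one node per reaction; an edge joins reactions i and j
    when a product of one is a substrate of the other.  Signaling mode: one
    node per protein entity; one edge per relation.  ``mode='auto'`` picks
    metabolic when the document declares reactions, signaling otherwise.
    The document should already be metabolite-filtered.
    """
    if mode not in ("auto", "metabolic", "signaling"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "metabolic" if doc.reactions else "signaling"

    if mode == "metabolic":
        nodes = [r.reaction_id for r in doc.reactions]
        node_genes = {r.reaction_id: r.gene_ids for r in doc.reactions}
        n = len(nodes)
        a = np.zeros((n, n), dtype=np.uint8)
        subs = [set(r.substrates) for r in doc.reactions]
        prods = [set(r.products) for r in doc.reactions]
        for i in range(n):
            for j in range(i + 1, n):
                if prods[i] & subs[j] or prods[j] & subs[i]:
                    a[i, j] = a[j, i] = 1
        kind = "metabolic"
    else:
        nodes = sorted(e for e, genes in doc.entities.items() if genes)
        node_genes = {e: doc.entities[e] for e in nodes}
        n = len(nodes)
        pos = {v: i for i, v in enumerate(nodes)}
        a = np.zeros((n, n), dtype=np.uint8)
        for x, y in doc.relations:
            if x in pos and y in pos and x != y:
                a[pos[x], pos[y]] = a[pos[y], pos[x]] = 1
            else:
                logger.debug("skipping relation (%s, %s): non-protein endpoint", x, y)
        kind = "signaling"

    return PathwayNetwork(
        pathway_id=doc.pathway_id, nodes=nodes, node_genes=dict(node_genes),
        adjacency=a, title=doc.title, kind=kind,
    )


def connected_components(net: PathwayNetwork) -> list[PathwayNetwork]:
    """Split a network into its maximal connected subnetworks.

    Components are ordered by decreasing size, ties broken by the
    lexicographically smallest node id; node order inside a component
    follows the parent network.
    """
    comps = [sorted(c) for c in nx.connected_components(net.graph())]
    comps.sort(key=lambda c: (-len(c), c[0]))
    order = {v: i for i, v in enumerate(net.nodes)}
    return [net.subnetwork(sorted(c, key=order.__getitem__)) for c in comps]


def read_edge_list_network(
    edges_tsv: str,
    annotations_tsv: str | None = None,
    pathway_id: str = "edge_list",
    title: str = "",
    kind: str = "metabolic",
) -> PathwayNetwork:
    """Build a network from a plain TSV edge list (node_a<TAB>node_b per line).

    ``annotations_tsv`` optionally maps nodes to comma-separated gene ids
    (node_id<TAB>g1,g2 per line); singleton nodes may be declared there.
    """
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(edges_tsv.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"edge list line {lineno}: expected 2 tab-separated fields")
        edges.append((parts[0], parts[1]))

    node_genes: dict[str, frozenset[str]] = {}
    if annotations_tsv is not None:
        for lineno, line in enumerate(annotations_tsv.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            node = parts[0]
            genes = frozenset(g for g in parts[1].split(",") if g) if len(parts) > 1 else frozenset()
            node_genes[node] = genes

    nodes = sorted({v for e in edges for v in e} | set(node_genes))
    pos = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    for u, v in edges:
        if u != v:
            a[pos[u], pos[v]] = a[pos[v], pos[u]] = 1
    return PathwayNetwork(pathway_id=pathway_id, nodes=nodes, node_genes=node_genes,
                          adjacency=a, title=title, kind=kind)
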