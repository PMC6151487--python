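"""Metabolic pathways as undirected graphs of enzyme and compound nodes.

A pathway graph has two node kinds: *enzyme* nodes carrying a non-empty set
of gene identifiers (the genes coding the catalyzing enzyme), and *compound*
nodes carrying exactly one metabolite (KEGG compound) identifier.  Edges are
undirected and come from reaction structure (enzyme <-> substrate, enzyme <->
product) and, optionally, enzyme-enzyme relations.  All downstream distance
computations treat the graph as undirected; reaction reversibility is
deliberately ignored so that reachability is symmetric.

Two serializations are supported:

* a KGML subset (KEGG pathway markup: ``pathway``, ``entry``, ``reaction``,
  ``relation`` elements), read with :func:`parse_kgml` and written with
  :func:`write_kgml`;
* the pipeline's own JSON exchange format (``format_version`` 1), read and
  written at the collection level.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

from .errors import FormatError, KGMLParseError, ValidationError

logger = logging.getLogger(__name__)

JSON_FORMAT_VERSION = 1

_COMPOUND_ID_RE = re.compile(r"^(cpd:)?C\d{5}$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayNode:
    """One vertex of a pathway graph.

    Parameters
    ----------
    node_id : str
        Identifier unique within the pathway (KGML entry id).
    kind : str
        ``"enzyme"`` or ``"compound"``.
    members : frozenset of str
        Gene ids for an enzyme node; exactly one compound id for a
        compound node.
    label : str
        Display string (EC number, compound name, ...).
    """

    node_id: str
    kind: str
    members: frozenset
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("enzyme", "compound"):
            raise ValidationError(f"node {self.node_id!r}: unknown kind {self.kind!r}")
        if self.kind == "enzyme" and not self.members:
            raise ValidationError(f"enzyme node {self.node_id!r} has no member genes")
        if self.kind == "compound" and len(self.members) != 1:
            raise ValidationError(
                f"compound node {self.node_id!r} must carry exactly one compound id, "
                f"got {sorted(self.members)}"
            )

    @property
    def compound_id(self) -> str:
        if self.kind != "compound":
            raise ValueError(f"node {self.node_id!r} is not a compound node")
        return next(iter(self.members))


@dataclass
class PathwayGraph:
    """One metabolic pathway as an undirected graph."""

    pathway_id: str
    name: str = ""
    nodes: dict = field(default_factory=dict)  # node_id -> PathwayNode
    edges: set = field(default_factory=set)  # frozenset({u, v}) pairs

    def validate(self) -> None:
        for node_id, node in self.nodes.items():
            if node.node_id != node_id:
                raise ValidationError(
                    f"{self.pathway_id}: node key {node_id!r} != node id {node.node_id!r}"
                )
        for edge in self.edges:
            if len(edge) != 2:
                raise ValidationError(f"{self.pathway_id}: self-loop or malformed edge {set(edge)}")
            for endpoint in edge:
                if endpoint not in self.nodes:
                    raise ValidationError(
                        f"{self.pathway_id}: edge endpoint {endpoint!r} is not a declared node"
                    )

    def add_node(self, node: PathwayNode) -> None:
        if node.node_id in self.nodes:
            raise ValidationError(f"{self.pathway_id}: duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def add_edge(self, u: str, v: str) -> None:
        """Add an undirected edge; self-loops are dropped with a warning."""
        if u == v:
            logger.warning("%s: dropping self-loop on node %r", self.pathway_id, u)
            return
        for endpoint in (u, v):
            if endpoint not in self.nodes:
                raise ValidationError(
                    f"{self.pathway_id}: edge references unknown node {endpoint!r}"
                )
        self.edges.add(frozenset((u, v)))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node_id, node in self.nodes.items():
            g.add_node(node_id, kind=node.kind, members=node.members, label=node.label)
        for edge in self.edges:
            u, v = sorted(edge)
            g.add_edge(u, v)
        return g

    @property
    def gene_ids(self) -> set:
        out = set()
        for node in self.nodes.values():
            if node.kind == "enzyme":
                out |= node.members
        return out

    @property
    def compound_ids(self) -> set:
        return {n.compound_id for n in self.nodes.values() if n.kind == "compound"}


@dataclass
class PathwayCollection:
    """A set of pathways plus the annotation universe they induce.

    The background gene / metabolite sets are recomputed on access so they
    can never go stale when pathways are added or edited.
    """

    pathways: list = field(default_factory=list)

    @property
    def background_genes(self) -> set:
        out = set()
        for p in self.pathways:
            out |= p.gene_ids
        return out

    @property
    def background_metabolites(self) -> set:
        out = set()
        for p in self.pathways:
            out |= p.compound_ids
        return out

    def validate(self) -> None:
        seen = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise ValidationError(f"duplicate pathway id {p.pathway_id!r}")
            seen.add(p.pathway_id)
            p.validate()

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self):
        return len(self.pathways)

    def get(self, pathway_id: str) -> PathwayGraph:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


@dataclass
class AnnotatedPathway:
    """A pathway plus the node ids flagged as differential (signature)."""

    graph: PathwayGraph
    signature_nodes: set = field(default_factory=set)

    def validate(self) -> None:
        self.graph.validate()
        unknown = self.signature_nodes - set(self.graph.nodes)
        if unknown:
            raise ValidationError(
                f"{self.graph.pathway_id}: signature nodes not in graph: {sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# KGML subset parsing / writing
# ---------------------------------------------------------------------------

def parse_kgml(
    xml_text: str,
    *,
    include_relations: bool = True,
    strict_compounds: bool = False,
) -> PathwayGraph:
    """Parse the KGML subset into a :class:`PathwayGraph`.

    ``entry`` elements of type ``gene``/``enzyme`` become enzyme nodes whose
    members are the whitespace-split ``name`` attribute; ``compound`` entries
    become compound nodes.  Each ``reaction`` contributes undirected edges
    enzyme<->substrate and enzyme<->product, where the catalyzing enzyme
    entries are those whose ``reaction`` attribute lists the reaction name.
    ``relation`` elements (enzyme-enzyme links) also contribute edges unless
    ``include_relations`` is False.  Duplicate edges collapse; self-loops are
    dropped with a warning.
    """
    try:
        root = etree.fromstring(xml_text.encode() if isinstance(xml_text, str) else xml_text)
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed XML in <pathway> document: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(f"expected root element <pathway>, got <{root.tag}>")

    graph = PathwayGraph(
        pathway_id=root.get("name", "").strip() or root.get("id", "").strip(),
        name=root.get("title", "").strip(),
    )
    if not graph.pathway_id:
        raise KGMLParseError("<pathway> element lacks a name/id attribute")

    reaction_of_entry = {}  # entry id -> set of reaction names it catalyzes
    for entry in root.iter("entry"):
        entry_id = (entry.get("id") or "").strip()
        if not entry_id:
            raise ValidationError("<entry> without id attribute")
        etype = (entry.get("type") or "").strip()
        name = (entry.get("name") or "").strip()
        label = (entry.get("label") or name).strip()
        if etype in ("gene", "enzyme", "ortholog"):
            members = frozenset(tok.strip() for tok in name.split() if tok.strip())
            if not members:
                raise ValidationError(f"<entry id={entry_id!r}> of type {etype!r} lists no genes")
            graph.add_node(PathwayNode(entry_id, "enzyme", members, label))
            rxn = (entry.get("reaction") or "").strip()
            if rxn:
                reaction_of_entry[entry_id] = set(rxn.split())
        elif etype == "compound":
            if not name:
                raise ValidationError(f"<entry id={entry_id!r}> of type compound lists no compound id")
            if strict_compounds and not _COMPOUND_ID_RE.match(name):
                raise ValidationError(
                    f"<entry id={entry_id!r}>: compound id {name!r} does not match C#####"
                )
            graph.add_node(PathwayNode(entry_id, "compound", frozenset({name}), label))
        else:
            logger.debug("%s: skipping entry %s of type %r", graph.pathway_id, entry_id, etype)

    for reaction in root.iter("reaction"):
        rname = (reaction.get("name") or "").strip()
        enzymes = [eid for eid, rxns in reaction_of_entry.items() if rname in rxns]
        explicit = (reaction.get("enzyme") or "").strip()
        if explicit:
            if explicit not in graph.nodes:
                raise ValidationError(
                    f"<reaction name={rname!r}> references unknown enzyme entry {explicit!r}"
                )
            enzymes.append(explicit)
        if not enzymes:
            raise ValidationError(
                f"<reaction name={rname!r}> matches no enzyme entry "
                f"(no entry lists it in its reaction attribute)"
            )
        partners = []
        for child in reaction:
            if child.tag not in ("substrate", "product"):
                continue
            ref = (child.get("id") or "").strip()
            if ref not in graph.nodes:
                raise ValidationError(
                    f"<reaction name={rname!r}>: <{child.tag}> references unknown entry {ref!r}"
                )
            partners.append(ref)
        for enzyme_id in enzymes:
            for ref in partners:
                graph.add_edge(enzyme_id, ref)

    if include_relations:
        for relation in root.iter("relation"):
            e1 = (relation.get("entry1") or "").strip()
            e2 = (relation.get("entry2") or "").strip()
            for ref in (e1, e2):
                if ref not in graph.nodes:
                    raise ValidationError(
                        f"<relation> references unknown entry {ref!r}"
                    )
            graph.add_edge(e1, e2)

    graph.validate()
    return graph


def write_kgml(graph: PathwayGraph) -> str:
    """Serialize a pathway back to the KGML subset (inverse of :func:`parse_kgml`).

    Every edge incident to an enzyme node is emitted as a one-substrate
    reaction catalyzed by that enzyme; enzyme-enzyme edges are emitted as
    ``relation`` elements.  Output element order is sorted, so serialization
    is deterministic.
    """
    root = etree.Element("pathway", name=graph.pathway_id, title=graph.name)
    for node_id in sorted(graph.nodes):
        node = graph.nodes[node_id]
        if node.kind == "enzyme":
            etree.SubElement(
                root, "entry", id=node_id, type="gene",
                name=" ".join(sorted(node.members)), label=node.label,
            )
        else:
            etree.SubElement(
                root, "entry", id=node_id, type="compound",
                name=node.compound_id, label=node.label,
            )
    k = 0
    for edge in sorted(graph.edges, key=sorted):
        u, v = sorted(edge)
        ku, kv = graph.nodes[u].kind, graph.nodes[v].kind
        if ku == "enzyme" and kv == "enzyme":
            etree.SubElement(root, "relation", entry1=u, entry2=v, type="ECrel")
        else:
            enzyme, compound = (u, v) if ku == "enzyme" else (v, u)
            k += 1
            rxn = etree.SubElement(
                root, "reaction", name=f"rn:R{k:05d}", type="reversible", enzyme=enzyme,
            )
            etree.SubElement(rxn, "substrate", id=compound)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# JSON exchange format
# ---------------------------------------------------------------------------

def collection_to_json(collection: PathwayCollection) -> str:
    collection.validate()
    payload = {
        "format_version": JSON_FORMAT_VERSION,
        "pathways": [
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "nodes": [
                    {
                        "node_id": n.node_id,
                        "kind": n.kind,
                        "members": sorted(n.members),
                        "label": n.label,
                    }
                    for n in (p.nodes[i] for i in sorted(p.nodes))
                ],
                "edges": sorted(sorted(e) for e in p.edges),
            }
            for p in sorted(collection.pathways, key=lambda p: p.pathway_id)
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def collection_from_json(text: str) -> PathwayCollection:
    payload = json.loads(text)
    version = payload.get("format_version")
    if version != JSON_FORMAT_VERSION:
        raise FormatError(
            f"unsupported pathway exchange format_version {version!r} "
            f"(expected {JSON_FORMAT_VERSION})"
        )
    collection = PathwayCollection()
    for p in payload["pathways"]:
        graph = PathwayGraph(pathway_id=p["pathway_id"], name=p.get("name", ""))
        for n in p["nodes"]:
            graph.add_node(
                PathwayNode(n["node_id"], n["kind"], frozenset(n["members"]), n.get("label", ""))
            )
        for u, v in p["edges"]:
            graph.add_edge(u, v)
        collection.pathways.append(graph)
    collection.validate()
    return collection


def write_collection(collection: PathwayCollection, path) -> None:
    Path(path).write_text(collection_to_json(collection))


def read_collection(path) -> PathwayCollection:
    return collection_from_json(Path(path).read_text())


def pathway_io_roundtrip(collection: PathwayCollection) -> PathwayCollection:
    """Serialize to the JSON exchange format and parse back (identity check)."""
    return collection_from_json(collection_to_json(collection))


def write_sif(graph: PathwayGraph, path) -> None:
    """Export one pathway as SIF (``node <TAB> link <TAB> node``)."""
    lines = []
    for edge in sorted(graph.edges, key=sorted):
        u, v = sorted(edge)
        lines.append(f"{u}\tlink\t{v}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Signature annotation
# ---------------------------------------------------------------------------

def annotate_signatures(graph: PathwayGraph, genes, metabolites) -> AnnotatedPathway:
    """Flag the nodes mapped by differential genes or metabolites.

    An enzyme node is a signature node iff any of its member genes is
    differential; a compound node iff its compound id is differential.
    Ids absent from the graph are ignored (their count is logged).
    """
    genes = set(genes)
    metabolites = set(metabolites)
    signature = set()
    for node_id, node in graph.nodes.items():
        if node.kind == "enzyme":
            if node.members & genes:
                signature.add(node_id)
        elif node.compound_id in metabolites:
            signature.add(node_id)
    unmapped = len(genes - graph.gene_ids) + len(metabolites - graph.compound_ids)
    if unmapped:
        logger.debug(
            "%s: %d signature ids not annotated to this pathway", graph.pathway_id, unmapped
        )
    return AnnotatedPathway(graph=graph, signature_nodes=signature)
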