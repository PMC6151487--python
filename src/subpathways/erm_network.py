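"""The global disease-related metabolic (ERM) network.

Significant subpathways are merged into one network at gene/metabolite
resolution: every enzyme node is expanded into its individual member genes,
every compound node contributes its metabolite, and an edge joins two
molecules whenever some significant subpathway places them on adjacent
pathway nodes.  Member genes of a single enzyme node share a reaction and
are connected as a clique (switchable).  Each node remembers the set of
parent pathways whose significant subpathways contain it, which drives the
pathway-multiplicity statistics; each edge keeps the set of subpathways
that contributed it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .pathway_model import PathwayCollection

logger = logging.getLogger(__name__)


@dataclass
class ERMNode:
    molecule_id: str
    kind: str  # "gene" | "metabolite"
    is_signature: bool = False
    pathways: set = field(default_factory=set)
    is_prognostic: bool = False


@dataclass
class ERMNetwork:
    nodes: dict = field(default_factory=dict)  # molecule_id -> ERMNode
    edges: dict = field(default_factory=dict)  # frozenset({u,v}) -> set of subpathway ids

    def validate(self) -> None:
        for edge, provenance in self.edges.items():
            if len(edge) != 2:
                raise ValidationError(f"self-loop or malformed edge {set(edge)}")
            if not provenance:
                raise ValidationError(f"edge {sorted(edge)} has empty provenance")
            for endpoint in edge:
                if endpoint not in self.nodes:
                    raise ValidationError(f"edge endpoint {endpoint!r} is not a declared node")
        for node in self.nodes.values():
            if not node.pathways:
                raise ValidationError(f"node {node.molecule_id!r} has no parent pathways")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for mid, node in self.nodes.items():
            g.add_node(
                mid, kind=node.kind, is_signature=node.is_signature,
                is_prognostic=node.is_prognostic, n_pathways=len(node.pathways),
            )
        for edge, provenance in self.edges.items():
            u, v = sorted(edge)
            g.add_edge(u, v, provenance=",".join(sorted(provenance)))
        return g

    @property
    def n_genes(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == "gene")

    @property
    def n_metabolites(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == "metabolite")


def build_erm_network(significant, collection: PathwayCollection, signature=None,
                      isoenzyme_clique: bool = True) -> ERMNetwork:
    """Merge significant subpathways into the molecule-level network.

    Parameters
    ----------
    significant : list of SubpathwayResult
        The FDR-selected subpathways.
    collection : PathwayCollection
        Parent pathways (supplies node membership and adjacency).
    signature : CommonSignature, optional
        Marks molecule nodes as differential.
    isoenzyme_clique : bool
        Link the member genes of one enzyme node pairwise (they catalyze the
        same reaction).  Switch off to keep only cross-node edges.
    """
    network = ERMNetwork()
    if not significant:
        logger.warning("no significant subpathways: returning an empty network")
        return network

    sig_genes = set(signature.selected_genes) if signature is not None else set()
    sig_mets = set(signature.metabolites) if signature is not None else set()

    def molecule_entry(molecule_id, kind, pathway_id):
        node = network.nodes.get(molecule_id)
        if node is None:
            node = ERMNode(
                molecule_id=molecule_id, kind=kind,
                is_signature=(molecule_id in sig_genes if kind == "gene"
                              else molecule_id in sig_mets),
            )
            network.nodes[molecule_id] = node
        node.pathways.add(pathway_id)
        return node

    def add_edge(u, v, subpathway_id):
        if u == v:
            return
        network.edges.setdefault(frozenset((u, v)), set()).add(subpathway_id)

    for result in significant:
        sub = result.subpathway
        graph = collection.get(sub.pathway_id)
        molecules = {}  # pathway node id -> list of molecule ids
        for node_id in sub.node_ids:
            pnode = graph.nodes[node_id]
            if pnode.kind == "enzyme":
                mols = sorted(pnode.members)
                for g in mols:
                    molecule_entry(g, "gene", sub.pathway_id)
                if isoenzyme_clique:
                    for i, g in enumerate(mols):
                        for h in mols[i + 1:]:
                            add_edge(g, h, sub.subpathway_id)
            else:
                mols = [pnode.compound_id]
                molecule_entry(mols[0], "metabolite", sub.pathway_id)
            molecules[node_id] = mols
        for edge in graph.edges:
            u, v = sorted(edge)
            if u in molecules and v in molecules:
                for mu in molecules[u]:
                    for mv in molecules[v]:
                        add_edge(mu, mv, sub.subpathway_id)

    network.validate()
    return network


def mark_prognostic(network: ERMNetwork, prognostic_genes) -> int:
    """Flag network gene nodes found prognostic; returns how many matched."""
    hits = 0
    for node in network.nodes.values():
        node.is_prognostic = node.kind == "gene" and node.molecule_id in set(prognostic_genes)
        hits += node.is_prognostic
    return hits


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def membership_multiplicity(network: ERMNetwork):
    """Per-molecule pathway multiplicity plus the >=2-pathways summary.

    Returns ``(table, summary)`` where the table has one row per molecule
    (molecule_id, kind, n_pathways) and the summary reports, per kind, the
    count and fraction of molecules annotated to at least two pathways.
    """
    rows = [
        {"molecule_id": mid, "kind": node.kind, "n_pathways": len(node.pathways)}
        for mid, node in sorted(network.nodes.items())
    ]
    table = pd.DataFrame(rows, columns=["molecule_id", "kind", "n_pathways"])
    summary = {}
    for kind in ("gene", "metabolite"):
        sub = table[table["kind"] == kind]
        multi = int((sub["n_pathways"] >= 2).sum())
        summary[kind] = {
            "n_total": int(len(sub)),
            "n_multi_pathway": multi,
            "fraction_multi_pathway": multi / len(sub) if len(sub) else 0.0,
        }
    return table, summary


def betweenness_centrality(network: ERMNetwork, normalized: bool = False) -> dict:
    """Unweighted shortest-path betweenness per molecule.

    Unnormalized counts by default (each unordered pair of other nodes
    contributes the fraction of its shortest paths through the node);
    disconnected pairs contribute nothing.
    """
    return dict(nx.betweenness_centrality(network.to_networkx(), normalized=normalized))


def degree_centrality(network: ERMNetwork) -> dict:
    g = network.to_networkx()
    return {node: deg for node, deg in g.degree()}


@dataclass(frozen=True)
class GroupTestResult:
    p_value: float
    statistic: float
    method: str  # "exact" | "asymptotic"


def centrality_group_test(values_a, values_b, alternative: str = "two-sided") -> GroupTestResult:
    """Wilcoxon rank-sum comparison of two centrality samples.

    Exact null enumeration when both groups have at most 12 observations
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = list(values_a)
    b = list(values_b)
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    no_ties = len(set(a) | set(b)) == len(a) + len(b)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True,
    )
    return GroupTestResult(p_value=float(res.pvalue), statistic=float(res.statistic), method=method)


def prognostic_centrality_comparison(network: ERMNetwork, alternative: str = "two-sided"):
    """Compare degree and betweenness of prognostic vs other gene nodes."""
    degrees = degree_centrality(network)
    betweenness = betweenness_centrality(network)
    prog = [m for m, n in network.nodes.items() if n.kind == "gene" and n.is_prognostic]
    other = [m for m, n in network.nodes.items() if n.kind == "gene" and not n.is_prognostic]
    return {
        "degree": centrality_group_test(
            [degrees[m] for m in prog], [degrees[m] for m in other], alternative),
        "betweenness": centrality_group_test(
            [betweenness[m] for m in prog], [betweenness[m] for m in other], alternative),
    }


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_graphml(network: ERMNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)


def write_sif(network: ERMNetwork, path) -> None:
    lines = []
    for edge in sorted(network.edges, key=sorted):
        u, v = sorted(edge)
        lines.append(f"{u}\tlink\t{v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
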