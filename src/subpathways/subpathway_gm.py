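"""Subpathway location by the lenient shortest-path rule, plus joint
gene+metabolite hypergeometric enrichment with Benjamini-Hochberg FDR.

The location rule: two signature nodes belong to the same subpathway when
their unweighted shortest-path distance in the pathway graph is at most the
lenient threshold ``n`` (default 5, i.e. "shorter than n + 1" hops).  The
relation is closed transitively — connected components of the auxiliary
signature-node graph — and each component is completed with every node lying
on any shortest path between any two of its signature nodes, so the reported
region is a connected piece of the pathway map.

Enrichment is scored at the *molecule* level: a subpathway's molecule set is
the union of its enzyme nodes' member genes plus its compound ids, and the
tail probability P(X >= x) of drawing x differential molecules among its m
annotated molecules from a universe of N pathway-annotated molecules
containing K differential ones is computed under the hypergeometric law.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .pathway_model import AnnotatedPathway, PathwayCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubpathwayParams:
    """Tuning knobs of the location/selection step.

    distance_threshold
        Maximum hop distance ``n`` at which two signature nodes merge
        (inclusive; "shorter than n + 1").
    min_nodes
        Smallest subpathway reported.  Unreported in the originating method;
        default 4 and always logged.
    fdr_threshold
        BH FDR cutoff for significance (strict ``<``).
    """

    distance_threshold: int = 5
    min_nodes: int = 4
    fdr_threshold: float = 0.01

    def __post_init__(self):
        if self.distance_threshold < 0:
            raise ConfigurationError("distance_threshold must be >= 0")
        if self.min_nodes < 1:
            raise ConfigurationError("min_nodes must be >= 1")
        if not (0 < self.fdr_threshold <= 1):
            raise ConfigurationError("fdr_threshold must be in (0, 1]")


@dataclass(frozen=True)
class Subpathway:
    """A located connected region of one pathway."""

    subpathway_id: str
    pathway_id: str
    node_ids: frozenset
    signature_node_ids: frozenset

    def __post_init__(self):
        if not self.signature_node_ids <= self.node_ids:
            raise ValidationError(
                f"{self.subpathway_id}: signature nodes not contained in node set"
            )


@dataclass
class SubpathwayResult:
    """A subpathway with its enrichment statistics.

    ``n_molecules`` (m) and ``n_signature`` (x) count individual genes and
    metabolites, not pathway nodes; ``universe_size`` (N) and
    ``universe_signature`` (K) describe the annotation universe.
    """

    subpathway: Subpathway
    n_molecules: int
    n_signature: int
    universe_size: int
    universe_signature: int
    p_value: float
    fdr: float = float("nan")
    degenerate: bool = False
    n_signature_genes: int = 0
    n_signature_metabolites: int = 0
    member_genes: frozenset = frozenset()
    member_metabolites: frozenset = frozenset()


# ---------------------------------------------------------------------------
# Location
# ---------------------------------------------------------------------------

def locate_subpathways(annotated: AnnotatedPathway, params: SubpathwayParams = None) -> list:
    """Locate candidate subpathway regions in one annotated pathway.

    Returns subpathways numbered ``<pathway_id>_1``, ``_2``, ... in
    decreasing node-count order (ties broken by the lexicographically
    smallest node id), after removing candidates smaller than
    ``params.min_nodes``.
    """
    params = params or SubpathwayParams()
    annotated.validate()
    graph = annotated.graph.to_networkx()
    signature = sorted(annotated.signature_nodes)
    if not signature:
        return []

    # One BFS per signature node gives both the pairwise distances and, for
    # any pair (s, t), the on-a-shortest-path test d_s[v] + d_t[v] == d_s[t].
    dist = {s: nx.single_source_shortest_path_length(graph, s) for s in signature}

    n = params.distance_threshold
    aux = nx.Graph()
    aux.add_nodes_from(signature)
    for i, s in enumerate(signature):
        for t in signature[i + 1:]:
            if t in dist[s] and dist[s][t] <= n:
                aux.add_edge(s, t)

    candidates = []
    for component in nx.connected_components(aux):
        members = sorted(component)
        node_set = set(members)
        for i, s in enumerate(members):
            for t in members[i + 1:]:
                if t not in dist[s]:
                    continue
                d_st = dist[s][t]
                node_set.update(
                    v for v in dist[s]
                    if v in dist[t] and dist[s][v] + dist[t][v] == d_st
                )
        if len(node_set) >= params.min_nodes:
            candidates.append((frozenset(node_set), frozenset(component)))

    candidates.sort(key=lambda c: (-len(c[0]), min(c[0])))
    pathway_id = annotated.graph.pathway_id
    return [
        Subpathway(
            subpathway_id=f"{pathway_id}_{k}",
            pathway_id=pathway_id,
            node_ids=nodes,
            signature_node_ids=sig,
        )
        for k, (nodes, sig) in enumerate(candidates, start=1)
    ]


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail(x: int, N: int, K: int, m: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, m), via the survival function."""
    if not (0 <= K <= N and 0 <= m <= N):
        raise ValidationError(f"inconsistent hypergeometric parameters N={N} K={K} m={m}")
    if x <= 0:
        return 1.0
    if x > min(m, K):
        raise ValidationError(f"x={x} exceeds min(m={m}, K={K})")
    return float(stats.hypergeom.sf(x - 1, N, K, m))


def subpathway_molecules(sub: Subpathway, collection: PathwayCollection):
    """(genes, metabolites) of a subpathway, restricted to the universe."""
    graph = collection.get(sub.pathway_id)
    genes, metabolites = set(), set()
    for node_id in sub.node_ids:
        node = graph.nodes[node_id]
        if node.kind == "enzyme":
            genes |= node.members
        else:
            metabolites.add(node.compound_id)
    return (
        genes & collection.background_genes,
        metabolites & collection.background_metabolites,
    )


def enrich_subpathway(sub: Subpathway, collection: PathwayCollection, signature) -> SubpathwayResult:
    """Joint gene+metabolite hypergeometric enrichment of one subpathway.

    The universe is every molecule annotated to any pathway of the
    collection; the differential pool K is the merged signature intersected
    with that universe.  A subpathway with no universe molecules is flagged
    degenerate with p = 1.
    """
    bg_genes = collection.background_genes
    bg_mets = collection.background_metabolites
    sig_genes = set(signature.selected_genes) & bg_genes
    sig_mets = set(signature.metabolites) & bg_mets

    genes, mets = subpathway_molecules(sub, collection)
    hit_genes = genes & sig_genes
    hit_mets = mets & sig_mets

    N = len(bg_genes) + len(bg_mets)
    K = len(sig_genes) + len(sig_mets)
    m = len(genes) + len(mets)
    x = len(hit_genes) + len(hit_mets)

    if m == 0:
        return SubpathwayResult(
            subpathway=sub, n_molecules=0, n_signature=0, universe_size=N,
            universe_signature=K, p_value=1.0, degenerate=True,
        )
    p = hypergeom_tail(x, N, K, m)
    return SubpathwayResult(
        subpathway=sub,
        n_molecules=m,
        n_signature=x,
        universe_size=N,
        universe_signature=K,
        p_value=p,
        n_signature_genes=len(hit_genes),
        n_signature_metabolites=len(hit_mets),
        member_genes=frozenset(genes),
        member_metabolites=frozenset(mets),
    )


# ---------------------------------------------------------------------------
# Multiple testing and selection
# ---------------------------------------------------------------------------

def adjust_fdr(p_values, family_size: int = None) -> list:
    """Benjamini-Hochberg step-up adjusted values.

    ``family_size`` may exceed the list length when the list is a subset of
    a larger tested family (the remaining members' raw p-values are then
    irrelevant to the step-up minimum as long as they rank after the listed
    ones, which holds for a top-k slice).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    M = len(p) if family_size is None else family_size
    if M < len(p):
        raise ConfigurationError(
            f"family_size={M} is smaller than the number of p-values ({len(p)})"
        )
    if p.size == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    scaled = p[order] * M / ranks
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def select_significant(results, fdr_threshold: float = 0.01) -> list:
    """Keep results with FDR strictly below the threshold, sorted by p."""
    kept = [r for r in results if r.fdr < fdr_threshold]
    kept.sort(key=lambda r: (r.p_value, r.subpathway.subpathway_id))
    return kept


def select_significant_table(table: pd.DataFrame, fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Table variant of :func:`select_significant` (for replayed result tables)."""
    kept = table[table["fdr"] < fdr_threshold]
    return kept.sort_values(["p_value", "subpathway_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole-collection driver
# ---------------------------------------------------------------------------

def analyze_collection(collection: PathwayCollection, signature,
                       params: SubpathwayParams = None) -> list:
    """Annotate, locate, enrich, and BH-adjust across a whole collection.

    Returns every candidate tested (not only the significant ones); the BH
    family size is the number of candidates, matching the convention that
    all tested hypotheses enter the correction.
    """
    from .pathway_model import annotate_signatures

    params = params or SubpathwayParams()
    logger.info(
        "locating subpathways: n=%d, min_nodes=%d, fdr<%g",
        params.distance_threshold, params.min_nodes, params.fdr_threshold,
    )
    results = []
    for graph in collection:
        annotated = annotate_signatures(graph, signature.selected_genes, signature.metabolites)
        for sub in locate_subpathways(annotated, params):
            results.append(enrich_subpathway(sub, collection, signature))
    fdrs = adjust_fdr([r.p_value for r in results], family_size=len(results))
    for r, q in zip(results, fdrs):
        r.fdr = q
    return results


def results_table(results, collection: PathwayCollection = None) -> pd.DataFrame:
    """Flatten enrichment results into the exportable TSV layout."""
    rows = []
    for r in results:
        name = ""
        if collection is not None:
            try:
                name = collection.get(r.subpathway.pathway_id).name
            except KeyError:
                pass
        rows.append({
            "subpathway_id": r.subpathway.subpathway_id,
            "pathway_name": name,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "n_nodes": len(r.subpathway.node_ids),
            "n_signature_genes": r.n_signature_genes,
            "n_signature_metabolites": r.n_signature_metabolites,
            "member_genes": ";".join(sorted(r.member_genes)),
            "member_metabolites": ";".join(sorted(r.member_metabolites)),
        })
    return pd.DataFrame(
        rows,
        columns=[
            "subpathway_id", "pathway_name", "p_value", "fdr", "n_nodes",
            "n_signature_genes", "n_signature_metabolites",
            "member_genes", "member_metabolites",
        ],
    )


def load_escc_subpathway_table() -> pd.DataFrame:
    """Packaged reference table: published significant ESCC metabolic
    subpathways with their hypergeometric p-values and BH FDR values."""
    ref = importlib.resources.files("subpathways").joinpath("data/escc_subpathways.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
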