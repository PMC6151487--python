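"""Partitioning the merged metabolic network into modules.

The default detector is a deterministic greedy modularity agglomeration
(Clauset-Newman-Moore style): start from singleton communities and repeatedly
merge the pair of connected communities with the largest modularity gain,
breaking ties by the lexicographically smallest community pair, until no
merge improves modularity.  An import path accepts externally computed
(possibly overlapping) assignments, so module-level statistics can also be
run on partitions from any other community-detection tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .erm_network import ERMNetwork

logger = logging.getLogger(__name__)


@dataclass
class ModuleAssignment:
    modules: dict = field(default_factory=dict)  # module_id -> set of molecule ids
    method: str = "greedy"
    parameters: dict = field(default_factory=dict)

    def module_of(self) -> dict:
        """molecule id -> sorted list of module ids (overlaps allowed)."""
        out = {}
        for module_id, members in self.modules.items():
            for m in members:
                out.setdefault(m, []).append(module_id)
        return {m: sorted(v) for m, v in out.items()}

    def validate(self, network: ERMNetwork) -> None:
        for module_id, members in self.modules.items():
            if not members:
                raise ValidationError(f"module {module_id!r} is empty")
            unknown = set(members) - set(network.nodes)
            if unknown:
                raise ValidationError(
                    f"module {module_id!r} references unknown molecules: {sorted(unknown)}"
                )


@dataclass
class CrosstalkGraph:
    """Meta-graph of modules: edge weight = inter-module network edges."""

    module_ids: list = field(default_factory=list)
    weights: dict = field(default_factory=dict)  # frozenset({a,b}) -> int


# ---------------------------------------------------------------------------
# Greedy modularity agglomeration
# ---------------------------------------------------------------------------

def _greedy_modularity_partition(network: ERMNetwork) -> list:
    """CNM-style agglomeration with lexicographic tie-breaking.

    Modularity of a partition: sum over communities of
    ``L_c/m - (D_c/2m)^2`` with L_c intra-community edges, D_c total degree,
    m total edges.  The merge gain for communities i, j is
    ``L_ij/m - 2 (D_i/2m)(D_j/2m)``.
    """
    g = network.to_networkx()
    m = g.number_of_edges()
    if m == 0:
        return [{node} for node in sorted(g.nodes)]

    # community label = lexicographically smallest member (stable under merges)
    members = {node: {node} for node in g.nodes}
    degree_sum = {node: float(g.degree(node)) for node in g.nodes}
    between = {}  # frozenset({a,b}) -> inter-community edge count
    for u, v in g.edges:
        between[frozenset((u, v))] = between.get(frozenset((u, v)), 0) + 1

    two_m = 2.0 * m
    while True:
        best = None
        for pair, l_ij in between.items():
            a, b = sorted(pair)
            gain = l_ij / m - 2.0 * (degree_sum[a] / two_m) * (degree_sum[b] / two_m)
            key = (-gain, a, b)
            if best is None or key < best[0]:
                best = (key, a, b)
        if best is None:
            break
        (neg_gain, _, _), a, b = best
        if -neg_gain <= 1e-12:
            break
        # merge b into a (a < b lexicographically)
        members[a] |= members.pop(b)
        degree_sum[a] += degree_sum.pop(b)
        merged = {}
        for pair, w in between.items():
            if pair == frozenset((a, b)):
                continue
            pair = frozenset(a if x == b else x for x in pair)
            if len(pair) < 2:
                continue
            merged[pair] = merged.get(pair, 0) + w
        between = merged

    return sorted(members.values(), key=lambda c: (-len(c), min(c)))


def detect_modules(network: ERMNetwork, method: str = "greedy", seed: int = 0,
                   assignment_path=None) -> ModuleAssignment:
    """Partition the network into modules.

    ``method="greedy"`` runs the deterministic modularity agglomeration
    (``seed`` is recorded but unused — the algorithm has no randomness);
    ``method="import"`` reads a TSV assignment from ``assignment_path``.
    Module ids are ``Module_0``, ``Module_1``, ... in decreasing size order.
    """
    if not network.nodes:
        raise ValidationError("cannot detect modules in an empty network")
    if method == "greedy":
        communities = _greedy_modularity_partition(network)
        modules = {f"Module_{k}": set(c) for k, c in enumerate(communities)}
        assignment = ModuleAssignment(modules=modules, method="greedy",
                                      parameters={"seed": seed})
    elif method == "import":
        if assignment_path is None:
            raise ConfigurationError("method='import' requires assignment_path")
        assignment = read_assignment(assignment_path)
    else:
        raise ConfigurationError(f"unknown module detection method {method!r}")
    assignment.validate(network)
    return assignment


# ---------------------------------------------------------------------------
# Module statistics
# ---------------------------------------------------------------------------

def module_summaries(assignment: ModuleAssignment, network: ERMNetwork,
                     prognostic_genes=()) -> pd.DataFrame:
    """Per-module composition counts.

    Columns: ``n_nodes``, ``n_differential_genes``,
    ``n_differential_metabolites``, ``n_pathways`` (distinct parent pathways
    of the members), ``n_prognostic_genes``, ``mean_betweenness`` (mean
    member betweenness, a quantitative proxy for how central a module sits).
    With overlapping assignments a molecule is counted in every module that
    contains it.
    """
    from .erm_network import betweenness_centrality

    assignment.validate(network)
    prognostic = set(prognostic_genes)
    betweenness = betweenness_centrality(network)
    rows = []
    for module_id in sorted(assignment.modules):
        members = assignment.modules[module_id]
        nodes = [network.nodes[m] for m in sorted(members)]
        pathways = set()
        for node in nodes:
            pathways |= node.pathways
        rows.append({
            "module_id": module_id,
            "n_nodes": len(nodes),
            "n_differential_genes": sum(
                1 for n in nodes if n.kind == "gene" and n.is_signature),
            "n_differential_metabolites": sum(
                1 for n in nodes if n.kind == "metabolite" and n.is_signature),
            "n_pathways": len(pathways),
            "n_prognostic_genes": sum(
                1 for n in nodes if n.kind == "gene" and n.molecule_id in prognostic),
            "mean_betweenness": (
                sum(betweenness[n.molecule_id] for n in nodes) / len(nodes)),
        })
    return pd.DataFrame(rows)


def multi_pathway_module_stats(summaries: pd.DataFrame) -> dict:
    """How many modules mix members from at least two distinct pathways."""
    multi = int((summaries["n_pathways"] >= 2).sum())
    total = int(len(summaries))
    return {
        "n_modules": total,
        "n_multi_pathway_modules": multi,
        "fraction_multi_pathway_modules": multi / total if total else 0.0,
    }


def module_crosstalk(assignment: ModuleAssignment, network: ERMNetwork) -> CrosstalkGraph:
    """Module meta-graph: weight = number of network edges between modules."""
    assignment.validate(network)
    module_of = assignment.module_of()
    weights = {}
    for edge in network.edges:
        u, v = sorted(edge)
        for mu in module_of.get(u, []):
            for mv in module_of.get(v, []):
                if mu != mv:
                    key = frozenset((mu, mv))
                    weights[key] = weights.get(key, 0) + 1
    return CrosstalkGraph(module_ids=sorted(assignment.modules), weights=weights)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_assignment(assignment: ModuleAssignment, path) -> None:
    rows = []
    for module_id in sorted(assignment.modules):
        for molecule in sorted(assignment.modules[module_id]):
            rows.append((molecule, module_id))
    rows.sort()
    pd.DataFrame(rows, columns=["molecule_id", "module_id"]).to_csv(path, sep="\t", index=False)


def read_assignment(path) -> ModuleAssignment:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("molecule_id", "module_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    modules = {}
    for _, row in df.iterrows():
        modules.setdefault(row["module_id"], set()).add(row["molecule_id"])
    return ModuleAssignment(modules=modules, method="import",
                            parameters={"path": str(path)})


def write_crosstalk_sif(crosstalk: CrosstalkGraph, path) -> None:
    lines = ["module_a\tinteraction\tmodule_b\tweight"]
    for pair in sorted(crosstalk.weights, key=sorted):
        a, b = sorted(pair)
        lines.append(f"{a}\tcrosstalk\t{b}\t{crosstalk.weights[pair]}")
    Path(path).write_text("\n".join(lines) + "\n")
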