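"""Synthetic study generator: pathway collections, differential signatures
with a planted abnormal region, and survival cohorts with planted prognostic
genes.

The generator emulates the shape of the real inputs — a few dozen metabolic
pathway maps, six differential gene lists from independent expression
datasets, seven metabolite study lists, and a paired tumor/normal cohort
with follow-up — with known ground truth.  One connected region of one
pathway is "planted": its genes and metabolites are called differential at
a high per-dataset rate against a low background rate, so the subpathway
search should recover it.  In the survival cohort a latent binary group per
planted gene shifts that gene's tumor-minus-normal expression and multiplies
the patient's event hazard, so the mean-split log-rank scan should flag the
planted genes.

One global seed fans out to independent substreams (pathways, signatures,
survival) via ``numpy.random.SeedSequence``, so changing one block's
parameters does not perturb the draws of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pathway_model import (
    PathwayCollection, PathwayGraph, PathwayNode, write_collection, write_kgml,
)
from .signatures import (
    GeneDatasetSignature, MetaboliteStudySignature,
    write_gene_signatures, write_metabolite_signatures,
)
from .survival import SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines every output.

    Defaults mirror the structure of the real study inputs: 6 gene
    datasets, 7 metabolite studies, ~5% background differential rate per
    dataset against a 90% rate inside the planted region, and a cohort of
    120 patients with a planted hazard ratio of 3.
    """

    seed: int = 0
    # pathway structure
    n_pathways: int = 8
    nodes_per_pathway: tuple = (18, 30)
    enzyme_fraction: float = 0.5
    genes_per_enzyme: tuple = (1, 3)
    gene_pool_size: int = 240
    compound_pool_size: int = 140
    extra_edge_fraction: float = 0.35
    planted_region_size: int = 6
    # signatures
    n_gene_datasets: int = 6
    background_differential_rate: float = 0.05
    planted_gene_rate: float = 0.9
    n_metabolite_studies: int = 7
    background_metabolite_rate: float = 0.02
    planted_metabolite_rate: float = 0.9
    # survival
    n_patients: int = 120
    baseline_hazard: float = 0.02
    planted_hazard_ratio: float = 3.0
    censoring_rate: float = 0.2
    n_planted_prognostic: int = 3
    expression_shift: float = 3.0

    def __post_init__(self):
        rates = (
            self.enzyme_fraction, self.background_differential_rate,
            self.planted_gene_rate, self.background_metabolite_rate,
            self.planted_metabolite_rate, self.censoring_rate,
        )
        if any(not (0 <= r <= 1) for r in rates):
            raise ConfigurationError("all rates/fractions must lie in [0, 1]")
        if self.planted_region_size < 2:
            raise ConfigurationError("planted_region_size must be >= 2")
        if self.nodes_per_pathway[0] > self.nodes_per_pathway[1]:
            raise ConfigurationError("nodes_per_pathway range is inverted")
        if self.planted_region_size > self.nodes_per_pathway[0]:
            raise ConfigurationError(
                "planted_region_size exceeds the smallest possible pathway"
            )


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic study."""

    planted_pathway_id: str = ""
    planted_node_ids: frozenset = frozenset()
    planted_genes: frozenset = frozenset()
    planted_metabolites: frozenset = frozenset()
    planted_prognostic_genes: frozenset = frozenset()
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_pathway_id": self.planted_pathway_id,
            "planted_node_ids": sorted(self.planted_node_ids),
            "planted_genes": sorted(self.planted_genes),
            "planted_metabolites": sorted(self.planted_metabolites),
            "planted_prognostic_genes": sorted(self.planted_prognostic_genes),
            "parameters": self.parameters,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _substream(config: SyntheticConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[index])


# ---------------------------------------------------------------------------
# Pathway collection
# ---------------------------------------------------------------------------

def _random_pathway(rng, config: SyntheticConfig, pathway_index: int) -> PathwayGraph:
    lo, hi = config.nodes_per_pathway
    n_nodes = int(rng.integers(lo, hi + 1))
    n_enzymes = max(1, round(config.enzyme_fraction * n_nodes))
    n_compounds = n_nodes - n_enzymes
    if n_compounds < 1:
        raise ConfigurationError(
            "enzyme_fraction leaves no compound nodes; every edge must touch a compound"
        )
    pathway_id = f"path:{90000 + pathway_index:05d}"
    graph = PathwayGraph(pathway_id=pathway_id, name=f"synthetic pathway {pathway_index}")

    g_lo, g_hi = config.genes_per_enzyme
    for i in range(n_enzymes):
        k = int(rng.integers(g_lo, g_hi + 1))
        members = rng.choice(config.gene_pool_size, size=k, replace=False)
        graph.add_node(PathwayNode(
            f"e{i:03d}", "enzyme",
            frozenset(f"G{int(m):04d}" for m in members),
            label=f"EC:{pathway_index}.{i}",
        ))
    for i in range(n_compounds):
        cid = int(rng.integers(0, config.compound_pool_size))
        graph.add_node(PathwayNode(
            f"c{i:03d}", "compound", frozenset({f"C{cid:05d}"}), label=f"compound {cid}",
        ))

    # Random spanning tree in which every edge touches >= 1 compound node:
    # start from a compound; an enzyme may only attach to an in-tree compound.
    enzymes = [f"e{i:03d}" for i in range(n_enzymes)]
    compounds = [f"c{i:03d}" for i in range(n_compounds)]
    pending = enzymes + compounds[1:]
    rng.shuffle(pending)
    in_tree = [compounds[0]]
    in_tree_compounds = [compounds[0]]
    for node in pending:
        if node.startswith("e"):
            anchor = in_tree_compounds[int(rng.integers(len(in_tree_compounds)))]
        else:
            anchor = in_tree[int(rng.integers(len(in_tree)))]
        graph.add_edge(node, anchor)
        in_tree.append(node)
        if node.startswith("c"):
            in_tree_compounds.append(node)

    n_extra = round(config.extra_edge_fraction * n_nodes)
    attempts = 0
    while n_extra > 0 and attempts < 50 * n_nodes:
        attempts += 1
        u = compounds[int(rng.integers(n_compounds))]
        v = (enzymes + compounds)[int(rng.integers(n_nodes))]
        if u == v or frozenset((u, v)) in graph.edges:
            continue
        graph.add_edge(u, v)
        n_extra -= 1
    graph.validate()
    return graph


def _connected_region(graph: PathwayGraph, size: int, rng) -> frozenset:
    """A random connected node subset of the requested size (BFS growth)."""
    g = graph.to_networkx()
    start = sorted(g.nodes)[int(rng.integers(g.number_of_nodes()))]
    region = [start]
    frontier = sorted(g.neighbors(start))
    while len(region) < size and frontier:
        nxt = frontier.pop(int(rng.integers(len(frontier))))
        if nxt in region:
            continue
        region.append(nxt)
        frontier.extend(v for v in sorted(g.neighbors(nxt)) if v not in region)
    if len(region) < size:
        raise ConfigurationError("pathway too small for the requested planted region")
    return frozenset(region)


def generate_pathway_collection(config: SyntheticConfig):
    """Generate the collection and plant one connected abnormal region."""
    rng = _substream(config, 0)
    collection = PathwayCollection(
        pathways=[_random_pathway(rng, config, i) for i in range(config.n_pathways)]
    )
    collection.validate()
    planted_pathway = collection.pathways[0]
    region = _connected_region(planted_pathway, config.planted_region_size, rng)
    genes, metabolites = set(), set()
    for node_id in region:
        node = planted_pathway.nodes[node_id]
        if node.kind == "enzyme":
            genes |= node.members
        else:
            metabolites.add(node.compound_id)
    truth = PlantedTruth(
        planted_pathway_id=planted_pathway.pathway_id,
        planted_node_ids=region,
        planted_genes=frozenset(genes),
        planted_metabolites=frozenset(metabolites),
        parameters=dataclasses.asdict(config),
    )
    return collection, truth


# ---------------------------------------------------------------------------
# Differential signatures
# ---------------------------------------------------------------------------

def generate_signature_datasets(collection: PathwayCollection, truth: PlantedTruth,
                                config: SyntheticConfig):
    """Bernoulli differential calls per dataset/study, planted region enriched."""
    rng = _substream(config, 1)
    bg_genes = sorted(collection.background_genes)
    bg_mets = sorted(collection.background_metabolites)
    gene_datasets = []
    for d in range(config.n_gene_datasets):
        called = set()
        for g in bg_genes:
            rate = (config.planted_gene_rate if g in truth.planted_genes
                    else config.background_differential_rate)
            if rng.random() < rate:
                called.add(g)
        gene_datasets.append(GeneDatasetSignature(
            dataset_id=f"DS{d + 1:02d}", genes=frozenset(called),
            platform="microarray" if d < 4 else "rnaseq",
        ))
    metabolite_studies = []
    for s in range(config.n_metabolite_studies):
        called = set()
        for m in bg_mets:
            rate = (config.planted_metabolite_rate if m in truth.planted_metabolites
                    else config.background_metabolite_rate)
            if rng.random() < rate:
                called.add(m)
        metabolite_studies.append(MetaboliteStudySignature(
            study_id=f"MS{s + 1:02d}", metabolites=frozenset(called),
        ))
    return gene_datasets, metabolite_studies


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

def generate_survival_cohort(genes, config: SyntheticConfig, planted_genes=None):
    """Cohort where planted genes carry an expression-linked hazard.

    For each planted gene, patients get an independent latent Bernoulli(1/2)
    group; membership shifts the gene's tumor-minus-normal expression by
    ``expression_shift`` and multiplies the event hazard by
    ``planted_hazard_ratio``.  Event times are exponential; independent
    exponential censoring is calibrated so each patient is censored with
    probability ``censoring_rate`` (0 means fully observed).
    """
    rng = _substream(config, 2)
    genes = sorted(genes)
    if planted_genes is None:
        k = min(config.n_planted_prognostic, len(genes))
        planted_genes = [genes[i] for i in rng.choice(len(genes), size=k, replace=False)]
    planted_genes = sorted(planted_genes)
    missing = set(planted_genes) - set(genes)
    if missing:
        raise ConfigurationError(f"planted prognostic genes not in gene list: {sorted(missing)}")

    n = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    groups = {g: rng.integers(0, 2, size=n) for g in planted_genes}

    expression = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(genes), n)), index=genes, columns=patients,
    )
    for g in planted_genes:
        expression.loc[g] += config.expression_shift * groups[g]

    exponent = np.sum([groups[g] for g in planted_genes], axis=0) if planted_genes else np.zeros(n)
    hazard = config.baseline_hazard * config.planted_hazard_ratio ** exponent
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        c = config.censoring_rate
        # one shared censoring rate, calibrated against the baseline hazard so a
        # baseline patient is censored with probability c; independent of risk
        censor_time = rng.exponential(1.0 / (config.baseline_hazard * c / (1 - c)), size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    time = np.maximum(time, 1e-6)  # follow-up must be strictly positive

    cohort = SurvivalCohort(
        time=pd.Series(time, index=patients, name="time"),
        event=pd.Series(event, index=patients, name="event"),
        expression=expression,
    )
    cohort.validate()
    truth = PlantedTruth(
        planted_prognostic_genes=frozenset(planted_genes),
        parameters=dataclasses.asdict(config),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Whole-study emission
# ---------------------------------------------------------------------------

def write_synthetic_study(out_dir, config: SyntheticConfig) -> dict:
    """Generate and write a complete synthetic study to ``out_dir``.

    Emits the JSON pathway collection, per-pathway KGML, the signature TSVs,
    the cohort TSVs (clinical + tumor-minus-normal expression), and
    ``truth.json``.  Returns the file manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection, truth = generate_pathway_collection(config)
    gene_datasets, metabolite_studies = generate_signature_datasets(collection, truth, config)
    cohort, survival_truth = generate_survival_cohort(
        sorted(collection.background_genes), config)

    manifest = {}
    write_collection(collection, out / "pathways.json")
    manifest["pathways"] = "pathways.json"
    kgml_dir = out / "kgml"
    kgml_dir.mkdir(exist_ok=True)
    for p in collection:
        (kgml_dir / f"{p.pathway_id.replace(':', '_')}.xml").write_text(write_kgml(p))
    write_gene_signatures(gene_datasets, out / "gene_signatures.tsv")
    manifest["gene_signatures"] = "gene_signatures.tsv"
    write_metabolite_signatures(metabolite_studies, out / "metabolite_signatures.tsv")
    manifest["metabolite_signatures"] = "metabolite_signatures.tsv"

    clinical = pd.DataFrame({
        "patient_id": cohort.patients,
        "time": cohort.time.to_numpy(),
        "event": cohort.event.to_numpy().astype(int),
    })
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    manifest["clinical"] = "clinical.tsv"
    cohort.expression.to_csv(out / "expression_diff.tsv", sep="\t")
    manifest["expression"] = "expression_diff.tsv"

    combined = PlantedTruth(
        planted_pathway_id=truth.planted_pathway_id,
        planted_node_ids=truth.planted_node_ids,
        planted_genes=truth.planted_genes,
        planted_metabolites=truth.planted_metabolites,
        planted_prognostic_genes=survival_truth.planted_prognostic_genes,
        parameters=dataclasses.asdict(config),
    )
    (out / "truth.json").write_text(combined.to_json())
    manifest["truth"] = "truth.json"
    return manifest
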