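"""Merging per-dataset differential gene lists and per-study metabolite lists.

Transcriptomic experiments each yield thousands of differential genes, so the
merge is strict: a gene enters the common signature only if it is called
differential in at least ``min_gene_support`` datasets (default 4 of 6).
Metabolomic studies each report only dozens of compounds, so the merge is
lenient: a metabolite enters if it appears in at least ``min_metabolite_support``
studies (default 1, i.e. the plain union).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

PLATFORMS = ("microarray", "rnaseq", "other")


@dataclass(frozen=True)
class GeneDatasetSignature:
    """The differential genes called in one expression dataset."""

    dataset_id: str
    genes: frozenset
    platform: str = "other"

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")


@dataclass(frozen=True)
class MetaboliteStudySignature:
    """The differential metabolites reported by one metabolomic study."""

    study_id: str
    metabolites: frozenset


@dataclass
class CommonSignature:
    """Merged differential signature with per-gene support counts."""

    genes: dict = field(default_factory=dict)  # gene id -> support count
    selected_genes: set = field(default_factory=set)
    metabolites: set = field(default_factory=set)
    min_gene_support: int = 4
    min_metabolite_support: int = 1
    n_gene_datasets: int = 0

    def validate(self) -> None:
        expected = {g for g, c in self.genes.items() if c >= self.min_gene_support}
        if expected != self.selected_genes:
            raise ValidationError("selected_genes inconsistent with support counts")
        if any(c > self.n_gene_datasets for c in self.genes.values()):
            raise ValidationError("a support count exceeds the number of datasets")


def _check_unique_ids(ids, what: str) -> None:
    dupes = [i for i, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(dupes)}")


def case_collision_report(ids) -> dict:
    """Ids that differ only by case — a silent merge hazard worth surfacing."""
    by_fold = {}
    for i in ids:
        by_fold.setdefault(i.casefold(), set()).add(i)
    return {k: sorted(v) for k, v in by_fold.items() if len(v) > 1}


def merge_gene_signatures(datasets, min_support: int = 4) -> CommonSignature:
    """Merge differential gene lists under the >=``min_support``-datasets rule.

    Support counts one per dataset (a gene listed twice in one dataset still
    counts once).  The result is independent of dataset order.
    """
    datasets = list(datasets)
    _check_unique_ids([d.dataset_id for d in datasets], "dataset_id")
    if min_support < 1:
        raise ConfigurationError(f"min_support must be >= 1, got {min_support}")
    if min_support > len(datasets):
        raise ConfigurationError(
            f"min_support={min_support} exceeds the number of datasets ({len(datasets)})"
        )
    support = Counter()
    for d in datasets:
        support.update({g.strip() for g in d.genes})
    collisions = case_collision_report(support)
    if collisions:
        logger.warning("gene ids differing only by case: %s", collisions)
    genes = dict(sorted(support.items()))
    selected = {g for g, c in genes.items() if c >= min_support}
    return CommonSignature(
        genes=genes,
        selected_genes=selected,
        min_gene_support=min_support,
        n_gene_datasets=len(datasets),
    )


def merge_metabolite_signatures(studies, min_support: int = 1) -> set:
    """Merge metabolite study lists; with ``min_support=1`` this is the union."""
    studies = list(studies)
    _check_unique_ids([s.study_id for s in studies], "study_id")
    if min_support < 1:
        raise ConfigurationError(f"min_support must be >= 1, got {min_support}")
    support = Counter()
    for s in studies:
        support.update({m.strip() for m in s.metabolites})
    return {m for m, c in support.items() if c >= min_support}


def build_common_signature(
    gene_datasets,
    metabolite_studies,
    min_gene_support: int = 4,
    min_metabolite_support: int = 1,
) -> CommonSignature:
    """Full merged signature: strict gene rule plus lenient metabolite rule."""
    sig = merge_gene_signatures(gene_datasets, min_gene_support)
    sig.metabolites = merge_metabolite_signatures(metabolite_studies, min_metabolite_support)
    sig.min_metabolite_support = min_metabolite_support
    return sig


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_gene_signatures(path) -> list:
    """Read gene lists from TSV with columns ``dataset_id``, ``gene_id``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("dataset_id", "gene_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    out = []
    for dataset_id, grp in df.groupby("dataset_id", sort=True):
        out.append(
            GeneDatasetSignature(
                dataset_id=str(dataset_id),
                genes=frozenset(g.strip() for g in grp["gene_id"].dropna()),
            )
        )
    return out


def read_metabolite_signatures(path) -> list:
    """Read metabolite lists from TSV with columns ``study_id``, ``compound_id``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("study_id", "compound_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    out = []
    for study_id, grp in df.groupby("study_id", sort=True):
        out.append(
            MetaboliteStudySignature(
                study_id=str(study_id),
                metabolites=frozenset(m.strip() for m in grp["compound_id"].dropna()),
            )
        )
    return out


def write_gene_signatures(datasets, path) -> None:
    rows = []
    for d in sorted(datasets, key=lambda d: d.dataset_id):
        for g in sorted(d.genes):
            rows.append((d.dataset_id, g))
    pd.DataFrame(rows, columns=["dataset_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def write_metabolite_signatures(studies, path) -> None:
    rows = []
    for s in sorted(studies, key=lambda s: s.study_id):
        for m in sorted(s.metabolites):
            rows.append((s.study_id, m))
    pd.DataFrame(rows, columns=["study_id", "compound_id"]).to_csv(path, sep="\t", index=False)
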