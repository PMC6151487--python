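"""Mean-split Kaplan-Meier / log-rank screening for prognostic genes.

For every gene, the cohort's patients are split at the mean of the gene's
tumor-minus-normal log2 expression: strictly above the mean is the high
group, at or below is the low group.  The two groups' survival curves are
compared with the standard log-rank test (chi-square with 1 df from the
observed-minus-expected deaths in the risk-set table), and genes with raw
p < alpha (default 0.05) are declared prognostic.  No multiple-testing
correction is applied to the scan — the screen is deliberately a raw
per-gene filter — though a BH column is attached for reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGeneError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Paired tumor/normal expression with follow-up per patient.

    ``expression`` is genes x patients of tumor-minus-normal log2 values;
    ``time`` (strictly positive, months) and ``event`` (True = death) are
    indexed by the same patient ids.
    """

    time: pd.Series
    event: pd.Series
    expression: pd.DataFrame

    def validate(self) -> None:
        patients = list(self.expression.columns)
        if list(self.time.index) != patients or list(self.event.index) != patients:
            raise ValidationError("time/event index does not match expression columns")
        if (self.time <= 0).any():
            bad = list(self.time.index[self.time <= 0])
            raise ValidationError(f"non-positive follow-up times for patients {bad}")

    @property
    def patients(self) -> list:
        return list(self.expression.columns)


@dataclass(frozen=True)
class GroupSplit:
    gene: str
    threshold: float
    high_group: frozenset
    low_group: frozenset


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    observed: tuple  # (O_high, O_low)
    expected: tuple  # (E_high, E_low)
    variance: float
    degenerate: bool = False


def paired_difference(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Elementwise tumor - normal on the log2 scale (indices must match)."""
    if list(tumor.index) != list(normal.index) or list(tumor.columns) != list(normal.columns):
        bad_genes = sorted(set(tumor.index).symmetric_difference(normal.index))
        bad_patients = sorted(set(tumor.columns).symmetric_difference(normal.columns))
        raise ValidationError(
            f"tumor/normal indexing mismatch; offending genes={bad_genes[:10]} "
            f"patients={bad_patients[:10]}"
        )
    return tumor - normal


def mean_split_groups(values: pd.Series, gene: str = "") -> GroupSplit:
    """Split patients at the mean value; ties at the mean go to the low group."""
    if len(values) < 2:
        raise ValidationError("need at least two patients to split")
    if values.nunique() == 1:
        raise DegenerateGeneError(
            f"gene {gene or values.name!r}: all expression values identical; no split"
        )
    threshold = float(values.mean())
    high = frozenset(values.index[values > threshold])
    low = frozenset(values.index[values <= threshold])
    return GroupSplit(gene=gene or str(values.name), threshold=threshold,
                      high_group=high, low_group=low)


def logrank_test(split: GroupSplit, cohort: SurvivalCohort) -> LogrankResult:
    """Two-group log-rank test from the risk-set table.

    At each distinct event time, the expected deaths in the high group are
    ``d * n_high / n`` and the hypergeometric variance term is
    ``d (n_high/n)(1 - n_high/n)(n - d)/(n - 1)``; censored patients leave
    the risk set after their recorded time (deaths precede censorings at
    ties).  If no variance accumulates (e.g. no events), the result is
    degenerate with p = 1.
    """
    if not split.high_group or not split.low_group:
        raise ValidationError("both groups must be non-empty")
    patients = list(split.high_group | split.low_group)
    time = cohort.time.loc[patients].to_numpy(dtype=float)
    event = cohort.event.loc[patients].to_numpy(dtype=bool)
    in_high = np.array([p in split.high_group for p in patients])

    o_high = 0.0
    e_high = 0.0
    variance = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n_high = (at_risk & in_high).sum()
        dying = event & (time == t)
        d = dying.sum()
        d_high = (dying & in_high).sum()
        o_high += d_high
        e_high += d * n_high / n
        if n > 1:
            variance += d * (n_high / n) * (1 - n_high / n) * (n - d) / (n - 1)

    o_total = float(event.sum())
    o_low = o_total - o_high
    e_low = o_total - e_high
    if variance <= 0:
        return LogrankResult(0.0, 1.0, (o_high, o_low), (e_high, e_low), 0.0, degenerate=True)
    chi_square = (o_high - e_high) ** 2 / variance
    p = float(stats.chi2.sf(chi_square, df=1))
    return LogrankResult(float(chi_square), p, (float(o_high), float(o_low)),
                         (float(e_high), float(e_low)), float(variance))


def kaplan_meier_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier survival curve coordinates (via lifelines)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=bool))
    df = km.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    return df


def km_curves_for_gene(split: GroupSplit, cohort: SurvivalCohort) -> pd.DataFrame:
    """High/low-group KM coordinates for one gene, stacked with a group column."""
    frames = []
    for name, group in (("high", split.high_group), ("low", split.low_group)):
        patients = sorted(group)
        curve = kaplan_meier_curve(cohort.time.loc[patients], cohort.event.loc[patients])
        curve.insert(0, "group", name)
        frames.append(curve)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "gene", split.gene)
    return out


def prognostic_scan(cohort: SurvivalCohort, genes=None, alpha: float = 0.05,
                    bh_column: bool = True) -> pd.DataFrame:
    """Per-gene mean-split log-rank scan.

    Returns one row per gene: ``p_value``, ``chi_square``, ``is_prognostic``
    (raw p < alpha), the group sizes, and ``direction`` (+1 when the high
    expression group has more deaths than expected, -1 otherwise).
    Degenerate genes (constant expression or zero log-rank variance) get
    p = NaN / 1 and are never prognostic.
    """
    cohort.validate()
    if genes is None:
        genes = list(cohort.expression.index)
    else:
        genes = sorted(genes)
        missing = set(genes) - set(cohort.expression.index)
        if missing:
            raise ValidationError(f"genes absent from expression matrix: {sorted(missing)}")
    rows = []
    for gene in genes:
        values = cohort.expression.loc[gene]
        try:
            split = mean_split_groups(values, gene=gene)
        except DegenerateGeneError:
            logger.info("gene %s skipped: constant expression", gene)
            rows.append({
                "gene": gene, "p_value": np.nan, "chi_square": np.nan,
                "n_high": 0, "n_low": len(values), "direction": 0,
                "degenerate": True, "is_prognostic": False,
            })
            continue
        res = logrank_test(split, cohort)
        rows.append({
            "gene": gene, "p_value": res.p_value, "chi_square": res.chi_square,
            "n_high": len(split.high_group), "n_low": len(split.low_group),
            "direction": int(np.sign(res.observed[0] - res.expected[0])),
            "degenerate": res.degenerate,
            "is_prognostic": bool((not res.degenerate) and res.p_value < alpha),
        })
    table = pd.DataFrame(
        rows, columns=["gene", "p_value", "chi_square", "n_high", "n_low",
                       "direction", "degenerate", "is_prognostic"],
    )
    if bh_column and len(table):
        from .subpathway_gm import adjust_fdr

        valid = table["p_value"].notna()
        fdr = pd.Series(np.nan, index=table.index)
        if valid.any():
            fdr[valid] = adjust_fdr(table.loc[valid, "p_value"].tolist())
        table["fdr_reference"] = fdr
    return table


def prognostic_genes(table: pd.DataFrame) -> set:
    return set(table.loc[table["is_prognostic"], "gene"])


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def read_cohort(clinical_path, tumor_path=None, normal_path=None,
                expression_path=None) -> SurvivalCohort:
    """Load a cohort from TSV files.

    Either ``expression_path`` (already tumor-minus-normal) or both
    ``tumor_path`` and ``normal_path`` (paired matrices, differenced here)
    must be given.  The clinical table needs ``patient_id``, ``time``,
    ``event`` columns.
    """
    clinical = pd.read_csv(clinical_path, sep="\t", comment="#")
    for col in ("patient_id", "time", "event"):
        if col not in clinical.columns:
            raise ValidationError(f"{clinical_path}: missing required column {col!r}")
    clinical = clinical.set_index("patient_id")
    if expression_path is not None:
        expression = pd.read_csv(expression_path, sep="\t", index_col=0)
    elif tumor_path is not None and normal_path is not None:
        tumor = pd.read_csv(tumor_path, sep="\t", index_col=0)
        normal = pd.read_csv(normal_path, sep="\t", index_col=0)
        expression = paired_difference(tumor, normal)
    else:
        raise ValidationError("provide expression_path or both tumor_path and normal_path")
    expression.columns = expression.columns.astype(str)
    clinical.index = clinical.index.astype(str)
    missing = set(expression.columns).symmetric_difference(clinical.index)
    if missing:
        raise ValidationError(f"clinical/expression patient mismatch: {sorted(missing)}")
    clinical = clinical.loc[expression.columns]
    cohort = SurvivalCohort(
        time=clinical["time"].astype(float),
        event=clinical["event"].astype(bool),
        expression=expression,
    )
    cohort.validate()
    return cohort
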