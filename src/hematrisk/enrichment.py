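"""Enrichment of clinical risk characteristics across patient clusters.

Cross-tabulates each clinical characteristic (final diagnosis category,
proteinuria, pathological stage and grade, urine cytology) against the
patient clusters, merges sparse categories into the non-life-threatening /
life-threatening grouping when more than 80% of cells hold fewer than five
observations, tests non-random distribution with Pearson's chi-square,
designates clusters low/high risk, and reports the headline low-vs-high
risk percentages with their characteristic-specific denominators (all
patients; UC patients for stage; graded UC patients for grade; patients
with evaluable cytology).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .errors import ConfigError, DegenerateInputError, ParameterError, SchemaError

# characteristic name -> (clinical column, canonical level order)
_CHARACTERISTICS: dict[str, tuple[str, tuple[str, ...]]] = {
    "final_diagnosis": ("final_diagnosis", datasets.DIAGNOSIS_CATEGORIES),
    "proteinuria": ("proteinuria", ("normal", "proteinuria")),
    "stage": ("stage", datasets.STAGES),
    "grade": ("grade", ("grade1", "grade2", "grade3")),
    "cytology": ("cytology", ("benign", "malignant")),
}


@dataclass
class ContingencyTable:
    """Cluster x characteristic-level counts with a merge audit trail."""

    counts: pd.DataFrame
    characteristic: str = ""
    excluded: int = 0
    merge_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ConfigError("negative counts in contingency table")
        self.counts = self.counts.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_fixture(cls, name: str) -> "ContingencyTable":
        """A bundled published cross-table as a ContingencyTable."""
        counts = datasets.load_crosstab(name)
        excluded = 0
        if name == "cytology":
            excluded = sum(datasets.CLUSTER_SIZES.values()) - int(counts.to_numpy().sum())
        return cls(counts=counts, characteristic=name, excluded=excluded)


def build_contingency(
    clinical: pd.DataFrame,
    assignment,
    characteristic: str,
) -> ContingencyTable:
    """Exact cross-tabulation of a characteristic across patient clusters.

    ``assignment`` is a per-patient cluster label Series (or a
    ``ClusterAssignment``). Patients with a missing/ineligible value
    (e.g. insufficient cells for cytology, non-UC patients for stage) are
    excluded and their count recorded.
    """
    if characteristic not in _CHARACTERISTICS:
        raise SchemaError(f"unknown characteristic {characteristic!r}")
    column, levels = _CHARACTERISTICS[characteristic]
    if column not in clinical.columns:
        raise SchemaError(f"clinical table has no column {column!r}")
    labels = getattr(assignment, "labels", assignment)
    labels = labels.reindex(clinical.index)

    values = clinical[column]
    if characteristic == "proteinuria":
        values = values.map(lambda v: "proteinuria" if bool(v) else "normal")
    eligible = values.notna() & values.isin(levels)
    excluded = int((~eligible).sum())

    row_order = list(pd.unique(labels.dropna()))
    counts = pd.crosstab(labels[eligible], values[eligible])
    counts = counts.reindex(index=row_order, columns=list(levels), fill_value=0)
    counts.index.name = "cluster"
    return ContingencyTable(counts=counts, characteristic=characteristic, excluded=excluded)


def merge_if_sparse(
    table: ContingencyTable,
    count_threshold: int = 5,
    cell_fraction: float = 0.8,
    merge_map: dict | None = None,
) -> ContingencyTable:
    """Merge characteristic levels when the table is too sparse to test.

    If strictly more than ``cell_fraction`` of cells hold fewer than
    ``count_threshold`` observations, columns are pooled according to
    ``merge_map`` (fine level -> coarse group; defaults to the
    non-life-threatening / life-threatening diagnosis grouping) and the
    merge is recorded in the trace. Otherwise the table is returned
    unchanged.
    """
    arr = table.counts.to_numpy()
    if arr.size == 0:
        return table
    sparse_frac = float((arr < count_threshold).mean())
    if sparse_frac <= cell_fraction:
        return table
    if merge_map is None:
        if table.characteristic == "stage":
            merge_map = dict(datasets.STAGE_GROUP_MAP)
        else:
            merge_map = dict(datasets.DIAGNOSIS_GROUP_MAP)
    uncovered = [c for c in table.counts.columns if c not in merge_map]
    if uncovered:
        raise ConfigError(f"merge map does not cover columns {uncovered}")
    groups = [merge_map[c] for c in table.counts.columns]
    order = list(dict.fromkeys(groups))
    merged = table.counts.T.groupby(pd.Index(groups, name=table.counts.columns.name)).sum().T
    merged = merged[order]
    trace = list(table.merge_trace) + [
        {
            "rule": f"<{count_threshold} in >{cell_fraction:.0%} of cells",
            "sparse_fraction": sparse_frac,
            "mapping": {c: merge_map[c] for c in table.counts.columns},
        }
    ]
    return ContingencyTable(
        counts=merged,
        characteristic=table.characteristic,
        excluded=table.excluded,
        merge_trace=trace,
    )


@dataclass
class EnrichmentResult:
    """Chi-square test of a cluster x characteristic table."""

    table: ContingencyTable
    statistic: float
    dof: int
    p_value: float
    percentages: pd.DataFrame  # per-row percentage composition


def chi_square(table: ContingencyTable, continuity_correction: bool = False) -> EnrichmentResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the row/column marginals; the p-value from
    the chi-square law with (r-1)(c-1) degrees of freedom. Yates continuity
    correction is optional and only applies to 2x2 tables.
    """
    counts = table.counts
    arr = counts.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateInputError("chi-square needs at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero row or column marginal")
    correction = continuity_correction and arr.shape == (2, 2)
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=correction)
    row_totals = arr.sum(axis=1, keepdims=True)
    percentages = pd.DataFrame(
        100.0 * arr / row_totals, index=counts.index, columns=counts.columns
    )
    return EnrichmentResult(
        table=table, statistic=float(stat), dof=int(dof), p_value=float(p), percentages=percentages
    )


@dataclass
class RiskDesignation:
    """Low/high risk label per cluster with the supporting prevalences."""

    labels: dict
    prevalences: dict
    cohort_prevalence: float
    rule: str

    @property
    def low(self) -> list:
        return [c for c, lab in self.labels.items() if lab == "low"]

    @property
    def high(self) -> list:
        return [c for c, lab in self.labels.items() if lab == "high"]


def designate_from_table(
    table: ContingencyTable, positive_column: str | list, rule_name: str
) -> RiskDesignation:
    """Label clusters high-risk when their prevalence of the positive
    column(s) exceeds the cohort prevalence."""
    cols = [positive_column] if isinstance(positive_column, str) else list(positive_column)
    counts = table.counts
    pos = counts[cols].sum(axis=1)
    tot = counts.sum(axis=1)
    cohort = float(pos.sum()) / float(tot.sum()) if tot.sum() else float("nan")
    labels, prev = {}, {}
    for c in counts.index:
        p = float(pos[c]) / float(tot[c]) if tot[c] else float("nan")
        prev[c] = p
        labels[c] = "high" if np.isfinite(p) and p > cohort else "low"
    return RiskDesignation(labels=labels, prevalences=prev, cohort_prevalence=cohort, rule=rule_name)


def risk_designation(clinical: pd.DataFrame, assignment, rule: str = "proteinuria") -> RiskDesignation:
    """Designate clusters low/high risk from per-patient clinical data.

    Default rule: a cluster is high-risk when its proteinuria prevalence
    exceeds the cohort prevalence. Alternative rule ``"lt_fraction"``: its
    life-threatening-diagnosis fraction exceeds the cohort fraction.
    """
    if rule == "proteinuria":
        table = build_contingency(clinical, assignment, "proteinuria")
        return designate_from_table(table, "proteinuria", rule)
    if rule == "lt_fraction":
        table = build_contingency(clinical, assignment, "final_diagnosis")
        return designate_from_table(table, list(datasets.LT_CATEGORIES), rule)
    raise ParameterError(f"unknown risk rule {rule!r}")


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numer: float, denom: float, ndigits: int = 1) -> float | None:
    if denom == 0:
        return None
    return _round_half_up(100.0 * numer / denom, ndigits)


def headline_percentages(
    tables: dict[str, ContingencyTable], designation: RiskDesignation
) -> dict[str, float | None]:
    """The headline risk proportions, from published-style cross-tables.

    Expects tables keyed ``final_diagnosis, proteinuria, stage, grade,
    cytology``. Percentages are rounded half-up to one decimal (integer
    style for the three share-of-characteristic figures), matching the
    reporting convention. Zero denominators yield ``None``.
    """
    low, high = designation.low, designation.high
    out: dict[str, float | None] = {}

    diag = tables["final_diagnosis"].counts
    lt = diag[list(datasets.LT_CATEGORIES)].sum(axis=1)
    uc = diag[list(datasets.UC_CATEGORIES)].sum(axis=1)
    mi = diag["MI_UC"]
    tot = diag.sum(axis=1)
    out["life_threatening_low"] = _pct(lt[low].sum(), tot[low].sum())
    out["life_threatening_high"] = _pct(lt[high].sum(), tot[high].sum())
    out["mi_uc_low"] = _pct(mi[low].sum(), uc[low].sum())
    out["mi_uc_high"] = _pct(mi[high].sum(), uc[high].sum())
    out["no_diagnosis_in_low"] = _pct(
        diag.loc[low, "no_diagnosis"].sum(), diag["no_diagnosis"].sum(), ndigits=0
    )

    prot = tables["proteinuria"].counts
    out["proteinuria_low"] = _pct(prot.loc[low, "proteinuria"].sum(), prot.loc[low].sum().sum())
    out["proteinuria_high"] = _pct(prot.loc[high, "proteinuria"].sum(), prot.loc[high].sum().sum())
    out["normal_protein_in_low"] = _pct(
        prot.loc[low, "normal"].sum(), prot.loc[low].sum().sum(), ndigits=0
    )

    grade = tables["grade"].counts
    out["grade3_low"] = _pct(grade.loc[low, "grade3"].sum(), grade.loc[low].sum().sum())
    out["grade3_high"] = _pct(grade.loc[high, "grade3"].sum(), grade.loc[high].sum().sum())

    cyto = tables["cytology"].counts
    out["malignant_cytology_low"] = _pct(cyto.loc[low, "malignant"].sum(), cyto.loc[low].sum().sum())
    out["malignant_cytology_high"] = _pct(
        cyto.loc[high, "malignant"].sum(), cyto.loc[high].sum().sum()
    )

    stage = tables["stage"].counts
    if "green" in stage.index:
        out["pta_in_green"] = _pct(stage.loc["green", "pTa"], stage.loc["green"].sum(), ndigits=0)
    return out


def risk_percentages(
    clinical: pd.DataFrame, assignment, designation: RiskDesignation
) -> dict[str, float | None]:
    """Headline low/high-risk percentages from per-patient clinical data."""
    tables = {
        name: build_contingency(clinical, assignment, name)
        for name in ("final_diagnosis", "proteinuria", "stage", "grade", "cytology")
    }
    return headline_percentages(tables, designation)


def mann_whitney(values_a, values_b, alternative: str = "two-sided"):
    """Mann-Whitney U test for a location shift between two samples.

    Uses exact enumeration when both samples have at most 20 observations
    and no ties, otherwise the tie-corrected normal approximation. Returns
    ``(U, p_value)`` with U computed for the first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
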