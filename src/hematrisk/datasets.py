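"""Bundled reference tables from the hematuria biomarker study.

The package ships, as plain TSV, the published per-cluster biomarker
summaries (median and interquartile range for 29 urine/serum biomarkers in
each of five patient clusters), the clinical cross-tables (final diagnosis,
proteinuria, pathological stage and grade, cytology, by patient cluster)
and the reported per-subpopulation classifier panels. These tables are the
calibration source for the synthetic-cohort generator and the input to the
enrichment analysis.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

# Patient clusters in dendrogram (top-to-bottom) order, with published sizes.
CLUSTERS = ("blue", "red", "green", "purple", "gold")
CLUSTER_SIZES = {"blue": 57, "red": 13, "green": 49, "purple": 15, "gold": 23}
# Urothelial-cancer patients per cluster.
CLUSTER_UC = {"blue": 28, "red": 8, "green": 18, "purple": 11, "gold": 15}
LOW_RISK_CLUSTERS = ("blue", "green")
HIGH_RISK_CLUSTERS = ("red", "purple", "gold")

# Final-diagnosis categories and their life-threatening grouping.
DIAGNOSIS_CATEGORIES = (
    "no_diagnosis",
    "benign",
    "stones_inflammation",
    "BPE",
    "other_cancers",
    "NMI_UC",
    "MI_UC",
)
NLT_CATEGORIES = ("no_diagnosis", "benign", "stones_inflammation", "BPE")
LT_CATEGORIES = ("other_cancers", "NMI_UC", "MI_UC")
DIAGNOSIS_GROUP_MAP = {c: ("NLT" if c in NLT_CATEGORIES else "LT") for c in DIAGNOSIS_CATEGORIES}

UC_CATEGORIES = ("NMI_UC", "MI_UC")
NMI_STAGES = ("pTa", "pT1", "CIS")
MI_STAGES = ("pT2a", "pT2b", "pT3a", "pT3b", "pT4a")
STAGES = ("pTa", "pT1", "pT2a", "pT2b", "pT3a", "pT3b", "pT4a", "CIS")
STAGE_GROUP_MAP = {s: ("NMI" if s in NMI_STAGES else "MI") for s in STAGES}

CROSSTAB_FILES = {
    "final_diagnosis": "crosstab_final_diagnosis.tsv",
    "proteinuria": "crosstab_proteinuria.tsv",
    "stage": "crosstab_stage.tsv",
    "grade": "crosstab_grade.tsv",
    "cytology": "crosstab_cytology.tsv",
    "pta_grade": "crosstab_pta_grade.tsv",
}

# Binary split covariates: per-level (n UC, n control) counts in the cohort
# of 80 UC and 77 controls. Rows not summing to the cohort imply patients
# with a missing value for that covariate.
SPLIT_COVARIATES = {
    "smoking": {"smoker": (60, 41), "non_smoker": (20, 36)},
    "gender": {"male": (65, 55), "female": (15, 22)},
    "hx_stone": {"yes": (14, 16), "no": (66, 61)},
    "hx_bpe": {"yes": (14, 16), "no": (66, 61)},
    "antihypertensive": {"yes": (51, 22), "no": (28, 55)},
    "antiplatelet": {"yes": (25, 12), "no": (53, 65)},
    "antiulcer": {"yes": (17, 16), "no": (62, 61)},
}


def _data_path(name: str):
    return resources.files("hematrisk.data").joinpath(name)


def _parse_cell(raw: str) -> tuple[float, bool, bool]:
    """Parse a summary cell into (value, censored '<', below-LOD flag)."""
    s = str(raw).strip()
    if s == "BLOD":
        return (np.nan, False, True)
    if s.startswith("<"):
        return (float(s[1:]), True, False)
    return (float(s), False, False)


def load_biomarker_summaries() -> pd.DataFrame:
    """Long-format per-(cluster, biomarker) summary statistics.

    Returns a DataFrame with columns ``biomarker, block, unit, lod,
    cluster, median, q1, q3`` plus boolean flags ``median_censored,
    q1_censored, q3_censored, below_lod``. ``below_lod`` marks cells whose
    entire interquartile range fell under the assay detection limit.
    """
    df = pd.read_csv(_data_path("biomarker_summaries.tsv"), sep="\t", dtype=str)
    df["lod"] = df["lod"].astype(float)
    for col in ("median", "q1", "q3"):
        parsed = df[col].map(_parse_cell)
        df[col] = [p[0] for p in parsed]
        df[f"{col}_censored"] = [p[1] for p in parsed]
        if col == "median":
            df["below_lod"] = [p[2] for p in parsed]
    return df


def biomarker_blocks(summaries: pd.DataFrame | None = None) -> dict[str, list[str]]:
    """Ordered biomarker blocks (the seven published biomarker clusters)."""
    if summaries is None:
        summaries = load_biomarker_summaries()
    blocks: dict[str, list[str]] = {}
    for _, row in summaries.drop_duplicates("biomarker").iterrows():
        blocks.setdefault(row["block"], []).append(row["biomarker"])
    return blocks


def load_crosstab(name: str) -> pd.DataFrame:
    """A published cluster x characteristic cross-table as an int DataFrame.

    ``name`` is one of ``final_diagnosis, proteinuria, stage, grade,
    cytology, pta_grade``. Rows are the five patient clusters in canonical
    order.
    """
    if name not in CROSSTAB_FILES:
        raise KeyError(f"unknown cross-table {name!r}")
    df = pd.read_csv(_data_path(CROSSTAB_FILES[name]), sep="\t", index_col="cluster")
    return df.astype(int)


def load_reported_classifiers() -> pd.DataFrame:
    """Published winning biomarker panels per subpopulation.

    The ``biomarkers`` column is parsed into a tuple of member names.
    """
    df = pd.read_csv(_data_path("reported_classifiers.tsv"), sep="\t", index_col="subpopulation")
    df["biomarkers"] = df["biomarkers"].map(lambda s: tuple(s.split(",")))
    return df
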