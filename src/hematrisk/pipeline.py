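"""End-to-end risk-stratification pipeline with file I/O and manifests.

Ties the stages together: cohort simulation (or file input), patient
clustering with bootstrap stability, biomarker clustering, constrained
tuple enumeration, per-subpopulation classifier search, and clinical
enrichment. Every run writes a manifest (config snapshot, seeds, stage
timings, input checksums, package version) so any reported number can be
re-derived.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, datasets
from .classify import Subpopulation, search_best, split_subpopulations
from .clustering import agglomerate, bootstrap_stability, cut_tree
from .enrichment import (
    build_contingency,
    chi_square,
    merge_if_sparse,
    risk_designation,
    risk_percentages,
)
from .errors import ParseError
from .feature_space import BiomarkerClustering, count_constrained, count_unconstrained
from .matrix import BiomarkerMatrix
from .synthetic import default_config, generate_cohort

log = logging.getLogger("hematrisk")


@dataclass
class PipelineConfig:
    """Run parameters. Defaults mirror the study protocol: five patient
    clusters, seven biomarker clusters, forests of 1000 trees averaged
    over 100 repetitions, 100 bootstrap resamples."""

    matrix_path: str | None = None
    clinical_path: str | None = None
    k_patients: int = 5
    k_biomarkers: int = 7
    n_trees: int = 1000
    n_repetitions: int = 100
    n_boot: int = 100
    seed: int = 0
    scaled_down: bool = False
    min_cluster_size: int = 10
    tuple_subsample: int | None = None
    split_variables: tuple[str, ...] = tuple(datasets.SPLIT_COVARIATES)
    out_dir: str = "hematrisk_run"

    def effective(self) -> "PipelineConfig":
        """Desk-scale protocol when ``scaled_down`` is set: fewer trees,
        repetitions and bootstrap resamples, and a tuple subsample."""
        if not self.scaled_down:
            return self
        cfg = PipelineConfig(**asdict(self))
        cfg.n_trees = min(cfg.n_trees, 50)
        cfg.n_repetitions = min(cfg.n_repetitions, 3)
        cfg.n_boot = min(cfg.n_boot, 20)
        if cfg.tuple_subsample is None:
            cfg.tuple_subsample = 40
        return cfg


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    version: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **info})

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def read_matrix(path, missing: str = "error") -> BiomarkerMatrix:
    """Read a patient x biomarker CSV/TSV into a validated matrix.

    First column = patient id, header = biomarker names. ``missing``
    selects the NA policy: ``"error"`` rejects the file, ``"median"``
    imputes the per-biomarker median (logged).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: {exc}") from exc
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated patient id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        if missing == "median":
            log.warning("imputing %d missing cells with column medians", int(df.isna().sum().sum()))
            df = df.fillna(df.median())
        else:
            row = df.index[df.isna().any(axis=1)][0]
            raise ParseError(f"{path}: missing value in row {row!r}")
    return BiomarkerMatrix(df)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write reports under ``config.out_dir``."""
    cfg = config.effective()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__, seed=cfg.seed)

    # --- stage: data -----------------------------------------------------
    t0 = time.perf_counter()
    if cfg.matrix_path:
        matrix = read_matrix(cfg.matrix_path)
        manifest.checksums["matrix"] = _sha256(cfg.matrix_path)
        clinical = None
        if cfg.clinical_path:
            clinical = pd.read_csv(cfg.clinical_path, index_col=0)
            manifest.checksums["clinical"] = _sha256(cfg.clinical_path)
    else:
        cohort = generate_cohort(default_config(), seed=cfg.seed)
        matrix, clinical = cohort.matrix, cohort.clinical
        cohort.true_cluster.to_csv(out / "truth.csv")
    matrix.to_csv(out / "matrix.csv")
    if clinical is not None:
        clinical.to_csv(out / "clinical.csv", index_label="patient_id")
    manifest.add_stage("data", time.perf_counter() - t0, n_patients=matrix.shape[0])

    # --- stage: patient clustering ---------------------------------------
    t0 = time.perf_counter()
    patient_dend = agglomerate(matrix, axis="rows")
    patient_assign = cut_tree(patient_dend, cfg.k_patients)
    (out / "patient_dendrogram.newick").write_text(patient_dend.to_newick())
    patient_assign.labels.to_csv(out / "patient_clusters.csv")
    boot = bootstrap_stability(matrix, k=cfg.k_patients, n_boot=cfg.n_boot, seed=cfg.seed + 1)
    pd.Series(boot.scores, name="ari").to_csv(out / "bootstrap_scores.csv", index_label="rep")
    manifest.add_stage(
        "patient_clustering",
        time.perf_counter() - t0,
        k=cfg.k_patients,
        mean_bootstrap_ari=float(np.nanmean(boot.scores)),
    )

    # --- stage: biomarker clustering & feature space ---------------------
    t0 = time.perf_counter()
    biomarker_dend = agglomerate(matrix, axis="columns")
    biomarker_assign = cut_tree(biomarker_dend, cfg.k_biomarkers)
    clustering = BiomarkerClustering.from_assignment(biomarker_assign)
    (out / "biomarker_dendrogram.newick").write_text(biomarker_dend.to_newick())
    (out / "biomarker_clusters.json").write_text(json.dumps(clustering.clusters, indent=2))
    n_constrained = count_constrained(clustering.sizes)
    n_unconstrained = count_unconstrained(matrix.shape[1], cfg.k_biomarkers)
    manifest.add_stage(
        "biomarker_clustering",
        time.perf_counter() - t0,
        sizes=list(clustering.sizes),
        n_constrained_tuples=n_constrained,
        n_unconstrained_subsets=n_unconstrained,
    )

    # --- stage: classification -------------------------------------------
    t0 = time.perf_counter()
    subpops: list[Subpopulation] = []
    if clinical is not None and "uc" in clinical.columns:
        labels = clinical["uc"].astype(bool)
        subpops.append(Subpopulation(name="all", labels=labels))
        for lab in range(1, cfg.k_patients + 1):
            ids = patient_assign.members(lab)
            sp = Subpopulation(name=f"cluster_{lab}", labels=labels.loc[ids])
            if sp.n < cfg.min_cluster_size:
                log.warning("skipping %s: only %d patients (< %d)", sp.name, sp.n, cfg.min_cluster_size)
            elif not sp.trainable:
                log.warning("skipping %s: fewer than 2 patients in one class", sp.name)
            else:
                subpops.append(sp)
        for var in cfg.split_variables:
            if var not in clinical.columns:
                continue
            for sp in split_subpopulations(clinical, var):
                if sp.trainable and sp.n >= cfg.min_cluster_size:
                    subpops.append(sp)
                else:
                    log.warning("skipping untrainable split %s", sp.name)
    reports = {}
    for i, sp in enumerate(subpops):
        rep = search_best(
            matrix,
            sp,
            clustering,
            n_trees=cfg.n_trees,
            n_repetitions=cfg.n_repetitions,
            seed=cfg.seed + 1000 + i,
            tuple_subsample=cfg.tuple_subsample,
        )
        reports[sp.name] = rep
        rep.to_frame().head(50).to_csv(out / f"ranking_{sp.name}.csv", index=False)
    summary = pd.DataFrame(
        {
            "subpopulation": list(reports),
            "n": [r.subpopulation.n for r in reports.values()],
            "n_uc": [r.subpopulation.n_positive for r in reports.values()],
            "biomarkers": [",".join(r.best.tuple.members) for r in reports.values()],
            "mean_error": [r.best.mean_error for r in reports.values()],
            "sd_error": [r.best.sd_error for r in reports.values()],
            "mean_auroc": [r.best.mean_auroc for r in reports.values()],
            "sd_auroc": [r.best.sd_auroc for r in reports.values()],
        }
    )
    summary.to_csv(out / "classifier_summary.csv", index=False)
    manifest.add_stage("classification", time.perf_counter() - t0, subpopulations=list(reports))

    # --- stage: enrichment ------------------------------------------------
    t0 = time.perf_counter()
    if clinical is not None and "final_diagnosis" in clinical.columns:
        designation = risk_designation(clinical, patient_assign, rule="proteinuria")
        percentages = risk_percentages(clinical, patient_assign, designation)
        tests = {}
        for name in ("final_diagnosis", "proteinuria", "stage", "grade", "cytology"):
            table = merge_if_sparse(build_contingency(clinical, patient_assign, name))
            try:
                res = chi_square(table)
                tests[name] = {
                    "statistic": res.statistic,
                    "dof": res.dof,
                    "p_value": res.p_value,
                    "merged": bool(table.merge_trace),
                }
            except Exception as exc:  # degenerate synthetic tables stay reported
                tests[name] = {"error": str(exc)}
        report = {
            "designation": designation.labels,
            "rule": designation.rule,
            "prevalences": designation.prevalences,
            "percentages": percentages,
            "chi_square": tests,
        }
        (out / "enrichment.json").write_text(json.dumps(report, indent=2, default=str))
    manifest.add_stage("enrichment", time.perf_counter() - t0)

    manifest.to_json(out / "manifest.json")
    return manifest
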