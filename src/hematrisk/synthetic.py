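"""Synthetic hematuria-cohort generator.

The original study measured 29 biomarkers in 157 hematuria patients; the
raw per-patient matrix was never deposited. This module rebuilds a cohort
with the same statistical structure from what *was* published: per-cluster
medians and interquartile ranges for every biomarker, and per-cluster
cross-tables of the clinical characteristics.

Each (patient cluster, biomarker) cell is modelled as a log-normal
distribution whose parameters are inverted from the printed quantiles:
``location = ln(median)`` and ``scale = ln(q3/q1) / (2 * z_0.75)`` with
``z_0.75 ~= 0.6745``. The fitted law reproduces the printed median and
the printed quartile ratio q3/q1 exactly; the individual quartiles are
matched exactly only where they are log-symmetric around the median (a
two-parameter law cannot pin three quantiles). Biomarkers are organised in the
seven published correlation blocks; within a block, log-values share a
latent factor giving a configurable intra-block correlation. Values below
a biomarker's limit of detection are replaced by LOD/2 and flagged
censored, which is also how cells printed as "IQR below LOD" are realised
(a point mass at LOD/2 with a small multiplicative jitter).

Clinical covariates are sampled conditionally on the (ground-truth)
cluster from the published cross-tables, either by exact-proportion
assignment (counts reproduced exactly, order randomised) or
multinomially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .errors import CalibrationError, ConfigError
from .matrix import BiomarkerMatrix

#: z-score of the 75th percentile of the standard normal; 2*Z75 ~= 1.349.
Z75 = 0.6744897501960817

#: multiplicative log-scale jitter applied to below-LOD point masses so the
#: generated column is not exactly constant (constant columns are
#: degenerate under Canberra distances).
BLOD_JITTER = 0.05


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    ``location``/``scale`` are cluster x biomarker DataFrames of log-normal
    parameters; ``point_mass`` marks cells realised as an LOD/2 point mass;
    ``lod`` is the per-biomarker detection limit (0 = no censoring);
    ``clinical_freqs`` maps characteristic name to its cluster x level
    count table; ``split_freqs`` maps each binary split covariate to
    per-level (n UC, n control) cohort counts.
    """

    cluster_names: tuple[str, ...]
    cluster_sizes: tuple[int, ...]
    blocks: dict[str, list[str]]
    location: pd.DataFrame
    scale: pd.DataFrame
    point_mass: pd.DataFrame
    lod: pd.Series
    clinical_freqs: dict[str, pd.DataFrame] = field(default_factory=dict)
    split_freqs: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    intra_block_corr: float = 0.6
    clinical_mode: str = "exact"

    def __post_init__(self) -> None:
        if len(self.cluster_names) != len(self.cluster_sizes):
            raise ConfigError("cluster_names and cluster_sizes length mismatch")
        if any(s < 0 for s in self.cluster_sizes):
            raise ConfigError("cluster sizes must be nonnegative")
        if not 0.0 <= self.intra_block_corr < 1.0:
            raise ConfigError("intra_block_corr must be in [0, 1)")
        if self.clinical_mode not in ("exact", "multinomial"):
            raise ConfigError(f"unknown clinical_mode {self.clinical_mode!r}")
        biomarkers = self.biomarkers
        for name, df in (("location", self.location), ("scale", self.scale)):
            missing = set(biomarkers) - set(df.columns)
            if missing:
                raise ConfigError(f"{name} table missing biomarkers {sorted(missing)}")
            arr = df[biomarkers].to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ConfigError(f"non-finite entries in {name} table")
        if (self.scale[biomarkers].to_numpy(dtype=float) < 0).any():
            raise ConfigError("scale parameters must be nonnegative")
        if (self.lod < 0).any():
            raise ConfigError("LOD values must be nonnegative")
        sizes = dict(zip(self.cluster_names, self.cluster_sizes))
        for key in ("final_diagnosis", "proteinuria"):
            if key in self.clinical_freqs:
                tab = self.clinical_freqs[key]
                for c, size in sizes.items():
                    if c in tab.index and int(tab.loc[c].sum()) != size:
                        raise ConfigError(
                            f"clinical table {key!r} row {c!r} sums to "
                            f"{int(tab.loc[c].sum())}, expected cluster size {size}"
                        )

    @property
    def biomarkers(self) -> list[str]:
        return [b for members in self.blocks.values() for b in members]

    @property
    def n_patients(self) -> int:
        return int(sum(self.cluster_sizes))


@dataclass
class SyntheticCohort:
    """A generated cohort: measurements, clinical metadata, ground truth."""

    matrix: BiomarkerMatrix
    clinical: pd.DataFrame
    true_cluster: pd.Series
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.matrix.shape[0]
        if len(self.clinical) != n or len(self.true_cluster) != n:
            raise ConfigError("matrix, clinical table and ground truth disagree on n")


def _cell_scale(median: float, q1: float, q3: float) -> float:
    """Log-normal sigma from printed quartiles (one-sided fallback for q1<=0)."""
    if np.isfinite(q1) and np.isfinite(q3) and q1 > 0:
        if q3 < q1:
            raise CalibrationError(f"q3 {q3} < q1 {q1}")
        return 0.0 if q3 == q1 else math.log(q3 / q1) / (2 * Z75)
    if np.isfinite(q3) and q3 > median > 0:
        return math.log(q3 / median) / Z75
    return 0.0


def calibrate_from_tables(
    summaries: pd.DataFrame | None = None,
    *,
    cluster_sizes: dict[str, int] | None = None,
    intra_block_corr: float = 0.6,
    clinical_mode: str = "exact",
    include_clinical: bool = True,
) -> CohortConfig:
    """Build a :class:`CohortConfig` from per-cluster median/IQR summaries.

    ``summaries`` defaults to the bundled published table (long format as
    returned by :func:`hematrisk.datasets.load_biomarker_summaries`).
    Censored medians (printed "<LOD") are anchored at the detection limit;
    "IQR below LOD" cells become an LOD/2 point mass.
    """
    if summaries is None:
        summaries = datasets.load_biomarker_summaries()
    if cluster_sizes is None:
        cluster_sizes = dict(datasets.CLUSTER_SIZES)
    blocks = datasets.biomarker_blocks(summaries)
    biomarkers = [b for members in blocks.values() for b in members]
    clusters = list(cluster_sizes)

    loc = pd.DataFrame(np.nan, index=clusters, columns=biomarkers)
    scale = pd.DataFrame(np.nan, index=clusters, columns=biomarkers)
    point = pd.DataFrame(False, index=clusters, columns=biomarkers)
    lod = summaries.drop_duplicates("biomarker").set_index("biomarker")["lod"]
    lod = lod.reindex(biomarkers)

    for _, row in summaries.iterrows():
        c, b = row["cluster"], row["biomarker"]
        if c not in cluster_sizes:
            continue
        cell = f"({c}, {b})"
        if row["below_lod"]:
            if not row["lod"] > 0:
                raise CalibrationError(f"cell {cell} is below LOD but no LOD is configured")
            loc.loc[c, b] = math.log(row["lod"] / 2.0)
            scale.loc[c, b] = BLOD_JITTER
            point.loc[c, b] = True
            continue
        m = row["median"]
        if not (np.isfinite(m) and m > 0):
            raise CalibrationError(f"cell {cell}: median {m!r} is not positive")
        loc.loc[c, b] = math.log(m)
        try:
            scale.loc[c, b] = _cell_scale(m, row["q1"], row["q3"])
        except CalibrationError as exc:
            raise CalibrationError(f"cell {cell}: {exc}") from None

    clinical_freqs: dict[str, pd.DataFrame] = {}
    split_freqs: dict[str, dict[str, tuple[int, int]]] = {}
    if include_clinical:
        clinical_freqs = {name: datasets.load_crosstab(name) for name in datasets.CROSSTAB_FILES}
        split_freqs = {k: dict(v) for k, v in datasets.SPLIT_COVARIATES.items()}

    return CohortConfig(
        cluster_names=tuple(clusters),
        cluster_sizes=tuple(int(cluster_sizes[c]) for c in clusters),
        blocks=blocks,
        location=loc,
        scale=scale,
        point_mass=point,
        lod=lod.astype(float),
        clinical_freqs=clinical_freqs,
        split_freqs=split_freqs,
        intra_block_corr=intra_block_corr,
        clinical_mode=clinical_mode,
    )


def apply_lod(matrix: BiomarkerMatrix, lod: pd.Series) -> BiomarkerMatrix:
    """Censor values below the per-biomarker detection limit at LOD/2.

    Values ``v < lod`` are stored as ``lod / 2`` with the censoring flag
    set; values at or above the limit (and biomarkers with ``lod == 0``)
    are unchanged.
    """
    if (lod < 0).any():
        raise ConfigError("LOD values must be nonnegative")
    values = matrix.values.copy()
    censored = matrix.censored.copy()
    for b in values.columns:
        limit = float(lod.get(b, 0.0))
        if limit <= 0:
            continue
        below = values[b] < limit
        values.loc[below, b] = limit / 2.0
        censored.loc[below, b] = True
    return BiomarkerMatrix(values, censored)


def _allocate_exact(levels: list, counts: np.ndarray, n: int, rng) -> np.ndarray:
    """Assign exactly `counts[i]` patients to `levels[i]`, in random order."""
    if int(counts.sum()) != n:
        raise ConfigError(f"counts {counts.tolist()} do not sum to group size {n}")
    out = np.repeat(np.asarray(levels, dtype=object), counts.astype(int))
    return rng.permutation(out)


def _allocate(levels: list, counts: np.ndarray, n: int, rng, mode: str) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=object)
    counts = np.asarray(counts, dtype=float)
    if mode == "exact":
        return _allocate_exact(levels, counts, n, rng)
    total = counts.sum()
    p = np.full(len(levels), 1.0 / len(levels)) if total == 0 else counts / total
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=p)


def _draw_cluster_block(rng, loc, scales, n, rho):
    """Correlated log-normal draws for one (cluster, block): n x len(loc)."""
    k = len(loc)
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * eps
    return np.exp(loc[None, :] + scales[None, :] * z)


def generate_cohort(config: CohortConfig, seed: int = 0) -> SyntheticCohort:
    """Draw a full synthetic cohort. Deterministic given ``seed``.

    The biomarker matrix is drawn per (ground-truth cluster, biomarker)
    from the calibrated log-normal laws with intra-block correlation, then
    LOD-censored. Clinical covariates are drawn from the cluster-conditional
    frequency tables; binary split covariates (smoking, gender, histories,
    medications) are drawn conditionally on urothelial-cancer status from
    the published cohort totals. Patient order is randomised so row order
    carries no cluster information.
    """
    rng = np.random.default_rng(seed)
    biomarkers = config.biomarkers
    n = config.n_patients
    width = max(3, len(str(max(n, 1))))
    ids = pd.Index([f"P{i + 1:0{width}d}" for i in range(n)], name="patient_id")

    labels = np.repeat(
        np.asarray(config.cluster_names, dtype=object), np.asarray(config.cluster_sizes, dtype=int)
    )
    values = np.empty((n, len(biomarkers)), dtype=float)
    offset = 0
    for c, size in zip(config.cluster_names, config.cluster_sizes):
        col = 0
        for members in config.blocks.values():
            locs = config.location.loc[c, members].to_numpy(dtype=float)
            scales = config.scale.loc[c, members].to_numpy(dtype=float)
            block = _draw_cluster_block(rng, locs, scales, size, config.intra_block_corr)
            values[offset : offset + size, col : col + len(members)] = block
            col += len(members)
        offset += size

    clinical = _draw_clinical(config, labels, rng)

    # shuffle patient order so cluster blocks are not contiguous
    perm = rng.permutation(n)
    values = values[perm]
    labels = labels[perm]
    clinical = clinical.iloc[perm].set_index(ids) if n else clinical.set_index(ids)

    matrix = BiomarkerMatrix(pd.DataFrame(values, index=ids, columns=biomarkers))
    matrix = apply_lod(matrix, config.lod)
    true = pd.Series(labels, index=ids, name="true_cluster")
    return SyntheticCohort(matrix=matrix, clinical=clinical, true_cluster=true, seed=seed)


def _draw_clinical(config: CohortConfig, labels: np.ndarray, rng) -> pd.DataFrame:
    """Cluster-conditional clinical covariates for patients in `labels` order."""
    n = len(labels)
    mode = config.clinical_mode
    freqs = config.clinical_freqs
    out = pd.DataFrame(index=pd.RangeIndex(n))
    out["cluster"] = labels
    if not freqs or n == 0:
        if freqs:
            for col in ("final_diagnosis", "group", "stage", "grade", "cytology"):
                out[col] = pd.Series(dtype=object)
            out["proteinuria"] = pd.Series(dtype=bool)
            out["uc"] = pd.Series(dtype=bool)
        return out.drop(columns="cluster")

    diag = np.empty(n, dtype=object)
    stage = np.full(n, None, dtype=object)
    grade = np.full(n, None, dtype=object)
    cyto = np.empty(n, dtype=object)
    prot = np.zeros(n, dtype=bool)

    diag_tab = freqs["final_diagnosis"]
    prot_tab = freqs["proteinuria"]
    cyto_tab = freqs["cytology"]
    stage_tab = freqs.get("stage")
    grade_tab = freqs.get("grade")
    pta_tab = freqs.get("pta_grade")

    for c in config.cluster_names:
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        diag[idx] = _allocate(
            list(diag_tab.columns), diag_tab.loc[c].to_numpy(), idx.size, rng, mode
        )
        p_counts = prot_tab.loc[c].to_numpy()
        prot[idx] = (
            _allocate(["normal", "proteinuria"], p_counts, idx.size, rng, mode) == "proteinuria"
        )
        # cytology: patients beyond the evaluable total had insufficient cells
        c_counts = np.append(cyto_tab.loc[c].to_numpy(), idx.size - cyto_tab.loc[c].sum())
        if c_counts[-1] < 0:
            raise ConfigError(f"cytology counts exceed cluster size for {c!r}")
        cyto[idx] = _allocate(
            list(cyto_tab.columns) + ["insufficient"], c_counts, idx.size, rng, mode
        )

        # stage among UC patients, split into non-muscle/muscle invasive
        if stage_tab is not None:
            nmi_idx = idx[diag[idx] == "NMI_UC"]
            mi_idx = idx[diag[idx] == "MI_UC"]
            nmi_stages = [s for s in stage_tab.columns if s in datasets.NMI_STAGES]
            mi_stages = [s for s in stage_tab.columns if s in datasets.MI_STAGES]
            if mode == "multinomial":
                if nmi_idx.size:
                    stage[nmi_idx] = _allocate(
                        nmi_stages, stage_tab.loc[c, nmi_stages].to_numpy(), nmi_idx.size, rng, mode
                    )
                if mi_idx.size:
                    stage[mi_idx] = _allocate(
                        mi_stages, stage_tab.loc[c, mi_stages].to_numpy(), mi_idx.size, rng, mode
                    )
            else:
                stage[nmi_idx] = _allocate(
                    nmi_stages, stage_tab.loc[c, nmi_stages].to_numpy(), nmi_idx.size, rng, mode
                )
                stage[mi_idx] = _allocate(
                    mi_stages, stage_tab.loc[c, mi_stages].to_numpy(), mi_idx.size, rng, mode
                )

        # grade among staged UC: pTa tumours from their own grade table,
        # CIS ungraded, remaining stages from the residual grade counts
        if grade_tab is not None and pta_tab is not None and stage_tab is not None:
            grades = list(grade_tab.columns)
            pta_idx = idx[stage[idx] == "pTa"]
            other_idx = idx[
                np.isin(stage[idx].astype(object), [s for s in datasets.STAGES if s not in ("pTa", "CIS")])
            ]
            if pta_idx.size:
                grade[pta_idx] = _allocate(
                    grades, pta_tab.loc[c].to_numpy(), pta_idx.size, rng, mode
                )
            if other_idx.size:
                residual = grade_tab.loc[c].to_numpy() - pta_tab.loc[c].to_numpy()
                residual = np.clip(residual, 0, None)
                if mode == "exact" and residual.sum() != other_idx.size:
                    residual = grade_tab.loc[c].to_numpy()  # fall back to marginal
                    grade[other_idx] = _allocate(grades, residual, other_idx.size, rng, "multinomial")
                else:
                    grade[other_idx] = _allocate(grades, residual, other_idx.size, rng, mode)

    out["final_diagnosis"] = diag
    out["group"] = [datasets.DIAGNOSIS_GROUP_MAP[d] for d in diag]
    out["uc"] = np.isin(diag.astype(object), list(datasets.UC_CATEGORIES))
    out["stage"] = stage
    out["grade"] = grade
    out["cytology"] = cyto
    out["proteinuria"] = prot

    # cohort-wide binary splits conditional on UC status
    uc_mask = out["uc"].to_numpy()
    for var, levels in config.split_freqs.items():
        col = np.full(n, None, dtype=object)
        names = list(levels)
        uc_counts = np.array([levels[name][0] for name in names], dtype=float)
        ct_counts = np.array([levels[name][1] for name in names], dtype=float)
        for mask, counts in ((uc_mask, uc_counts), (~uc_mask, ct_counts)):
            g = np.flatnonzero(mask)
            if g.size == 0:
                continue
            if mode == "exact":
                filled = counts.copy()
                missing = g.size - counts.sum()
                if missing < 0:
                    # stratum smaller than published counts: rescale proportionally
                    col[g] = _allocate(names, counts, g.size, rng, "multinomial")
                    continue
                col[g] = _allocate(names + [None], np.append(filled, missing), g.size, rng, mode)
            else:
                col[g] = _allocate(names, counts, g.size, rng, mode)
        out[var] = col
    return out.drop(columns="cluster")


def default_config(**kwargs) -> CohortConfig:
    """The study-condition configuration: 157 patients in five clusters of
    sizes (57, 13, 49, 15, 23), 29 biomarkers in the seven published blocks,
    calibrated from the bundled summary tables."""
    return calibrate_from_tables(**kwargs)
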