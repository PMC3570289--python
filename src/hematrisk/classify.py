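"""Out-of-bag random-forest evaluation of biomarker tuples.

Every candidate feature tuple (one biomarker per biomarker cluster) is
scored on a patient subpopulation with a random forest: each tree is
trained on a bootstrap sample that omits roughly one third of the
patients, and each patient is classified by the majority vote of the
trees for which they were out-of-bag (OOB). The OOB classification error
and the AUROC of the OOB positive-vote fractions are averaged over
independent forest repetitions; the winning tuple per subpopulation
maximises mean OOB AUROC (ties broken by minimal mean error, then
lexicographic tuple order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .errors import EvaluationError, SchemaError
from .feature_space import BiomarkerClustering, FeatureTuple, enumerate_tuples
from .matrix import BiomarkerMatrix


@dataclass
class Subpopulation:
    """A named patient subset with binary class labels (True = UC)."""

    name: str
    labels: pd.Series  # index = patient ids, values = bool

    @property
    def patient_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def trainable(self) -> bool:
        """Both classes represented by at least two patients."""
        pos = self.n_positive
        return pos >= 2 and (self.n - pos) >= 2


@dataclass
class TupleEvaluation:
    """OOB error/AUROC summary for one tuple on one subpopulation."""

    tuple: FeatureTuple
    mean_error: float
    sd_error: float
    mean_auroc: float
    sd_auroc: float
    n_repetitions: int
    n_trees: int


@dataclass
class SubpopulationReport:
    """Ranking of all evaluated tuples for one subpopulation."""

    subpopulation: Subpopulation
    ranking: list[TupleEvaluation] = field(default_factory=list)

    @property
    def best(self) -> TupleEvaluation:
        return self.ranking[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.ranking) + 1),
                "biomarkers": [",".join(e.tuple.members) for e in self.ranking],
                "mean_error": [e.mean_error for e in self.ranking],
                "sd_error": [e.sd_error for e in self.ranking],
                "mean_auroc": [e.mean_auroc for e in self.ranking],
                "sd_auroc": [e.sd_auroc for e in self.ranking],
            }
        )


def _repetition_seed(master_seed: int, *counters: int) -> int:
    """Deterministic per-repetition seed from a counter-based stream."""
    ss = np.random.SeedSequence([int(master_seed), *[int(c) for c in counters]])
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_tuple(
    matrix: BiomarkerMatrix,
    subpop: Subpopulation,
    feature_tuple: FeatureTuple,
    n_trees: int = 1000,
    n_repetitions: int = 100,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> TupleEvaluation:
    """OOB error and AUROC of a random forest on one biomarker tuple.

    Per repetition an independent forest of ``n_trees`` trees is trained on
    the tuple's columns restricted to the subpopulation. Patients that were
    in-bag for every tree abstain and are excluded from that repetition's
    error and AUROC. Deterministic given ``seed``; invariant to patient row
    order (rows are canonicalised by sorted patient id before training).
    """
    missing = [b for b in feature_tuple if b not in matrix.col_ids]
    if missing:
        raise SchemaError(f"tuple members not in matrix: {missing}")
    if not subpop.trainable:
        raise EvaluationError(
            f"subpopulation {subpop.name!r} needs >= 2 patients in each class "
            f"(n={subpop.n}, positives={subpop.n_positive})"
        )
    ids = subpop.patient_ids.sort_values()
    X = matrix.values.loc[ids, list(feature_tuple)].to_numpy(dtype=float)
    y = subpop.labels.loc[ids].to_numpy(dtype=int)

    errors = np.full(n_repetitions, np.nan)
    aurocs = np.full(n_repetitions, np.nan)
    for rep in range(n_repetitions):
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            oob_score=True,
            bootstrap=True,
            n_jobs=1,
            random_state=_repetition_seed(seed, rep),
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*out-of-bag.*")
            warnings.filterwarnings("ignore", message=".*OOB.*")
            clf.fit(X, y)
        oob = clf.oob_decision_function_
        voted = np.isfinite(oob).all(axis=1) & (oob.sum(axis=1) > 0)
        if not voted.any():
            continue
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        pred = clf.classes_[np.argmax(oob[voted], axis=1)]
        errors[rep] = float(np.mean(pred != y[voted]))
        yv = y[voted]
        if len(np.unique(yv)) == 2:
            aurocs[rep] = float(roc_auc_score(yv, oob[voted, pos_col]))

    ddof = 1 if n_repetitions > 1 else 0
    return TupleEvaluation(
        tuple=feature_tuple,
        mean_error=float(np.nanmean(errors)),
        sd_error=float(np.nanstd(errors, ddof=ddof)) if np.isfinite(errors).sum() > ddof else 0.0,
        mean_auroc=float(np.nanmean(aurocs)) if np.isfinite(aurocs).any() else float("nan"),
        sd_auroc=float(np.nanstd(aurocs, ddof=ddof)) if np.isfinite(aurocs).sum() > ddof else 0.0,
        n_repetitions=n_repetitions,
        n_trees=n_trees,
    )


def _ranking_key(ev: TupleEvaluation):
    auroc = ev.mean_auroc if np.isfinite(ev.mean_auroc) else -1.0
    error = ev.mean_error if np.isfinite(ev.mean_error) else 2.0
    return (-auroc, error, ev.tuple.members)


def search_best(
    matrix: BiomarkerMatrix,
    subpop: Subpopulation,
    clustering: BiomarkerClustering,
    n_trees: int = 1000,
    n_repetitions: int = 100,
    seed: int = 0,
    tuple_subsample: int | None = None,
) -> SubpopulationReport:
    """Exhaustive cluster-constrained tuple search for one subpopulation.

    Evaluates every one-per-cluster tuple (or a deterministic random
    subsample of ``tuple_subsample`` tuples for desk-scale runs) and ranks
    by mean OOB AUROC, tie-broken by mean error then tuple order.
    """
    candidates = list(enumerate_tuples(clustering))
    if tuple_subsample is not None and tuple_subsample < len(candidates):
        rng = np.random.default_rng(_repetition_seed(seed, 0xFEED))
        idx = np.sort(rng.choice(len(candidates), size=tuple_subsample, replace=False))
        candidates = [candidates[i] for i in idx]
    evaluations = [
        evaluate_tuple(
            matrix,
            subpop,
            t,
            n_trees=n_trees,
            n_repetitions=n_repetitions,
            seed=_repetition_seed(seed, i),
        )
        for i, t in enumerate(candidates)
    ]
    evaluations.sort(key=_ranking_key)
    return SubpopulationReport(subpopulation=subpop, ranking=evaluations)


def tuple_overlap(a: FeatureTuple, b: FeatureTuple) -> int:
    """Number of biomarkers shared by two tuples (set intersection size)."""
    return len(set(a.members) & set(b.members))


def split_subpopulations(
    clinical: pd.DataFrame, variable: str, label_column: str = "uc"
) -> tuple[Subpopulation, Subpopulation]:
    """Split a cohort into two subpopulations on a binary covariate.

    Patients with a missing value for ``variable`` are excluded. Returns
    one subpopulation per level (level order = sorted observed values,
    which makes the split deterministic); a level with no patients yields
    an empty, untrainable subpopulation.
    """
    if variable not in clinical.columns:
        raise SchemaError(f"clinical table has no column {variable!r}")
    if label_column not in clinical.columns:
        raise SchemaError(f"clinical table has no column {label_column!r}")
    col = clinical[variable]
    present = col.notna()
    levels = sorted(col[present].unique())
    if len(levels) > 2:
        raise SchemaError(f"variable {variable!r} has {len(levels)} levels; expected <= 2")
    while len(levels) < 2:
        levels.append(None)
    subpops = []
    for level in levels:
        mask = present & (col == level) if level is not None else pd.Series(False, index=clinical.index)
        labels = clinical.loc[mask, label_column].astype(bool)
        subpops.append(Subpopulation(name=f"{variable}={level}", labels=labels))
    return subpops[0], subpops[1]
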