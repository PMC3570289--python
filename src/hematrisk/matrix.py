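"""Patient x biomarker measurement container.

A :class:`BiomarkerMatrix` holds nonnegative biomarker measurements for a
cohort (rows = patients, columns = biomarkers) together with a boolean
censoring mask marking values that fell below the assay's limit of
detection and were substituted by LOD/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class BiomarkerMatrix:
    """Nonnegative patient x biomarker measurements with a censoring mask.

    Parameters
    ----------
    values
        DataFrame of measurements; index = patient ids, columns = biomarker
        names, both unique. All entries must be finite and >= 0.
    censored
        Boolean mask of the same shape; True where the stored value is an
        LOD/2 substitution for a below-detection measurement. Defaults to
        an all-False mask.
    """

    values: pd.DataFrame
    censored: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        v = self.values
        if not v.index.is_unique:
            raise ConfigError("duplicate patient ids in matrix")
        if not v.columns.is_unique:
            raise ConfigError("duplicate biomarker names in matrix")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ConfigError("matrix entries must be finite and nonnegative")
        if self.censored.shape != v.shape:
            raise ConfigError("censoring mask shape differs from values")

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def col_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_rows(self, ids) -> "BiomarkerMatrix":
        return BiomarkerMatrix(self.values.loc[ids], self.censored.loc[ids])

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="patient_id")
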