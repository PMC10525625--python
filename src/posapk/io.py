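"""Dataset I/O: NONMEM-style CSV reading and writing.

One row per event. Dose rows (EVID=1) carry AMT in mg; observation rows
(EVID=0) carry DV in mg/L plus a BLQ flag (below-quantification values are
stored at the LLOQ). Covariate columns are constant within subject and are
split into a per-subject table on read. Times are hours since first dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import TdmDataset, DATASET_COLUMNS

__all__ = ["DatasetDialect", "read_dataset", "write_dataset"]

COVARIATE_COLUMNS = [
    "age", "sex", "height", "weight", "bmi", "bsa", "creatinine", "egfr",
    "alt", "ast", "ggt", "cystic_fibrosis", "indication",
    "comed_calcineurin", "comed_mmf", "comed_acid_suppressant",
    "therapy_duration",
]


@dataclass(frozen=True)
class DatasetDialect:
    """Column naming of the on-disk CSV."""

    id: str = "ID"
    time: str = "TIME"
    evid: str = "EVID"
    amt: str = "AMT"
    dv: str = "DV"
    blq: str = "BLQ"
    covariates: tuple = tuple(COVARIATE_COLUMNS)

    @property
    def mandatory(self) -> list[str]:
        return [self.id, self.time, self.evid, self.amt, self.dv]


def read_dataset(path, dialect: DatasetDialect = DatasetDialect(),
                 lloq: float = 0.1) -> TdmDataset:
    """Read and validate a NONMEM-style CSV into a :class:`TdmDataset`.

    Raises ValueError naming any missing mandatory column; structural
    violations (observation before first dose, negative times, ...) raise
    with the offending subject identified. Row order within subject is
    preserved.
    """
    raw = pd.read_csv(path)
    missing = [c for c in dialect.mandatory if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = pd.DataFrame({
        "ID": raw[dialect.id],
        "TIME": raw[dialect.time].astype(float),
        "EVID": raw[dialect.evid].astype(int),
        "AMT": raw[dialect.amt].astype(float),
        "DV": raw[dialect.dv].astype(float),
        "BLQ": (raw[dialect.blq].astype(int) if dialect.blq in raw.columns
                else 0),
    })
    both = (df["EVID"] == 0) & df["AMT"].notna() | (
        (df["EVID"] == 1) & df["DV"].notna())
    if both.any():
        raise ValueError(
            f"{path}: rows {list(df.index[both][:5])} populate both AMT and "
            "DV (exactly one must be set per row)")
    cov_cols = [c for c in dialect.covariates if c in raw.columns]
    cov = (raw.loc[:, [dialect.id] + cov_cols]
           .drop_duplicates(subset=dialect.id)
           .rename(columns={dialect.id: "ID"})
           .set_index("ID"))
    ds = TdmDataset(df=df, covariates=cov, lloq=lloq)
    ds.validate()
    return ds


def write_dataset(dataset: TdmDataset, path,
                  dialect: DatasetDialect = DatasetDialect()) -> None:
    """Write a TdmDataset to CSV, merging covariates onto every row."""
    df = dataset.df.rename(columns={
        "ID": dialect.id, "TIME": dialect.time, "EVID": dialect.evid,
        "AMT": dialect.amt, "DV": dialect.dv, "BLQ": dialect.blq,
    })
    cov = dataset.covariates.copy()
    cov.index.name = dialect.id
    out = df.merge(cov.reset_index(), on=dialect.id, how="left")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
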