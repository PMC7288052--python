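"""Packaged reference tables.

``load_printed_binding`` returns the µOR competition-assay results that are
printed numerically in the source study's text (compound 1 is the parent
TAPP; 10–15 are scan analogues; compound 10 is a censored ">1000 nM"
record).  Compounds whose affinities are only described qualitatively are
not in the table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .pharmacology import BindingRecord

__all__ = ["load_printed_binding", "read_binding_csv", "binding_records"]

_BINDING_CSV_COLUMNS = ["compound_id", "receptor", "ic50_nM", "sem_nM", "censored"]


def read_binding_csv(path: str | Path) -> pd.DataFrame:
    """Read a binding table (compound_id, receptor, ic50_nM, sem_nM, censored)."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    missing = [c for c in _BINDING_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"binding CSV missing columns {missing}")
    df["censored"] = df["censored"].astype(bool)
    return df


def load_printed_binding() -> pd.DataFrame:
    """The packaged µOR IC50 ± S.E.M. fixture table (values in nM)."""
    with resources.as_file(
        resources.files("betascan").joinpath("data/binding_mu.csv")
    ) as p:
        return read_binding_csv(p)


def binding_records(df: pd.DataFrame) -> list[BindingRecord]:
    """Convert a binding table into BindingRecord objects."""
    return [
        BindingRecord(
            compound_id=str(row.compound_id),
            receptor=str(row.receptor),
            ic50=float(row.ic50_nM),
            sem=None if pd.isna(row.sem_nM) else float(row.sem_nM),
            censored=bool(row.censored),
        )
        for row in df.itertuples()
    ]
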