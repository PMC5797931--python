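"""Reading, validation and filtering of NONMEM-style longitudinal PK event tables.

An analysis dataset is a flat table of event records: one dose row per
subject (EVID=1, AMT in pg) followed by observation rows (EVID=0, DV in
pg/mL), with subject-constant covariates (BW kg, BSA m2, GFR mL/min/m2,
age-group label) repeated on every row.  Pre-dose baseline samples are
carried as MDV=1 placeholder rows, never as observations.

Internal units are fixed throughout the package: time in hours, amounts in
pg, concentrations in pg/mL.  A 120 ug dose is stored as 1.2e8 pg.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PKDataset",
    "DatasetError",
    "ColumnConfigError",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_LOQ",
    "read_dataset",
    "write_dataset",
    "apply_loq_filter",
    "log_transform",
]

#: Default limit of quantification used for exclusion, pg/mL.  The assay
#: itself quantifies down to 4.2 pg/mL; the analysis excludes below 4 pg/mL.
DEFAULT_LOQ = 4.0

#: Conventional NONMEM-style column names; keys are canonical field names.
DEFAULT_COLUMN_MAP = {
    "id": "id",
    "time": "time",
    "amount": "amt",
    "observation": "dv",
    "evid": "evid",
    "mdv": "mdv",
}

#: Covariate columns recognised if present.
COVARIATE_COLUMNS = ("BW", "BSA", "GFR", "age_group", "age_weeks")

CANONICAL_COLUMNS = ("id", "time", "amt", "dv", "evid", "mdv")


class DatasetError(ValueError):
    """A row-level violation of the event-record invariants."""


class ColumnConfigError(KeyError):
    """A mandatory column could not be resolved through the column map."""


@dataclass
class PKDataset:
    """An ordered collection of dosing and observation event records.

    Parameters
    ----------
    records
        Canonical table with columns ``id, time, amt, dv, evid, mdv`` plus
        any covariate columns; sorted by ``(id, time, evid desc)`` so the
        dose precedes same-time samples.
    loq
        Limit of quantification in pg/mL associated with the dataset.
    log_scale
        True once observations have been natural-log transformed.
    provenance
        Free-text origin note (file path or generator seed).
    """

    records: pd.DataFrame
    loq: float = DEFAULT_LOQ
    log_scale: bool = False
    provenance: str = ""

    # -- accessors ---------------------------------------------------------
    @property
    def observation_mask(self) -> pd.Series:
        return (self.records["evid"] == 0) & (self.records["mdv"] == 0)

    @property
    def observations(self) -> pd.DataFrame:
        return self.records.loc[self.observation_mask]

    @property
    def doses(self) -> pd.DataFrame:
        return self.records.loc[self.records["evid"] == 1]

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.records["id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int(self.observation_mask.sum())

    @property
    def below_loq(self) -> pd.Series:
        """Boolean mask over rows: quantifiable-scale observation < LOQ."""
        if self.log_scale:
            return self.observation_mask & (self.records["dv"] < np.log(self.loq))
        return self.observation_mask & (self.records["dv"] < self.loq)

    def covariate_columns(self) -> list[str]:
        return [c for c in COVARIATE_COLUMNS if c in self.records.columns]

    def subject_covariates(self, subject_id) -> dict:
        rows = self.records.loc[self.records["id"] == subject_id]
        if rows.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return {c: rows.iloc[0][c] for c in self.covariate_columns()}

    def subject_table(self) -> pd.DataFrame:
        """One row per subject with its covariates and dose amount."""
        cols = ["id"] + self.covariate_columns()
        tab = self.doses[cols + ["amt"]].drop_duplicates("id").reset_index(drop=True)
        return tab.rename(columns={"amt": "dose"})

    def __len__(self) -> int:
        return len(self.records)


def _sort_records(df: pd.DataFrame) -> pd.DataFrame:
    # stable sort; dose (evid=1) before same-time observation rows
    df = df.copy()
    df["_evid_order"] = -df["evid"]
    key = df["id"]
    # preserve first-appearance subject order for opaque ids
    order = {s: i for i, s in enumerate(dict.fromkeys(key))}
    df["_subj_order"] = key.map(order)
    df = df.sort_values(["_subj_order", "time", "_evid_order"], kind="stable")
    return df.drop(columns=["_evid_order", "_subj_order"]).reset_index(drop=True)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate event-record invariants, returning the sorted canonical table.

    Raises :class:`DatasetError` with row indices on the first violation.
    """
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise ColumnConfigError(f"mandatory column {col!r} missing")
    df = df.copy()
    for col in ("time", "amt", "dv", "evid", "mdv"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        bad &= ~df[col].astype(str).str.upper().isin({"NA", "NAN", "."})
        if bad.any():
            rows = list(df.index[bad][:5])
            raise DatasetError(f"non-numeric values in column {col!r} at rows {rows}")
        df[col] = coerced

    t = df["time"]
    bad = ~np.isfinite(t) | (t < 0)
    if bad.any():
        raise DatasetError(f"time must be finite and >= 0; rows {list(df.index[bad][:5])}")
    bad = ~df["evid"].isin([0, 1])
    if bad.any():
        raise DatasetError(f"evid must be 0 or 1; rows {list(df.index[bad][:5])}")

    obs = (df["evid"] == 0) & (df["mdv"] == 0)
    bad = obs & (~np.isfinite(df["dv"]) | (df["dv"] <= 0))
    if bad.any():
        raise DatasetError(
            "observation rows need a finite positive DV; "
            f"rows {list(df.index[bad][:5])}"
        )
    dose = df["evid"] == 1
    bad = dose & (~np.isfinite(df["amt"]) | (df["amt"] < 0))
    if bad.any():
        raise DatasetError(f"dose rows need a finite AMT >= 0; rows {list(df.index[bad][:5])}")
    # exactly one of amount/observation populated per event type
    bad = dose & df["dv"].notna()
    if bad.any():
        raise DatasetError(f"dose rows must not carry DV; rows {list(df.index[bad][:5])}")

    for sid, grp in df.groupby("id", sort=False):
        d = grp[(grp["evid"] == 1)]
        if d.empty or not np.any(np.isclose(d["time"], 0.0)):
            raise DatasetError(f"subject {sid!r} has no dose record at time 0")
        for cov in COVARIATE_COLUMNS:
            if cov in grp.columns and grp[cov].nunique(dropna=False) > 1:
                raise DatasetError(
                    f"covariate {cov!r} varies within subject {sid!r} (single-occasion study)"
                )
    return _sort_records(df)


def from_records(df: pd.DataFrame, loq: float = DEFAULT_LOQ,
                 provenance: str = "") -> PKDataset:
    """Build a validated :class:`PKDataset` from a canonical table."""
    return PKDataset(validate_records(df), loq=loq, provenance=provenance)


def read_dataset(path, column_map: Mapping[str, str] | None = None,
                 loq: float = DEFAULT_LOQ) -> PKDataset:
    """Read a delimited-text (CSV/TSV, header) event table into a PKDataset.

    ``column_map`` maps canonical field names (``id, time, amount,
    observation, evid, mdv``) to the file's column names; unmapped fields
    fall back to the conventional NONMEM-style defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "na", "."])
    rename = {}
    for canon, actual in cmap.items():
        if actual not in raw.columns:
            raise ColumnConfigError(
                f"column {actual!r} (field {canon!r}) not found in {path.name}; "
                f"available: {list(raw.columns)}"
            )
        rename[actual] = {"amount": "amt", "observation": "dv"}.get(canon, canon)
    df = raw.rename(columns=rename)
    return from_records(df, loq=loq, provenance=str(path))


def write_dataset(ds: PKDataset, path) -> None:
    """Write the canonical event table as delimited text (by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    ds.records.to_csv(path, sep=sep, index=False)


def apply_loq_filter(ds: PKDataset, loq: float | None = None
                     ) -> tuple[PKDataset, float]:
    """Drop observation records below the limit of quantification.

    Returns the filtered dataset and the excluded fraction in percent of
    all observation records.  Dose and placeholder rows are untouched.
    """
    if ds.log_scale:
        raise DatasetError("apply the LOQ filter before the log transform")
    loq = ds.loq if loq is None else float(loq)
    if loq <= 0:
        raise ValueError("loq must be > 0")
    obs = ds.observation_mask
    drop = obs & (ds.records["dv"] < loq)
    total = int(obs.sum())
    frac = 100.0 * int(drop.sum()) / total if total else 0.0
    out = ds.records.loc[~drop].reset_index(drop=True)
    return replace(ds, records=out, loq=loq), frac


def log_transform(ds: PKDataset) -> PKDataset:
    """Natural-log transform the observations (log-transform-both-sides).

    Requires a LOQ-filtered dataset with strictly positive observations; a
    scale marker guards against double transformation.
    """
    if ds.log_scale:
        raise DatasetError("dataset is already on the log scale")
    obs = ds.observation_mask
    vals = ds.records.loc[obs, "dv"]
    if (vals <= 0).any():
        rows = list(ds.records.index[obs & (ds.records["dv"] <= 0)][:5])
        raise DatasetError(f"nonpositive observation cannot be log-transformed; rows {rows}")
    out = ds.records.copy()
    out.loc[obs, "dv"] = np.log(vals.astype(float))
    return replace(ds, records=out, log_scale=True)
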