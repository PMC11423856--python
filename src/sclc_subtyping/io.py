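"""TSV/JSON/YAML input and output with strict schema validation.

Conventions: tab-delimited UTF-8 with a header row; matrices are proteins x
samples with protein ids in the first column; the missing-value token is the
empty string (a literal 0 in an intensity table means "not detected" and is
disallowed in abundance tables, where zeros are written as "").  Clinical
tables carry one row per sample with the fixed column set below.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import AbundanceMatrix, IntensityTable

__all__ = [
    "read_intensity",
    "write_intensity",
    "read_abundance",
    "write_abundance",
    "read_clinical",
    "write_clinical",
    "file_digest",
]

CLINICAL_COLUMNS = [
    "sample_id",
    "os_years",
    "os_event",
    "pfs_years",
    "pfs_event",
    "age",
    "gender",
    "smoking",
    "lnm",
    "tnm_stage",
    "valg_stage",
    "chemotherapy",
    "ici_line",
]
_TNM = {"I", "II", "III", "IV"}
_VALG = {"LS", "ES"}
_ICI = {"first", "later", "none"}
_BOOL = {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.duplicated().any():
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate {what}(s): {dupes[:5]}")


def read_intensity(path) -> IntensityTable:
    """Read a raw-intensity TSV; requires a ``theoretical_peptides`` column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    _check_unique(df.index, "protein id", path)
    _check_unique(df.columns, "column", path)
    if "theoretical_peptides" not in df.columns:
        raise ValueError(f"{path}: missing theoretical_peptides column")
    pep = df["theoretical_peptides"]
    mat = df.drop(columns=["theoretical_peptides"]).astype(float)
    return IntensityTable(raw_intensity=mat, theoretical_peptides=pep.astype(int))


def write_intensity(table: IntensityTable, path) -> None:
    out = table.raw_intensity.copy()
    out.insert(0, "theoretical_peptides", table.theoretical_peptides)
    out.to_csv(path, sep="\t", index_label="protein_id")


def write_abundance(m: AbundanceMatrix, path) -> None:
    """Write FOT with "" for never-observed entries; masks go to sidecars.

    ``<stem>.detected.tsv`` and ``<stem>.imputed.tsv`` hold the boolean
    masks so a written matrix round-trips exactly.
    """
    path = Path(path)
    vals = m.fot.where(m.detected | m.imputed)  # NaN -> "" on write
    vals.to_csv(path, sep="\t", index_label="protein_id", na_rep="")
    m.detected.to_csv(path.with_suffix(".detected.tsv"), sep="\t", index_label="protein_id")
    m.imputed.to_csv(path.with_suffix(".imputed.tsv"), sep="\t", index_label="protein_id")


def read_abundance(path) -> AbundanceMatrix:
    """Read an abundance TSV; blank cells are missing (not detected).

    If mask sidecar files exist they are honoured; otherwise detected means
    a non-blank positive value and nothing is marked imputed.
    """
    path = Path(path)
    fot = pd.read_csv(path, sep="\t", index_col=0)
    fot.index.name = None
    _check_unique(fot.index, "protein id", path)
    _check_unique(fot.columns, "sample id", path)
    fot = fot.astype(float)
    det_path = path.with_suffix(".detected.tsv")
    imp_path = path.with_suffix(".imputed.tsv")
    if det_path.exists() and imp_path.exists():
        detected = pd.read_csv(det_path, sep="\t", index_col=0).astype(bool)
        imputed = pd.read_csv(imp_path, sep="\t", index_col=0).astype(bool)
        detected.index.name = imputed.index.name = None
    else:
        detected = fot.notna() & (fot > 0)
        imputed = pd.DataFrame(False, index=fot.index, columns=fot.columns)
    fot = fot.fillna(0.0)
    if (fot.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    return AbundanceMatrix(fot=fot, detected=detected, imputed=imputed)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, na_rep="")


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical TSV, with row/column-addressed errors."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns and c not in
               ("pfs_years", "pfs_event", "ici_line")]
    if missing:
        raise ValueError(f"{path}: missing clinical column(s): {missing}")
    _check_unique(pd.Index(df["sample_id"]), "sample id", path)
    out = pd.DataFrame({"sample_id": df["sample_id"]})

    def _num(col, optional=False):
        if col not in df.columns:
            return np.full(len(df), np.nan)
        vals = np.full(len(df), np.nan)
        for i, cell in enumerate(df[col]):
            if cell == "":
                if optional:
                    continue
                raise ValueError(f"{path}: row {i}, column {col}: missing value")
            try:
                vals[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: row {i}, column {col}: non-numeric value {cell!r}"
                ) from None
        return vals

    def _bool(col, optional=False):
        if col not in df.columns:
            return np.full(len(df), np.nan)
        vals = np.full(len(df), np.nan)
        for i, cell in enumerate(df[col]):
            if cell == "" and optional:
                continue
            if cell in _BOOL:
                vals[i] = float(_BOOL[cell])
            elif cell in ("1.0", "0.0"):
                vals[i] = float(cell)
            else:
                raise ValueError(f"{path}: row {i}, column {col}: not a boolean: {cell!r}")
        return vals

    out["os_years"] = _num("os_years")
    if (out["os_years"] < 0).any():
        bad = int(np.argmax(out["os_years"].to_numpy() < 0))
        raise ValueError(f"{path}: row {bad}, column os_years: negative time")
    out["os_event"] = _bool("os_event").astype(bool)
    out["pfs_years"] = _num("pfs_years", optional=True)
    out["pfs_event"] = _bool("pfs_event", optional=True)
    out["age"] = _num("age")
    out["gender"] = df["gender"]
    out["smoking"] = _bool("smoking").astype(bool)
    out["lnm"] = _bool("lnm").astype(bool)
    for col, allowed in (("tnm_stage", _TNM), ("valg_stage", _VALG)):
        for i, cell in enumerate(df[col]):
            if cell not in allowed:
                raise ValueError(
                    f"{path}: row {i}, column {col}: unknown stage code {cell!r}"
                )
        out[col] = df[col]
    out["chemotherapy"] = _bool("chemotherapy").astype(bool)
    if "ici_line" in df.columns:
        for i, cell in enumerate(df["ici_line"]):
            if cell not in _ICI and cell != "":
                raise ValueError(f"{path}: row {i}, column ici_line: unknown code {cell!r}")
        out["ici_line"] = df["ici_line"].replace("", "none")
    else:
        out["ici_line"] = "none"
    return out


def file_digest(path) -> str:
    """SHA-256 of a file's bytes, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
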