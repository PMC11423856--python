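"""Label-free protein quantification: iBAQ, FOT, and missing-value imputation.

The quantification convention follows standard label-free proteomics practice:

* iBAQ (intensity-based absolute quantification): a protein's raw MS intensity
  divided by its number of theoretically observable tryptic peptides, which
  removes the protein-length bias of summed intensities.
* FOT (fraction of total): a protein's iBAQ divided by the sum of iBAQs of all
  proteins identified in the same sample, i.e. a per-sample normalisation to a
  unit-sum composition that makes abundances comparable across runs.
* Missing values (proteins not identified in a run) are imputed with 1/10 of
  the smallest non-zero FOT of that sample, a conservative "below detection
  limit" fill-in.

Matrices are proteins x samples throughout. A value of exactly zero in a raw
intensity matrix means "not detected in this run"; the detection mask is
recorded before imputation so downstream filters can distinguish genuinely
quantified values from imputed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTable",
    "AbundanceMatrix",
    "compute_ibaq",
    "compute_fot",
    "impute_missing",
]


@dataclass
class IntensityTable:
    """Raw protein intensities plus theoretical peptide counts.

    Attributes
    ----------
    raw_intensity : pandas.DataFrame
        Non-negative intensities, proteins (index) x samples (columns).
        Zero means not detected.
    theoretical_peptides : pandas.Series
        Positive integer count of theoretically observable peptides per
        protein, indexed like ``raw_intensity``.
    """

    raw_intensity: pd.DataFrame
    theoretical_peptides: pd.Series

    def __post_init__(self) -> None:
        idx = self.raw_intensity.index
        cols = self.raw_intensity.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if not self.theoretical_peptides.index.equals(idx):
            self.theoretical_peptides = self.theoretical_peptides.reindex(idx)
        if self.theoretical_peptides.isna().any():
            missing = self.theoretical_peptides.index[
                self.theoretical_peptides.isna()
            ].tolist()
            raise ValueError(f"theoretical peptide count missing for: {missing[:5]}")
        if (self.raw_intensity.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.raw_intensity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw_intensity.columns)


@dataclass
class AbundanceMatrix:
    """Per-sample normalised abundances (FOT) with detection bookkeeping.

    ``detected`` is True where the pre-imputation value was > 0; ``imputed``
    is True where a missing entry was filled in.  Before imputation, each
    sample's FOT values sum to 1 over its detected proteins.
    """

    fot: pd.DataFrame
    detected: pd.DataFrame
    imputed: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.fot.index, columns=self.fot.columns
            )
        for name, mask in (("detected", self.detected), ("imputed", self.imputed)):
            if not mask.index.equals(self.fot.index) or not mask.columns.equals(
                self.fot.columns
            ):
                raise ValueError(f"{name} mask does not align with the fot matrix")
        if bool((self.imputed.to_numpy() & self.detected.to_numpy()).any()):
            raise ValueError("an entry cannot be both detected and imputed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.fot.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fot.columns)

    @property
    def n_samples(self) -> int:
        return self.fot.shape[1]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.fot.copy(), self.detected.copy(), self.imputed.copy()
        )


def compute_ibaq(table: IntensityTable) -> pd.DataFrame:
    """Raw intensity divided by theoretical peptide count, per protein.

    Zeros (undetected) stay zero.  Raises ``ValueError`` naming the offending
    protein if any peptide count is < 1.
    """
    pep = table.theoretical_peptides
    bad = pep[pep < 1]
    if len(bad) > 0:
        raise ValueError(
            f"theoretical peptide count < 1 for protein(s): {list(bad.index)[:5]}"
        )
    return table.raw_intensity.div(pep.astype(float), axis=0)


def compute_fot(ibaq: pd.DataFrame) -> AbundanceMatrix:
    """Normalise each sample column to its sum over identified proteins.

    The detection mask is ``ibaq > 0``; each FOT column sums to 1 over
    detected entries.  A sample with no positive iBAQ is an error.
    """
    vals = ibaq.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("iBAQ values must be non-negative")
    colsums = vals.sum(axis=0)
    empty = np.flatnonzero(colsums <= 0)
    if empty.size:
        raise ValueError(
            f"sample(s) with no identified proteins: {list(ibaq.columns[empty])}"
        )
    fot = ibaq / colsums
    detected = ibaq > 0
    return AbundanceMatrix(fot=fot, detected=detected)


def impute_missing(m: AbundanceMatrix, *, global_minimum: bool = False) -> AbundanceMatrix:
    """Fill undetected entries with (minimum positive FOT)/10.

    By default the minimum is taken per sample ("the global non-zero minimum
    value of the sample"); ``global_minimum=True`` switches to the smallest
    positive value of the whole matrix for sensitivity analysis.  Idempotent:
    entries already imputed are left alone, detected entries never change.
    """
    fot = m.fot.to_numpy(dtype=float).copy()
    det = m.detected.to_numpy(dtype=bool)
    imp = m.imputed.to_numpy(dtype=bool).copy()
    no_detect = np.flatnonzero(det.sum(axis=0) == 0)
    if no_detect.size:
        raise ValueError(
            f"sample(s) with zero detected proteins: {list(m.fot.columns[no_detect])}"
        )
    positive = np.where(fot > 0, fot, np.inf)
    if global_minimum:
        fill = np.full(fot.shape[1], positive.min() / 10.0)
    else:
        fill = positive.min(axis=0) / 10.0
    target = ~det & ~imp
    fot[target] = np.broadcast_to(fill, fot.shape)[target]
    imp = imp | target
    return AbundanceMatrix(
        fot=pd.DataFrame(fot, index=m.fot.index, columns=m.fot.columns),
        detected=m.detected.copy(),
        imputed=pd.DataFrame(imp, index=m.fot.index, columns=m.fot.columns),
    )
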