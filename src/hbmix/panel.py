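"""Core data containers for urinary biomarker panels.

An :class:`ExposurePanel` holds a samples x biomarkers matrix of urinary
concentrations together with per-biomarker limits of quantification (LOQ)
and per-cell censoring/missingness flags.  Values below the LOQ are
left-censored: the stored value is the LOQ itself and the ``censored``
flag marks the cell.  Missing cells (biomarker not measured for that
sample) are NaN and flagged in ``missing``.

The companion covariate table carries the per-sample adjustment
variables (sex, age, BMI, smoking, education and urinary creatinine in
g/L) used to correct the network input for dilution and basic
determinants.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COVARIATES = ("sex", "age", "bmi", "smoking", "education", "creatinine")

#: Allowed measurement scales for a panel.
SCALES = ("raw", "log", "standardized")


@dataclasses.dataclass
class ExposurePanel:
    """Samples x biomarkers concentration matrix with censoring metadata.

    Parameters
    ----------
    values : DataFrame
        Concentrations, samples as rows and biomarkers as columns.  On
        the raw scale these are in ug/L; after :func:`~hbmix.preprocess.log_transform`
        they are natural logs.
    loq : Series
        Per-biomarker limit of quantification, on the same scale as
        ``values``.
    censored : DataFrame
        Boolean mask, True where the measurement fell below the LOQ.
    missing : DataFrame
        Boolean mask, True where the biomarker was not measured.
    meta : DataFrame, optional
        Per-biomarker metadata (parent substance, family, ...), indexed
        by biomarker id.
    scale : str
        One of ``raw``, ``log`` or ``standardized``.
    """

    values: pd.DataFrame
    loq: pd.Series
    censored: pd.DataFrame
    missing: pd.DataFrame
    meta: pd.DataFrame | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def biomarkers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_biomarkers(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExposurePanel":
        return ExposurePanel(
            values=self.values.copy(),
            loq=self.loq.copy(),
            censored=self.censored.copy(),
            missing=self.missing.copy(),
            meta=None if self.meta is None else self.meta.copy(),
            scale=self.scale,
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        cols = list(self.values.columns)
        for name, frame in (("censored", self.censored), ("missing", self.missing)):
            if list(frame.columns) != cols or len(frame) != len(self.values):
                raise ValueError(f"{name} flags are not aligned with values")
        if list(self.loq.index) != cols:
            raise ValueError("loq is not aligned with values columns")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw" and (self.loq <= 0).any():
            bad = self.loq.index[self.loq <= 0].tolist()
            raise ValueError(f"non-positive LOQ for biomarkers {bad}")
        both = (self.censored.to_numpy() & self.missing.to_numpy())
        if both.any():
            i, j = np.argwhere(both)[0]
            raise ValueError(
                f"cell ({self.values.index[i]}, {cols[j]}) flagged both censored and missing"
            )

    def subset(self, biomarkers: list[str]) -> "ExposurePanel":
        """Return a panel restricted to ``biomarkers`` (order preserved)."""
        return ExposurePanel(
            values=self.values[biomarkers].copy(),
            loq=self.loq[biomarkers].copy(),
            censored=self.censored[biomarkers].copy(),
            missing=self.missing[biomarkers].copy(),
            meta=None if self.meta is None else self.meta.loc[self.meta.index.intersection(biomarkers)].copy(),
            scale=self.scale,
        )

    # -- I/O ---------------------------------------------------------------
    def to_dir(self, out_dir: str | Path) -> None:
        """Write the panel as plain CSV files under ``out_dir``.

        Layout: ``values.csv`` (samples x biomarkers), ``loq.csv``,
        ``censored.csv`` / ``missing.csv`` (0/1 masks) and optionally
        ``biomarker_meta.csv``.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(out / "values.csv", index_label="sample")
        self.loq.rename("loq").to_csv(out / "loq.csv", index_label="biomarker")
        self.censored.astype(int).to_csv(out / "censored.csv", index_label="sample")
        self.missing.astype(int).to_csv(out / "missing.csv", index_label="sample")
        if self.meta is not None:
            self.meta.to_csv(out / "biomarker_meta.csv", index_label="biomarker")

    @classmethod
    def from_dir(cls, in_dir: str | Path, scale: str = "raw") -> "ExposurePanel":
        src = Path(in_dir)
        values = pd.read_csv(src / "values.csv", index_col="sample")
        loq = pd.read_csv(src / "loq.csv", index_col="biomarker")["loq"]
        censored = pd.read_csv(src / "censored.csv", index_col="sample").astype(bool)
        missing = pd.read_csv(src / "missing.csv", index_col="sample").astype(bool)
        meta_path = src / "biomarker_meta.csv"
        meta = pd.read_csv(meta_path, index_col="biomarker") if meta_path.exists() else None
        return cls(values=values, loq=loq, censored=censored, missing=missing,
                   meta=meta, scale=scale)


def validate_covariates(covariates: pd.DataFrame, n_samples: int | None = None) -> pd.DataFrame:
    """Check a covariate table for the required columns and sane ranges."""
    missing_cols = [c for c in REQUIRED_COVARIATES if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"covariate table lacks columns {missing_cols}")
    if n_samples is not None and len(covariates) != n_samples:
        raise ValueError(
            f"covariate table has {len(covariates)} rows, panel has {n_samples} samples"
        )
    if covariates[list(REQUIRED_COVARIATES)].isna().any().any():
        raise ValueError("covariate table contains missing values")
    if (covariates["creatinine"] <= 0).any():
        raise ValueError("creatinine must be strictly positive (g/L)")
    if (covariates["age"] < 0).any():
        raise ValueError("age must be non-negative")
    return covariates
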