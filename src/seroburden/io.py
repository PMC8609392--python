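"""Domain types and TSV readers/writers.

The pipeline's in-memory containers are thin, validated wrappers around
pandas objects:

* :class:`MeasurementMatrix` — a proteins × samples grid on a declared
  scale (``log2_npx`` for relative log2 units, ``concentration`` for
  absolute pg/mL-style values) with optional per-protein lower limits of
  detection (LLD, always on the linear scale) and a per-matrix dilution
  factor.
* :class:`SampleSheet` — maps samples to subject, role
  (patient/control), timepoint (pre/post surgery) and technical
  replicate.
* :class:`AnalysisConfig` — every tunable threshold of the analysis.

All file interfaces are plain wide-format TSV/CSV (UTF-8, dot decimal);
missing cells are empty or ``NA`` and stay missing — they are never
silently turned into zeros.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    PairingError,
    ParseError,
)

LOG2_NPX = "log2_npx"
CONCENTRATION = "concentration"
_SCALES = (LOG2_NPX, CONCENTRATION)

_MISSING_TOKENS = ("", "NA", "NaN", "nan")

ROLE_PATIENT = "patient"
ROLE_CONTROL = "control"
TP_PRE = "pre"
TP_POST = "post"
TP_NONE = "none"


# ---------------------------------------------------------------------------
# MeasurementMatrix
# ---------------------------------------------------------------------------

@dataclass
class MeasurementMatrix:
    """Proteins × samples measurement grid with assay metadata.

    Parameters
    ----------
    platform_id
        Free-text label for the assay platform.
    scale
        ``"log2_npx"`` (relative, log2 units) or ``"concentration"``
        (absolute, linear units).
    units
        Unit label, e.g. ``"NPX"`` or ``"pg/mL"``.
    values
        DataFrame indexed by protein label with sample columns; ``NaN``
        encodes a missing measurement.
    lld
        Optional per-protein lower limit of detection, expressed on the
        *linear* scale regardless of ``scale``.
    dilution_factor
        Fold-dilution of the input serum for this run (1 = undiluted,
        10 = 1:10).
    """

    platform_id: str
    scale: str
    units: str
    values: pd.DataFrame
    lld: pd.Series | None = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ConfigurationError(
                f"unknown scale {self.scale!r}; expected one of {_SCALES}"
            )
        if not isinstance(self.values, pd.DataFrame):
            raise ConfigurationError("values must be a pandas DataFrame")
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ParseError(f"duplicate protein labels: {sorted(dups)}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ParseError(f"duplicate sample labels: {sorted(dups)}")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ParseError("non-finite (infinite) measurement values")
        if self.scale == CONCENTRATION and np.nanmin(arr, initial=0.0) < 0:
            bad = self.values.lt(0).any(axis=1)
            raise ParseError(
                "negative concentration values for proteins: "
                f"{list(self.values.index[bad])}"
            )
        if not self.dilution_factor > 0:
            raise ConfigurationError("dilution_factor must be > 0")
        if self.lld is not None:
            self.lld = pd.Series(self.lld, dtype=float).reindex(self.values.index)
            if (self.lld.dropna() < 0).any():
                raise ConfigurationError("LLD values must be nonnegative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def replace_values(self, values: pd.DataFrame, **meta) -> "MeasurementMatrix":
        """Copy of this matrix with new values (and optional metadata)."""
        kw = dict(
            platform_id=self.platform_id,
            scale=self.scale,
            units=self.units,
            values=values,
            lld=None if self.lld is None else self.lld.copy(),
            dilution_factor=self.dilution_factor,
        )
        kw.update(meta)
        return MeasurementMatrix(**kw)

    def subset(self, proteins: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "MeasurementMatrix":
        vals = self.values
        if proteins is not None:
            vals = vals.loc[list(proteins)]
        if samples is not None:
            vals = vals[list(samples)]
        out = self.replace_values(vals)
        return out


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_id", "subject_id", "role", "timepoint", "replicate_id"]


@dataclass
class SampleSheet:
    """Sample → (subject, role, timepoint, replicate) mapping.

    Validation enforces the study design: each patient has exactly one
    pre- and one post-surgical specimen (possibly measured in several
    technical replicates), and each control subject contributes at
    least two replicate measurements of a single specimen.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows)
        missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"sample sheet missing columns: {missing}")
        df = df[_SHEET_COLUMNS].copy()
        for col in ("sample_id", "subject_id", "role", "timepoint"):
            df[col] = df[col].astype(str)
        df["replicate_id"] = df["replicate_id"].astype(int)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"]
            raise ParseError(f"duplicate sample_ids: {sorted(set(dups))}")
        bad_role = set(df["role"]) - {ROLE_PATIENT, ROLE_CONTROL}
        if bad_role:
            raise ParseError(f"unknown role tokens: {sorted(bad_role)}")
        bad_tp = set(df["timepoint"]) - {TP_PRE, TP_POST, TP_NONE}
        if bad_tp:
            raise ParseError(f"unknown timepoint tokens: {sorted(bad_tp)}")
        self.rows = df.reset_index(drop=True)
        self._validate_design()

    def _validate_design(self) -> None:
        df = self.rows
        problems = []
        for subject, grp in df[df["role"] == ROLE_PATIENT].groupby("subject_id"):
            tps = set(grp["timepoint"])
            if TP_PRE not in tps or TP_POST not in tps:
                problems.append(subject)
        if problems:
            raise PairingError(
                f"patients missing a pre or post sample: {sorted(problems)}"
            )
        few = []
        for subject, grp in df[df["role"] == ROLE_CONTROL].groupby("subject_id"):
            if len(grp) < 2:
                few.append(subject)
        if few:
            raise PairingError(
                f"control subjects need >=2 replicates, got fewer for: {sorted(few)}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def patients(self) -> list[str]:
        df = self.rows
        out = sorted(set(df.loc[df["role"] == ROLE_PATIENT, "subject_id"]))
        return out

    @property
    def controls(self) -> list[str]:
        df = self.rows
        return sorted(set(df.loc[df["role"] == ROLE_CONTROL, "subject_id"]))

    def samples_for(self, subject: str, timepoint: str | None = None) -> list[str]:
        df = self.rows
        sel = df["subject_id"] == subject
        if timepoint is not None:
            sel &= df["timepoint"] == timepoint
        return list(df.loc[sel, "sample_id"])

    def pre_post_pairs(self) -> dict[str, tuple[list[str], list[str]]]:
        """Per patient: (pre sample ids, post sample ids), replicates kept.

        The mapping is independent of the row order of the sheet.
        """
        return {
            p: (self.samples_for(p, TP_PRE), self.samples_for(p, TP_POST))
            for p in self.patients
        }

    def control_replicates(self) -> dict[str, list[str]]:
        return {c: self.samples_for(c) for c in self.controls}


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All analysis thresholds in one place.

    fd_threshold
        Fold-decrease cutoff calling a per-patient decrease "real"
        (default 2, i.e. a two-fold or higher post-surgical drop).
    min_patients
        Minimum number of patients above ``fd_threshold`` for a protein
        to be selected as a tumor-burden candidate (default 6 of 9).
    tiers / tier_min_patients
        Additional fold-decrease tiers reported alongside selection
        (default: >=5-fold in >=2 patients, >=10-fold in >=1).
    replicate_fc_cutoff
        Symmetric fold change between control technical replicates above
        which a protein is deemed unstable and removed (default 2).
    strict_threshold
        If True, threshold comparisons use ``>`` instead of ``>=``.
    loa_z
        z-multiplier for Bland–Altman limits of agreement (1.96 ≈ 95%).
    alpha
        Two-sided significance level for reported p-values.
    """

    fd_threshold: float = 2.0
    min_patients: int = 6
    tiers: tuple[float, ...] = (5.0, 10.0)
    tier_min_patients: tuple[int, ...] = (2, 1)
    replicate_fc_cutoff: float = 2.0
    strict_threshold: bool = False
    loa_z: float = 1.96
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.tiers = tuple(float(t) for t in self.tiers)
        self.tier_min_patients = tuple(int(m) for m in self.tier_min_patients)
        if not self.fd_threshold > 1:
            raise ConfigurationError("fd_threshold must be > 1")
        if self.min_patients < 1:
            raise ConfigurationError("min_patients must be >= 1")
        if len(self.tiers) != len(self.tier_min_patients):
            raise ConfigurationError("tiers and tier_min_patients differ in length")
        if any(t <= 1 for t in self.tiers):
            raise ConfigurationError("every tier threshold must be > 1")
        if any(m < 1 for m in self.tier_min_patients):
            raise ConfigurationError("tier_min_patients must be >= 1")
        if not self.loa_z > 0:
            raise ConfigurationError("loa_z must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} is not a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["tiers"] = list(self.tiers)
        data["tier_min_patients"] = list(self.tier_min_patients)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tiers"] = list(self.tiers)
        d["tier_min_patients"] = list(self.tier_min_patients)
        return d


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_measurement_table(
    path: str | Path,
    platform_id: str = "platform",
    scale: str = CONCENTRATION,
    units: str = "pg/mL",
    dilution_factor: float = 1.0,
    lld: Mapping[str, float] | pd.Series | None = None,
    missing_tokens: Iterable[str] = _MISSING_TOKENS,
) -> MeasurementMatrix:
    """Read a wide proteins × samples table.

    First column holds protein labels; remaining columns are samples.
    Cells must be numeric or one of ``missing_tokens``. Errors name the
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                      keep_default_na=False, encoding="utf-8")
    if raw.shape[1] < 1:
        raise ParseError(f"{path}: no columns found")
    protein_col = raw.columns[0]
    proteins = raw[protein_col].astype(str)
    if proteins.duplicated().any():
        dups = sorted(set(proteins[proteins.duplicated()]))
        raise ParseError(f"{path}: duplicate protein labels {dups}")
    sample_cols = list(raw.columns[1:])
    if len(set(sample_cols)) != len(sample_cols):
        raise ParseError(f"{path}: duplicate sample labels in header")
    missing = set(missing_tokens)
    data = {}
    for col in sample_cols:
        parsed = []
        for prot, cell in zip(proteins, raw[col]):
            cell = cell.strip()
            if cell in missing:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at protein "
                    f"{prot!r}, sample {col!r}"
                ) from None
        data[col] = parsed
    values = pd.DataFrame(data, index=pd.Index(proteins, name="protein"))
    lld_series = None
    if lld is not None:
        lld_series = pd.Series(lld, dtype=float)
    return MeasurementMatrix(
        platform_id=platform_id, scale=scale, units=units,
        values=values, lld=lld_series, dilution_factor=dilution_factor,
    )


def write_measurement_table(matrix: MeasurementMatrix, path: str | Path) -> None:
    """Write a matrix in the same wide TSV/CSV layout the reader consumes."""
    df = matrix.values.copy()
    df.index.name = "protein"
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", encoding="utf-8")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV with the five mandatory columns."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     keep_default_na=False, encoding="utf-8")
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    try:
        df["replicate_id"] = df["replicate_id"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer replicate_id ({exc})") from None
    return SampleSheet(rows=df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.rows.to_csv(path, sep=_sep_for(path), index=False, encoding="utf-8")


def collapse_replicates(matrix: MeasurementMatrix, sheet: SampleSheet) -> MeasurementMatrix:
    """Average technical replicates into one column per (subject, timepoint).

    Averaging is arithmetic on the matrix's own scale for concentration
    data and on the linear scale for log2 matrices (values are
    exponentiated, averaged, and re-logged). Output columns are named
    ``<subject>:<timepoint>`` and carry one value per specimen.
    """
    df = sheet.rows[sheet.rows["sample_id"].isin(matrix.sample_ids)]
    if df.empty:
        raise ConfigurationError("sample sheet shares no samples with the matrix")
    vals = matrix.values
    if matrix.scale == LOG2_NPX:
        vals = np.power(2.0, vals)
    cols = {}
    for (subject, tp), grp in df.groupby(["subject_id", "timepoint"], sort=True):
        cols[f"{subject}:{tp}"] = vals[list(grp["sample_id"])].mean(axis=1)
    out = pd.DataFrame(cols)
    if matrix.scale == LOG2_NPX:
        out = np.log2(out)
    return matrix.replace_values(out)


# ---------------------------------------------------------------------------
# Candidate-table writer (layout mirrors the published heatmap tables)
# ---------------------------------------------------------------------------

def write_candidate_table(table, path: str | Path) -> None:
    """Write a CandidateTable as TSV.

    One row per protein: per-patient fold decreases (1 decimal), control
    replicate fold changes, median FD, count of patients above the main
    threshold, and the selection verdict. Rows are ordered by descending
    median FD, ties broken by descending count then label.
    """
    df = table.as_frame()
    fd_cols = table.patient_columns + table.control_columns
    out = df.copy()
    for col in fd_cols + ["median_fd"]:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    out.index.name = "protein"
    out.to_csv(path, sep="\t", encoding="utf-8")


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read back a candidate-table TSV as a plain DataFrame."""
    return pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")


def read_fd_matrix(path: str | Path) -> pd.DataFrame:
    """Read a proteins × patients fold-decrease grid (plain wide TSV)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, encoding="utf-8")
    return df.astype(float)


def write_fd_matrix(values: pd.DataFrame, path: str | Path) -> None:
    out = values.copy()
    out.index.name = "protein"
    out.to_csv(path, sep=_sep_for(path), na_rep="NA", encoding="utf-8")
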