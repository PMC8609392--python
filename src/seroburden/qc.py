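"""Technical-replicate quality control.

Two precision measures drive QC:

* the symmetric replicate fold change ``max/min`` between technical
  replicate measurements of a control specimen — proteins exceeding a
  cutoff (default 2-fold) in any control are removed as unstable;
* the coefficient of variation (CV, %) across technical replicates,
  profiled as the fraction of the panel under 10%, under 20% and over
  100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma, sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .io import LOG2_NPX, MeasurementMatrix, SampleSheet


@dataclass
class QcReport:
    """Replicate-stability summary for one platform."""

    replicate_fc: pd.DataFrame = field(default_factory=pd.DataFrame)
    """Proteins × control-subjects grid of symmetric replicate fold changes."""
    removed_proteins: set[str] = field(default_factory=set)
    cv_percent: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    cv_profile: dict[str, float] = field(default_factory=dict)
    """Fractions of proteins with CV <10%, <20% and >100%."""

    def to_tsv(self, path) -> None:
        out = self.replicate_fc.copy()
        out.columns = [f"replicate_fc_{c}" for c in out.columns]
        if len(self.cv_percent):
            out["cv_percent"] = self.cv_percent
        out["removed"] = [p in self.removed_proteins for p in out.index]
        out.index.name = "protein"
        out.to_csv(path, sep="\t", encoding="utf-8")


def replicate_fold_change(a: float, b: float) -> float:
    """Symmetric fold change between two replicate measurements.

    ``max(a, b) / min(a, b)`` — always >= 1 and invariant under argument
    order, unlike a directional ratio.
    """
    if not (a > 0 and b > 0):
        raise DomainError(f"replicate values must be positive, got ({a}, {b})")
    return max(a, b) / min(a, b)


def _replicate_fc_over(values: pd.DataFrame) -> pd.Series:
    """Per-protein max/min over >=2 replicate columns (NaN if any missing)."""
    hi = values.max(axis=1)
    lo = values.min(axis=1)
    if (lo <= 0).any():
        bad = list(values.index[lo <= 0])[:5]
        raise DomainError(f"non-positive replicate values for proteins {bad}")
    out = hi / lo
    out[values.isna().any(axis=1)] = np.nan
    return out


def filter_unstable_proteins(
    matrix: MeasurementMatrix,
    sheet: SampleSheet,
    cutoff: float = 2.0,
    whitelist: Iterable[str] = (),
) -> tuple[set[str], set[str], QcReport]:
    """Remove proteins whose control replicates disagree too much.

    A protein is removed iff its replicate fold change strictly exceeds
    ``cutoff`` in ANY control subject (conservative: one bad control
    condemns the protein). ``whitelist`` names proteins exempt from
    removal regardless of their replicate behavior.

    Fold changes are computed on the linear scale; log2 matrices are
    linearized internally.
    """
    controls = sheet.control_replicates()
    controls = {
        c: [s for s in samples if s in set(matrix.sample_ids)]
        for c, samples in controls.items()
    }
    controls = {c: s for c, s in controls.items() if len(s) >= 2}
    if not controls:
        raise ConfigurationError("no control subject with >=2 replicates in matrix")
    values = matrix.values
    if matrix.scale == LOG2_NPX:
        values = np.power(2.0, values)
    fc = pd.DataFrame({
        c: _replicate_fc_over(values[samples]) for c, samples in controls.items()
    })
    whitelist = set(whitelist)
    exceed = fc.gt(cutoff).any(axis=1)
    removed = set(fc.index[exceed]) - whitelist
    kept = set(matrix.protein_ids) - removed
    report = QcReport(replicate_fc=fc, removed_proteins=removed)
    return kept, removed, report


def cv_percent(replicates: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    Sample SD uses the n-1 denominator; at least two positive
    replicates are required.
    """
    arr = np.asarray(list(replicates), dtype=float)
    if arr.size < 2:
        raise DomainError(f"need >=2 replicates, got {arr.size}")
    if not (arr > 0).all():
        raise DomainError("replicate values must be positive")
    return float(100.0 * arr.std(ddof=1) / arr.mean())


def cv_profile(
    matrix: MeasurementMatrix,
    sheet: SampleSheet,
) -> tuple[dict[str, float], pd.Series]:
    """Panel-wide CV profile from technical replicates.

    For every specimen (subject, timepoint) with >=2 replicate columns
    in the matrix, a per-protein CV is computed on the linear scale;
    per-protein CVs are then averaged over specimens. Returns the
    fractions of proteins with mean CV < 10%, < 20% and > 100%, plus the
    per-protein mean CV series.
    """
    df = sheet.rows[sheet.rows["sample_id"].isin(matrix.sample_ids)]
    values = matrix.values
    if matrix.scale == LOG2_NPX:
        values = np.power(2.0, values)
    per_specimen = []
    for (_subject, _tp), grp in df.groupby(["subject_id", "timepoint"]):
        samples = list(grp["sample_id"])
        if len(samples) < 2:
            continue
        sub = values[samples]
        if (sub.min(axis=1) <= 0).any():
            raise DomainError("non-positive replicate values in CV computation")
        per_specimen.append(100.0 * sub.std(axis=1, ddof=1) / sub.mean(axis=1))
    if not per_specimen:
        raise ConfigurationError("no specimen with >=2 replicates for CV profiling")
    cv = pd.concat(per_specimen, axis=1).mean(axis=1)
    n = float(len(cv))
    profile = {
        "frac_cv_lt_10": float((cv < 10.0).sum()) / n,
        "frac_cv_lt_20": float((cv < 20.0).sum()) / n,
        "frac_cv_gt_100": float((cv > 100.0).sum()) / n,
    }
    return profile, cv


def _c4(n: int) -> float:
    """Finite-sample bias of the sample SD: E[s] = c4(n) * sigma."""
    return sqrt(2.0 / (n - 1)) * gamma(n / 2.0) / gamma((n - 1) / 2.0)


def estimate_platform_cv(matrix: MeasurementMatrix, sheet: SampleSheet) -> float:
    """Debiased estimate of a platform's technical CV (as a fraction).

    Averages per-protein replicate CVs over the panel and divides by the
    c4 small-sample factor: at quadruplicates the raw sample SD
    underestimates sigma by ~8%, which matters when the estimate is read
    back as the platform's noise parameter.
    """
    df = sheet.rows[sheet.rows["sample_id"].isin(matrix.sample_ids)]
    rep_counts = [len(g) for _, g in df.groupby(["subject_id", "timepoint"])
                  if len(g) >= 2]
    if not rep_counts:
        raise ConfigurationError("no replicated specimens for CV estimation")
    _, cv = cv_profile(matrix, sheet)
    n_rep = int(round(float(np.mean(rep_counts))))
    return float(cv.mean()) / 100.0 / _c4(max(n_rep, 2))
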