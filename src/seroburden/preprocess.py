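"""Scale handling, LLD normalization, and Hook-effect handling.

Order of operations ahead of fold-change computation:

1. linearize log2-scale matrices (:func:`npx_to_linear`) — ratios are
   only meaningful on the linear scale;
2. floor sub-LLD values at the limit of detection
   (:func:`clip_to_lld`), recording which cells were clipped;
3. for panels re-run at higher dilution, find analytes showing the
   Hook (prozone) effect (:func:`detect_hook_effect`) — a diluted run
   reading *higher* than the undiluted one after dilution correction —
   and take those analytes from the diluted run
   (:func:`prefer_diluted`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, ScaleError
from .io import CONCENTRATION, LOG2_NPX, MeasurementMatrix


@dataclass
class HookFlagSet:
    """Analytes showing prozone behavior, with the supporting evidence.

    ``evidence`` has one row per flagged (protein, sample) with the
    undiluted value, the dilution-corrected diluted value and their
    ratio.
    """

    flagged_proteins: set[str] = field(default_factory=set)
    evidence: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["protein", "sample", "undiluted", "diluted_corrected", "ratio"]
        )
    )


def npx_to_linear(matrix: MeasurementMatrix) -> MeasurementMatrix:
    """Exponentiate a log2-scale matrix to the linear scale (2**value)."""
    if matrix.scale != LOG2_NPX:
        raise ScaleError(f"expected log2_npx matrix, got {matrix.scale}")
    values = np.power(2.0, matrix.values)
    return matrix.replace_values(values, scale=CONCENTRATION,
                                 units=f"linear({matrix.units})")


def linear_to_npx(matrix: MeasurementMatrix, units: str = "NPX") -> MeasurementMatrix:
    """Inverse of :func:`npx_to_linear` (log2 of a positive linear matrix)."""
    if matrix.scale != CONCENTRATION:
        raise ScaleError(f"expected concentration matrix, got {matrix.scale}")
    if (matrix.values <= 0).any().any():
        raise ScaleError("cannot log2-transform non-positive values")
    return matrix.replace_values(np.log2(matrix.values), scale=LOG2_NPX, units=units)


def clip_to_lld(matrix: MeasurementMatrix) -> tuple[MeasurementMatrix, pd.DataFrame]:
    """Floor sub-LLD values at the limit of detection.

    Values below the per-protein LLD are replaced by the LLD; values at
    or above it are untouched, so the operation is idempotent. LLDs are
    stored on the linear scale; for log2 matrices the comparison happens
    at ``log2(LLD)``.

    Returns the clipped matrix and a boolean proteins × samples flag
    grid marking which cells were raised.
    """
    if matrix.lld is None:
        raise ConfigurationError(
            f"matrix {matrix.platform_id!r} has no LLD metadata"
        )
    lld = matrix.lld
    missing = lld.index[lld.isna()]
    if len(missing):
        raise ConfigurationError(
            f"missing LLD for proteins: {sorted(missing)[:10]}"
        )
    floor = lld if matrix.scale == CONCENTRATION else np.log2(lld.where(lld > 0))
    if matrix.scale == LOG2_NPX and (lld <= 0).any():
        raise ConfigurationError("log2-scale clipping needs strictly positive LLDs")
    values = matrix.values
    floor_grid = pd.DataFrame(
        np.broadcast_to(floor.to_numpy()[:, None], values.shape),
        index=values.index, columns=values.columns,
    )
    clipped = values.lt(floor_grid) & values.notna()
    out = values.where(~clipped, floor_grid)
    return matrix.replace_values(out), clipped


def detect_hook_effect(
    undiluted: MeasurementMatrix,
    diluted: MeasurementMatrix,
    samples: list[str] | None = None,
    margin: float = 1.0,
) -> HookFlagSet:
    """Flag analytes whose diluted run reads higher than the undiluted one.

    After correcting the diluted run by the dilution-factor ratio, a
    well-behaved analyte reads the same or lower; a strictly higher
    corrected reading (by more than ``margin``-fold) is the signature of
    antibody saturation at high concentration (prozone/Hook effect). By
    default the comparison runs over all shared samples; pass the
    pre-surgical samples to reproduce the high-tumor-load use case.
    """
    if undiluted.scale != CONCENTRATION or diluted.scale != CONCENTRATION:
        raise ScaleError("hook detection needs linear-scale matrices")
    if not diluted.dilution_factor > undiluted.dilution_factor:
        raise ConfigurationError(
            "diluted matrix must have the larger dilution factor"
        )
    if margin <= 0:
        raise ConfigurationError("margin must be > 0")
    missing_u = set(diluted.protein_ids) - set(undiluted.protein_ids)
    missing_d = set(undiluted.protein_ids) - set(diluted.protein_ids)
    if missing_u or missing_d:
        raise AlignmentError(
            f"protein sets differ; missing from undiluted: {sorted(missing_u)}; "
            f"missing from diluted: {sorted(missing_d)}"
        )
    if samples is None:
        samples = [s for s in undiluted.sample_ids if s in set(diluted.sample_ids)]
    correction = diluted.dilution_factor / undiluted.dilution_factor
    u = undiluted.values[samples]
    d = diluted.values.loc[u.index, samples] * correction
    # strict exceedance, with an ulp-scale guard so that values equal up
    # to dilution-correction round-off do not count as excess
    excess = d.gt(u * margin * (1.0 + 1e-9)) & u.notna() & d.notna()
    records = []
    for prot in u.index[excess.any(axis=1)]:
        for sample in excess.columns[excess.loc[prot]]:
            records.append({
                "protein": prot, "sample": sample,
                "undiluted": u.at[prot, sample],
                "diluted_corrected": d.at[prot, sample],
                "ratio": d.at[prot, sample] / u.at[prot, sample],
            })
    evidence = pd.DataFrame(
        records,
        columns=["protein", "sample", "undiluted", "diluted_corrected", "ratio"],
    )
    return HookFlagSet(flagged_proteins=set(evidence["protein"]), evidence=evidence)


def prefer_diluted(
    undiluted: MeasurementMatrix,
    diluted: MeasurementMatrix,
    flags: HookFlagSet,
) -> tuple[MeasurementMatrix, pd.Series]:
    """Merge two runs, taking flagged analytes from the diluted run.

    Diluted-run values are corrected back to the undiluted scale by the
    dilution-factor ratio so rows are commensurable. Returns the merged
    matrix plus a per-protein provenance Series ("undiluted"/"diluted").
    """
    unknown = flags.flagged_proteins - set(undiluted.protein_ids)
    if unknown:
        raise AlignmentError(f"flagged proteins not in matrices: {sorted(unknown)}")
    correction = diluted.dilution_factor / undiluted.dilution_factor
    values = undiluted.values.copy()
    provenance = pd.Series("undiluted", index=values.index, name="provenance")
    flagged = [p for p in values.index if p in flags.flagged_proteins]
    if flagged:
        shared = [s for s in values.columns if s in set(diluted.sample_ids)]
        values.loc[flagged, shared] = (
            diluted.values.loc[flagged, shared] * correction
        )
        provenance.loc[flagged] = "diluted"
    return undiluted.replace_values(values), provenance


def write_hook_flags(flags: HookFlagSet, path) -> None:
    """Export the flag set as a two-column TSV (protein, max evidence ratio)."""
    if flags.evidence.empty:
        out = pd.DataFrame(columns=["protein", "ratio"])
    else:
        out = (flags.evidence.groupby("protein")["ratio"].max()
               .reset_index().sort_values("protein"))
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")
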