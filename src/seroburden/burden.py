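"""Per-patient fold decrease and tiered tumor-burden candidate selection.

The effect measure is the fold decrease FD = pre / post on the linear
scale: FD > 1 means the protein dropped after tumor debulking, FD < 1
means it rose (and can never be selected). A protein becomes a
tumor-burden candidate when at least ``min_patients`` of the cohort show
FD at or above ``fd_threshold`` (default: two-fold or higher in at least
six of nine patients); higher tiers (five-fold, ten-fold) are reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, PairingError
from .io import AnalysisConfig, CONCENTRATION, MeasurementMatrix, SampleSheet

FLAG_LLD_PRE = "lld_clipped_pre"
FLAG_LLD_POST = "lld_clipped_post"
FLAG_HOOK = "hook_substituted"


@dataclass
class FoldDecreaseMatrix:
    """Proteins × patients fold-decrease grid with per-cell provenance.

    ``flags`` maps flag name -> boolean grid aligned with ``values``;
    recognized flags mark cells whose pre or post value was raised to
    the LLD and proteins taken from a diluted re-run.
    """

    values: pd.DataFrame
    flags: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if (self.values.dropna(how="all").fillna(1.0) <= 0).any().any():
            raise DomainError("fold decreases must be positive")
        for name, grid in self.flags.items():
            if not grid.index.equals(self.values.index) or \
               not grid.columns.equals(self.values.columns):
                raise ConfigurationError(f"flag grid {name!r} misaligned with values")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CandidateTable:
    """Per-protein selection summary (the in-memory heatmap table).

    Wraps a DataFrame with per-patient FD columns, optional per-control
    replicate-FC columns, ``median_fd``, one ``n_above_<t>`` count per
    threshold, and the boolean ``selected`` verdict. Rows are ordered by
    descending median FD, ties by descending count then label.
    """

    frame: pd.DataFrame
    patient_columns: list[str]
    control_columns: list[str]
    config: AnalysisConfig

    def as_frame(self) -> pd.DataFrame:
        return self.frame

    @property
    def selected(self) -> list[str]:
        return list(self.frame.index[self.frame["selected"]])

    def n_selected(self) -> int:
        return int(self.frame["selected"].sum())


def fold_decrease(pre: float, post: float) -> float:
    """pre/post ratio on the linear scale; > 1 is a post-surgical drop."""
    if not (pre > 0 and post > 0):
        raise DomainError(f"pre/post must be positive, got ({pre}, {post})")
    return pre / post


def build_fd_matrix(
    matrix: MeasurementMatrix,
    sheet: SampleSheet,
    clipped: pd.DataFrame | None = None,
    hook_provenance: pd.Series | None = None,
) -> FoldDecreaseMatrix:
    """One fold decrease per (protein, patient).

    Technical replicates of a specimen are averaged (arithmetic mean on
    the linear scale) before the ratio. The matrix must already be
    linear-scale and LLD-clipped; ``clipped`` (a boolean proteins ×
    samples grid from :func:`~seroburden.preprocess.clip_to_lld`) and
    ``hook_provenance`` propagate provenance into per-cell flags.
    """
    if matrix.scale != CONCENTRATION:
        raise DomainError("fold decreases need a linear-scale matrix; "
                          "linearize log2 data first")
    pairs = sheet.pre_post_pairs()
    if not pairs:
        raise PairingError("sample sheet contains no patients")
    missing = {
        p for p, (pre_s, post_s) in pairs.items()
        if not set(pre_s) <= set(matrix.sample_ids)
        or not set(post_s) <= set(matrix.sample_ids)
    }
    if missing:
        raise PairingError(f"matrix lacks samples for patients: {sorted(missing)}")
    values = {}
    flag_pre = {}
    flag_post = {}
    for patient, (pre_s, post_s) in pairs.items():
        pre = matrix.values[pre_s].mean(axis=1)
        post = matrix.values[post_s].mean(axis=1)
        if ((pre <= 0) | (post <= 0)).any():
            bad = list(pre.index[(pre <= 0) | (post <= 0)])[:5]
            raise DomainError(
                f"non-positive pre/post means for {patient}: proteins {bad}"
            )
        values[patient] = pre / post
        if clipped is not None:
            flag_pre[patient] = clipped[pre_s].any(axis=1)
            flag_post[patient] = clipped[post_s].any(axis=1)
    fd = pd.DataFrame(values)
    flags: dict[str, pd.DataFrame] = {}
    if clipped is not None:
        flags[FLAG_LLD_PRE] = pd.DataFrame(flag_pre)
        flags[FLAG_LLD_POST] = pd.DataFrame(flag_post)
    if hook_provenance is not None:
        hook = hook_provenance.reindex(fd.index).eq("diluted")
        flags[FLAG_HOOK] = pd.DataFrame(
            np.broadcast_to(hook.to_numpy()[:, None], fd.shape),
            index=fd.index, columns=fd.columns,
        )
    return FoldDecreaseMatrix(values=fd, flags=flags)


def median_fd(values) -> float:
    """Median of per-patient fold decreases (mean of middles for even n)."""
    arr = np.asarray([v for v in values], dtype=float)
    if arr.size == 0:
        raise DomainError("median of empty list")
    if not (arr > 0).all():
        raise DomainError("fold decreases must be positive")
    return float(np.median(arr))


def _count_above(row: pd.Series, threshold: float, strict: bool) -> int:
    vals = row.dropna()
    return int((vals > threshold).sum() if strict else (vals >= threshold).sum())


def select_candidates(
    fd: FoldDecreaseMatrix,
    config: AnalysisConfig | None = None,
    control_fc: pd.DataFrame | None = None,
) -> CandidateTable:
    """Tiered candidate selection over a fold-decrease matrix.

    Per protein: the count of patients with FD at or above
    ``config.fd_threshold`` (strictly above if ``strict_threshold``) and
    each tier threshold, the median FD, and the verdict
    ``count >= min_patients``. ``control_fc`` (proteins × controls
    replicate fold changes) is carried through for reporting.
    """
    config = config or AnalysisConfig()
    values = fd.values
    if values.empty:
        raise ConfigurationError("empty fold-decrease matrix")
    n_patients = values.shape[1]
    if config.min_patients > n_patients:
        raise ConfigurationError(
            f"min_patients={config.min_patients} exceeds cohort size {n_patients}"
        )
    strict = config.strict_threshold
    frame = pd.DataFrame(index=values.index)
    patient_cols = list(values.columns)
    frame[patient_cols] = values
    control_cols: list[str] = []
    if control_fc is not None:
        control_cols = list(control_fc.columns)
        frame[control_cols] = control_fc.reindex(values.index)
    frame["median_fd"] = values.apply(
        lambda row: median_fd(row.dropna()) if row.notna().any() else np.nan, axis=1
    )
    thresholds = [config.fd_threshold, *config.tiers]
    for t in thresholds:
        frame[_count_col(t)] = values.apply(
            lambda row, t=t: _count_above(row, t, strict), axis=1
        )
    frame["selected"] = frame[_count_col(config.fd_threshold)] >= config.min_patients
    frame["_label"] = frame.index
    frame = frame.sort_values(
        by=["median_fd", _count_col(config.fd_threshold), "_label"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_label")
    return CandidateTable(frame=frame, patient_columns=patient_cols,
                          control_columns=control_cols, config=config)


def _count_col(threshold: float) -> str:
    t = f"{threshold:g}"
    return f"n_above_{t}"


def tier_counts(fd: FoldDecreaseMatrix, tier: float, min_patients: int) -> int:
    """Number of proteins with FD >= tier in at least ``min_patients``."""
    if tier <= 1:
        raise ConfigurationError("tier threshold must be > 1")
    if min_patients < 1:
        raise ConfigurationError("min_patients must be >= 1")
    counts = fd.values.apply(lambda row: _count_above(row, tier, False), axis=1)
    return int((counts >= min_patients).sum())


def patient_signatures(
    fd: FoldDecreaseMatrix,
    threshold: float = 2.0,
    strict: bool = False,
) -> dict[str, list[str]]:
    """Per patient, the proteins at/above threshold, sorted by descending FD.

    Each patient's list is their personal tumor-protein signature: the
    analytes whose serum level fell at least ``threshold``-fold after
    their surgery.
    """
    out: dict[str, list[str]] = {}
    for patient in fd.values.columns:
        col = fd.values[patient].dropna()
        hit = col[col > threshold] if strict else col[col >= threshold]
        hit = hit.sort_values(ascending=False, kind="mergesort")
        out[patient] = list(hit.index)
    return out


def write_signatures(signatures: dict[str, list[str]], path) -> None:
    rows = [
        {"patient": patient, "n_proteins": len(prots),
         "signature": ";".join(prots)}
        for patient, prots in signatures.items()
    ]
    pd.DataFrame(rows, columns=["patient", "n_proteins", "signature"]).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )
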