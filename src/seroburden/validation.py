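"""Orthogonal validation against single-target reference assays.

A multiplex platform's per-patient fold decreases are compared with an
independent single-target (ELISA-style) assay of the same sera: per
target protein, Pearson correlation and absolute-mode Bland–Altman over
the shared subjects, plus a qualitative verdict — *directionally
concordant* when both methods put the same subjects at/above the
fold-decrease threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .concordance import ConcordanceResult, MODE_ABSOLUTE, bland_altman, pearson
from .errors import SampleSizeError, ScaleError, TargetError
from .io import CONCENTRATION, MeasurementMatrix


@dataclass
class TargetValidation:
    """Per-target comparison of multiplex vs reference fold decreases."""

    target: str
    subjects: list[str]
    result: ConcordanceResult
    concordant: bool
    above_multiplex: list[str] = field(default_factory=list)
    above_reference: list[str] = field(default_factory=list)


def validate_fold_changes(
    multiplex_fd,
    reference_fd,
    targets,
    threshold: float = 2.0,
    z: float = 1.96,
) -> dict[str, TargetValidation]:
    """Compare per-patient FDs between a multiplex and a reference assay.

    For each target protein: Pearson (when >=3 shared subjects) and
    absolute-mode Bland–Altman over the shared subjects' fold
    decreases. The verdict is directionally concordant iff the two
    methods agree on *which* subjects reached ``threshold``-fold
    decrease — a symmetric criterion.
    """
    out: dict[str, TargetValidation] = {}
    shared_subjects = [
        s for s in multiplex_fd.values.columns
        if s in set(reference_fd.values.columns)
    ]
    for target in targets:
        if target not in multiplex_fd.values.index:
            raise TargetError(f"target {target!r} missing from multiplex matrix")
        if target not in reference_fd.values.index:
            raise TargetError(f"target {target!r} missing from reference matrix")
        m = multiplex_fd.values.loc[target, shared_subjects]
        r = reference_fd.values.loc[target, shared_subjects]
        keep = m.notna() & r.notna()
        subjects = list(m.index[keep])
        if len(subjects) < 2:
            raise SampleSizeError(
                f"target {target!r}: need >=2 shared subjects, got {len(subjects)}"
            )
        res = bland_altman(m[keep], r[keep], mode=MODE_ABSOLUTE, z=z, ids=subjects)
        above_m = [s for s in subjects if m[s] >= threshold]
        above_r = [s for s in subjects if r[s] >= threshold]
        out[target] = TargetValidation(
            target=target,
            subjects=subjects,
            result=res,
            concordant=set(above_m) == set(above_r),
            above_multiplex=above_m,
            above_reference=above_r,
        )
    return out


def concentration_correlation(
    a: MeasurementMatrix,
    b: MeasurementMatrix,
    protein: str,
    samples,
) -> tuple[float, float, int]:
    """Pearson correlation of absolute concentrations for one protein.

    Both matrices must be concentration-scale (the comparison only
    makes sense for absolute quantitation); pre- and post-surgical
    samples of the validation subjects are pooled into one vector per
    method.
    """
    if a.scale != CONCENTRATION or b.scale != CONCENTRATION:
        raise ScaleError("concentration correlation needs concentration-scale "
                         f"matrices, got {a.scale} and {b.scale}")
    for m, name in ((a, "a"), (b, "b")):
        if protein not in m.values.index:
            raise TargetError(f"protein {protein!r} missing from matrix {name}")
    samples = list(samples)
    missing = [s for s in samples
               if s not in a.values.columns or s not in b.values.columns]
    if missing:
        raise TargetError(f"samples missing from a matrix: {missing}")
    x = a.values.loc[protein, samples]
    y = b.values.loc[protein, samples]
    keep = x.notna() & y.notna()
    if keep.sum() < 3:
        raise SampleSizeError(
            f"need >=3 shared finite samples, got {int(keep.sum())}"
        )
    return pearson(x[keep], y[keep])


def write_validation_report(reports: dict[str, TargetValidation], path) -> None:
    rows = []
    for target, rep in reports.items():
        rows.append({
            "target": target,
            "n_subjects": len(rep.subjects),
            "r": rep.result.r,
            "p_two_sided": rep.result.p_two_sided,
            "bias": rep.result.bias,
            "loa_low": rep.result.loa_low,
            "loa_high": rep.result.loa_high,
            "concordant": rep.concordant,
            "above_multiplex": ";".join(rep.above_multiplex),
            "above_reference": ";".join(rep.above_reference),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
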