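"""Cross-platform and cross-method agreement statistics.

Agreement between two measurement methods is assessed two ways, as is
standard in method-comparison studies:

* Pearson correlation with a two-sided p-value (t distribution with
  n - 2 degrees of freedom) — association, not agreement;
* Bland–Altman analysis — the mean paired difference (bias) and the
  95% limits of agreement ``bias ± 1.96 · SD`` of the differences, in
  absolute units or as percent of the pair mean for wide-ranged data.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AmbiguityError,
    DegenerateInputError,
    DomainError,
    SampleSizeError,
)

MODE_ABSOLUTE = "absolute"
MODE_PERCENT = "percent"


@dataclass
class ConcordanceResult:
    """Paired-method agreement summary.

    ``r``/``p_two_sided`` are NaN when fewer than 3 pairs are available
    (the correlation is undefined there; the Bland–Altman part only
    needs 2). ``outlier_ids`` lists pairs whose difference falls outside
    the closed LOA interval.
    """

    n: int
    r: float
    p_two_sided: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    within_loa_fraction: float
    outlier_ids: list = field(default_factory=list)
    mode: str = MODE_ABSOLUTE

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D vectors of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values in paired vectors")
    return x, y


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p-value.

    r is the normalized covariance; the p-value comes from
    ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise SampleSizeError(f"need >=3 pairs for a correlation, got {n}")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateInputError("zero variance in one input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)


def bland_altman(
    x, y,
    mode: str = MODE_ABSOLUTE,
    z: float = 1.96,
    ids=None,
) -> ConcordanceResult:
    """Bland–Altman agreement of two paired measurement vectors.

    Differences are ``x - y`` (absolute mode) or
    ``100 * (x - y) / ((x + y)/2)`` (percent mode); bias is their mean,
    the limits of agreement are ``bias ± z · SD`` with the sample
    (n-1) standard deviation. Pairs whose difference falls outside the
    closed LOA interval are reported as outliers; ``ids`` (default
    0-based positions) labels them.
    """
    if mode not in (MODE_ABSOLUTE, MODE_PERCENT):
        raise DomainError(f"unknown mode {mode!r}")
    if z <= 0:
        raise DomainError("z must be > 0")
    x, y = _paired(x, y)
    n = x.size
    if n < 2:
        raise SampleSizeError(f"need >=2 pairs, got {n}")
    ids = list(ids) if ids is not None else list(range(n))
    if len(ids) != n:
        raise DomainError("ids length does not match data")
    if mode == MODE_ABSOLUTE:
        d = x - y
    else:
        m = (x + y) / 2.0
        if np.any(m == 0):
            bad = [ids[i] for i in np.flatnonzero(m == 0)]
            raise DomainError(f"zero pair mean in percent mode for pairs: {bad}")
        d = 100.0 * (x - y) / m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - z * sd
    loa_high = bias + z * sd
    outside = (d < loa_low) | (d > loa_high)
    outliers = [ids[i] for i in np.flatnonzero(outside)]
    if n >= 3 and not (np.allclose(x, x[0]) or np.allclose(y, y[0])):
        r, p, _ = pearson(x, y)
    else:
        r, p = float("nan"), float("nan")
    return ConcordanceResult(
        n=n, r=r, p_two_sided=p, bias=bias, sd_diff=sd,
        loa_low=float(loa_low), loa_high=float(loa_high),
        within_loa_fraction=1.0 - len(outliers) / n,
        outlier_ids=outliers, mode=mode,
    )


# ---------------------------------------------------------------------------
# Analyte matching across platforms
# ---------------------------------------------------------------------------

@dataclass
class MatchedTargets:
    """One-to-one pairing of analyte labels across two platforms."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    """(label in A, label in B, normalized key that joined them)."""
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)


_PAREN = re.compile(r"\(([^()]*)\)")


def _normalize(label: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", label.upper())


def _keys_for(label: str, aliases: dict[str, str] | None) -> set[str]:
    """Normalized keys for a label: the full name, each parenthetical
    synonym, and the name with parentheticals stripped."""
    keys = {_normalize(label)}
    for syn in _PAREN.findall(label):
        if syn.strip():
            keys.add(_normalize(syn))
    stripped = _PAREN.sub("", label)
    if stripped.strip():
        keys.add(_normalize(stripped))
    keys.discard("")
    if aliases:
        keys |= {aliases[k] for k in keys if k in aliases}
    return keys


def match_targets(
    labels_a,
    labels_b,
    aliases: dict[str, str] | None = None,
) -> MatchedTargets:
    """Pair analyte labels across platforms by normalized name.

    Keys are uppercase alphanumeric reductions of the label, its
    parenthetical synonyms ("Cancer antigen 125 (CA125)" yields both
    CANCERANTIGEN125 and CA125), and user aliases (alias key -> normalized
    canonical key, consulted before literal matching). Pairing must be
    one-to-one; a key resolving to several labels on one side, or a
    label matching several on the other, raises :class:`AmbiguityError`.
    """
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if not labels_a or not labels_b:
        raise DomainError("label lists must be non-empty")
    if aliases:
        aliases = {_normalize(k): _normalize(v) for k, v in aliases.items()}

    def key_index(labels, side):
        idx: dict[str, str] = {}
        per_label = {}
        for lab in labels:
            keys = _keys_for(lab, aliases)
            per_label[lab] = keys
            for k in keys:
                if k in idx and idx[k] != lab:
                    raise AmbiguityError(
                        f"key {k!r} matches several labels on side {side}: "
                        f"{[idx[k], lab]}"
                    )
                idx[k] = lab
        return idx, per_label

    idx_b, _ = key_index(labels_b, "B")
    _, keys_a = key_index(labels_a, "A")

    pairs = []
    matched_b = set()
    for lab_a in labels_a:
        shared = [k for k in keys_a[lab_a] if k in idx_b]
        hits = {idx_b[k] for k in shared}
        if len(hits) > 1:
            raise AmbiguityError(
                f"label {lab_a!r} matches several labels on side B: "
                f"{sorted(hits)}"
            )
        if hits:
            lab_b, = hits
            # report the shortest joining key (the symbol-like synonym)
            key = min(shared, key=lambda k: (len(k), k))
            pairs.append((lab_a, lab_b, key))
            matched_b.add(lab_b)
    matched_a = {a for a, _, _ in pairs}
    return MatchedTargets(
        pairs=pairs,
        unmatched_a=[l for l in labels_a if l not in matched_a],
        unmatched_b=[l for l in labels_b if l not in matched_b],
    )


def overlap_concordance(fd_a, fd_b, matches: MatchedTargets,
                        z: float = 1.96) -> ConcordanceResult:
    """Pooled agreement over all matched (protein, patient) FD pairs.

    Every matched protein contributes one pair per shared patient; the
    pooled vectors feed Pearson plus percent-mode Bland–Altman (percent
    differences tame the wide fold-change range).
    """
    patients = [p for p in fd_a.values.columns if p in set(fd_b.values.columns)]
    if not patients:
        raise SampleSizeError("no shared patients between platforms")
    xs, ys, ids = [], [], []
    for lab_a, lab_b, _key in matches.pairs:
        if lab_a not in fd_a.values.index or lab_b not in fd_b.values.index:
            continue
        for patient in patients:
            va = fd_a.values.at[lab_a, patient]
            vb = fd_b.values.at[lab_b, patient]
            if np.isfinite(va) and np.isfinite(vb):
                xs.append(va)
                ys.append(vb)
                ids.append((lab_a, patient))
    if len(xs) < 3:
        raise SampleSizeError(f"need >=3 matched finite FD pairs, got {len(xs)}")
    return bland_altman(xs, ys, mode=MODE_PERCENT, z=z, ids=ids)


def write_concordance(result: ConcordanceResult, path) -> None:
    row = result.as_dict()
    row["outlier_ids"] = ";".join(str(i) for i in result.outlier_ids)
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_pair_data(x, y, path, ids=None) -> None:
    """Export per-pair plot data (x, y, mean, diff) for external plotting."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    df = pd.DataFrame({
        "id": list(ids) if ids is not None else list(range(x.size)),
        "x": x, "y": y, "mean": (x + y) / 2.0, "diff": x - y,
    })
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
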