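"""Synthetic two-platform serum cohort generator, with ground truth.

The generator emulates the structure of a pre-/post-surgery serum
profiling study on two multiplex immunoassay platforms:

* platform A — a large relative-quantitation panel reported on a log2
  scale, run in singlicate with duplicate control sera and low
  technical noise;
* platform B — an absolute-quantitation antibody array (pg/mL) run in
  technical quadruplicates with higher noise, lower-limit-of-detection
  censoring, and saturation (Hook/prozone) behavior above a
  concentration knee.

A subset of the shared (overlap) analytes are planted tumor-burden
proteins: their pre-surgical level is multiplied by a per-patient true
fold decrease relative to post-surgery, applied with a per-patient
penetrance. Everything needed for parameter-recovery tests is returned
as :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .burden import FoldDecreaseMatrix
from .errors import ConfigurationError
from .io import (
    CONCENTRATION,
    LOG2_NPX,
    MeasurementMatrix,
    SampleSheet,
)


@dataclass
class SimulationParams:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults mirror the reference design: 9 patients sampled pre and
    post surgery, 2 healthy controls split into duplicate aliquots,
    1073 analytes on platform A vs 1000 on platform B with 444 shared,
    15 planted burden proteins with ~4-fold typical decreases, ~8%
    technical CV on platform A and ~25% on platform B (quadruplicates),
    5% LLD censoring and a saturation knee at the 99.5th abundance
    percentile.
    """

    n_patients: int = 9
    n_controls: int = 2
    n_proteins_a: int = 1073
    n_proteins_b: int = 1000
    n_overlap: int = 444
    n_burden: int = 15
    burden_log2fd_mean: float = 2.0
    burden_log2fd_sd: float = 1.0
    burden_fd_min: float = 1.0
    burden_penetrance: float = 0.85
    cv_a: float = 0.08
    cv_b: float = 0.25
    subject_cv: float = 0.30
    lld_quantile: float = 0.05
    hook_knee_quantile: float = 0.995
    n_replicates_a_control: int = 2
    n_replicates_b: int = 4
    baseline_log10_mean: float = 2.5
    baseline_log10_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_proteins_a, self.n_proteins_b):
            raise ConfigurationError("n_overlap exceeds a platform's panel size")
        if self.n_burden > self.n_overlap:
            raise ConfigurationError("n_burden exceeds n_overlap")
        if min(self.cv_a, self.cv_b, self.subject_cv) < 0:
            raise ConfigurationError("CVs must be >= 0")
        if not 0 <= self.burden_penetrance <= 1:
            raise ConfigurationError("burden_penetrance must be in [0, 1]")
        if not 0 <= self.lld_quantile < 1:
            raise ConfigurationError("lld_quantile must be in [0, 1)")
        if not 0 < self.hook_knee_quantile <= 1:
            raise ConfigurationError("hook_knee_quantile must be in (0, 1]")
        if self.burden_fd_min < 1:
            raise ConfigurationError("burden_fd_min must be >= 1")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ConfigurationError("need >=1 patient and >=1 control")
        if self.n_replicates_b < 2 or self.n_replicates_a_control < 2:
            raise ConfigurationError("replicate counts must be >= 2")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    burden_proteins: list[str]
    true_fd: pd.DataFrame
    """Burden proteins × patients grid of realized true fold decreases
    (1.0 where the effect did not penetrate)."""
    hook_affected: list[str]
    """Proteins whose true pre-surgical level exceeds the saturation knee
    for at least one patient (platform B)."""
    hook_knee: float
    params: SimulationParams = None

    def fd_for(self, protein: str, patient: str) -> float:
        if protein in self.true_fd.index and patient in self.true_fd.columns:
            return float(self.true_fd.at[protein, patient])
        return 1.0

    def to_tsv(self, path) -> None:
        out = self.true_fd.copy()
        out.index.name = "protein"
        out.to_csv(path, sep="\t", encoding="utf-8")


@dataclass
class CohortData:
    """Everything :func:`simulate_cohort` produces."""

    matrix_a: MeasurementMatrix
    matrix_b: MeasurementMatrix
    sheet_a: SampleSheet
    sheet_b: SampleSheet
    truth: SyntheticTruth


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal error with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=shape)


def _hook_transform(conc: np.ndarray, knee: float) -> np.ndarray:
    """Saturating response: linear up to the knee, then knee^2 / conc.

    The simplest smooth decreasing branch consistent with prozone
    behavior — the reported signal falls as the true concentration
    rises beyond the knee.
    """
    out = conc.copy()
    over = conc > knee
    out[over] = knee ** 2 / conc[over]
    return out


def _draw_true_fd(rng, params: SimulationParams,
                  burden: list[str], patients: list[str]) -> pd.DataFrame:
    lo = np.log2(params.burden_fd_min)
    a = (lo - params.burden_log2fd_mean) / params.burden_log2fd_sd
    n = len(burden) * len(patients)
    log2fd = stats.truncnorm.rvs(
        a, np.inf, loc=params.burden_log2fd_mean,
        scale=params.burden_log2fd_sd, size=n, random_state=rng,
    ).reshape(len(burden), len(patients))
    respond = rng.random((len(burden), len(patients))) < params.burden_penetrance
    fd = np.where(respond, np.exp2(log2fd), 1.0)
    return pd.DataFrame(fd, index=burden, columns=patients)


def simulate_cohort(params: SimulationParams | None = None,
                    seed: int | None = None) -> CohortData:
    """Simulate one full two-platform cohort.

    Baseline abundances are lognormal spanning roughly four decades;
    each subject modulates every protein by a lognormal subject effect
    (30% CV by default), making the pre/post pairing intra-individual.
    Post-surgical truth is the pre-surgical truth divided by the
    planted fold decrease. Measurements multiply truth by lognormal
    platform noise; platform A is reported as log2 values with a global
    run offset, platform B as concentrations with technical replicates
    and a saturating response above the knee. Fully reproducible from
    the seed.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    overlap = [f"SP{i:04d}" for i in range(1, params.n_overlap + 1)]
    only_a = [f"PA{i:04d}" for i in range(1, params.n_proteins_a - params.n_overlap + 1)]
    only_b = [f"PB{i:04d}" for i in range(1, params.n_proteins_b - params.n_overlap + 1)]
    proteins_a = overlap + only_a
    proteins_b = overlap + only_b
    all_proteins = overlap + only_a + only_b
    patients = [f"P{i}" for i in range(1, params.n_patients + 1)]
    controls = [f"C{i}" for i in range(1, params.n_controls + 1)]

    burden = sorted(rng.choice(overlap, size=params.n_burden, replace=False))
    true_fd = _draw_true_fd(rng, params, burden, patients)

    baseline = pd.Series(
        10.0 ** rng.normal(params.baseline_log10_mean,
                           params.baseline_log10_sd, len(all_proteins)),
        index=all_proteins,
    )
    sigma_s = np.sqrt(np.log1p(params.subject_cv ** 2))
    subj_eff = pd.DataFrame(
        rng.lognormal(-sigma_s ** 2 / 2.0, sigma_s,
                      (len(all_proteins), len(patients) + len(controls))),
        index=all_proteins, columns=patients + controls,
    )

    # true concentrations per (protein, specimen)
    pre_true = subj_eff[patients].mul(baseline, axis=0)
    fd_grid = pd.DataFrame(1.0, index=all_proteins, columns=patients)
    fd_grid.loc[burden, patients] = true_fd
    post_true = pre_true / fd_grid
    control_true = subj_eff[controls].mul(baseline, axis=0)

    # ---- platform A: log2 singlicate, duplicate controls -----------------
    cols_a = {}
    for p in patients:
        cols_a[f"{p}_pre"] = pre_true.loc[proteins_a, p]
        cols_a[f"{p}_post"] = post_true.loc[proteins_a, p]
    for c in controls:
        for r in range(1, params.n_replicates_a_control + 1):
            cols_a[f"{c}_r{r}"] = control_true.loc[proteins_a, c]
    conc_a = pd.DataFrame(cols_a)
    conc_a = conc_a * _lognormal_noise(rng, params.cv_a, conc_a.shape)
    plate_offset = rng.normal(0.0, 0.25)
    npx = np.log2(conc_a) + plate_offset
    lld_a = float(np.quantile(baseline[proteins_a], params.lld_quantile)) \
        if params.lld_quantile > 0 else float(baseline[proteins_a].min()) * 0.5
    # LLD metadata is linear-scale and per protein; offset moves it too so
    # that clipping on reported values stays consistent with the run.
    matrix_a = MeasurementMatrix(
        platform_id="platform_a", scale=LOG2_NPX, units="NPX",
        values=npx,
        lld=pd.Series(lld_a * 2.0 ** plate_offset, index=proteins_a),
    )
    rows_a = []
    for p in patients:
        rows_a.append((f"{p}_pre", p, "patient", "pre", 1))
        rows_a.append((f"{p}_post", p, "patient", "post", 1))
    for c in controls:
        for r in range(1, params.n_replicates_a_control + 1):
            rows_a.append((f"{c}_r{r}", c, "control", "none", r))
    sheet_a = SampleSheet(rows=pd.DataFrame(
        rows_a, columns=["sample_id", "subject_id", "role",
                         "timepoint", "replicate_id"]))

    # ---- platform B: concentration, quadruplicates, hook + LLD -----------
    knee = float(np.quantile(pre_true.loc[proteins_b].to_numpy(),
                             params.hook_knee_quantile))
    cols_b = {}
    rows_b = []

    def add_specimen(sample_base, subject, role, tp, truth_col):
        signal = _hook_transform(truth_col.to_numpy(copy=True), knee)
        for r in range(1, params.n_replicates_b + 1):
            noisy = signal * _lognormal_noise(rng, params.cv_b, signal.shape)
            cols_b[f"{sample_base}_r{r}"] = pd.Series(noisy, index=proteins_b)
            rows_b.append((f"{sample_base}_r{r}", subject, role, tp, r))

    for p in patients:
        add_specimen(f"{p}_pre", p, "patient", "pre", pre_true.loc[proteins_b, p])
        add_specimen(f"{p}_post", p, "patient", "post", post_true.loc[proteins_b, p])
    for c in controls:
        add_specimen(c, c, "control", "none", control_true.loc[proteins_b, c])
    conc_b = pd.DataFrame(cols_b)
    lld_b = float(np.quantile(baseline[proteins_b], params.lld_quantile)) \
        if params.lld_quantile > 0 else float(baseline[proteins_b].min()) * 0.5
    matrix_b = MeasurementMatrix(
        platform_id="platform_b", scale=CONCENTRATION, units="pg/mL",
        values=conc_b, lld=pd.Series(lld_b, index=proteins_b),
    )
    sheet_b = SampleSheet(rows=pd.DataFrame(
        rows_b, columns=["sample_id", "subject_id", "role",
                         "timepoint", "replicate_id"]))

    hook_affected = sorted(
        pre_true.loc[proteins_b].index[(pre_true.loc[proteins_b] > knee).any(axis=1)]
    )
    truth = SyntheticTruth(
        burden_proteins=list(burden), true_fd=true_fd,
        hook_affected=hook_affected, hook_knee=knee, params=params,
    )
    return CohortData(matrix_a=matrix_a, matrix_b=matrix_b,
                      sheet_a=sheet_a, sheet_b=sheet_b, truth=truth)


def simulate_dilution_pair(
    params: SimulationParams | None = None,
    seed: int | None = None,
    dilution: float = 10.0,
    cv: float | None = None,
) -> tuple[MeasurementMatrix, MeasurementMatrix, SyntheticTruth]:
    """Simulate an undiluted + diluted re-run of the pre-surgical sera.

    Both runs share the same true concentrations and saturation knee;
    the diluted run measures ``conc / dilution``, which usually falls
    back into the linear range. Returns (undiluted, diluted, truth) —
    the proteins above the knee in truth are exactly those a
    Hook-effect screen should flag.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cv = params.cv_b if cv is None else cv

    proteins = [f"SP{i:04d}" for i in range(1, params.n_proteins_b + 1)]
    patients = [f"P{i}" for i in range(1, params.n_patients + 1)]
    baseline = pd.Series(
        10.0 ** rng.normal(params.baseline_log10_mean,
                           params.baseline_log10_sd, len(proteins)),
        index=proteins,
    )
    sigma_s = np.sqrt(np.log1p(params.subject_cv ** 2))
    pre_true = pd.DataFrame(
        rng.lognormal(-sigma_s ** 2 / 2.0, sigma_s, (len(proteins), len(patients))),
        index=proteins, columns=[f"{p}_pre" for p in patients],
    ).mul(baseline, axis=0)
    knee = float(np.quantile(pre_true.to_numpy(), params.hook_knee_quantile))

    undil = _hook_transform(pre_true.to_numpy(copy=True), knee)
    undil = undil * _lognormal_noise(rng, cv, undil.shape)
    dil = _hook_transform(pre_true.to_numpy() / dilution, knee)
    dil = dil * _lognormal_noise(rng, cv, dil.shape)

    undiluted = MeasurementMatrix(
        platform_id="undiluted", scale=CONCENTRATION, units="pg/mL",
        values=pd.DataFrame(undil, index=proteins, columns=pre_true.columns),
        dilution_factor=1.0,
    )
    diluted = MeasurementMatrix(
        platform_id="diluted", scale=CONCENTRATION, units="pg/mL",
        values=pd.DataFrame(dil, index=proteins, columns=pre_true.columns),
        dilution_factor=dilution,
    )
    hook_affected = sorted(pre_true.index[(pre_true > knee).any(axis=1)])
    truth = SyntheticTruth(
        burden_proteins=[], true_fd=pd.DataFrame(index=[], columns=pre_true.columns),
        hook_affected=hook_affected, hook_knee=knee, params=params,
    )
    return undiluted, diluted, truth


# ---------------------------------------------------------------------------
# Published-table fixtures
# ---------------------------------------------------------------------------

@dataclass
class TableFixture:
    """A published fold-decrease heatmap table, as shipped in-repo."""

    fd: FoldDecreaseMatrix
    control_fc: pd.DataFrame
    printed_median: pd.Series
    printed_count: pd.Series

    @property
    def proteins(self) -> list[str]:
        return list(self.fd.values.index)


_FIXTURE_FILES = {"pea": "table1_pea.tsv", "qka": "table2_qka.tsv"}


def make_table_fixture(which: str) -> TableFixture:
    """Load one of the two published fold-decrease tables.

    ``which`` is ``"pea"`` (15 proteins × 9 patients, relative
    log2-panel platform) or ``"qka"`` (11 × 9, absolute-concentration
    array). Values are the printed 1-decimal fold decreases, control
    fold changes, medians and per-row patient counts.
    """
    if which not in _FIXTURE_FILES:
        raise ConfigurationError(
            f"unknown fixture {which!r}; expected one of {sorted(_FIXTURE_FILES)}"
        )
    ref = resources.files("seroburden.data") / _FIXTURE_FILES[which]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    patient_cols = [c for c in df.columns if c.startswith("P")]
    control_cols = [c for c in df.columns if c.startswith("C")]
    fd = FoldDecreaseMatrix(values=df[patient_cols].astype(float))
    return TableFixture(
        fd=fd,
        control_fc=df[control_cols].astype(float),
        printed_median=df["median_fd"].astype(float),
        printed_count=df["n_above"].astype(int),
    )
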