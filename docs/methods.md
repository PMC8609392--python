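# Methods

## Study design the pipeline assumes

The pipeline targets an intra-individual pre/post design: each patient
serves as their own control, with serum drawn shortly before
tumor-debulking surgery and again a few weeks after. Two multiplex
immunoassay platforms measure largely overlapping protein panels:

* **platform A** — relative quantitation on a log2 scale (one unit =
  two-fold), run in singlicate with duplicate control sera; typical
  technical CV well under 10%;
* **platform B** — absolute quantitation (pg/mL) against standard
  curves, run in technical quadruplicates; typical CV 20–25% with a
  heavy tail.

Healthy-control sera split into identical aliquots anchor the
technical-noise estimate: any pre/post-style "fold change" seen between
identical aliquots is pure measurement error.

## Fold decrease and candidate selection

All ratios are taken on the linear scale; log2 data are exponentiated
first (`npx_to_linear`), because differences of log2 units — not raw
log values — correspond to concentration ratios. Values below the
lower limit of detection are raised to the LLD before ratioing, so a
protein undetectable at both timepoints yields FD = 1 exactly (no
change), and a protein falling from detectable to undetectable yields a
conservative lower bound on its true decrease. Per-cell flags record
which fold decreases involve clipped values.

Technical replicates of a specimen are averaged arithmetically on the
linear scale before the ratio (the convention of concentration-scale
immunoassay software).

Selection is inclusive (`FD >= 2`), counting patients per protein and
requiring at least 6 of 9 by default. The inclusive comparison is a
deliberate choice: on 1-decimal data a printed "2.0" cell may be
either side of the threshold, and the inclusive rule reproduces the
shipped tables' headline counts (15 and 11 selected proteins) exactly.
A `strict_threshold` switch provides the `>` variant. Per-row counts
recomputed from rounded values can differ by ±1 from originally
published counts wherever a cell prints exactly at the threshold; the
tests treat the `[strict, inclusive]` bracket as the information a
1-decimal table actually carries, rather than forcing either reading.

Output ordering is deterministic: median FD descending, then count
descending, then label ascending.

## Replicate QC

The replicate fold change is symmetric, `max/min >= 1`, so duplicate
order cannot flip a verdict. A protein is removed if it exceeds the
cutoff (default 2) in *any* control subject — the conservative reading,
since a single unstable control already demonstrates assay
instability. A whitelist exists because a high-priority analyte (e.g. a
clinically established marker) may be retained by design despite noisy
controls; published candidate tables appear to have done exactly this
for their positive-control analyte.

CV is `100 · sample SD / mean` (n−1 denominator) per protein per
replicated specimen, averaged over specimens; profile fractions report
the panel shares under 10%, under 20% and over 100% CV. For
parameter-recovery use, `estimate_platform_cv` divides the mean
replicate CV by the c4 small-sample factor (≈0.921 at n = 4): the raw
sample SD is biased low at quadruplicate depth, and without the
correction a platform simulated at CV 0.25 reads back as ≈0.225.

## Hook (prozone) handling

At very high analyte concentration both capture and detection
antibodies saturate and the reported signal *drops*. The detectable
signature is a dilution series that misbehaves: after multiplying by
the dilution factor, a diluted run should read the same or slightly
lower than the undiluted one — reading strictly higher flags the
analyte. The comparison defaults to all shared samples; passing only
pre-surgical samples reproduces the high-tumor-load use case. No
numeric margin beyond strict excess is imposed by default (the margin
is configurable); an ulp-scale guard keeps exactly-equal values from
counting as excess. Flagged analytes are then taken wholesale from the
diluted run (`prefer_diluted`), dilution-corrected, with provenance
recorded.

## Agreement statistics

Pearson r uses the standard normalized covariance with a two-sided p
from `t = r·sqrt((n−2)/(1−r²))` on n−2 df; it is reported, never used
as a selection gate. Bland–Altman bias is the mean paired difference
and the limits of agreement are `bias ± z·SD` with z = 1.96 and the
**sample** (n−1) SD — recomputing the shipped FOLR1 limits from the
printed fold decreases reproduces them exactly only with the n−1
denominator. Outlier membership uses the closed interval (boundary
values are inside). Percent mode divides by the pair mean
`(x+y)/2` — the standard percent Bland–Altman variant — and is used
when pooling many analytes whose fold changes span orders of magnitude.

Analyte matching across platforms normalizes labels to uppercase
alphanumerics, expands parenthetical synonyms ("Cancer antigen 125
(CA125)" matches both the long name and CA125), consults a user alias
map first, and insists on one-to-one pairing, raising on ambiguity.

## Synthetic cohort generator

`simulate_cohort` draws, in order:

| parameter | default | meaning |
|---|---|---|
| `n_patients` / `n_controls` | 9 / 2 | cohort and control design |
| `n_proteins_a` / `n_proteins_b` / `n_overlap` | 1073 / 1000 / 444 | panel sizes and shared analytes |
| `n_burden` | 15 | planted tumor-burden proteins (on the shared panel) |
| `burden_log2fd_mean` / `sd` | 2.0 / 1.0 | log2 of the true fold decrease, i.e. ~4-fold typical |
| `burden_fd_min` | 1.0 | truncation floor of the planted FD |
| `burden_penetrance` | 0.85 | probability a burden protein responds in a given patient |
| `cv_a` / `cv_b` | 0.08 / 0.25 | multiplicative technical CV per platform |
| `subject_cv` | 0.30 | between-subject lognormal variation |
| `baseline_log10_mean` / `sd` | 2.5 / 1.0 | lognormal abundance, ~4 decades across the panel |
| `lld_quantile` | 0.05 | baseline quantile used as the LLD |
| `hook_knee_quantile` | 0.995 | abundance quantile above which the response saturates |
| `n_replicates_b` | 4 | platform B technical replicates |

Baselines are lognormal (`10^N(2.5, 1)` pg/mL), matching the ~3–4
decade dynamic range of concentration-scale arrays. Noise is
multiplicative lognormal with exact unit mean (`σ² = ln(1+cv²)`,
`μ = −σ²/2`) — the immunoassay-standard error model; the published CV
summaries for the two platform families (mostly <10% vs ~20–25%)
calibrate the defaults. Subject effects (30% CV) make the pre/post
pairing genuinely intra-individual: an unpaired analysis of the same
data is visibly noisier. Above the knee the response follows
`signal = knee²/conc`, the simplest smooth decreasing branch
consistent with prozone behavior. Platform A adds a single log2 run
offset (median-normalization surrogate) that cancels in all
intra-run ratios; its LLD metadata is shifted by the same offset so
clipping stays consistent with reported values. All draws flow from a
single seeded generator; identical seeds give bit-identical cohorts.

`simulate_dilution_pair` produces an undiluted/1:10 pair sharing one
truth, for exercising the Hook screen: at zero noise the flagged set
equals exactly the proteins whose true concentration exceeds the knee.

The two platforms return separate sample sheets because their
replicate designs differ (singlicate log2 panel vs quadruplicate
array); a single sheet cannot validate both matrices.

**What the generator does not emulate**: plate spatial effects, batch
drift, inter-plate bridging, PCR/chemistry artifacts, correlated
(panel-structured) noise, or missing-at-random dropout. Passing
recovery tests therefore demonstrate correctness of the pipeline's
arithmetic and decision rules under the stated noise model — not
robustness to every failure mode of real assay data.

## Problem sizes in tests

Recovery studies run at reduced panel sizes chosen to keep the suite
quick while leaving the per-protein statistics unchanged (selection
operates row-wise, so panel width only affects counting): 200 cohorts
of 40/30/20-protein panels for sensitivity/specificity of selection
(planted FD ≥ 4, default noise and penetrance — expected per-protein
sensitivity `P(Binomial(9, 0.85) ≥ 6) ≈ 0.97`), a full 1000-protein
platform for CV recovery, and 10,000 normal draws for limits-of-
agreement coverage.

## Known limitations

* The control "fold changes" printed alongside published candidate
  tables are directional and can sit below 1; the symmetric replicate
  FC used for QC is deliberately different (and documented) — the two
  are not comparable cell-by-cell.
* LLD clipping biases fold decreases toward 1 for low-abundance
  proteins; the per-cell flags allow downstream sensitivity analyses
  but no imputation-based correction is attempted.
* Hook detection requires a dilution re-run; without one, saturated
  analytes silently report compressed fold changes (as the clipped
  positive-control comparison in the motivating design shows).
* With n = 9 patients, Bland–Altman limits of agreement are themselves
  highly uncertain; outlier calls at this n are descriptive, not
  inferential.
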