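# Methods

## Scope and model

`nodax` implements a quantitative sonographic assessment of the
joint-draining axillary lymph node (LN) complex in rheumatoid arthritis
(RA), together with the statistics battery used to analyze it in a
two-group, three-visit treatment study design (40 RA patients starting a TNF
inhibitor, 20 healthy controls, examinations at weeks 0, 4 and 24).

Three nodal parameters are measured per detected node and graded 0–3:

* **LNV** (nodal volume, cm³) from the two sonographic axes by the ellipsoid
  formula `V = 4/3·π·a²·b`, with `a` the short-axis radius and `b` the
  long-axis radius — a prolate spheroid about the long axis.
* **LNCW** (cortical width, mm), the maximum cortical measurement from the
  medulla–cortex interface to the capsule.
* **LNPD**, the count of discrete power-Doppler-positive signals in the
  cortex.

Grade 0 is anchored at the control-derived upper limit of normal (ULN =
control mean + 2 SD; sample SD with the n−1 denominator, the usual
convention for reference intervals from a small control group). Bands are
closed on their upper bound: LNV 0: ≤1·ULN, 1: ≤2·ULN, 2: ≤3·ULN, 3: above;
LNCW steps of 1 mm above a 4 mm ULN; LNPD counts 0–1 / 2–3 / 4–5 / ≥6.
Shipped default thresholds (volume ULN 0.65 cm³, cortical ULN 4 mm) are
constants adopted from the reference study; a `CalibrationModel` built from
any user-supplied control cohort overrides them. The per-subject
**cumulative index** for each parameter is the maximum grade in the right
axilla plus the maximum in the left (0–6); subjects without detectable nodes
score 0. Nodes with a missing PD assessment are excluded from the side
maximum; if no node on either side has one, the LNPD index is missing rather
than 0, since 0 is reserved for observed absent flow.

Synovitis is graded 0–3 for gray-scale and power-Doppler findings over a
12-joint bilateral model — the wrist complex graded as one site plus MCP
I–V per side — and summed into 0–36 indices (0–18 per side).

## Digital image analysis

Power-Doppler overlays are saturated color on a grayscale B-mode background,
so a pixel counts as Doppler signal when its chroma (`max(R,G,B) −
min(R,G,B)`) strictly exceeds a threshold, default 24/255. The rule is
invariant to global brightness shifts and never fires on gray pixels. The
color fraction is the share of ROI pixels classified as color; a video's PD
relative signal is the mean fraction over its snapshots (canonically three).
ROIs are supplied as binary masks or closed polygons rasterized at pixel
centers. Frames are treated independently; there is no motion correction,
video decoding, or automatic node segmentation.

## Reliability

Exact agreement (percent identical) and weighted kappa
`κ_w = 1 − Σ w_ij O_ij / Σ w_ij E_ij` with disagreement weights
`|i−j|/(k−1)` (linear, default) or its square (quadratic), computed over the
full fixed 0–3 category set even when grades are unobserved. Linear weights
are the convention for short ordinal clinical scales. A zero
chance-corrected denominator (e.g. both raters constant) is reported as
*undefined*, never as a silent NaN. Only the two-rater / two-session design
is supported.

## Clinical scores

DAS28-ESR, four-variable form:
`0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln(ESR) + 0.014·VAS`. EULAR response from
baseline and follow-up DAS28: good = follow-up ≤ 3.2 and improvement > 1.2;
none = improvement ≤ 0.6, or ≤ 1.2 with follow-up > 5.1; moderate otherwise;
remission = follow-up < 2.6. Outcome analyses collapse moderate with none.
The ESR (not CRP) variant is used because the cohort design reports ESR and
the patient global VAS.

## Statistics battery

* **Group comparisons**: two-sided Mann–Whitney for indices and continuous
  per-subject maxima (exact for small tie-free samples, tie-corrected normal
  approximation otherwise — scipy's selection rule); chi-square with Fisher
  exact fallback (any expected cell < 5) for detection/palpability
  proportions.
* **Correlation panel** at baseline: Spearman's rho with Fisher-z 95 % CI
  using variance 1.06/(n−3), between each LN index and autoantibody titers
  (all and seropositive-only), tender/swollen counts, and the 12-joint GS/PD
  indices. *Ipsilateral* pairs the nondominant arm's side-restricted joint
  index with that side's LN grade; *contralateral* pairs it with the
  dominant side's joint index. Pairs with fewer than 4 complete observations
  are skipped with a recorded reason. No multiplicity correction is applied
  across the panel (the presentation is descriptive, as is conventional for
  such correlation tables).
* **Longitudinal response**: per LN index, restricted to subjects whose
  baseline index exceeds the control range (the maximum observed among the
  cohort's controls); for the joint PD index, restricted to baseline
  pd12 > 0. Friedman chi-square (tie-corrected) across weeks 0/4/24, then
  pairwise post-hoc comparisons of weeks 4 and 24 against baseline with Holm
  control. The default pairwise test is the exact Wilcoxon signed-rank.
  Conover's Friedman post-hoc is also implemented and selectable, but it is
  not the default: its denominator pools variance across all visits and
  shrinks with the overall Friedman statistic, so a strong week-24 effect
  makes the week-4 comparison anticonservative (observed false-significance
  ≈ 0.15 under this package's own study conditions, and a null pattern rate
  outside the binomial band), whereas the signed-rank comparison stays
  calibrated because it uses only the two visits it compares.
* **External responsiveness**: OLS of LN index change on ipsilateral joint
  PD change and on DAS28 change, weeks 4 and 24 separately. Change scores
  are baseline − follow-up throughout, so positive values mean reduction.
  Zero-variance regressors yield an explicitly undefined fit.
* **Outcome prediction**: logistic regression of good (vs moderate/none)
  EULAR response on the indicator [baseline LNPD index = 0]; model 1 adjusts
  for baseline pd12, model 2 additionally for age, sex, disease duration,
  glucocorticoid co-medication and baseline DAS28 (both models are reported
  side by side). Complete separation or a divergent ML fit (non-convergence,
  |coefficient| > 12, or a standard error > 50) is flagged and refit by
  Firth's Jeffreys-prior penalized likelihood, which keeps estimates finite;
  the output marks the method used. Wald CIs throughout.

## Synthetic cohort generator

The generator emulates the study conditions the analyses assume. Its
defaults are the study conditions; every distribution is configurable.

* **Controls** (n = 20): 0–9 detectable nodes (zero-inflated truncated
  Poisson, median 2, 15 % with none). Node volumes are lognormal with median
  0.18 cm³ and log-SD 0.75, chosen so that mean + 2 SD of a large control
  sample reproduces a 0.65 cm³ ULN; cortical widths are gamma with mean
  2.7 mm and SD 0.65 mm (ULN 4 mm). Each node carries a persistent cortical
  flow propensity: zero in 60 % of nodes, otherwise a gamma-distributed
  rate; per-visit PD counts are Poisson draws around it, so repeated scans
  of a node are correlated, as in real re-examination.
* **RA patients** (n = 40, DAS28 ≥ 3.2 enforced): median 3 nodes, 10 % with
  none, and a mild cohort-wide elevation of cortical flow. Synovial PD
  activity is drawn per arm independently (per-arm activity probability
  calibrated so 62.5 % have PD+ synovitis in at least one arm), giving the
  strong within-patient side asymmetry needed for ipsilateral/contralateral
  contrasts. Gray-scale burden is drawn to match a 12-joint GS median near
  13 and couples weakly to PD burden.
* **LN-abnormal subgroup** (≈40 %): membership probability increases with
  the *nondominant-arm* joint PD burden (axillary nodes drain the arm), and
  members carry a shared per-subject reactivity latent (floored gamma) that
  jointly elevates volume, cortical width, and PD counts — inducing the
  within-patient correlation of the three parameters. Two ipsilateral
  couplings act on nondominant-side nodes only: a drainage-driven extra PD
  rate proportional to the nondominant joint burden (all RA; vascular flow
  responds to drainage before structure does) and an extra reactivity term
  (abnormal subjects). No contralateral coupling is injected anywhere.
* **Treatment course** (35 of 40 followed up at weeks 4 and 24): joint PD
  thins early (weeks 4 and 24), LN reactivity falls at week 24 only —
  more in good responders — and never at week 4. Good EULAR response is
  assigned by a logistic model whose only systematic term is a strongly
  negative log-odds (−3.1, odds ratio ≈ 0.045) on the indicator of a
  baseline LNPD index of 0, with the intercept solved so the marginal
  responder fraction is 55 %. Follow-up DAS28 values consistent with the
  assigned category are produced by root-finding a common scale factor on
  the baseline clinical components, so the emitted tender/swollen counts,
  ESR and VAS always reproduce the emitted DAS28 exactly. Labels are then
  *re-derived* from the tables downstream; the generator's assignment is
  only a target.
* **Clinical and serologic marginals** follow the reference baseline table
  (age, sex, disease duration, RF/ACPA positivity and titers — seronegative
  subjects carry sub-cutoff titers so whole-group correlations are defined —
  glucocorticoid use, TJC/SJC/ESR/VAS medians and spreads). The DAS28 is
  computed from the components rather than drawn, because the published
  component medians imply a slightly higher DAS28 (≈5.2) than the published
  DAS28 mean (4.87); the components take priority and the DAS28 is emergent.

Two null constructors support calibration studies:
`null_cross_sectional()` removes the abnormal subgroup, all ipsilateral
coupling, the RA-wide flow elevation, the RA–control node-count difference
and the LNPD–response association; `null_longitudinal()` zeroes only the LN
treatment effect while keeping the cross-sectional structure.

**Calibration.** Effect-size defaults were fixed once in a design study and
then frozen. Under the defaults (200 seeded cohorts): the RA-vs-control LNPD
index difference is detected (Mann–Whitney p < 0.05) in 92 % of replicates;
the ipsilateral rho exceeds the contralateral in 92 %; the week-24-only
post-hoc pattern appears in 82 % at subgroup n ≈ 10–18 (the reference design
had n = 10); the model-1 odds ratio is below 1 in 100 % with median ≈ 0.04;
and the week-24 LN-vs-ipsilateral-joint change R² exceeds the week-4 one in
87 %. Under the null constructors (400 seeded cohorts each) every detection
sits at its nominal rate: group test 0.050, directional rho comparison
0.465, odds-ratio direction 0.515, and the Holm-gated week-24 pattern 0.018
against its ≈0.024 nominal.

**What the generator does not emulate**: real speckle or scanner physics,
intra-rater grading noise (grades are deterministic given measurements),
missing visits and dropouts, erosion status, or any attempt to reproduce the
reference study's individual patients (its per-patient data are not
published). Passing recovery tests therefore shows the pipeline detects the
*injected* structure at the stated rates, not that the biological effects
are real.

## Synthetic PD frames

`generate_pd_frame` draws a grayscale elliptical node (hypoechoic cortex
around a brighter medulla) on a dark speckle background and paints a
grade-banded number of saturated color blobs (palette chroma ≥ 150) inside
the cortex, clipped to the node. Because all non-painted pixels are pure
gray, the chroma classifier recovers the painted set exactly, and the
returned ground truth (blob count, painted-pixel count) serves as a
counting oracle for the color-fraction pipeline.

## Numerical choices and edge cases

* Grade bands are upper-inclusive; boundary values sit in the lower band,
  and the chroma threshold is strictly exceeded before a pixel is color.
* Spearman rho within 1e-12 of ±1 is snapped to ±1 with a degenerate CI.
* Mann–Whitney exactness follows scipy's rule (exact only when small and
  tie-free); the acceptance suite checks the exact branch against full
  enumeration.
* Friedman blocks that are completely tied yield p = 1 rather than 0/0.
* Signed-rank p-values are computed from the full sign-flip null
  distribution by dynamic programming over doubled (tie-averaged) ranks, so
  they are exact and deterministic at any subgroup size that occurs here —
  no normal approximation and no resampling.
* Firth iterations damp steps larger than 5 in the max norm and use a
  pseudoinverse for near-singular information matrices.
* Reports serialize deterministically (sorted keys, 6 significant digits,
  non-finite values rendered as `undefined` in text and `null` in JSON).

## Problem sizes

Simulation-based tests use 200 replicate cohorts for parameter recovery and
400 per null configuration, with the study-sized cohort (60 subjects, three
visits); the exhaustive weighted-kappa check covers all 735 454 four-by-four
tables with 2–8 items; grading oracles run on 10⁵-point grids and 10³
random node sets. These sizes keep every Monte-Carlo rate's binomial error
well below the margins being asserted.

## Known limitations

* Only two raters / two sessions for reliability (no Fleiss/Krippendorff).
* No DICOM ingestion; measurements are inputs, not derived from images.
* No imputation: subjects lacking a complete visit triplet are excluded
  from longitudinal analyses and logged.
* The correlation panel reports unadjusted p-values by design.
* Ipsilateral tender/swollen counts are used only when the optional
  nondominant-count columns are present in `visits.csv`.
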