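# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the known limitations of `dopascreen`.

## The campaign being modeled

The package analyzes a cell-based antagonist screen against AaDOP2, a
Gαs-coupled D1-like dopamine receptor of *Aedes aegypti*, expressed in
HEK293 cells carrying a cAMP-response-element luciferase (CRELuc) reporter.
Receptor activation by dopamine raises cAMP and hence luminescence; an
antagonist suppresses the dopamine-stimulated signal. Downstream stages
confirm hits in direct cAMP dose–response assays, compare potencies against
the human D1 receptor, and test lead compounds on mosquito larvae.

## Plate QC

The Z-factor compares control separation to control variability:
`Z = 1 − 3(σ₊+σ₋)/|µ₊−µ₋|`. Because each library compound is screened in
quadruplicate, assay qualification uses the replicate-adjusted variant that
shrinks both control SDs by √n (n = planned replicates, default 4). The
adjustment is the plate-uniformity replicate form recommended in
assay-guidance practice; since different laboratories write slightly
different "replicate-corrected" equations, both the classical and the
adjusted statistic are always reported, and the adjusted form is an explicit,
documented choice rather than an inference. Sample SDs use the n−1
denominator because control-well counts per plate are small (8–192). A zero
control separation yields a flagged-undefined report, not an exception.

Z is invariant under affine rescaling of all signals and monotone
non-increasing in either σ; both properties are property-tested.

## Screen normalization and hit calling

Normalization is strictly per plate: the plate's mean background (cells
without agonist or compound) is subtracted, and the plate's mean net
maximum-stimulation signal (300 nM dopamine) defines 100% stimulation.
Percent inhibition is `100 − %stimulation`. Per-plate normalization makes
scores exactly invariant to multiplicative plate effects, which is the reason
the design splits each compound's quadruplicate across two plates.

Replicates are averaged unweighted, with no outlier rejection among
quadruplicates (the simplest defensible default; the count and SD are
retained so a caller can apply its own policy).

The hit threshold is `mean − k·SD` of the antagonist-control percent
inhibitions, pooled across all plates of the run; normalization stays
per-plate while the threshold is campaign-wide because the campaign quotes a
single cutoff. Phrasing the criterion as "control effect + k standard
deviations" means widening the acceptance band *below* the control mean:
that is the only reading under which a larger k (3 → 6) admits more
compounds, consistent with the published cutoff pair (81% at k = 3, 69% at
k = 6). The comparison is closed (≥, "at least"). A compound's
`pct_of_control_effect` is its mean inhibition as a percentage of the control
mean inhibition; it equals 100 exactly at the control mean.

## Dose–response potency

The four-parameter logistic is fitted in log10-concentration space with free
Hill slope (the convention of the commercial packages used for such assays),
by bounded trust-region least squares with multi-start initialization:
top = max(y), bottom = min(y), midpoint candidates at the half-range crossing
and the center of the tested range, Hill ∈ {+1, −1}. The midpoint is
box-bounded one decade beyond the tested range; Hill is bounded in ±10. The
lowest-SSE start wins. In tests the optimizer is checked against an
independent dense grid search over (log-potency, Hill) with top/bottom solved
linearly at each node.

A fitted curve whose span |top − bottom| is below 3 residual SDs is declared
flat: its potency is not identifiable and the compound is censored at the
activity limit. Orientation is normalized after fitting — (t, b, h) and
(b, t, −h) describe the same curve, so agonist fits report h > 0 and
antagonist fits a descending curve.

Experiments are fitted independently and then aggregated — matching the
"≥ 3 independent experiments" design and the mean ± SEM presentation — rather
than pooled into one fit. The aggregate potency is the geometric mean
(potencies are log-normally distributed); the SEM is computed on log10
potencies and mapped to the linear scale by the delta method
(`potency · ln10 · SEM_log`). Whether published ± values are SEMs over
experiments or fit standard errors is ambiguous in general; SEM over
experiments is implemented. Censoring at 10 µM (configurable) is applied
after aggregation and rendered as "≥10 µM".

## Selectivity

Fold selectivity for the mosquito receptor is `IC50(hD1) / IC50(AaDOP2)`;
values above 1 mean more potent at the mosquito receptor. It is unit-free and
inverts exactly when the receptors are swapped. Censored potencies make the
record not-computable rather than producing a pseudo-ratio.

The rank-order statistic is the tie-aware Spearman correlation (Pearson on
mid-ranks) squared. Rank-based correlation is the choice here because the
claim being quantified is about *rank order* of potencies — and on the eight
printed confirmation pairs the squared Pearson correlation of log potencies
(0.46) would not support a "no correlation" reading, while the rank statistic
(R² = 0.114) does; Pearson-on-logs is available as a secondary diagnostic in
tests only. Two pairs tie at the printed precision, hence mid-ranks. The
p-value is a two-sided permutation test of one margin: exhaustive for n ≤ 8
(8! = 40,320 permutations, vectorized), seeded Monte Carlo with the +1
observed-ordering correction above that.

## Larval bioassay

Single-dose assays use a one-sample two-tailed t-test of per-biological-
replicate percent mortalities against the observed control mean (0% in the
modeled campaign), df = replicates − 1. Zero replicate variance with a
nonzero difference is flagged and the p-value floored at the smallest
positive double rather than reported as 0.

The dose–mortality model is a binomial GLM of deaths on log10 dose with a
logit link — the log-logistic tolerance distribution. Logit is the default
(rather than probit) because it yields the closed-form identity
`log10(LC90/LC50) = log10 9 / slope_base10` used as an internal consistency
test; probit is available via `link="probit"` and agrees with logit to well
within the recovery tolerances in the interior of the dose range. Control
wells are excluded from the regression (control mortality is 0% in the
modeled design); Abbott's correction is implemented but off by default.
Confidence intervals are percentile bootstrap with the well as the resampling
unit — technical replicates share a plate and day, so resampling wells is the
conservative choice. Bootstrap refits with non-positive slope or a degenerate
dose set are dropped.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs.

**Plate layout.** 384 wells; columns 1–2 hold controls (8 background, 8
maximum-stimulation, 8 antagonist-control, 8 dopamine-curve wells at
14 nM–30 µM), columns 3–24 hold test wells. A compound occupies two wells on
each of two plates; the two wells of a plate sit in different quadrants (row
parity × column parity of the interleaved grid) and the second plate is
shifted one column, so the four replicates cover all four quadrants. A plate
pair carries 176 compounds; 1,280 compounds need 8 pairs. The original
campaign's exact control-well layout is unpublished, so the layout is a
documented configuration, not an inference.

**Signal model.** Background mean 1000 cps with a 9000 cps net window at
full stimulation — the ~10-fold dopamine response of the modeled assay. Well
noise is multiplicative lognormal parameterized by CV (luminescence is
positive and heteroscedastic; the true per-well noise magnitude is
unpublished), default CV 0.10 for screens; each plate carries a
multiplicative lognormal plate effect, default SD 0.10. A test well's
expected net signal is `max_net × (1 − true inhibition at 10 µM)`.

**Antagonist controls.** Control wells are generated directly on the
percent-inhibition scale, Normal(93%, 4%). That (mean, SD) pair is the unique
solution of the two published cutoff equations µ − 3σ = 81 and µ − 6σ = 69,
so the generator reproduces both thresholds by construction.

**Checkerboard.** Min/max conditions alternate by (row+column) parity. The
checkerboard default well CV is 0.24, the value at which the expected
replicate-adjusted Z (n = 4) of a simulated plate sits at 0.5 — the
qualification value of the original assay, whose raw data are unpublished.

**Planted truth.** Each compound is a true antagonist (4%, matching the
campaign's hit rate), an off-target reporter inhibitor (1%, modeling
chemistries that suppress the CRELuc readout without touching the receptor),
or inactive. Antagonist IC50s are log-uniform on 1 nM–1 µM; inhibition at the
10 µM screening concentration follows single-site occupancy with unit Hill
slope, `1/(1 + IC50/10 µM)`, unless overridden. Inactive compounds have
exactly zero effect (no low-level pharmacology tail is modeled).

**Dose–response and bioassay.** Dose–response experiments draw responses as
the 4PL mean times mean-1 lognormal noise (default CV 0.10), with triplicate
samples per concentration and three independent experiments, the stated assay
design. Larval assays draw deaths per well as Binomial(10, p) with p from the
log-logistic implied by the (LC50, LC90) truth pair, at the standard design
of five doses (400/200/100/50/25 µM) × five wells × three assay repeats.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: spatial/edge effects within plates (no B-score stage,
as none was used in the modeled campaign), liquid-handling failures,
compound-specific fluorescence/luminescence interference beyond the planted
off-target class, receptor pharmacology beyond single-site occupancy, and
day-to-day drift beyond the per-plate multiplicative effect.

## Problem sizes and determinism

Simulated problem sizes are chosen at the modeled campaign's own scale: the
full screen is 1,280 compounds on 16 plates (generated in under a second),
checkerboards are 3 plates, dose–response recovery uses 3 experiments × 10
concentrations × 3 replicates, and larval recovery uses the 75-well published
design. Bootstrap sizes in tests are 50–200 resamples; coverage is assessed
over 60 seeded simulations. Every random draw flows from an explicit seed
through `numpy.random.default_rng`, fixing a seed fixes every generated byte,
and the campaign report is byte-identical across reruns with the same
(config, seed).

## Known limitations

- The replicate-adjusted Z-factor equation of the original campaign was
  cited from a now-defunct guidance page and not reprinted; the SD/√n form
  implemented here is a documented choice and the classical Z is always
  reported alongside.
- The published hit summary lists the library copy of SCH23390 at 83% of the
  control effect even though the control defines the baseline; no behavior in
  this package is keyed to that discrepancy.
- Fold-selectivity values recomputed from rounded printed potencies can
  differ in the last digit from published folds computed on unrounded data
  (e.g. amitriptyline 34 vs 36); ratios here are reported at two significant
  figures alongside full precision.
- Sub-threshold screen results of the original campaign are not printed in
  the main tables, so the k = 6 "additional hits" behaviour is exercised on
  synthetic screens rather than on the published library data.
- EC50/LC50 recovery tolerances (±20%, ±15%) describe simulation recovery at
  the stated designs, not agreement with any particular laboratory rerun.
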