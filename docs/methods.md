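# Methods

## The measurement and the model

Two-photon FLIM of NAD(P)H records, per pixel, a TCSPC histogram of photon
arrival times synchronized to a pulsed laser (80 MHz, i.e. a 12.5 ns
repetition period).  The NAD(P)H decay is modeled as biexponential,

    I(t) ∝ a1 · exp(−t/τ1) + a2 · exp(−t/τ2),   a1 + a2 = 100 %,

with τ1 the short lifetime of free NAD(P)H (~0.35–0.47 ns) and τ2 the long
lifetime of protein-bound NAD(P)H (~2.0–3.3 ns).  The amplitude-weighted
mean lifetime is τm = (a1·τ1 + a2·τ2)/(a1 + a2).  A high a1 (low τm)
indicates a glycolytic shift; a1 is the parameter whose per-cell
distribution carries the heterogeneity signal.

The forward model (`flimhet.model`) computes expected counts per bin as the
bin-integrated decay, circularly convolved with a discrete IRF kernel,
scaled and offset:

* **Bin integration, not point sampling.**  Each bin receives
  exp(−t_k/τ) − exp(−t_{k+1}/τ), exact at any binning; with the default
  256 bins over 12.5 ns, point sampling would misplace ~6 % of the fast
  component's mass.
* **Periodic excitation.**  With τ2 up to ~3.3 ns, e^(−12.5/3.3) ≈ 2 % of
  the slow component survives into the next period.  Periodic (steady-state)
  mode divides each component by 1 − exp(−T/τ); it is the default and is
  toggleable.  Circular convolution is exact when the acquisition window
  equals the period (the default configuration).
* **IRF kernel alignment.**  The IRF is stored as a mass function over
  circular *shifts*: kernel index j covers shifts in
  [j·w − w/2, j·w + w/2).  This keeps discrete convolution aligned with the
  continuous one (an identity kernel at index 0 is a no-op); binning the
  kernel on bin edges instead would shift every curve half a bin early.
* **IRF shape.**  The laser pulse (~120 fs) is irrelevant next to detector
  timing jitter, so the effective IRF is modeled as a Gaussian,
  default FWHM 0.25 ns centered at 1.0 ns — typical for GaAsP/hybrid
  detectors on commercial TCSPC systems.  Measured IRFs can be loaded from
  text or TIFF.

## Decay fitting

`flimhet.fitting` fits (a1, τ1, τ2, amplitude, offset, and optionally an IRF
temporal shift) by bounded nonlinear least squares (lmfit,
trust-region-reflective).  Default bounds: τ1 ∈ [0.1, 1.0] ns,
τ2 ∈ [1.0, 10.0] ns, a1 ∈ [0.1, 99.9] %; initial values a1 = 80 %,
τ1 = 0.4 ns, τ2 = 2.5 ns (the typical NAD(P)H decomposition); offset ≥ 0.
Components are re-sorted after convergence so τ1 is always the short
lifetime; during optimization no ordering is imposed, which makes the result
invariant to a swapped initialization.

**Objective.**  The default is the Poisson-deviance MLE (deviance
residuals).  Neyman-weighted least squares — residuals divided by
√max(observed, 1), the convention of commercial TCSPC fitters — is
available by configuration, but at per-cell budgets of a few thousand
photons it overweights downward fluctuations: at 5,000 photons and truth
(a1 = 80, τ1 = 0.4, τ2 = 2.5) the Neyman median estimates are a1 ≈ 83.3 and
τ2 ≈ 2.13, versus a1 ≈ 79.6 and τ2 ≈ 2.42 for the deviance objective.  Both
recover noiseless input to 10⁻³ relative accuracy.

**Goodness of fit.**  The reduced χ² is Σ(O−E)²/max(O,1) over bins with at
least `chi2_floor` (default 1) observed counts, divided by
(n_used − n_free).  Cells pass quality control iff the optimizer converged
and χ² lies in the closed window [0.8, 1.2] (boundaries inclusive).
`min_photons` defaults to 1,000 per cell-level decay — below that the
biexponential decomposition is not reliably identifiable.

## Per-cell aggregation

Cytoplasm masks are inputs (labels ≥ 1; 0 = background); segmentation is out
of scope.  The default strategy sums the pixel histograms within a cell
footprint and fits once ("sum-then-fit"), which at ~5,000 photons per cell
is far better conditioned than per-pixel fitting; a fit-per-pixel-then-
average mode exists for sensitivity analysis.  Sum-then-fit on a homogeneous
cell is exactly the fit of the pooled histogram — the test suite asserts
this identity.  Samples with fewer than 50 usable cells warn (per-sample
distributions are normally built from 50–200 cells) but are not rejected, so
small fixtures still run.

## Heterogeneity metrics

For each sample and each parameter (a1, τm, τ2; τ1 fluctuations have no
biological interpretation and are excluded):

* **Bimodality index.**  A two-component, common-variance Gaussian mixture
  is fitted by EM (best of 10 quantile-seeded restarts, log-likelihood
  tolerance 1e-8, iteration cap 200 — beyond which BI changes only in the
  4th decimal; σ floor 1e-6 of the data range; all configurable), and

      BI = √(p(1−p)) · |μ1 − μ2| / σ .

  BI ≥ 1.1 is the accepted cutoff for a bimodal (two-subpopulation)
  distribution.  The common-σ form is the default because the 1.1 cutoff
  was calibrated for it; an unequal-variance variant with σ = √(σ1σ2) is
  available behind `equal_variance=False`.  Degenerate fits (a component
  capturing less than one observation) collapse to a single Gaussian and
  return BI = 0.  A caveat worth knowing: on a *unimodal* Gaussian sample
  the ML mixture still separates its means by roughly one SD (it models the
  tails), so the component means are not individually interpretable; only
  BI, which also discounts unbalanced weights, is calibrated (false-bimodal
  rate ≈ 3 % at n = 150 under the default settings).
* **Dispersion.**  D = Q3 − Q1 with linear interpolation between order
  statistics (the mainstream default; nearest/midpoint variants are
  configurable).  D is in the parameter's own units (percentage points for
  a1).
* **Category.**  homogeneous (BI-a1 < 0.5), intermediate, bimodal
  (BI-a1 ≥ 1.1); band edges configurable.  Published cohorts used both
  0.5–1.0 and 0.7–1.0 as the intermediate band; 0.5/1.1 is adopted as the
  default.

## Clinical association

TNM stage and grade are dichotomized: T1+2 → 0 vs T3+4 → 1; N0M0 → 0 vs any
metastasis → 1; G1+2 → 0 vs G3 → 1.  The six features (D and BI of a1, τm,
τ2) are z-normalized (n−1 denominator) to remove scale differences.  Group
differences use the two-sided Mann–Whitney U (exact enumeration for combined
n ≤ 20 without ties, tie-corrected normal approximation otherwise), effect
direction the point-biserial correlation (identically Pearson's r against
the 0/1 label).  Raw p-values are reported; Holm adjustment is optional and
off by default.  A Lilliefors normality screen is provided as a reporting
utility only — it never switches tests.

**Feature attribution.**  A random forest (500 trees, Gini splitting,
square-root feature subsampling, no depth limit, fixed seed) is fitted
in-sample — this is explanatory, not predictive, analysis — and explained
with *exact* Shapley values.  With only six features, all 2⁶ coalitions are
enumerated over a per-leaf decomposition of each tree (interval indicator
per in-coalition feature × training cover fraction per out-of-coalition
feature), which computes exactly the quantity path-dependent TreeSHAP
approximates; an interventional variant marginalizing over a background set
is behind a flag.  Attributions satisfy additivity to machine precision
(Σφ + base = predicted probability).  Features are ranked by mean absolute
attribution.

## Synthetic data generator

The generator is the test bed for everything above and emulates the study's
conditions:

* per-sample a1 populations are Gaussian mixtures; means ~62–87 %,
  per-population spreads ~2–12 percentage points; unimodal for homogeneous
  samples, two modes for bimodal ones; draws truncated to [0.1, 99.9] to
  keep the biexponential identifiable;
* lifetimes τ1 ≈ 0.35–0.47 ns (fixed per sample) and τ2 drawn per cell
  (default 2.5 ± 0.25 ns, matching reported per-line spreads);
* 50–200 cells per sample (default 150), Poisson photon noise,
  default 5,000 photons per cell — photon budgets are not reported for the
  original acquisitions, so this default is a choice, flagged in the config
  documentation;
* acquisition: 256 bins over 12.5 ns, Gaussian IRF as above, optional
  uniform background.

Two-group cohorts plant a difference `group_effect` in the true D-a1
(interquartile range of per-cell a1) between dichotomized clinical groups,
linked to T, NM or G; a Gaussian sample's IQR is 1.349σ, so the per-sample
σ is `target_D / 1.349`.  Samples also vary between each other in mean a1
(SD 4 points) and in their τ2 spread (SD 0.1 ns around the 0.25 ns default)
— real cohorts show substantial intertumor variability in both.  The τ2-
spread variability matters for interpretation: τm is a deterministic
function of a1 and τ2, so a planted a1-spread difference unavoidably leaks
into D-τm; with realistic intertumor τ2 variability that leaked component is
small against D-τm's own noise, and D-a1 is the top-ranked feature in ≈ 94 %
of replicate cohorts.  With τ2 spread held artificially constant across a
cohort, D-τm becomes a clean proxy of the planted signal and ties with D-a1
— a caution that applies to real data too, where D-τm and D-a1 are
intrinsically correlated.

What the generator does *not* emulate: spatial structure (no PSF, no
blur — cell footprints are ideal rectangles), detector afterpulsing and
dead time, autofluorescence from other fluorophores, and segmentation
errors.  Passing tests therefore validate the statistical pipeline, not the
upstream imaging chain.

## Problem sizes used in the replicated studies

Parameter recovery: 200 Poisson replicates at 5,000 photons.  BI
calibration: 200 seeds, n = 150 cells, cutoff 1.1, mixture separation 10
points at σ = 2.  Mann–Whitney power: 200 replicate cohorts, 20 samples per
group, 5-point D-a1 effect.  Attribution rank stability: 50 replicate
cohorts, 15 samples per group.  These sizes give Monte-Carlo standard errors
of a few percent on the reported rates.

## Known limitations

* The per-cell results of the original acquisitions cannot be reproduced
  numerically: commercial-fitter settings (binning, threshold) for the
  deposited raw data are not disclosed, and per-cell inputs are not printed.
  The reference tables shipped with the package carry the published
  per-sample summaries instead, and the checks recompute what is internally
  recomputable (τm identity, threshold counts, extremes).
* The equal-variance BI and the unequal-variance variant can disagree near
  the 1.1 cutoff; only the equal-variance form inherits the published
  cutoff's calibration.
* In-sample random-forest attribution describes this cohort; it is not an
  out-of-sample importance estimate.
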