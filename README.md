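# flimhet

Cell-level metabolic heterogeneity analysis of NAD(P)H FLIM data.

Tumors are metabolically heterogeneous: cells within one sample sit at
different points between glycolysis and oxidative phosphorylation.
Fluorescence lifetime imaging (FLIM) of the autofluorescent cofactor NAD(P)H
resolves this at single-cell level — the free form of NAD(P)H has a short
lifetime (τ1 ≈ 0.4 ns), the protein-bound form a long one (τ2 ≈ 2–3 ns), and
the relative contribution a1 of the free form (a1 + a2 = 100 %) shifts with
the glycolytic state of each cell.  `flimhet` implements the full analysis
from raw TCSPC photon histograms to clinical association statistics, for
researchers quantifying intratumor metabolic heterogeneity from FLIM
microscopy (e.g. of colorectal cancer samples):

1. **Decay fitting** (`flimhet.fitting`): per-cell biexponential fits
   I(t) ∝ a1·e^(−t/τ1) + a2·e^(−t/τ2), convolved with the instrument
   response, periodic in the 12.5 ns laser repetition period, with
   τm = (a1τ1 + a2τ2)/(a1 + a2) and a reduced-χ² quality gate (cells kept
   for χ² ∈ [0.8, 1.2]).
2. **Per-cell aggregation** (`flimhet.cells`): cytoplasm label masks +
   per-pixel histogram stacks → pooled per-cell fits (50–200 cells per
   sample).
3. **Heterogeneity metrics** (`flimhet.heterogeneity`): per sample and per
   parameter, the bimodality index from a two-Gaussian EM fit,

       BI = √(p(1−p)) · |μ1 − μ2| / σ ,   bimodal iff BI ≥ 1.1,

   and the dispersion D = Q3 − Q1 (interquartile range).
4. **Clinical association** (`flimhet.cohort`): dichotomized TNM stage and
   grade (T1+2 vs T3+4, N0M0 vs metastatic, G1+2 vs G3), z-normalized
   features, Mann–Whitney U tests, point-biserial correlations, and
   random-forest feature attribution with exact tree-Shapley values.
5. **Synthetic TCSPC generator** (`flimhet.synthetic`): ground-truth cell
   populations, Poisson photon histograms, label masks and two-group
   clinical cohorts, so every stage is testable end to end without any
   measured data.

## Worked example

Simulate one bimodal sample (two metabolic subpopulations at a1 = 70 % and
80 %), fit every cell's decay, and quantify the heterogeneity:

```python
import numpy as np
from flimhet import PopulationSpec, draw_cell_truths, simulate_histogram, fit_biexponential
from flimhet.synthetic import AcquisitionSpec, acquisition_irf
from flimhet.heterogeneity import compute_sample_metrics

pop = PopulationSpec(modes=[(70.0, 2.0, 0.5), (80.0, 2.0, 0.5)], n_cells=120, seed=7)
acq = AcquisitionSpec()          # 256 bins over 12.5 ns, Gaussian IRF
irf = acquisition_irf(acq)
rng = np.random.default_rng(7)

a1, tau_m, tau2 = [], [], []
for truth in draw_cell_truths(pop):
    hist = simulate_histogram(truth, acq, photons_per_cell=5000, rng=rng)
    fit = fit_biexponential(hist, irf)
    if fit.converged and 0.8 <= fit.chi2_reduced <= 1.2:
        a1.append(fit.params.a1); tau_m.append(fit.tau_m); tau2.append(fit.params.tau2)

m = compute_sample_metrics("demo", {"a1": a1, "tau_m": tau_m, "tau2": tau2}, seed=7)
print(f"cells passing QC : {m.n_cells}/120")
print(f"BI-a1 = {m.BI_a1:.2f}   D-a1 = {m.D_a1:.2f} %   category: {m.category}")
print(f"BI-tau_m = {m.BI_tau_m:.2f}   D-tau_m = {m.D_tau_m:.3f} ns")
```

```
cells passing QC : 95/120
BI-a1 = 1.85   D-a1 = 9.36 %   category: bimodal
BI-tau_m = 1.62   D-tau_m = 0.240 ns
```

The sample is correctly flagged bimodal (BI-a1 ≥ 1.1): the fitted mixture
recovers two balanced subpopulations ~10 points apart, and the dispersion
D-a1 ≈ 9 % reflects the wide per-cell spread.  A metabolically homogeneous
sample of the same width per mode would give BI-a1 well below 1.1 and
D-a1 ≈ 2·1.349 ≈ 2.7 %.

The same analysis is available from the shell:

```
flimhet run --outdir runs/demo --seed 0          # simulate → fit → metrics → cohort
flimhet verify-tables                              # reference-table consistency checks
flimhet metrics --cells cells.csv --out metrics.csv
flimhet cohort --metrics metrics.csv --clinical clinical.csv --target G --out assoc.csv
```

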