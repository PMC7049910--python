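# dcedyn

Dynamic spectral and texture descriptors for dynamic contrast-enhanced
(DCE) brain MRI, aimed at studying cerebral small vessel disease (SVD).

In DCE-MRI a series of T1-weighted volumes is acquired before and after an
intravenous Gadolinium bolus; subtle blood–brain-barrier leakage lets
contrast accumulate extravascularly and raise the signal over a ~24-minute
run. `dcedyn` quantifies how local signal *patterns* — not just the mean
enhancement — evolve over time in sampled brain regions, and tests whether
those dynamics track clinical markers of SVD burden. It is intended for
imaging researchers who want a reproducible, scriptable implementation of
this dynamic-descriptor analysis, complete with a synthetic phantom cohort
generator so the entire pipeline runs and is testable without patient
data.

## What it computes

1. **Region sampling.** An anatomical template of circular, non-overlapping
   samples of ≈12 mm² in-plane (radius ≈ 1.95 mm) distributed over four
   slice tiers (low, low-middle, middle-high, high) and five tissue classes:
   blood vessels (BL), CSF, deep grey matter (GMD), cortical grey matter
   (GMC) and white matter (WM). Placement is automatic, seeded, and honours
   an exclusion mask. Analysis granularity is the *region unit* — a
   (tissue, tier) pair; the default plan yields 13 units.
2. **Descriptors per region unit per frame.**
   - *Enh*: fractional enhancement E(t) = (μ_t − μ_0)/μ_0 of the region mean.
   - *RPS* (radial power spectrum): the region is zero-embedded in an N³
     cube, transformed with the 3D DFT
     F(u,v,w) = Σ_{i,j,k} I(i,j,k) exp(−2πι(ui+vj+wk)/N),
     and |F| is averaged over concentric rings of integer radius
     r = round(√(u²+v²+w²)), giving ⌊N/2⌋ values (128 at N=256).
   - *GLCM*: grey-level co-occurrence over 8-connected in-disc pairs after
     quantisation to 2⁴ levels, summarised by nine Haralick features
     (contrast, correlation, energy, variance, entropy, inverse difference
     moment, sum average, sum entropy, sum variance).
   - *ULBP*: uniform local binary patterns — 8-bit neighbour-comparison
     codes pooled into 59 bins (58 uniform codes + 1 pooled).
   - *LCP*: local configuration patterns — 9 rotation-invariant pattern
     occurrence frequencies plus 9 × 8 Fourier magnitudes of per-pattern
     least-squares reconstruction weights, 81 features.
3. **Multivariate functional PCA.** Each descriptor element r_i^(j)(t) is
   centred; univariate FPCA keeps M = 5 eigenfunctions Φ_k^(j) with scores
   ξ_ik^(j) = ∫ Φ_k^(j)(t) r_i^(j)(t) dt (trapezoidal quadrature); scores are
   stacked into Ξ ∈ ℝ^{P×ΣM^(j)}; the leading eigenvector of cov(Ξ) yields a
   single first-mode score per subject per region unit.
4. **Statistics.** Kruskal-Wallis across total-SVD-score groups (df = 4 for
   five groups) and standardized multiple regression
   score = β₀ + β_Age·Age + β_WMH·WMH + β_Sex·Sex + β_Lac·Lac,
   plus the scalar comparators AUEC (area under the enhancement curve) and
   post-peak enhancement slope.

## Worked example

Run a 12-subject synthetic cohort at the 64×64×8 test geometry:

```python
from dcedyn import pipeline

cfg = pipeline.PipelineConfig(n_subjects=12, seed=42, out_dir="out")
res = pipeline.run(cfg)

sc = res.scores
print(sc[(sc.unit == "WM@middle-high") & (sc.descriptor == "RPS")].head())
```

```
subject_id           unit descriptor         score  explained_var
     S0000 WM@middle-high        RPS  41874.242095       0.982847
     S0001 WM@middle-high        RPS -12663.584755       0.982847
     S0002 WM@middle-high        RPS  13455.769483       0.982847
```

Each row is one subject's first-mode MFPCA score for the radial power
spectrum of white matter in the middle-high slice; the first joint mode
explains 98.3 % of the stacked-score variance in this cohort. The phantom
programs a positive link from WMH burden to leakage rate, and the
regression on the AUEC comparator recovers it:

```python
print(res.regression_results.query(
    "unit=='WM@middle-high' and descriptor=='AUEC'")
    [["adj_r2", "model_p", "beta_WMH", "p_WMH"]])
```

```
  adj_r2      model_p  beta_WMH        p_WMH
0.997769 4.847141e-10  0.999039 4.895739e-11
```

AUEC is almost fully determined by WMH burden here (β_WMH ≈ 1.0,
p ≈ 5·10⁻¹¹) because the phantom's only programmed between-subject effect
on leakage is the WMH link and measurement noise is small.

The same stages are available from the shell:

```bash
dcedyn phantom  --n 12 --geometry small --seed 42 --out cohort/
dcedyn template --labels cohort/S0000_labels.nii --out template.json
dcedyn describe --subjects cohort/ --template template.json --out traj/
dcedyn reduce   --trajectories traj/ --out scores.csv
dcedyn validate --scores scores.csv --covariates cohort/covariates.csv --out results/
dcedyn run      --config config.yaml        # everything in one step
```

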