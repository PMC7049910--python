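# Methods

This note documents the models, conventions and design choices behind
`dcedyn`: what each stage computes, which parameters matter, what the
phantom does and does not emulate, and where genuinely open choices were
resolved.

## Acquisition model

`AcquisitionGeometry` encodes the protocol the package targets: a 3D
T1-weighted spoiled-gradient-echo series with a 24 cm field of view
reconstructed at 256×192 (0.9375 mm in-plane), 42 slices of 4 mm, and 21
frames at 73 s — one pre-contrast volume followed by 20 post-injection
acquisitions over ≈24 min. A single in-plane spacing (0.9375 mm) is used
even though the reconstruction matrix is anisotropic; in-plane anisotropy
is ignored throughout, consistent with the isotropic frequency radius used
by the spectral descriptor. The 64×64×8 test geometry keeps the same
0.9375 mm spacing (a cropped field of view, not a coarser grid) so that a
12 mm² disc still contains 13 voxels and texture descriptors remain
non-degenerate; at the test geometry the spectral cube is 64³ (32 rings)
instead of 256³ (128 rings), which scales the descriptor length but not
the method.

## Sampling template

Regions are sampled with circular discs of radius r = √(12/π) ≈ 1.954 mm
(π r² ≈ 12 mm²; the area, not the radius, is the primitive constraint). A
voxel belongs to a disc iff its center lies within the radius of the disc
center, measured in millimetres. Discs on the same slice may not overlap;
placement enforces a center distance of at least one diameter and tests
verify zero shared voxels exhaustively. The per-tier/per-tissue counts of
the default plan are: low — BL 3 (carotids, basilar, sagittal sinus);
low-middle — BL 1, CSF 12, GMD 12, GMC 12, WM 10; middle-high — BL 1,
CSF 8, GMC 6, WM 28; high — BL 1, GMC 6, WM 28.

Placement is automatic: candidate centers are voxels whose whole disc lies
inside the requested tissue (computed by binary erosion with the disc
footprint) and outside an optional exclusion mask (the stand-in for
manually avoiding lesions, WMH, enlarged perivascular spaces and
partial-volume areas); a seeded greedy pass over a permuted candidate list
accepts centers subject to the distance constraint, restarting with a
fresh permutation up to a bounded number of times before raising a
placement error that names the tier and tissue. Slice tiers are template
metadata supplied by the caller (or spread evenly by default), not
detected anatomy. Analysis proceeds per *region unit* — a (tissue, tier)
pair present in the template; the default plan yields 13 units.

## Descriptors

All descriptors are computed per region unit per frame and stacked into a
D×T trajectory.

**Enhancement (D = 1).** E(t) = (μ_t − μ_0)/μ_0 over the unit's voxels,
with μ_0 the pre-contrast mean. The literature leaves the normalisation
convention open; the ratio form is the default and a percent form is
selectable. A non-positive baseline raises a degenerate-baseline error.

**Radial power spectrum (D = ⌊N/2⌋).** The unit's voxels are zero-embedded
into an N³ cube with the bounding box centered — the magnitude spectrum is
invariant to the translation, verified numerically via the shift theorem.
The 3D DFT is taken (numpy FFT; a brute-force triple-sum oracle pins the
definition in tests) and |F| is averaged over rings of integer radius
round(√(u²+v²+w²)) on the DC-centered frequency lattice. Two deliberate
conventions: the continuous spherical-average normalisation is replaced by
the discrete ring mean, the standard lattice discretisation (it preserves
the descriptor's shape up to ring-wise scaling); and the *magnitude*, not
its square, is averaged — the descriptor keeps the customary "power
spectrum" name. Ring count is ⌊N/2⌋ (up to Nyquist): 128 features at the
256³ reconstruction matrix. No windowing or anisotropy correction is
applied. The volume transformed is the per-unit zero-embedded cube (the
alternative — a whole-brain masked transform — would mix tissues and
defeat per-unit scoring).

**GLCM / Haralick (D = 9).** Intensities are quantised into 2⁴ equal-width
levels with bounds taken over the unit's *entire time series* — per-frame
bounds would renormalise every frame and erase the enhancement dynamics
the method exists to measure. Co-occurrence counts accumulate over all
ordered 8-connected in-plane voxel pairs lying in the *same disc* (tissue
purity; symmetric by construction, so the two marginals coincide), then
normalise to sum 1. The nine features follow the classical formulas with
natural logarithms and 0·log 0 := 0; correlation is defined as 1 when a
marginal is degenerate. The inverse difference moment uses the standard
1 + (a−b)² denominator; a variant with 1 + (a+b)² appears in print and can
be reproduced verbatim via `idm_printed_form=True`, but as it is not a
homogeneity measure it is treated as a typographical slip. Sum variance is
Σ_c (c − SA)² C_{a+b}(c).

**Uniform LBP (D = 59).** Bit p of a voxel's code is 1 iff neighbour p is
strictly below the center, with neighbour order (E, NE, N, NW, W, SW, S,
SE) and bit p weighted 2^p. The opposite convention circulates as prose in
the literature; the two produce bijectively relabelled histograms, and the
worked numeric example (center 4, neighbours 1…8 → bits 1,1,1,0,0,0,0,0)
fixes this package's choice. Codes are computed for in-disc voxels but
neighbourhoods may use image voxels just outside the disc — discs hold
only ~13 voxels, so interior-only neighbourhoods would leave almost no
valid centers; voxels whose neighbourhood leaves the image are excluded
and counted. The histogram maps the 256 codes to 59 bins: the 58 codes
with at most two circular 0↔1 transitions get their own bins (ascending
order) and all others pool into the last bin. The u2 59-bin histogram is
*not* rotation invariant (rotation permutes the uniform bins); the 59-bin
cardinality is retained as the descriptor's defining property.

**Local configuration patterns (D = 81).** Each voxel's code is classified
into a rotation-invariant class: the number of set bits (0–8) for uniform
codes, a discard class otherwise. The feature vector concatenates (a) the
occurrence frequencies of the nine uniform classes among the unit's voxels
and (b), per class, the 8 magnitudes of the discrete Fourier transform of
the least-squares weights a ∈ ℝ⁸ minimising ‖c − N a‖² over that class's
voxels (c centers, N the 8-neighbour matrix) — the Fourier magnitude
removes the dependence on neighbour-order rotation. Classes that do not
occur contribute zeros. 9 + 9·8 = 81 features. The exact 81-feature
composition is defined in the original report only by citation; this block
structure is the package's reconstruction, chosen to satisfy the published
total. The normal equations carry a small trace-scaled ridge
(ε = 10⁻¹⁰·tr(NᵀN)/8) so rank-deficient classes (e.g. constant patches)
remain solvable; tests verify the unregularised least-squares solution is
recovered to 10⁻⁶ on well-posed systems.

## Comparator scalars

AUEC is the trapezoidal integral of E(t) over the frame times in minutes.
The slope is the OLS slope of E against time over frames strictly after
the bolus peak, the peak being the argmax of E within the first third of
frames: bolus arrival is early in a 24-minute protocol, and restricting
the search prevents a late leakage maximum from truncating the fit window.
All post-peak frames enter the fit (a fixed-window variant would be
arbitrary without a stated window); fewer than three post-peak frames
raise an insufficient-data error.

## Multivariate functional PCA

Four steps per (region unit, descriptor): center each element across
subjects; univariate FPCA per element; stack scores; joint eigenanalysis.
The covariance-operator eigenproblem is discretised with trapezoidal
quadrature weights w (exact for piecewise-linear curves on the frame
grid): with X the centered P×T data the SVD of X·diag(√w) yields
eigenfunctions Φ_k = V_k/√w (orthonormal under the weighted inner
product), eigenvalues λ_k = s_k²/(P−1), and scores ξ_k = U_k s_k, which
equal the quadrature inner products ∫Φ_k r_i dt and have sample variance
λ_k. M = 5 modes per element are kept (configurable); on smooth low-rank
trajectories five modes capture ≥99 % of the univariate variance, and
M is treated as fixed rather than selected per dataset. Elements with data
rank below M contribute zero-padded score columns with a warning, keeping
the stacked matrix Ξ ∈ ℝ^{P×ΣM^(j)} well defined. The first joint mode is
the projection of centered Ξ on the leading eigenvector of its covariance.
Eigen-signs are arbitrary; for reproducibility each univariate
eigenfunction has its largest-magnitude value positive and the joint mode
is oriented to correlate non-negatively with the row sums of Ξ. Only the
first mode is scored; no spline pre-smoothing and no cross-element
weighting are applied.

## Statistics

Kruskal-Wallis (scipy, tie-corrected; chi-square reference with g−1
degrees of freedom — df = 4 for the five total-SVD-score groups) and
standardized multiple regression per (unit, descriptor) cell: response and
predictors are z-scored before OLS, binary predictors included — the
published single coefficient per binary term implies a standardized
treatment. Coding is female = 1/male = 0 and lacunar = 1/cortical = 0 and
is recorded in the output metadata, since β signs are meaningless without
it. Reported per cell: adjusted R², the model F-test p, and per-coefficient
standardized β with two-sided t-test p. No multiplicity correction gates
any result; a Benjamini-Hochberg column is emitted alongside for
reference. Degenerate cells (constant scores, too few subjects) are
flagged in a note column and skipped rather than aborting the run.

## Phantom

The phantom emulates the study conditions, not MR physics: no k-space,
coil, relaxometry, motion or lesion-geometry simulation.

*Covariates.* Marginals reproduce the published cohort of 42 recent mild
stroke patients: age binned 39–89 (mode 59–69), 71 % male, 79 %
hypertensive, 45 % lacunar index stroke, WMH burden 0.07–8.73 % of
intracranial volume (55 % below 1.8 %), total SVD score 0–4
(19/24/28/17/12 %). WMH and SVD score are coupled by a Gaussian copula
(latent correlation 0.6 by default) since the score grades the same
burden; other covariates are independent.

*Images.* The label map is a deterministic stripe layout (BL/CSF/GMD/GMC/WM
across columns, widths proportional to the sampling plan's needs) so every
slice contains every tissue. Per tissue, the baseline is a T1w-plausible
mean (CSF dark at 150, WM bright at 400, grey matter ≈300–320, blood 260,
arbitrary units) modulated multiplicatively by a stationary correlated
Gaussian field (white noise smoothed with a Gaussian kernel, correlation
length 1.5 voxels, unit-SD normalised) scaled by the tissue's
heterogeneity parameter. Enhancement is multiplicative on that baseline:
e(t) = gain·VIF(t) + leakage·∫₀ᵗ VIF dτ, with a gamma-variate vascular
input function VIF(t) = ((t−t₀)/t_p)^α exp(α(1−(t−t₀)/t_p)) (onset 73 s,
shape 3, time-to-peak 120 s, unit peak) — frame 0 precedes onset, so it is
an exact pre-contrast baseline, and with zero leakage the bolus washes out
below 1 % of peak by the final frame. Gains (BL 0.60, GM 0.15, WM 0.08,
CSF 0.02) give blood-dominant first-pass enhancement; leakage rates are
linear in WMH burden (slopes per tissue, largest in WM and CSF), which
programs the association the statistics stage must recover, and WMH also
raises CSF/WM texture heterogeneity. Gaussian noise with SD 2 % of the
tissue baseline is added per frame.

What passing tests on phantoms therefore show: the pipeline's operations
match their definitions, programmed effects of realistic size are
recovered, and the statistics are calibrated (type-I error ≈5 % on
pure-noise responses). What they do not show: robustness to motion,
partial-volume mixing, scanner drift, anatomy-dependent sampling bias, or
any physiological fidelity of the kinetic parameters.

## Numerical conventions and edge cases

- Quantisation: equal-width bins over [global min, global max]; the
  maximum maps to the top level; constant regions map to level 0.
- Entropies: natural log, 0·log 0 := 0.
- Ring averages: empty rings (none occur below Nyquist) would be 0.
- FPCA: eigenvalues below s₁²·10⁻²⁴ are treated as rank deficiency.
- First-mode eigenanalysis raises on an all-constant score matrix.
- Collinear predictors (condition number > 10⁸ after z-scoring) raise.
- All randomness flows from one master seed through named `SeedSequence`
  substreams (covariates / template / per-subject series); identical
  configuration and seed reproduce output files byte for byte.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at the 64×64×8 test geometry
with the full 21-frame protocol for cohort-level checks (20 cohorts of
n = 100 for sign recovery; 500 regression runs for type-I calibration),
and at the full 256³ spectral geometry for the descriptor-dimensionality
checks. These sizes are the package's chosen defaults for routine
verification; the full-protocol image geometry is available throughout via
configuration.

## Known limitations

- The sampling template knows slice *tiers*, not anatomy; automatic
  anatomical landmarking is out of scope.
- No partial-volume weighting at disc boundaries; boundary voxels are in
  or out by center-in-disc.
- GLCM is strictly 2D/8-connected and single-distance; LBP/LCP are single
  radius.
- No pharmacokinetic modelling (no Patlak/Tofts permeability estimates);
  AUEC and slope are semi-quantitative surrogates only.
- The copula links only WMH↔SVD score; real cohorts correlate age,
  hypertension and burden too.
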