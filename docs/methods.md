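# Methods

## Vessel mechanics

The artery is modeled as an incompressible, circular, thin-walled cylinder
under transmural pressure P and axial force f_T. Reference radii come from
traced ring perimeters, R = perimeter/2π, averaged over the two end rings;
"thickness" means the undeformed R_o − R_i. The deformed inner radius
follows from wall-volume conservation, the circumferential stretch is the
mid-wall value (r_o + r_i)/(R_o + R_i), and the stresses are mean (Laplace)
values across the wall — no radial stress distribution, residual stress,
or active tone is modeled.

Units are declared once and enforced: pressure stored in mmHg, converted
at 133.322 Pa/mmHg; force in mN; radii in µm; lengths in mm; stresses
reported in kPa. A non-physical input (outer radius too small to enclose
the wall volume, zero wall thickness) raises a typed error rather than
propagating NaN. The depressurization (80→0 mmHg, 10 mmHg steps) limb is
the analysis default, and every derived record must satisfy
λ_z(r_o² − r_i²) = R_o² − R_i² to better than 1e−12 relative error.

The in vivo axial stretch is the grid point (default λ_z ∈ [1.00, 1.30],
step 0.01) minimizing the sample SD of axial force over the pressure sweep
(0–80 mmHg); "variation" is not uniquely defined by convention, so a
max−min range objective is selectable. Ties break toward the smaller
stretch; an objective that is flat across the whole grid raises a
non-identifiability error.

## Stiffness fit

The circumferential stress–stretch curve is fitted with
σ(λ) = α(e^{β(λ−1)} − 1) on the *normalized* stretch, which pins σ(1) = 0
at the unloaded reference and gives the closed-form tangent
αβe^{β(λ−1)}. Alternatives (a free offset, raw-stretch fitting) are
deliberately excluded from the default: the zero-stress constraint at the
normalized reference is physical, and raw-stretch fitting is available by
flag. Initialization: β₀ from the log-ratio of the last two stress
increments, α₀ from matching the final point; trust-region least squares
with 1e−10 relative tolerances and non-negativity bounds. A fit is flagged
non-converged — never silently returned — when the optimizer fails, a
parameter pins at zero, or the residual RMS exceeds 25% of the stress
scale (exponentials describe monotone stiffening curves; anything that
bad is the wrong model for the data). Parameter standard errors come from
the Gauss–Newton covariance. Group stiffness curves are mean ± SEM of
per-sample tangent stiffness at matched pressures.

## Empty-band statistic

The ROI is partitioned into a 30×30 grid with cell edges by integer
flooring and remainder pixels merged into the last row/column — a
deterministic rule chosen over fractional-pixel weighting for exact
reproducibility. Binarization defaults to Otsu's between-class-variance
threshold (manual override available); foreground always means
fiber-signal pixels. Wall alignment is automatic via the principal axis of
the foreground pixels, with a manual angle override.

The band threshold is τ = μ − 2σ of the **media** column fractions (sample
SD, n−1): with the study-pooled media statistics (31.8%, 8.5%) this yields
the 14.8% cut. A combined media+adventitia mode exists for sensitivity
analysis, and a "pooled" mode accepts externally supplied (μ, σ) so a
study-wide threshold can be applied to individual images; whether
per-image or pooled statistics better match any given protocol is left to
the user — both are first-class. The band is the contiguous sub-threshold
run intersecting the span between the annotated media and adventitia
extents; isolated dips deep inside the media do not qualify, and multiple
qualifying runs raise an ambiguity error listing the candidates. Layer
annotation is user-supplied; automatic layer segmentation is out of scope.

## Birefringence inversion

The six-frame model I = a0(1 + r sin 2(θ−φ)) fixes the sign and offset
convention: φ is measured counterclockwise from the horizontal image axis
and is π-periodic. This convention is pinned by the synthetic forward
model (generator and inverter share it by construction) and documented as
a convention, not a claim about any particular instrument. Because 2θ
samples the circle at exact 60° steps, the harmonic coefficients are exact
discrete-Fourier sums, making noise-free inversion exact to machine
precision for r ∈ [0, 1]. Retardance is reported as the dimensionless
modulation ratio r (no conversion to optical path difference); noisy
estimates are clipped to [0, 1]. Orientation is masked below a retardance
floor (default 0.02) because hue is meaningless in isotropic pixels;
pixels with a0 ≤ 0 are masked invalid. Frames are assumed co-registered.

## Composition and differential expression

Collagen-type abundances are expressed per sample as percentages of total
collagen; group comparison per type uses a two-sided Welch t-test on the
percentages with Bonferroni correction over the number of quantified
types. Welch is used rather than pooled-variance because the group
variances of composition data are routinely unequal; testing percentages
(not raw abundances) matches the compositional question being asked.
Differential expression: per-protein log2 abundances with zeros imputed at
half the protein's minimum observed value, Welch t-tests, and
Benjamini–Hochberg adjustment across tested proteins at FDR < 0.05.
Proteins missing in more than half the samples of either group are flagged
and excluded from testing. Peptide rollup, database search, and gene-set
enrichment are consumed as pre-made tables, never recomputed.

## Gated group comparison

Shapiro–Wilk at α = 0.05 per group; a pooled-variance t-test when both
groups pass, Mann–Whitney otherwise — one non-normal group suffices for
the nonparametric fallback (the conservative rule; the contrast with the
omics module's Welch choice is intentional and documented). Report strings
round to one decimal, half away from zero, matching common table
formatting; SD uses the n−1 denominator and SEM = SD/√n.

## Synthetic data

The generators define the study conditions; their defaults are fixed once.

*Inflation simulator.* Circumferential law σ_θ = c(e^{b(λ_n−1)} − 1) on
the normalized stretch λ_n, with the zero-pressure reference at axial
stretch λ_z set by mid-wall radius scaling 1/√λ_z plus incompressibility;
equilibrium P r_i/(r_o − r_i) = σ_θ(λ_n) is solved per pressure by
bracketed root finding to 1e−15 relative tolerance. Defining the law on
normalized stretch makes (c, b) the exact ground truth of the downstream
fit. Defaults c = 30 kPa, b = 8 put σ_θ at 80 mmHg near 70 kPa at a
normalized stretch near 1.15 — a physiologic operating point for a ~2 mm
outer-diameter cerebral artery (R_o = 1000 µm, R_i = 830 µm, L = 10 mm).
The axial force is the phenomenological surface
f_T = F0 + k_f(λ_z − λ_z*)P (F0 = 18.8 mN, the control-scale axial force;
k_f = 2 mN/mmHg; λ_z* = 1.12), chosen over a full 2-D constitutive law so
the in vivo stretch ground truth is exact by construction. No hysteresis
or preconditioning is simulated. Instrument noise is additive Gaussian on
the recorded diameter and force (off by default); parameter-recovery
studies use 1% multiplicative noise on the stress observations.

*Fiber scenes.* 390×390 px at 1 µm/px: intima (39 px), media (156 px), an
optional fiber-free gap, then adventitia. Random 20–60 px line segments
(2 px thick) are placed per region until the region's area fraction
reaches its target — media 0.318, adventitia 0.478, intima 0.35, gap 0.02
(sparse bridging fibers) — with segment origins sampled from a padded box
so clipping keeps the density uniform to the region edge. Default true
gap 32 µm. Intensities: background 10, fiber 200, Gaussian noise SD 10.
The scene emulates area-fraction structure only: no fiber waviness,
orientation texture, depth projection artifacts, or uneven illumination —
so passing tests certify the grid/threshold/run logic, not robustness to
those real-image effects.

*Polarization stacks.* The exact forward model above plus additive
Gaussian noise.

*Abundance tables.* One protein per collagen type; per-sample type
percentages drawn as a Gaussian composition conditioned on the sum-to-100
closure (types are necessarily correlated; marginal SDs shrink by the
closure factor), floored at 1e−4 and renormalized, then scaled by a
log-normal per-sample total (log2 SD 0.3). Default group profiles are the
published control/advanced-disease composition tables (the printed SD of
0.00 for type XII is replaced by a strictly positive 0.005 so the type is
simulable); default sample sizes 5 vs 6. Optional background proteins get
log-normal abundances with specified log2 group effects as ground truth.

All generators are deterministic under a fixed seed.

## Problem sizes and numerical choices

Default analyses run at deliberately small scale: 9-record limbs, 100×100
px maps, 390×390 px scenes, 100-replicate recovery studies, 1000-replicate
null calibrations. Root finding and curve fitting use scipy (brentq /
trust-region reflective); image thresholding uses scikit-image;
multiple-testing corrections use statsmodels. Known limitations: the
thin-wall stress is a mid-wall average (no transmural distribution), the
empty-band detector requires a user annotation and a roughly
column-aligned wall, and the retardance scale is relative — values are
comparable within a study, not across instruments.
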