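# Methods

`capmech` reimplements, end to end, a follow-up analysis of lipid-rich
coronary plaques imaged with both intravascular ultrasound (IVUS) and
optical coherence tomography (OCT): quantify fibrous-cap thickness on
fused IVUS+OCT ("IO") versus IVUS-only cross-sections, compute cap
stress/strain with thin-layer hyperelastic finite-element models, and
predict cap-thickness progression from nine morphological and mechanical
predictors.  Patient data of this kind are not publicly deposited, so the
package ships a synthetic cohort generator that reproduces the statistical
structure the analysis assumes; everything downstream of segmentation is
real, tested computation.

## Synthetic cohort

`capmech.cohort` generates matched {baseline, follow-up} × {IO, IVUS}
contour sets for 9 patients × 12–14 slices (≈114 lipid slices, the scale
of the motivating study).

**Geometry.** Lumen cross-sections are ellipse-like closed curves: a base
radius (1.5 ± 0.25 mm) perturbed by low-order Fourier modes (modes 2–4,
amplitudes 0.08/0.05/0.03 mm).  The wall is eccentric, thickness
t(θ) = t₀(1 + ε cos(θ − θ_p)) with t₀ = 1.0 ± 0.15 mm and ε ∈ [0.05, 0.3];
the lipid core is a crescent on the thick side over a random arc
(70–160°).  The fibrous cap (lumen → lipid inner edge) has minimum
thickness drawn from U(0.10, 0.40) mm at the arc centre, rising toward the
arc ends by U(0.10, 0.55) mm with a random shape exponent in [1, 3].  The
wide, shape-varying rise keeps slice MeanCapT well separated from MinCapT
(correlation ≈ 0.8, as in segmented patient slices, rather than the ≈ 0.99
a fixed narrow rise would give) — without it the two predictors are
interchangeable and subset selection cannot attribute signal between them.
Per-patient diastolic/systolic pressures are drawn uniformly from the
ranges of the published nine-patient demographic table (55–90 /
117–155 mmHg).

**IVUS degradation.** The fused IO slice takes its outwall from IVUS, so
lumen and outwall are carried over unchanged; only the cap differs between
modalities.  The IVUS lipid inner boundary is displaced radially so cap
thickness is scaled by a patient-level bias factor 1 + b, b ~
N(−0.20, 0.30²) clipped to [−0.70, 0.35], plus pointwise noise
(sd 0.015 mm), then quantized to multiples of half the 0.15 mm IVUS
resolution floor with a one-step minimum.  These values emulate the
published patient-level MinCapT error distribution (mean ± SD
≈ −21 ± 30%, span ≈ −58% to +20%); a hard 0.15 mm floor would contradict
the published per-patient IVUS values (several are below 0.15 mm), hence
the half-resolution quantization.

**Planted progression signal.**  ΔMinCapT (follow-up minus baseline) is a
linear model in the standardized baseline predictors
(PA, MinCapT, S_proxy, PB) plus N(0, 0.025²) noise, where S_proxy is a
cap-stress proxy — the generator cannot run the FE stage it feeds, and FE
MeanCapS is strongly monotone in the proxy.  The proxy is the Laplace
estimate p_dia·r_lumen/MinCapT times a lipid-burden factor
1 + depth/wall + 0.35·arc/π whose sensitivities match the FE response to
pool size.  The factor matters for identifiability: the Laplace part is a
deterministic function of other predictors plus the patient-level pressure
(which a patient random intercept absorbs), so signal planted on it alone
could never be attributed to MeanCapS by any method; the lipid-burden part
varies independently of every morphological predictor and is carried only
by the computed cap stress.  The planted weights
(−0.025, +0.045, −0.048, −0.026 mm per SD)
are allocated proportionally to each predictor's √VIF in the generated
design (computed once from 2000 design draws): the stress proxy is
strongly collinear with MinCapT (r ≈ −0.8, VIF ≈ 4.7) and PB mildly with
PA, so equal raw weights would leave the proxy and PB with ~2× less
*unique* signal than the others and make the planted combination
unidentifiable by construction.  With the √VIF allocation every planted
factor carries comparable partial signal, and ΔMinCapT stays in the
tens-of-µm range reported for ≈1-year coronary follow-up.  The follow-up
geometry displaces the lipid inner edge by the planted amount (clipped to
keep the polygon valid); lumen and outwall are unchanged, because the
prediction target is cap-thickness change only.  The progressive /
non-progressive balance is governed by the intercept knob
(`progression_intercept_mm`, default 0 ⇒ ≈50/50), since the study does not
report its class balance.

**What the generator does not emulate:** raw image texture/speckle,
segmentation error in lumen/outwall, multi-component plaques (several
lipid pools, large calcifications — a `calcification` role is supported
end to end but not drawn by default), 3D continuity between adjacent
slices, and any within-patient correlation of geometry beyond the shared
pressure and IVUS bias.  Passing tests therefore demonstrate correctness
of the computational pipeline under the assumed statistical structure, not
clinical performance on real images.

## Cap geometry (Four-Quarter Even-Spacing)

Each slice is divided into 100 parts by 100 evenly spaced lumen points:
the lumen contour is cut into four quarters at its intersections with the
±principal axes of the lumen area (computed from the polygon's second
area moments about its centroid; sign conventions make the anchors
deterministic and rotation-consistent), and each quarter receives 25
points equally spaced in arc length.  The outwall is resampled 4 × 25 with
the *same* anchor rays, and lumen point i connects to the outwall point at
the same quarter-relative arc-length fraction — this reproduces the
non-crossing spoke pattern on convex-ish sections.  Wall thickness is the
connection-segment length; cap thickness is the distance from the lumen
point to the segment's nearest crossing of the lipid boundary, defined
only where the segment meets lipid; segments leaving the wall annulus are
flagged invalid and excluded.  The exact anchor/pairing rule of the
original method is described only in prior work; the principal-axis rule
here is one consistent reading and is isolated in `quarter_anchors` should
a different convention be needed.

Slice predictors: LA (lumen area), PA (outwall-enclosed area − LA),
PB = PA / outwall-enclosed area, MinCapT/MeanCapT over defined cap points.
Patient-level values pool the cap *point* values of all the patient's
lipid slices (patient MinCapT = minimum over all points of all slices).
IVUS-vs-IO errors are (IVUS − IO)/IO × 100 with IO as gold standard;
summary rows use the sample (n−1) SD.  The shipped validation dataset
(`capmech.datasets`) reproduces a published nine-patient table set cell by
cell; one published error cell (−5.86%) is internally inconsistent with
both its printed inputs and its own summary row, which imply −15.86%, and
is recorded as a known typo.

## Thin-layer mechanics

**Constitutive model.**  Modified Mooney–Rivlin:
W_iso = c1(I1−3) + c2(I2−3) + D1[exp(D2(I1−3)) − 1], with a fiber term
K1/K2 {exp[K2(I4−1)²] − 1} for vessel tissue (fibers circumferential).
Parameters (kPa): lipid c1=0.5, c2=0, D1=0.5, D2=1.5; calcification
c1=92, c2=0, D1=36, D2=2; vessel c1=−262.76, c2=22.9, D1=125.9, D2=2,
K1=7.19, K2=23.5.  The negative vessel c1 comes from prior calibrations
and is meaningful only inside the full expression (the exponential term
dominates); `validate_material` checks at model setup that W is
non-negative and monotone away from identity along equibiaxial radial
stretch in [0.9, 1.3] and raises otherwise.

Near-incompressibility uses the standard volumetric–isochoric split: the
Mooney–Rivlin terms act on reduced invariants Ī = J^(−2/3)-scaled, plus a
penalty κ/2 (J−1)² with κ = 3×10³ kPa.  On the incompressible manifold
(J = 1) the split energy equals the printed expressions exactly; off it,
the split makes the deviatoric stress traceless so the stress vanishes at
the identity — evaluating the printed form on full invariants instead
leaves a spurious hydrostatic offset 2(c1 + 2c2 + D1D2) that a penalty
formulation relaxes by unphysical volume loss.  κ = 3×10³ kPa keeps
|J−1| ≲ 0.5% at coronary pressures; raising it further degrades the
bilinear elements (mild locking) without improving the benchmark.

**Discretization.**  The 0.5 mm "3D thin-layer" slice is realized as
generalized plane strain: in-plane displacements with an imposed axial
stretch λz = 1.05 (F = blockdiag(Fp, λz)).  The wall annulus is meshed
with a structured spoke/layer grid of bilinear quadrilaterals (default 64
spokes; 2/3/4 radial layers in the cap/lipid/outer bands, band boundaries
following the lipid crossing radii per spoke and interpolated across the
lipid-free arc), so element edges conform to all tissue interfaces.
Quadrature is 2×2 Gauss for the isochoric energy and a single centroid
point for the volumetric penalty (selective reduced integration, avoiding
volumetric locking).

**Loads and solution.**  Lumen pressure is a follower load; on a closed
cavity it is conservative with potential −p·λz·A_cavity(deformed lumen),
so its residual and (constant) tangent follow from the shoelace-area
gradient of the lumen ring.  The outwall is traction free; rigid-body
modes are removed by three global Lagrange constraints (zero mean
translation and linearized rotation).  Newton's method uses an analytic
residual and a per-element forward-difference tangent (the tangent only
steers the iteration; the converged residual is exact), with incremental
load stepping — pressure and λz ramped together, step halved on
divergence (minimum 1/64), secant prediction along the load path, and
convergence at relative residual < 10⁻⁸.  Evaluation pressure defaults to
diastolic (configurable to systolic); 1 mmHg = 0.133322 kPa.

**Stress recovery.**  Reported fields are maximum-principal Cauchy stress
and maximum-principal Green–Lagrange strain.  The deviatoric part is
evaluated at the Gauss points, extrapolated bilinearly to element corners
and area-averaged to nodes; the penalty pressure κ(J−1) is taken from the
centroid (the only point where equilibrium controls J under reduced
integration — Gauss-point J is polluted by parasitic bilinear modes) and
rebuilt as a nodal field with linear radial extrapolation at the boundary
rings.  Cap aggregates (MaxCapS, MeanCapS, MaxCapSn, MeanCapSn) are taken
over the deformed lumen-boundary nodes nearest the slice's cap lumen
points; patient-level values pool all lipid slices.

**Verification.**  Against the semi-analytic incompressible tube-inflation
solution (1D quadrature of the radial equilibrium integral, independent of
the FE code), the hoop-stress profile agrees within 5% at 4/9.3/16 kPa at
the default density; at 0.1 kPa the radial displacement matches the
incompressible plane-strain Lamé solution within 5%; at zero load the
displacement is exactly zero.  `mesh_convergence` refines density by 10%
until the tracked cap quantity changes < 2% (the study's stated rule).

## Preshrink

Imaged contours are under load, so solving on them directly would
double-load the vessel.  `apply_shrink` scales the lumen about its
centroid by a factor s, rescales the outwall so wall area × λz is
conserved (s_out = √[(s²A_lumen + A_wall/λz)/A_outwall]), and maps
interior boundaries by linear radial interpolation.  `calibrate_shrink`
bisects s ∈ [0.85, 1.0] until re-inflation at the imaging pressure
restores the in vivo lumen area within 2% relative (the tolerance mirrors
the mesh-convergence threshold; the study states no number).  The
calibration pressure defaults to diastolic.  Calibrations warm-start from
the previous slice's factor and displacement field (the structured mesh
topology is density-determined, not geometry-determined), which typically
reduces a calibration to one or two Newton solves.

## Progression prediction

Records carry the nine baseline predictors of one arm (IO or IVUS) plus
ΔMinCapT computed from IO baseline/follow-up MinCapT — the benchmark is
always IO, whichever arm supplies predictors.  Label +1 (progressive) iff
ΔMinCapT < 0.

**GLMM (PQL).**  logit P(y=1|b_j) = β₀ + βᵀx + b_j with a per-patient
random intercept b_j ~ N(0, τ²).  Penalized quasi-likelihood iterates a
working-response linearization (z = η + (y−μ)/w, w = μ(1−μ)) around a
weighted random-intercept linear mixed model until the fixed effects move
< 10⁻⁶.  The inner LMM is solved directly: after √w scaling the
group blocks invert by Sherman–Morrison, the variance ratio λ = τ²/σ² is
profiled by 1D bounded minimization of the Gaussian ML criterion, and
BLUPs and GLS standard errors come for free.  This hand-rolled solver is
~50× faster than a generic mixed-model fit — necessary for the 511-subset
× 5-fold search — and is cross-checked in the tests against statsmodels
MixedLM (Gaussian case), an independent IRLS logistic fit (τ² pinned to
0, agreement 10⁻⁴), and R's MASS::glmmPQL (agreement ~10⁻⁶ on fixed
effects).  Separation or non-convergence triggers a small fixed-effect
ridge (10⁻³) with a warning.  Predictors are z-scored with training
statistics; test patients absent from training get the population-level
(zero-intercept) prediction.

**LSSVM.**  Gaussian-RBF least-squares SVM: training solves the KKT
system [[0, yᵀ],[y, Ω + I/γ]](b, α) = (0, 1), Ω_kl = y_k y_l K(x_k,x_l),
to residual < 10⁻⁸ (diagonal jitter with warning if singular).  (σ², γ)
are tuned per training fold by coordinate descent with a shrinking step on
3-fold inner-validation misclassification, multi-started from a 3×3
log₁₀ grid — deterministic given the seed, never touching test-fold
records, and never worse than every grid start.

**Cross-validation and search.**  5-fold CV, folds stratified by label
with a fixed seed (the study says only "randomly divided"; stratification
prevents degenerate folds at n ≈ 114; patient-blocked folds are available
as an option).  Out-of-fold scores are pooled into a single ROC; AUC is
the rank statistic with midrank ties; Acc/Sen/Spe use threshold 0.5
(GLMM probability) or 0 (LSSVM decision value), with sensitivity the
detection rate among progressive slices.  The search enumerates all 511
non-empty subsets of the nine predictors (deterministic size-then-
lexicographic order) and ranks by AUC, accuracy as tiebreak; failed
subsets are recorded with their error, not dropped.

## Problem sizes and numerical defaults

Default analysis scale mirrors the study: 9 patients, ≈114 lipid slices,
full 511-subset searches (analysis drivers; `--full`).  The test suite and
the acceptance script use desk-scale versions chosen for statistical
power per unit time: FE mesh density 0.5 (≈45 spokes × 7 layers; cap
aggregates at this density sit within ~1% of the 1.1×-refined values on
test slices), 20-slice preshrink round trips, GLMM parameter recovery at
n = 1000, CV calibration at n = 2000, and the reduced 127-subset search
over 7 predictors (LA, PA, PB, MinCapT, MeanCapT, MeanCapS, MaxCapSn) for
planted-signal recovery.  Subset-selection recovery is a large-sample
property: at 90 slices the top-ranked subset is unstable among
near-tied competitors (ΔAUC ~ 0.003 ≪ the ≈0.02 sampling noise of a
90-slice pooled AUC), so the recovery check generates 18 patients × 12
slices (216 records) and ranks subsets by metrics averaged over two CV
repetitions; the sign-recovery invariant of the generator is checked at
n ≥ 500 by direct regression.

Other defaults: polygon operations via shapely; areas/centroids/second
moments by exact polygon formulas; contour CSVs at 10⁻⁶ mm precision
(bit-identical regeneration from a fixed seed); report rounding 3 decimals
for mm/strain, 2 for kPa/percent.

## Known limitations

* 2D generalized plane strain approximates the 0.5 mm extruded slice;
  no 3D stacking along the centerline, no fluid (shear-stress) loading,
  no residual stress beyond the preshrink, no viscoelasticity.
* Bilinear quads with selective reduced integration limit stress accuracy
  to a few percent at the default density; the mesh-convergence loop is
  the guard for quantities that matter.
* The preshrink is a scalar circumferential calibration, not an inverse
  elastostatics solve; it restores lumen area, not the full boundary.
* Subset-selection results (which exact combination ranks first) carry
  the sampling noise of any model selection on ~100–200 slices; the
  package reports full ranked tables rather than a single "best" subset
  for this reason.  Two effects make the top-1 subset particularly
  unstable: near-tied candidates differ by less AUC (~0.003) than one
  cohort or fold draw moves, and once two or three predictors push the
  pooled AUC near its ceiling (≳0.95), genuinely informative additional
  predictors cannot measurably raise it, so parsimonious strict subsets
  of the true combination often win.  The planted-signal recovery check
  (top subset shares ≥3 of the 4 planted predictors) therefore holds at
  most — but not all — cohort draws even at twice the study scale with
  repeated-CV ranking; inclusion frequency across draws is the stable
  statistic.  Published studies show the same instability: the best
  combination differs between imaging arms of the same cohort.
* Headline published prediction metrics (e.g. AUC ≈ 0.93 on the real
  nine-patient cohort) are data-dependent and are not reproduction
  targets for the synthetic cohort.
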