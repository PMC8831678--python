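# Methods

This note documents the models implemented in `memdot`, the synthetic
phantom they are validated on, the numerical choices, and what the tests
do and do not demonstrate.

## Forward model and data

Surface diffuse optical tomography assumes the linear model `Y = A X + e`:
`Y` the channel optical-density changes (ΔOD, unitless log-ratios), `X`
the absorption changes at cortical-mesh vertices, `A` the Rytov-normalized
light-sensitivity matrix per wavelength, `e` additive noise.  All solvers
consume only `A`, a channel noise covariance `Σ_noise` (its inverse `Σ_d`
is the precision used for whitening), and `Y`.

## Depth-weighted MNE

`X = (AᵀΣ_d A + λ (ΛΛᵀ)⁻¹)⁻¹ AᵀΣ_d Y` with `diag(Λ) = g^(−ω)`,
`g = diag(AᵀΣ_d A)`.  ω ∈ [0, 1): 0 means an identity source covariance
(no depth compensation), 0.5 the standard variance-equalizing weighting;
larger ω moves reconstructed energy deeper.  The inverse is evaluated in
channel space (`X = W Aᵀ (A W Aᵀ + λ Σ_noise)⁻¹ Y`, `W = ΛΛᵀ`), identical
algebraically but p × p.  Vertices with zero sensitivity are flagged,
excluded, and reported as exact zeros.

**Regularization.**  The candidate grid is 60 log-spaced points spanning
`[10⁻⁶, 10²] × trace(A W Aᵀ)/trace(Σ_noise)` — λ multiplies the noise
covariance in the channel-space form, so this ratio centers the grid where
data term and prior balance for any ω.  Two selectors are provided:

* *L-curve*: maximum finite-difference curvature of the log–log
  (residual-norm, solution-norm) curve, ties toward larger λ, median-λ
  fallback on degenerate traces.  This is the classical choice and is what
  the unit tests validate on an analytic two-scale problem.
* *Morozov discrepancy* (pipeline default): the λ whose whitened residual
  norm is closest to √(#data).  On this phantom's noise-dominated windows
  the L-curve's global curvature maximum sits on the noise-fitting branch
  (the whitened residual there is far below the noise level), which
  under-regularizes every map; the discrepancy rule is the standard remedy
  and is exact here because the residual is whitened by the estimated
  precision.

## MEM

The reference prior factorizes over K parcels; parcel k is
`(1−α_k) δ(x_k) + α_k N(0, Σ_k(t))`.  Its log-Laplace transform (free
energy) and gradient are closed form:

    F_ν(ξ) = Σ_k log[(1−α_k) + α_k exp(½ ξ_kᵀ Σ_k ξ_k)]
    ∇F_ν|_k = γ_k Σ_k ξ_k,   γ_k = sigmoid(½ ξ_kᵀΣ_kξ_k + logit α_k)

evaluated in log space (logaddexp / expit) so large exponents cannot
overflow.  The dual `D(λ) = λᵀy − F_ν(Aᵀλ) − ½ λᵀΣ_noise λ` is concave; it
is maximized per time sample by L-BFGS with analytic gradients, the
previous sample's maximizer warm-starting the next (samples are otherwise
independent).  The estimate is `X̂ = ∇F_ν(Aᵀλ*)`; parcels with γ_k at
numerical zero are set to exactly zero (the switch-off that gives MEM its
spatial-extent accuracy).  In the α→1 limit the whole machinery collapses
to the Gaussian MAP estimator `Σ Aᵀ (A Σ Aᵀ + Σ_noise)⁻¹ y`, which the
tests verify against a direct linear solve.

**Prior construction.**  Parcels come from a data-driven parcellization:
a multivariate source prelocalization (MSP) score per vertex — the squared
projection of the unit-normalized sensitivity column onto the principal
subspace (95% energy) of the column-normalized data — and breadth-first
region growing from strict local maxima of that score (uniform scores
collapse to a single parcel; growth ties go to the higher-scoring seed).
Per parcel and time sample:

    Σ_k(t) = η_k(t) · Λ_k^{1/2} W_k(σ)ᵀ W_k(σ) Λ_k^{1/2}
    η_k(t) = 0.05 × mean_{i∈k} X̂²_dMNE-normalized(i, t)

where `W_k(σ)` is the row-stochastic smoothness operator
(`W(v,u) ∝ σ^order(v,u)`, σ = 0.6, support up to order 3), `Λ_k` the ω₁
depth-weighting diagonal restricted to the parcel, and the initializing
depth-weighted MNE (exponent ω₂) is *locally normalized* — divided by its
spatial maximum at each time sample — so the prior carries spatial
structure only and the temporal dynamics are estimated from the data.  The
product Λ η WᵀW is symmetrized by splitting Λ as Λ^{1/2}(·)Λ^{1/2}; this
keeps every Σ_k symmetric PSD and is identical to the unsymmetrized form
whenever Λ is constant on the parcel (and exactly the unweighted operator
at ω₁ = 0).  Means are initialized at zero; α_k is the parcel-mean MSP
score clamped to [0.05, 0.95]; η is floored at 10⁻¹² of its maximum so the
free energy stays finite when a parcel's prior energy vanishes.

Defaults: ω₁ = 0.3, ω₂ = 0.5 (the best-performing pairing on superficial
generators), η fraction 0.05, gradient tolerance 10⁻⁶ (scaled by ‖y‖),
500 iterations maximum.

## Synthetic phantom

No head model, fluence simulation or recordings ship with the method, so
validation runs on an analytic stand-in with the same qualitative physics:

* **Cortex** — a spherical cap (radius 80 mm scalp, 50° aperture) with
  sinusoidal folds so that 2500 vertices (≈2–4 mm edges) span depths
  4–36 mm: superficial gyral crowns (<10 mm), mid-depth walls (10–20 mm)
  and deep sulcal floors (>20 mm).
* **Montage** — the full double-density probe on a 1.5 cm lattice:
  8 sources, 10 shared detectors plus one 0.7 cm proximity detector per
  source; exactly 50 channels in classes 0.7/1.5/3.0/3.35 cm
  (8/6/24/12).  The planar layout is lifted onto the scalp sphere by the
  inverse azimuthal-equidistant map (distortion O((d/R)²)).
* **Sensitivity** — `exp(−(|v−src| + |v−det|)/10 mm)` per channel, a
  banana-path surrogate that makes longer channels relatively more
  sensitive at depth (the physical basis of multi-distance tomography),
  masked to an 18° cone about the channel midpoint's radial axis for
  lateral confinement, row-normalized (Rytov-style) with a small seeded
  per-channel gain; the second wavelength is a fixed 0.85 multiple.
* **Field of view** — vertices whose summed sensitivity exceeds 5% of the
  maximum; this calibrates the phantom's visibility reach to ≈28 mm depth,
  matching continuous-wave fNIRS.  Seeds are placed and generators grown
  inside the FOV, and solvers reconstruct FOV vertices only.  At much
  looser thresholds the deepest, nearly invisible shell wins the
  depth-weighted amplitude race for every method — an artifact of the
  analytic kernel's tail, not a property of real fluence models.
* **Generators** — seeds drawn per depth band by farthest-point sampling
  (100 superficial / 100 middle / 50 deep at full scale), grown to
  geodesic neighborhood order Se ∈ {3, 5, 7, 9} (≈2–20 cm² here).
* **Hemodynamics** — canonical double-gamma HRF (peak 6 s, undershoot
  16 s, ratio 6) convolved with one 20 s block inside 60 s pre/post
  baselines, unit peak; HbR = −HbO/3; converted to absorption at
  685/830 nm with bundled extinction coefficients; reconstruction and
  scoring use 830 nm.
* **Noise** — systemic physiology shared across channels with per-channel
  gains (slow AR(1) drift, Mayer ≈0.1 Hz, respiration ≈0.3 Hz, cardiac
  ≈1 Hz; proximity channels load strongest) plus local AR(1) and white
  noise, sampled at 4 Hz.  The record is preprocessed like task data
  (proximity-average regression, 0.01–0.1 Hz order-3 zero-phase
  Butterworth), cut into 10 disjoint trial-length epochs and averaged —
  mimicking a block average of real baselines.
* **SNR** — `max |ΔOD_task[0, 60 s]| / mean_c std_c(ΔOD[−60, 0])` with the
  numerator from the noise-free task signal (zero before onset, so the
  baseline window measures the added noise alone).  The noise scale
  solving this for a target is then unique and closed-form, and the
  achieved value is exact; with the noisy series in the numerator, targets
  below the noise's own max/std ratio (≈3–4) would be unconstructible.

**What the phantom does not emulate:** real sulcal geometry and partial
volume, fluence anisotropy and tissue heterogeneity, motion artifacts,
optode-coupling variation, and inter-subject variability.  Passing the
suite demonstrates correctness of the machinery and the *relative*
behavior of the solvers under controlled depth/extent/SNR conditions, not
absolute performance on a human head.

## Validation metrics

Maps are evaluated at the response peak (maximum of the ground-truth time
course); peak ties resolve to the lowest vertex index.

* **AUC** — ROC area of |amplitude| over in-FOV vertices, truth vs rest.
* **Dmin** — geodesic distance (edge-graph Dijkstra, mm) from the map
  peak to the truth border (truth vertices adjacent to non-truth); 0 when
  the peak is inside.
* **SD** — energy-weighted RMS geodesic distance to the truth region
  (d = 0 inside), penalizing spread and mislocalization together.
* **SE** — RMS difference between max-normalized reconstructed and true
  time courses; the reconstructed course is the energy-weighted mean over
  the truth region.

Aggregation reports medians/quartiles per (method, depth class, Se, SNR)
cell and Wilcoxon signed-rank tests on paired per-trial differences with
Bonferroni correction.

## Preprocessing

Fixed order for raw recordings: coefficient-of-variation screening
(reject std/mean > 8% on raw intensity), proximity-average superficial
regression (OLS with intercept; channel mean preserved), zero-phase
0.01–0.1 Hz order-3 Butterworth (mean re-added inside the chain so
intensities stay positive), ΔOD = −log(I/I_ref) against the reference
window, block averaging with per-epoch baseline correction.  The noise
covariance defaults to the diagonal baseline variance with 5% mean-trace
loading — with ~240 baseline samples for 50 channels a full sample
covariance is too noisy to whiten with, and it measurably degrades
reconstructions here.

## Numerical and design choices

* Geodesics are graph shortest paths over mesh edges; the error relative
  to exact polyhedral geodesics is bounded by mesh resolution.
* Voxel-to-vertex Voronoi projection breaks distance ties toward the
  lowest vertex index (determinism); empty cells get value 0.
* The evaluation time is the response peak, not the global
  spatial-energy maximum: per-sample local normalization of the MEM prior
  can make a pre-onset noise sample carry the largest energy, which would
  score maps at a time where no signal exists.
* Reconstruction runs on the [−10, 40] s window decimated to 1 Hz
  (50 channels × 51 samples); the problem sizes of the shipped study are
  2500-vertex meshes and 20 seeds per condition, chosen to keep a full
  multi-SNR suite in the minutes range while leaving the medians stable.
* Per-trial child seeds derive from the master seed by a counter, so any
  subset of the factorial grid reproduces identical trials.

## Known limitations

* α_k is a static function of the MSP score; the spatio-temporal score
  extension used in the original MEG formulation is not reproduced, and α
  is not updated across time samples.
* MEM runtime scales with K dense parcel kernels per gradient evaluation;
  very large parcels (uniform-score fallback) make Σ_k dense and slow.
* The discrepancy-based λ is tuned for whitened residuals; with a badly
  misspecified noise model both selectors degrade.
* The L-curve selector remains available and spec-tested but is not the
  pipeline default for the reason given above.
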