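# Methods

`visrsim` simulates and analyzes Viscoelastic Response (VisR) ultrasound
acquisitions in incompressible transversely isotropic (ITI) soft-tissue
materials, with the acoustic-radiation-force (ARF) push axis at varying
incidence angles to the material's axis of symmetry (AoS). Its purpose
is the in silico demonstration that the percent change of relative
elasticity with incidence angle, ΔRE, interrogates the ratio of the
longitudinal shear to Young's modulus, μL/EL.

## Constitutive model

An ITI material has three independent constants; the package stores the
full five-constant description with the incompressibility constraints
enforced at construction to 1e-12 relative:

    ν_LT = 1/2,   ν_TT = 1 − E_T/(2 E_L),   μ_T = E_T / (2 (1 + ν_TT)).

Note that ν_TT ≥ 1/2 whenever E_T ≤ E_L (the common soft-tissue case),
with equality exactly in the isotropic limit E_T = E_L, where μ_T = E/3.

The simulated panel contains twelve materials spanning E_T
11.74–24.96 kPa, E_L 35.23–82.78 kPa, μ_T 3.20–6.80 kPa and μ_L
4.80–40.80 kPa (skeletal muscle / kidney / breast range). Because only
ranges and cluster values are published for such panels, the individual
tuples are this package's own construction, fixed in a versioned CSV:
they include two pairs sharing μ_L (16.20 and 4.80 kPa) with different
E_L, two pairs sharing μ_T (3.60 and 3.20 kPa), a near-tied μL/EL group
{0.26, 0.26, 0.26, 0.27} that the rank tests must *fail* to separate,
one pair of ratios ~7% apart (0.42 vs 0.45) that they must separate, and
remaining ratios spread over 0.058–0.54.

## Creep model and forward solution

Tissue response to the two ARF pushes is a second-order
mass-spring-damper (MSD) system

    z'' + ωn² τ z' + ωn² z = S ωn² f(t),
    ωn = √(μ/m),  τ = η/μ,  S = A/μ,

with f(t) the normalized double rectangle: push 1 on [0, t_arf], push 2
on [t_arf + t_s, 2 t_arf + t_s]. t_arf = 70 μs and t_s = 0.4 ms is the
end-to-start separation; the tracking ensemble runs at 10 kHz PRF to
4.35 ms, skipping instants that fall inside a push. The closed-form
solution is the signed superposition of four Heaviside step responses,
with separate underdamped / critically damped / overdamped branches and
a switchover guard |ζ−1| < 1e-9 around the critical case. The closed
form is validated against a high-accuracy Runge–Kutta integration
(DOP853, rtol 1e-12) to 1e-8·S across ζ ∈ {0.2, 1, 3}.

Relative elasticity and viscosity are RE = 1/S = μ/A and RV = τ/S = η/A;
both are relative to the push amplitude A, which is unknown but assumed
constant over the field of view. RV is computed and emitted but not
analyzed further.

## Effective-stiffness surrogate

The full 3-D finite-element + acoustic-field simulation is replaced by a
closed-form surrogate for the apparent stiffness probed by a push at
deviation δ = 90° − incidence from normal incidence on the AoS:

    longitudinal (plane of symmetry):  μ_eff = μL + c_E · EL · sin²δ
    transverse  (plane of isotropy):   μ_eff = μT            (all δ)

This encodes the three findings the surrogate must reproduce: at normal
incidence RE reflects shear moduli only; RE grows as incidence deviates
from 90° in the plane of symmetry; the growth rate at fixed μL increases
with EL. The noise-free ΔRE is then exactly 100·c_E·(EL/μL)·sin²δ in
longitudinal orientation and 0 in transverse. The dimensionless coupling
c_E = 0.05 places ΔRE at δ = 44° in the tens of percent for low-μL/EL
materials (e.g. ~42% at μL/EL = 0.058, ~9% at 0.26). All statistics in
this package are interpreted through this surrogate; its sin² form is a
modeling choice, not a finite-element result, so absolute ΔRE magnitudes
should not be compared against measured tissue.

Incidence angles combine a beam tilt (±20°, the practical electronic
steering range) and a material tilt (0°, 12°, 24°); δ = |beam + material|.
The default angle set {90, 86, 78, 70, 66, 58, 46}° is the reference
plus the six non-normal angles such tilt combinations produce (the
−20°+12° combination's 82° is dropped, as the nine tilt combinations do
not map one-to-one onto distinct angles).

## Mapping stiffness to MSD parameters

The lumped spring constant is numerically equal to μ_eff through a unit
coupling length; the push amplitude A_ref = 0.25 N gives micrometer-scale
peaks (~1–5 μm across the panel) and the lumped mass m = 1e-3 kg puts
ωn in 2.2–6.7·10³ s⁻¹, where the 10 kHz PRF resolves the transient. The
damper follows a constant-damping-ratio model by default: τ = 2ζ₀/ωn at
the material's normal-incidence stiffness, ζ₀ = 1, angle-independent.
This choice is driven by identifiability: with a single fixed τ for all
materials the stiff end of the panel becomes heavily overdamped (ζ ≈ 2.7),
where the creep never approaches steady state and (ωn, τ, S) trade off
almost freely — Monte-Carlo characterization showed ~5% RE bias and
20-fold precision loss there, incompatible with sub-percent ΔRE work. A
`constant_tau` model remains available in the config. Near ζ = 1 the
response is non-negative for all t and all three parameters are well
identified (per-fit RE scatter ≈ 0.11% at the default noise).

## Synthetic data modes

`displacement` mode is the stand-in for the finite-element displacement
stage: noise-perturbed forward MSD profiles at the 11 analysis depths
(2 mm region of interest about the 20 mm focus, 0.2 mm spacing, matching
a 0.2 mm mesh). The default perturbation is zero-mean Gaussian noise
with σ = 0.2% of each profile's noise-free peak, the scale of
interpolation error when resampling smooth micrometer displacement
fields from a 0.2 mm mesh onto scatterer positions. It deliberately
excludes speckle-tracking noise — that belongs to `rf` mode — so
displacement-mode studies characterize the method under near-ideal
displacement estimates.

`rf` mode appends the ultrasonic chain: a 1-D line of point scatterers
(≥10 per resolution cell; fully developed speckle) spanning the ROI plus
margins, displaced uniformly inside the ROI with a Gaussian taper
(σ = 1 mm) outside to emulate the finite region of excitation, convolved
with a Gaussian-enveloped 6.15 MHz pulse (60% fractional bandwidth),
sampled at 40 MHz, with white Gaussian noise added so the ensemble
signal-to-noise power ratio is 40 dB. Lateral/elevational beam physics,
electronic-steering beam distortion and aberration are out of scope.

What passing displacement-mode tests do *not* show: robustness to
speckle decorrelation, scalloping bias of sub-sample interpolation, or
jitter-limited precision. In this package's own rf chain those effects
produce per-estimate errors of ~0.3–0.5 μm and per-realization RE errors
of several percent — an order of magnitude above the displacement-mode
noise floor — which is why the angle statistics are specified on
displacement-mode ensembles.

## Tracking

1-D axial normalized cross-correlation against the fixed pre-push
reference line: 512 μm kernel (27 samples at 40 MHz), search region
±4 samples (80 μm) about the running estimate, displacement =
lag · c/(2 fs). Sub-sample refinement is parabolic interpolation of the
peak over its two neighbors by default, with a cosine fit (exact for a
carrier-dominated correlation) behind a config switch; refinement is
skipped when the peak correlation is exactly 1, where the integer lag is
already exact. Estimates are flagged — not silently emitted — when the
peak lands on the search boundary or its correlation falls below 0.5.
Ties in peak value resolve to the smaller |lag| through `argmax`'s
first-occurrence rule on the symmetric lag grid.

## Fitting

Sum-of-squared-residual minimization of (ωn, τ, S) by Nelder–Mead on
log-transformed parameters (positivity without constraints), residuals
normalized by the profile peak for conditioning. Initialization:
S₀ = peak displacement, ωn₀ = π/t_peak, τ₀ = 2/ωn₀ (ζ₀ = 1); an optional
multi-start mode adds jittered starts and keeps the best objective, ties
broken toward smaller ωn. Termination at 2000 iterations or simplex
tolerances (xatol 1e-9 in log-space, fatol 1e-14 on the normalized
objective); non-convergence is reported in the result, never raised.
Noise-free round trips recover all three parameters to better than 0.1%.
ROI summaries are the mean and sample standard deviation (n−1) of RE
over converged fits in the 2 mm window.

## Angle statistics

ΔRE(θ) = 100·(RE(θ) − RE(90°))/RE(90°), referenced within realization.
Slopes are ordinary least squares of ΔRE against the deviation δ (so
slopes are positive and decrease with increasing μL/EL; the magnitude is
identical to regressing on the incidence angle), fit including the 90°
point, one slope per realization (n = 10 per material). Spearman's ρ
(Pearson correlation of midranks) relates per-material mean ΔRE to μL/EL
across the 12 materials at each angle separately. Pairwise two-sided
Wilcoxon rank-sum tests on replicate slopes compare materials adjacent
in μL/EL order plus all equal-ratio pairs; p-values are exact (full
enumeration of the C(n+m, n) rank assignments) for group sizes up to 10
and tie-corrected normal approximations beyond. No multiple-testing
correction is applied to the primary pairwise calls, matching common
reporting practice; a Holm-corrected column is emitted alongside for
transparency.

Degenerate cases: Spearman is undefined (recorded as NaN) when ΔRE is
constant across materials, which occurs by construction for noise-free
transverse studies; single-angle regressions and empty ROIs raise.

## Seeding and reproducibility

One master seed per study; each (material, orientation, angle,
realization) cell derives its generator from
`SeedSequence(master, spawn_key=(mi, oi, ai, ri))`, so results are
byte-identical across reruns and independent of execution order. Output
directories always contain the config snapshot and seed needed to
regenerate them.

## Problem sizes

The headline study runs 12 materials × 7 angles × 10 realizations × 11
depths in displacement mode (≈9,000 fits, a few minutes on one core);
rf-mode studies are exercised at single-cell scale in the test suite.
These sizes are the package's design choice for a desk-scale
demonstration of the method's statistics.

## Known limitations

- The sin² effective-stiffness surrogate is qualitative; only orderings
  and rank statistics, not absolute ΔRE magnitudes, transfer.
- The RF model is one-dimensional; lateral speckle decorrelation and
  beam distortions under steering are not represented.
- RE/RV are semi-quantitative (relative to the unknown push amplitude);
  no confidence intervals on μL/EL itself are produced.
- Ex vivo acquisition (scanner data ingestion) is out of scope.
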