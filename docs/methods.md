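# Methods

This note documents the models, numerical choices and known limitations of
`viscocap`, in the order the pipeline uses them.

## Constitutive model

The cell is treated as a liquid-filled capsule at constant volume whose
only resistance to indentation is the tension σ of its surface.  The
tension is a time-invariant prestress σ₀ (actomyosin contractility) plus
the viscoelastic response of the area-compressibility modulus, taken as a
power law K_A(t) = K_A⁰ (t/t₀)^(−β).  By the elastic–viscoelastic
correspondence principle the tension under an area-dilation history α(τ)
is the hereditary integral

σ(t) = σ₀ + ∫₀ᵗ K_A⁰ ((t−τ)/t₀)^(−β) (∂α/∂τ) dτ.

Parameters, units and defaults:

| parameter | meaning | units | typical range |
|---|---|---|---|
| σ₀ | shell prestress | N/m | 1e-4 … 5e-3 |
| K_A⁰ | area-compressibility scaling factor at t = t₀ | N/m | 0.005 … 0.5 |
| β | fluidity (0 solid, 1 fluid) | — | 0.05 … 0.95 |
| t₀ | reference time (conventional) | s | 1 |

t₀ merely fixes the time unit of K_A⁰ and is never fitted.  β = 1 is
excluded from the hereditary integral (non-integrable kernel); the
parameter bounds used in fitting stop at 0.999.

**Product integration.**  The strain history is piecewise linear between
samples, so on each segment the convolution has the closed form
slope·t₀^β·[(t−τ₁)^{1−β} − (t−τ₂)^{1−β}]/(1−β).  This integrates the
(t−τ)^(−β) endpoint singularity exactly with no tuning parameters.  For a
smooth underlying history sampled at spacing h the scheme converges at
O(h^{2−β}): the piecewise-linear interpolation error is O(h²) but the
singular weight concentrates it near τ = t, costing β orders.  The test
suite pins this rate and cross-checks the scheme against adaptive
quadrature with an algebraic endpoint weight to better than 1e-6 relative.

## Excess area and the membrane–cortex composite

Measured moduli refer to the projected area A₀ while the shell carries
A = A₀ + A_res.  Cortex extensibility (K_A^true) and reservoir recruitment
(K_A^res) act as 2D springs in series, and the projection multiplies the
result by ξ = A₀/(A₀+A_res):

K_A = ξ · K_A^true K_A^res / (K_A^true + K_A^res).

The no-reservoir limit is encoded as an explicit flag (`KAres=None`)
rather than an infinite modulus, avoiding overflow.

The membrane–cortex composite puts an elastic bilayer (modulus K_A^mem)
in parallel with the power-law cortex:
σ(t) = σ₀ + ∫ K_A^cort,0(…) dα + K_A^mem α(t).  Matching Laplace
transforms of the two kernels,
K̃⁰ Γ(1−β̃)/s^{1−β̃} ≈ K_cort,0 Γ(1−β)/s^{1−β} + K_mem/s,
defines an apparent single power law.  The match is exact only in the
degenerate limits (K_mem = 0 → β̃ = β; K_cort = 0 → β̃ = 0), which the
implementation returns exactly; otherwise the apparent pair is
window-dependent and is computed by least squares of the log-transforms on
50 log-spaced frequencies.  The default window (0.1–100 s⁻¹ in the tests)
corresponds to experiment durations of seconds and sampling of order
100 Hz; it is an exposed argument because no canonical window exists.
Because the matched amplitude carries a Γ(1−β)/Γ(1−β̃) factor, the fitted
K̃⁰ can slightly exceed K_cort,0 + K_mem at small membrane share — an
inherent property of log-domain matching, not a defect.

## Capsule geometry

The undeformed cell is a spherical cap of apical radius R₁ pinned at its
base circle (focal adhesions), default contact angle θ_c = π/2
(hemisphere).  Under a rigid probe (sphere, cone or flat punch) the
surface splits into a probe-conforming contact zone and a free zone
approximated as a spherical segment through the pinned base.  For each
depth the contact extent is the single unknown, solved by Brent's method
on the constant-volume constraint; all areas and volumes are closed-form,
so tabulated configurations conserve volume to the root tolerance
(relative error below 1e-8, tested).

The shape function follows from virtual work at constant tension,
f = σ dA/dz = 2π g̃_cap R₁ σ with g̃_cap = (dA/dz)/(2πR₁), computed by
centred differencing of the area on a half-step stencil.  g̃_cap and α are
dimensionless functions of z̃ = z/R₁ and shape ratios only (tested by
scale invariance), tabulated once per geometry and interpolated with
monotone cubics (no extrapolation).  Tables serialize to tab-separated
text, so an externally supplied (z̃, g̃, α) table — e.g. from a different
shape construction — can be substituted without touching the fitting code.

Deliberate approximations: the free surface is a spherical segment rather
than a general constant-mean-curvature surface; α is referenced to the
apical cap area (the basal disc is constant and drops out of dA/dz); the
probe–cell contact is adhesion-free.  The colloidal probe default is
R_p = 3.31 μm (a 6.62 μm sphere quoted by diameter).

## Curve preprocessing and fitting

Baseline: a line fitted to the first 50% (configurable) of the approach is
subtracted; an optional single-sinusoid notch (frequency seeded by the FFT
peak, then refined) removes the periodic artifact that thin elastomer
substrates imprint on force curves.  The pre-contact travel must dominate
the baseline window — the synthetic protocol defaults to 1.2·δ_max of
approach before contact for this reason.

Contact point: first crossing of threshold·(MAD noise) that persists for a
run length (defaults 5σ, 10 samples), refined to sub-sample precision by
scanning candidate contact heights over the one-sample interval before the
crossing and maximising the linearity of log f vs log(z−z₀).  The
power-law form absorbs the steep early transient of fluid-like cells
(f ~ (z−z₀)^p with p slightly above 1), where linear back-extrapolation
is biased.

Indentation: δ(t) = (z − z_contact) − f/k, with a rigid-cantilever flag
that drops the deflection term.  During a dwell the default is the rigid
approximation (δ held constant); with a compliant cantilever the measured
deflection can be used instead (`rigid_dwell=False`).

Fit: bounded trust-region least squares of the forward model over the
post-contact approach plus either the dwell (relaxation curves) or the
first 10% of the retraction — the short retraction window keeps the fit
clear of adhesion-contaminated data, which otherwise biases σ₀ downward
(regression-tested).  Samples above 1.05× the recorded setpoint are
excluded.  Residuals are nondimensionalized by the peak force so the
optimizer's tolerances see O(1) quantities.  Eight starts cycle β through
{0.2, 0.5, 0.8} with K_A⁰ log-spaced over 0.005–0.5 N/m and σ₀ seeded from
the low-indentation force; the best residual wins, with ties (<0.1%
relative) broken toward smaller β.  Noiseless round trips recover
generating parameters to ~1e-12 relative across β ∈ [0.1, 0.9],
K_A⁰ ∈ [0.005, 0.5] N/m.

## Population analyses

Cells, not indentations, are the replication unit: per-cell means feed all
population statistics.  The scaling line β = a − m·log₁₀K_A⁰ is fitted by
ordinary least squares through binned averages (default 8 bins; 1D bins on
log₁₀K_A⁰ or 2D bins on both axes, which de-weight dense scatter regions).
Base-10 logarithms are used throughout; the shift factor ξ⁻¹, being a
ratio of K_A⁰ values, is base-independent.

The parallel-shift estimator refits both populations' bin means with a
shared slope and separate intercepts; ξ⁻¹ = 10^{Δa/m}.  A shared-slope
refit (rather than averaging two independent slopes) matches the
nearly-parallel premise and stays well-posed when one arm is noisy; the
ratio of unconstrained slopes is reported as a parallelism diagnostic.
Shifts of 1.5× and 6× imposed on synthetic populations (200 cells,
scatter SD 0.05) are recovered within 10%.

Rank-sum comparisons use the two-sided Mann–Whitney U test — exact
enumeration for combined n ≤ 20 without ties, normal approximation with
tie correction otherwise — with Bonferroni correction over the number of
pairwise comparisons (significance codes ns/*/**/***/****).

Substrate strain is estimated from fiducial bead displacements: beads are
matched by nearest neighbour after per-axis standardisation (which removes
drift and the bulk stretch, so matching survives 30% strains), and the
per-axis strain is the mean of pairwise projected-distance ratios minus
one, excluding pairs whose baseline separation is below 5% of the field
span (jitter-dominated ratios).  Cell shape descriptors come from the
ellipse with the same second moments as the segmentation mask; orientation
is reported in [0°, 90°] against the axis perpendicular to the strain.

## Synthetic data

The generator produces every input the pipeline consumes, deterministic
under a fixed seed (recorded in output metadata):

- **Force curves** from the forward models under a trapezoidal piezo
  protocol.  With a compliant cantilever, δ = z − f/k is solved causally —
  sample by sample with the past strain frozen, each δᵢ by Brent on a
  monotone scalar equation — because a whole-curve fixed point loses
  contractivity when the cell's force gradient approaches the spring
  constant.  Protocol defaults mirror typical experiments (approach
  2 μm/s, setpoint 5 nN; the vesicle protocol runs 0.5–2.7 μm/s).  Noise
  is Gaussian on the force (defaults in the 10–50 pN range, instrument
  noise being otherwise unspecified), plus optional baseline sinusoid and
  an adhesion dip on retraction modeled as a negative Gaussian bump in z —
  a stress test for the retraction-window rule, not adhesion physics.
- **Populations** with log₁₀K_A⁰ uniform over [−2.3, −0.7], β on the line
  a − m·log₁₀K_A⁰ (defaults a = 0.21, m = 0.30, chosen so β spans
  ~0.3–0.9 over the K_A⁰ range) with Gaussian scatter (SD 0.05) clipped to
  [0.05, 0.95], σ₀ lognormal around 1 mN/m; the condition arm multiplies
  K_A⁰ by ξ⁻¹ at unchanged β.  Per-cell curves are emitted on request
  (`emit_curves=True`); the population analyses consume the records.
- **Bead fields** with a 5 μm minimum spacing (distinct clusters), affine
  per-axis stretch and Gaussian jitter.

What the generator does not emulate: instrument drift and hydrodynamic
drag on the cantilever, cell-to-cell geometry variation within a
population arm, adhesion physics, segmentation errors in masks, and any
active cellular response during the measurement.  Passing round trips
therefore demonstrate correctness of the inverse problem under the model's
own assumptions, not robustness to model mismatch on real instruments.

## Problem sizes used in tests and the acceptance script

Round-trip curves are sampled at 100 Hz (approach of seconds, dwell 3–4 s,
~500–1400 samples), shape tables use 100–150 nodes, and populations use
100–400 cells — sizes at which the full suite runs in a few minutes on one
CPU while leaving the recovery tolerances comfortably resolved.

## Known limitations

- The spherical-segment free surface is an approximation; a general
  constant-mean-curvature solver could replace it behind the same table
  interface.
- The hereditary fit assumes the shape table covers the deepest sample;
  curves that exceed it raise rather than extrapolate.
- The apparent-fluidity reduction is window-dependent by construction;
  comparisons across studies must fix the frequency window.
- Self-consistent dwell indentation for very soft cantilevers
  (k comparable to the cell's force gradient) is handled in the generator;
  the fitter's deflection correction uses the measured force and does not
  iterate on the model force.
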