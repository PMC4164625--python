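# Methods

## The kinetic model

Under saturating acetyl-peptide, the sirtuin catalytic cycle is reduced to
four enzyme species: the peptide complex E·Ac-Pr, the ternary complex
E·Ac-Pr·NAD⁺, and the alkylimidate intermediate with and without bound
nicotinamide (E·ADPR-Pr-Im·NAM, E·ADPR-Pr-Im). Free enzyme and direct NAM
binding to E·Ac-Pr are omitted: with peptide saturating, free enzyme is
captured immediately, and NAM's affinity for the peptide complex is
negligible next to its affinity for the intermediate. The steps are NAD⁺
binding/release (kon_nad·S, koff_nad), nicotinamide cleavage and its
reversal — the base-exchange step — (k_c, k_rex), NAM release/rebinding
from the intermediate (koff_nam, kon_nam·I), and two catalytic exits that
close the cycle: kcat from the NAM-free intermediate and kcat_bound from
the NAM-bound one (deacetylation with concurrent AADPR + product release;
products never rebind in the initial-rate regime).

The steady state of this linear pseudo-first-order network is obtained by
a direct 4×4 solve with one balance row replaced by mass conservation —
no time integration. Multiplying the resulting velocity expression
through by its binding denominators shows it is a ratio of polynomials
that are bilinear in (S, I), i.e. exactly the hyperbolic mixed form

v = vmax·S·(1 + I/K₁) / [ S·(1 + I/K₃) + Km·(1 + I/K₂) ],  K₃ ≡ αK₂.

`derive_macroscopic` makes that equivalence operational: it solves the
scheme on a 64×64 log-spaced grid spanning two decades either side of
Kd,NAD and Kd,NAM and fits the macroscopic form to the surface (linear
solve for the reparameterized unknowns, then a Levenberg–Marquardt polish
on log-parameters against relative residuals). The maximum relative
residual is reported and is at numerical noise (~1e-13) for every network
tested; a large residual would mean the supplied network departs from the
assumed topology. The slow-catalysis limits K₁ → Kd,NAM and
K₁/K₃ − 1 → k_rex/k_c (with the bound complex turning over at the same
kcat) are verified numerically in the sweep analysis rather than assumed.
The exact symbolic expressions of K₂, K₃ in the rate constants are
deliberately not derived — the numeric oracle replaces them — and the
α ↔ Kd,NAD/Km relation is exposed only as the qualitative direction
(larger Kd,NAD relative to Km favours larger α).

Kinetically silent networks (k_rex = 0 with a fully active bound complex)
make the inhibition constants degenerate; `derive_macroscopic` detects
the NAM-independent surface and reports K₁ = K₂ = K₃ at the NAM Kd scale
rather than an arbitrary least-squares null vector.

## Parameters and conventions

Concentrations are µM, velocities µM/min, time min, package-wide. K₁ is
stored as its reciprocal r1 = 1/K₁ so that "numerator term omitted" is
exactly r1 = 0 rather than a sentinel. Net inhibition requires K₁ ≥ K₃;
a finite fit below that is flagged, not rejected. ΔG conversions use
R = 1.9872·10⁻³ kcal·mol⁻¹·K⁻¹, T = 310.15 K (the assay temperature) and
a 1 M standard state.

## Fitting

All fits are global: one parameter vector against every point of the
grid, minimizing unweighted squared velocity residuals by default (the
convention of the common curve-fitting tools for this assay type; a
`weighting="relative"` option divides residuals by velocity).
Positivity is enforced by optimizing log10-parameters; log10(α) is boxed
to [−3, 20] so a competitive-limit estimate (α ~ 10¹⁹) remains
representable. Each fit starts from an algebraic initializer — the rate
law times its denominator is linear in (vmax, vmax/K₁, 1/K₃, Km, Km/K₂),
so ordinary linear least squares gives near-exact starts on clean data —
plus 8 Latin-hypercube starts over data-driven ranges, all under a fixed
seed; the lowest SSR wins with ties broken by start order, which also
makes estimates invariant to row order. Optimizer tolerances are 1e-15 so
noise-free round trips recover generating values to ≥5 significant
digits.

Standard errors come from the Gauss–Newton covariance
SSR/(n−p)·(JᵀJ)⁻¹ on the log scale, delta-propagated to the natural
scale. K₁ estimability follows a two-part rule: the term is omitted and
the model refit with r1 = 0 when the fitted K₁ exceeds 100× the largest
tested [NAM], or when pinning K₁ at that bound changes the SSR by less
than a χ²(1)-scaled fraction (a one-point profile-likelihood check). The
mixed fit reports "competitive limit reached" when the uncompetitive term
I/(αKi) is below 1e-6 across the design, since beyond that plateau α has
no finite estimate. Model comparison uses AICc with k = p + 1 (residual
variance counted), ties broken toward fewer parameters.

IC₅₀ curves are fit with the plain one-site law v₀/(1+I/IC₅₀); a Hill
exponent is available in the response function but off by default, since
50%-inhibition data of this kind are routinely summarized without one.

## Synthetic assays

The generator reproduces the study's concentration designs exactly
(SIRT3: 100–3000 µM NAD⁺ × 0–200 µM NAM; SIRT1: 50–1500 × 0–100;
isoNAM: 0–40 mM; the derepression series at 500 µM NAD⁺, 100 µM NAM,
0–900 µM isoNAM; and the IC₅₀ ladders) and perturbs model velocities
multiplicatively: v_obs = v·(1+ε), ε ~ N(0, CV²), truncated at zero.
Constant CV mimics fluorometric plate-reader initial rates, whose error
scales with signal. The assay's true noise level is not published;
CV = 0.05 is the package default as typical plate-reader precision, and
truncation bias is negligible below CV ≈ 0.2. One seeded stream per
dataset makes every table reproducible from (design, seed). Not emulated:
raw fluorescence time courses, developer chemistry, substrate depletion
(initial rates are treated as exact), pipetting layout effects, or
between-day drift — so passing round trips demonstrate identifiability
of the designs under well-behaved noise, not robustness to real-world
systematics.

## Uncertainty audit

Interval calibration is checked by simulation on the SIRT3 design at
CV 5% with 3 replicates per cell (matching the reported "means of three
or more replicates"): 500 simulated assays are refit and 1.96-SE interval
coverage is pooled over vmax, Km, K₂, α. The audit uses the
relative-weighted estimator, which is the likelihood-matched choice under
constant-CV noise; unweighted Wald intervals are materially anticonservative
there (~77% pooled coverage), which is a property of mismatched weighting,
not of the data. Measured coverage is ~0.95 per parameter. RMSE is
tracked over replicate counts 1, 2, 4, 8 (60 simulated assays each) and
falls close to the expected √2 per doubling. These sizes keep the full
audit around a minute on one CPU while leaving Monte-Carlo error on
coverage near ±1%.

## Known limitations

- Peptide-substrate dependence is out of scope (saturating throughout);
  the model cannot describe peptide-limited regimes.
- The finite-K₁ branch of the rate law is implemented and testable, but
  the published designs cannot identify K₁ — analyses of those designs
  always land on the omitted-term model, by construction.
- Dixon-slope and intersection-point formulas are exact only for K₁ = ∞;
  both raise outside that regime rather than approximating.
- AICc comparison assumes i.i.d. Gaussian residuals on the fitted scale;
  with replicate-correlated errors it would be optimistic.
- The steady-state solver targets the 4-species topology; other sirtuin
  mechanisms (e.g. NAM binding to the peptide complex) need a different
  balance matrix.
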