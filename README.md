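# sirtkin

Steady-state kinetics of sirtuin inhibition by nicotinamide (NAM):
hyperbolic mixed (base-exchange) rate laws, a microscopic reaction-scheme
solver, global nonlinear fitting, and mechanistic diagnostics.

Sirtuins (here SIRT3 and SIRT1) couple deacetylation of an acetyl-lysine
substrate to cleavage of NAD⁺. The reaction's own product, nicotinamide,
is an endogenous inhibitor: it rebinds the enzyme–alkylimidate
intermediate and drives the *base-exchange* back-reaction that regenerates
NAD⁺. Because the NAM-bound intermediate can still turn over, the
resulting inhibition is *hyperbolic* (partial) mixed rather than the
textbook linear kind, and the degree of apparent competition with NAD⁺
differs sharply between isoforms. This package implements that kinetic
model end to end, for kineticists analysing initial-rate inhibition data
and for anyone exploring sirtuin activation by derepression (displacing
NAM with an inert C-pocket ligand such as isonicotinamide, isoNAM).

## The models

With S = [NAD⁺] and I = [NAM], the base-exchange initial-rate law is

    v = vmax · S · (1 + I/K₁) / [ S·(1 + I/K₃) + Km·(1 + I/K₂) ],   K₃ ≡ αK₂

- K₁ is the numerator (bound-turnover) constant; when the data cannot
  resolve it, the I/K₁ term is omitted (K₁ = ∞), and the law coincides
  with the standard mixed model with Ki = K₂.
- α measures competitive character: α ≫ 1 competitive, α = 1
  noncompetitive, α ≪ 1 uncompetitive.
- At saturating S and I the residual activity is K₃/K₁ ≈ 1/(1+Kex),
  linking the fit to the base-exchange equilibrium constant
  Kex = k₋ex/k_c of the underlying scheme.

Unreactive inhibitors (isoNAM) follow the standard mixed law
v = vmax·S/[S·(1+I/(αKi)) + Km·(1+I/Ki)], dose–response curves the
one-site form v = v₀/(1+I/IC₅₀). The `steady_state` module solves the
4-species reaction scheme (E·Ac-Pr ⇌ E·Ac-Pr·NAD⁺ ⇌ E·ADPR-Pr-Im·NAM ⇌
E·ADPR-Pr-Im → E·Ac-Pr, plus bound turnover) and verifies numerically
that its steady-state surface is exactly of the hyperbolic mixed form.

## Worked example

```python
from sirtkin import fit_base_exchange, intersection_point
from sirtkin.reference import SIRT3_NAM
from sirtkin.synth import builtin_design, generate_rates

design = builtin_design("sirt3_nam")            # 5 [NAD+] x 4 [NAM] grid
data = generate_rates(SIRT3_NAM, design.with_noise(0.0, 1, 0))
fit = fit_base_exchange(data)                   # global fit, K1 omitted
print(fit.summary())
print(intersection_point(fit.params_base_exchange()))
```

prints

```
model: base_exchange   n=20  SSR=4.01107e-32  AICc=-1492
      vmax = 0.197  (se 8.78e-17)
        km = 673.3  (se 8.58e-13)
        k2 = 29.4  (se 6.95e-14)
     alpha = 2.735  (se 1.22e-14)
        k3 = 80.409  (se nan)
(-0.0005430427936727912, 3.2201486650766986, 'mixed (competitive character)')
```

i.e. the global fit recovers the generating constants (µM and µM/min)
exactly on noise-free data, and every double-reciprocal line crosses at
x = −1/(αKm) = −5.43·10⁻⁴ µM⁻¹ with positive y — the signature of mixed
inhibition with substantial competitive character (α = 2.735). For SIRT1
(α = 0.848) the point sits essentially on the x-axis: near-noncompetitive.

A command-line interface covers the same ground:

```sh
sirtkin designs
sirtkin simulate --design sirt3_nam --params sirt3_nam --out rates.csv
sirtkin fit --table rates.csv --model base_exchange --out fit.json
sirtkin diagnose --params sirt3_nam --k1-bound 4623 --out diag.json
```

## Analysis pipeline

The numbered drivers under `analysis/` rebuild the full kinetics story
into `results/`: `01_simulate_assays.py` (assay tables on the published
designs), `02_global_fits.py` (the parameter table and AICc model
ranking), `03_diagnostics.py` (double-reciprocal/Dixon geometry, model
IC₅₀s, the derepression prediction, Kex bound and ΔG conversions),
`04_mechanism_oracle.py` (reaction-scheme ⇄ rate-law equivalence and the
slow-catalysis limits), `05_uncertainty.py` (interval coverage and RMSE
scaling of the estimator).

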