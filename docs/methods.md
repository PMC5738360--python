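# Methods

## Models

**Receptor-cleavage reporter (five states).** Inactive receptor R is produced
at α_R and activated by ligand L at rate α_R*·R·L; active receptor R* decays
at β_R* and catalyzes cleavage of the adaptor–effector fusion A through the
term γ_C·R*·Aⁿ, which simultaneously consumes A (n molecules per catalytic
event) and produces free effector C; C is lost to degradation (β_C) and to
productive reporter activation (γ_G); reporter G is produced at γ_G·C and
degrades at β_G. The exponent n is the per-receptor effector stoichiometry
and may be non-integer (real-valued powers throughout); the two-state R/R*
scheme has no internalization or recycling states, no basal (ligand-free)
activation term, and no spatial or stochastic structure — heterogeneity is
modeled only as measurement noise in the data generators.

Setting all derivatives to zero collapses the system to
G_ss = G_max·L/(L+K_L)·A_ssⁿ/(K_A+A_ssⁿ) with
G_max = (γ_G/β_G)·α_R/(γ_G+β_C), K_L = β_R/α_R*, K_A = β_R*/γ_C. Because the
surface forces G = 0 at L = 0, leaky baselines in real data are handled by an
optional additive basal parameter in the fitting layer only (default off),
never in the core equations.

**Dox-induction cascade (two states).** Effector C is produced at
α₁·Dⁿʰ/(K_D+Dⁿʰ) and degrades at β₁; reporter G is produced at α₂·Cᵐ and
degrades at β₂. K_D is kept exactly as written in the induction term, so it
carries units of Dⁿʰ. The lumped exponent m (effector binding, transcription,
translation in series) defaults to 1 — the steady state is then the Hill form
κ₁κ₂·Dⁿʰ/(K_D+Dⁿʰ) — and general m is retained as an option
(G_ss = κ₂·C_ssᵐ).

## Coupled fixed point

For L > 0 the receptor and active-receptor balances are substituted into the
adaptor balance, leaving one scalar equation
f(A) = α_A − β_A·A − γ_C·R*(A)·Aⁿ. Since f(0⁺) = α_A > 0 and
f(α_A/β_A) < 0 (cleavage can only depress A below its no-ligand level), the
root is bracketed on (0, α_A/β_A] and found by Brent's method at machine
precision; the remaining states follow in closed form. Every returned
solution is verified against all five balances with residuals scaled by the
dominant flux in each equation (threshold 1e-8 relative); failure raises an
error carrying the per-equation residual report rather than returning a bad
point.

## Dynamics

Inputs are piecewise-constant schedules on right-open intervals. Integration
restarts at every breakpoint so discontinuities (e.g. a one-day ligand pulse)
are exact instead of smeared by adaptive step control. Degradation constants
may span decades, so the default integrator is LSODA (switches to implicit
BDF when stiff) with rtol 1e-6, atol 1e-9; tiny negative excursions within
10× atol are clipped to zero. The default initial condition is the
ligand-free coupled steady state — cells pre-equilibrated on the inducer
before ligand addition — with explicit zeros available for cold starts.

The reversibility demonstration uses a documented rate set (demo config)
chosen by coarse search so that the effector and reporter lifetimes
(1/(γ_G+β_C) ≈ 33 h, 1/β_G = 20 h) are slow relative to the one-day pulse:
the reporter then peaks ~19 h after ligand removal (residual free effector)
and decays to ~6% of peak six days later. The check is qualitative by design:
no rate constants for the five-state system are identifiable from
steady-state data, so only the lumped surface parameters carry quantitative
meaning.

## Synthetic data

Generators emulate well-level summaries of flow-cytometry readouts, not
per-cell events (no gating, spillover or single-cell heterogeneity). The
default design is 6 adaptor levels log-spaced 10–10,000 AU × 8 ligand doses
log-spaced 1–10,000 nM × 3 replicates. Default noise is multiplicative
lognormal with cv 0.10 and exactly unit mean, chosen because fluorescence
readouts are positive with roughly scale-proportional spread; no empirical
noise law was available, so recovery tolerances are stated relative to this
default. The adaptor covariate is emitted twice: the exact design level and
a noisy `adaptor_readout` (the same noise model), mimicking a fluorescent
proxy measurement; fits use the noisy readout by default and can switch to
the true levels for oracle checks. Errors-in-variables correction is out of
scope — with cv 0.10 over three decades of adaptor range the attenuation of
n is negligible relative to its sampling spread.

Truth values in the demo config: G_max = 1000 AU (arbitrary scale),
K_L = 105 nM (placing the ligand set-point at the dose-response EC50 scale),
n = 2.33, and K_A = 316.23^2.33 ≈ 6.68e5 so the adaptor half-point sits at
the geometric middle of the level grid. qPCR plates place detected Ct at
gapdh_ct − log2(factor) + N(0, sd) (one cycle per twofold change) and emit
explicit undetected wells below a dropout threshold.

## Fitting

All three fits (steady-state surface; 4PL Hill dose-response
bottom + (top−bottom)·dʰ/(EC50ʰ+dʰ); dox Hill curve) share one engine:
strictly positive parameters are optimized in log10 space (positivity is
structural; n and hill slopes bounded to [0.1, 10], a generous band around
plausible stoichiometries), using trust-region least squares via lmfit with
ftol/xtol/gtol 1e-12 so noiseless data are recovered to ≲1e-6. Multi-start
uses a deterministic 3-point-per-log-parameter lattice spanning ±2 decades
around moment-based guesses (plateau ≈ max response, EC50/K_L ≈ the dose
nearest half-range or the geometric median, exponents start at 1); the start
with the best final loss wins, so fits are reproducible without a seed, and
the best-so-far loss trace is kept as a diagnostic. Least squares is
unweighted on linear response values. Standard errors come from the
regression covariance, mapped to the natural scale by the delta method
(se_x = ln10·x·se_log10x). Goodness of fit is the Pearson correlation r
between observed and fitted responses (computed by the same `pearson_r`
the results expose). The 4PL form was chosen over a 3-parameter Hill because
real reporter data have a nonzero leaky baseline; `bottom` is fit in linear
space with a zero lower bound so noiseless zero-baseline data are still
recovered exactly.

Identifiability is enforced, not assumed: freeing n requires ≥2 distinct
adaptor levels and ≥2 doses, dose-response fits require ≥4 distinct doses,
and violations raise an explicit error instead of a silent degenerate fit.

## Problem sizes and expected precision

Recovery statements are medians over 20 seeded datasets at the default
design; at cv 0.10 a *single* dose series constrains EC50 only to ~15–20%
(the regression standard error says as much), while the 20-seed median lands
within a few percent of truth. The fixed-point/ODE equivalence check uses 50
loguniform rate draws with n ∈ {0.5, 1, 2, 2.33, 3}, integrating to
60× the slowest degradation time at rtol 1e-10 and comparing at 1e-4
relative. These sizes were chosen to make every statement a stable property
of the estimator rather than of one lucky draw.

## Known limitations

The steady-state fit identifies only the four lumped parameters, never the
eleven rate constants; dynamic claims are therefore qualitative. The noise
model is homogeneous across wells (no dose-dependent cv, no plate effects).
ΔΔCt assumes perfect amplification efficiency (no Pfaffl correction, no
standard curves), averages replicates in Ct space (geometric mean in
expression space; the order of averaging is a convention, recorded here),
and treats clamped wells as exactly 35 cycles while counting them in an
`n_clamped` flag. Passing recovery tests on these generators shows the
estimation machinery is correct and well-calibrated at the stated designs;
it does not validate the biological model against real cytometry data.
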