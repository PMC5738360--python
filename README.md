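# chachakit

Rate modeling, simulation and parameter estimation for GPCR-coupled
CRISPR-dCas9 reporter systems built on the receptor-cleavage ("ChaCha")
architecture: a ligand-activated GPCR carries a TEV protease that cleaves a
membrane-sequestered adaptor–dCas9-effector fusion, releasing free effector
that activates a reporter gene. The central biological question the model
answers is *how many effector molecules one activated receptor releases over
its lifetime* — the stoichiometry exponent *n* — together with the ligand
dose–response set-point (EC50).

The package is for quantitative cell engineers and systems biologists who
want to simulate this class of receptor reporters, design adaptor-titration ×
ligand-dose experiments, and estimate the model's parameters from well-level
fluorescence summaries (or from synthetic data with the same structure).

## The model

Five mass-action balances couple inactive receptor R, active receptor R*,
adaptor–effector fusion A, free effector C and reporter G:

    dR/dt  = α_R − α_R* · R·L − β_R · R
    dR*/dt = α_R* · R·L − β_R* · R* − γ_C · R*·Aⁿ
    dA/dt  = α_A − β_A · A − γ_C · R*·Aⁿ
    dC/dt  = γ_C · R*·Aⁿ − (γ_G + β_C) · C
    dG/dt  = γ_G · C − β_G · G

At steady state these reduce exactly to a product of two saturation terms:

    G_ss = G_max · L/(L + K_L) · A_ssⁿ/(K_A + A_ssⁿ)

with G_max = (γ_G/β_G)·α_R/(γ_G + β_C), K_L = β_R/α_R*, K_A = β_R*/γ_C.
The exponent *n* — adaptor molecules processed per active receptor — is what
nonlinear regression on an adaptor × dose grid estimates; *n* > 1 means one
receptor releases multiple effectors. A companion two-state model covers
dox-inducible effector expression (Hill form in the dox dose, used to verify
the effector→reporter step is non-cooperative), and a ΔΔCt module handles
qPCR quantification (relative expression = 2^−ΔΔCt against a housekeeping
gene and a reference sample, with the 35-cycle Ct clamping rule).

## Worked example

`examples/02_fit_stoichiometry.py` generates one synthetic 6 adaptor-level ×
8 dose grid (3 replicates, multiplicative lognormal noise, cv 0.10) from the
documented truth surface with n = 2.33 and re-fits all four surface
parameters:

```
$ python examples/02_fit_stoichiometry.py
generated 144 wells; truth n = 2.33
fitted n     = 2.467 +/- 0.098
fitted G_max = 985.0 AU (truth 1000.0)
fitted K_L   = 105.4 nM (truth 105.0)
goodness of fit r = 0.995 (Pearson, observed vs fitted)
```

The fitted n ≈ 2.5 ± 0.1 on this single dataset says each activated receptor
released more than two effector molecules; across many seeds the median
estimate centers on the generating 2.33. The other examples cover the
rate-constant → lumped-surface reduction (`01`), EC50 estimation from a dose
series (`03`), reversibility under a one-day ligand pulse (`04`: the
reporter peaks ~19 h *after* ligand removal, then decays to ~6% of peak),
and ΔΔCt qPCR analysis (`05`).

A thin CLI mirrors the pipeline stages (`chachakit generate-grid | fit-grid |
fit-dose | fit-dox | simulate | qpcr | demo`); `chachakit demo` runs the
packaged configuration end to end into a run directory with CSVs, fit JSONs
and a log.

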