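"""Hill dose-response fit: effective ligand concentration EC50.

Generates one synthetic ligand dose series (8 log-spaced doses over four
decades, 3 replicates, lognormal noise cv 0.10) from a 4PL truth curve with
EC50 = 105 nM, and fits bottom/top/EC50/hill_slope. The fitted EC50 is the
ligand concentration producing half-maximal reporter induction.
"""

import chachakit as ck

truth = ck.DoseResponseParams(bottom=0.0, top=1.0, EC50=105.0, hill_slope=1.0)
data = ck.generate_dose_response(truth, replicates=3,
                                 noise=ck.NoiseModel(cv_or_sd=0.10, seed=1))
fit = ck.fit_hill_dose_response(data)

ec50, se = fit.estimates["EC50"], fit.standard_errors["EC50"]
print(f"doses: {sorted(set(data['ligand_dose']))} nM")
print(f"fitted EC50       = {ec50:.1f} +/- {se:.1f} nM (truth {truth.EC50})")
print(f"fitted hill slope = {fit.estimates['hill_slope']:.2f} (truth 1)")
print(f"r = {fit.r:.3f}")
print("EC50 is the dose at half-maximal response; the standard error comes "
      "from the regression curvature at the optimum.")
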