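"""Parameter-recovery benchmark on the standard design.

Simulates replicates of the canonical censored benchmark (N=2000 cells,
K=10 markers, L=4 clusters, two covariate categories with proportions
(0.1, 0.2, 0.3, 0.4) and uniform), fits each with the stochastic-EM
censored-model fitter, and prints the per-category mean and SE of the
estimated proportions — alongside the covariate-blind Gaussian-mixture
baseline, which cannot attribute prevalence shifts to the covariate.

A few minutes at 10 replicates; the full benchmark uses 20+.
"""

import cytomix as cx

design = cx.benchmark_design()

res = cx.recovery_study(design, n_reps=10, method="lambda", seed=1)
print("covariate-dependent mixture (stochastic EM):")
print(res.table().round(3).to_string(index=False))

gmm = cx.recovery_study(design, n_reps=10, method="gmm", seed=1)
print("\ncovariate-blind Gaussian-mixture baseline:")
print(gmm.table().round(3).to_string(index=False))

print("\n'mean' close to 'true' with small 'se' means unbiased recovery;")
print("the baseline typically distorts the skewed category's larger clusters.")
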