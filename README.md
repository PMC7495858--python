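# cytomix

Covariate-dependent mixture-model clustering for flow and mass cytometry.

## The problem

Cytometry experiments ask two questions at once: *which cell populations are
present?* and *does their prevalence change with a clinical condition —
treatment arm, stimulation, time point, disease stage?*  The usual pipeline
answers them in two steps: cluster (or manually gate) first, then test the
cluster frequencies against the covariates.  The two-step route loses
information and propagates clustering mistakes into the association test.

`cytomix` fits both at once.  Cells are modelled as draws from a finite
mixture whose component ("cluster") parameters describe cell populations,
and whose mixing proportions depend on each cell's covariates through a
multinomial-logit link:

```
y_n | w_n = l  ~  N(mu_l, Sigma_l)
w_n | x_n      ~  Categorical(phi_n),    phi_n = softmax(x_n beta)
```

with conjugate priors `mu_l ~ N(0, Sigma_l / tau)` and
`Sigma_l^{-1} ~ Wishart(nu, Lambda)` regularising the cluster parameters.
The first column of `beta` is pinned at zero for identifiability; the
remaining columns are the log-odds effects of the covariates on cluster
membership — the quantity of scientific interest.

Two data regimes, two fitters:

* **Flow cytometry** (`fit_flow`): intensities are roughly Gaussian per
  population; the model is fit by a MAP EM algorithm with closed-form
  mean/covariance updates and a damped Newton ascent for `beta`.
* **Mass cytometry / CyTOF** (`fit_mass`): a large share of entries is
  exactly zero.  The model reads a zero as a latent Gaussian intensity
  `z <= 0` censored at the detection floor (`y = max(z, 0)`), and is fit by
  a stochastic EM: each iteration samples cluster labels from their
  posterior and refreshes censored latents by a Gibbs sweep of truncated-
  normal draws, then reuses the flow M-step on the imputed data.

Model selection uses BIC for the flow model and an SSE elbow scan for the
mass model (`scan_L`).

## Worked example

`examples/fit_mass_model.py` simulates two populations over two markers
(each population "on" in one marker, latent mean −1 in the other), censors
at zero, and fits the censored model:

```
46% of entries are zero (censored)
true cluster means (markers x clusters):
[[ 2. -1.]
 [-1.  2.]]
fitted cluster means:
[[ 1.98 -0.79]
 [-0.89  1.95]]
fitted category proportions:
[[0.26  0.74 ]
 [0.498 0.502]]
```

The "on" means (2.0) are recovered to ±0.05 although nearly half the matrix
is zeros; the "off" means (−1.0), identified only through the zero
fractions, are recovered more loosely.  The proportion rows say cluster 2
holds ~74% of category-1 cells versus ~50% of category-2 cells — the
covariate association estimated jointly with the clustering.  The other
examples cover the flow fitter, BIC selection, and the recovery benchmark.

A thin CLI mirrors the library (`cytomix fit / select / simulate`), reading
CSV/TSV or FCS expression matrices and writing TSV tables plus a JSON run
manifest.

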