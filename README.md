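# lsirt — latent space item response models

Binary test or questionnaire data are usually modeled under *conditional
independence* (CI): given a person's latent ability and the item's
parameters, responses are independent. Real data often violate this —
pairs of persons and items interact in ways the main effects cannot
explain (*conditional dependence*, CD). `lsirt` implements
multidimensional latent space item response models, which embed persons
and items in a shared Euclidean space and let their distances soak up
such interactions:

    logit P(y_pi = 1) = a_i θ_{p,d(i)} + β_i − γ ‖z_p − w_i‖

where θ_p holds D correlated abilities with between-item simple
structure (item i measures only factor d(i)), a_i > 0 and β_i are the
item discrimination and intercept, z_p and w_i are positions on a
K-dimensional interaction map, and the distance-tuning parameter γ ≥ 0
scales the distance penalty. Setting a_i ≡ 1, D = 1 and/or γ = 0 yields
the nested Rasch, unidimensional and conditionally independent variants
(MLSRM, ULS2PLM, ULSRM/LSIRM, MIRM).

The package is aimed at psychometricians and clinical researchers who
want to (1) estimate these models by Bayesian MCMC, (2) *test* whether CD
is substantial via a slab-and-spike prior on log γ (posterior inclusion
probability, PIP), (3) study how the detected amount of CD depends on
which main effects a model includes (its *relativity*), and (4) read
interaction maps: person–item distances, similarities exp(−γd), and
per-person symptom-profile analytics.

Everything runs on a hand-written adaptive Hamiltonian Monte Carlo
sampler with fully analytic gradients (including the LKJ/Cholesky
correlation transform); draws are Procrustes-aligned to the
highest-posterior configuration before any position summary. See
`docs/methods.md` for the model, priors, identification conventions, and
limitations.

## Worked example

Simulate data from the full model, fit it, test for CD, and profile a
respondent:

```python
from lsirt import (DGPConfig, ModelSpec, PriorConfig, compute_pip,
                   generate_parameters, generate_responses,
                   similarity_profile, summarize)
from lsirt.simulate import MCMCSettings, fit_model

cfg = DGPConfig(P=150, D=2, I_per_factor=5, gamma_true=1.0, seed=42)
truth = generate_parameters(cfg)
data = generate_responses(truth, ModelSpec.mls2plm(2), cfg.item_factor, seed=43)

spec = ModelSpec.mls2plm(2, prior=PriorConfig(gamma_prior_mode="slab_spike"))
draws, est, report = fit_model(data, spec,
                               MCMCSettings(n_chains=2, n_iter=1000), seed=44)
print(f"max R-hat (main parameters): {report.max_rhat:.3f}")
print(f"gamma-hat: {est.gamma:.3f}   PIP: {compute_pip(draws):.3f}")

summ = summarize(est, data.person_ids, data.item_ids)
print(similarity_profile(summ, "P1").head(3).to_string(index=False))
```

Output:

```
max R-hat (main parameters): 1.090
gamma-hat: 1.205   PIP: 0.978
item_id  similarity  distance
     I3    0.860062  0.125147
     I8    0.693823  0.303456
     I4    0.640891  0.369334
```

The chains mix (R̂ below the 1.1 cutoff), the distance-tuning estimate
1.21 is near its generating value 1.0, and PIP = 0.98 > 0.5 correctly
selects the slab — the data carry substantial conditional dependence.
The profile lists the items closest to person P1 on the interaction map:
similarity 0.86 to item I3 means P1's odds of endorsing I3 are 86% of
what a zero-distance configuration would give, the largest unexplained
affinity in their profile.

## Command line

`lsirt fit|simulate|recover|impact|relativity|map|profile --config c.yaml
--seed N --out dir/` run the same operations from a shell against wide
CSV response files (first column person id, cells 0/1/empty) plus an
`item_id,factor` map; every command echoes its config and is bitwise
reproducible from (config, seed, inputs).

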