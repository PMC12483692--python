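# Methods

## Model family

`lsirt` fits binary person × item response data with latent space item
response models. The full model (MLS2PLM) specifies

    logit P(y_pi = 1) = a_i θ_{p,d(i)} + β_i − γ ‖z_p − w_i‖

* θ_p ∈ R^D — latent abilities with between-item simple structure: item i
  loads only on its assigned factor d(i), so each item has a single
  discrimination a_i > 0 and intercept (easiness) β_i.
* z_p, w_i ∈ R^K — positions of persons and items in a shared Euclidean
  latent space (K = 2 by default, the planar convention of latent space
  models).
* γ ≥ 0 — the distance-tuning parameter. The distance term always lowers
  the logit: a person far from an item is less likely to answer it
  correctly (or endorse the symptom) than their ability alone predicts.
  γ = 0 recovers a conditionally independent multidimensional IRT model.

The distance effects quantify *conditional dependence* (CD): person–item
interaction left over after the main person and item effects. The
similarity exp(−γ·d) maps distances to (0, 1] and equals the
multiplicative change in the odds of success relative to a zero-distance
configuration.

Constraining a_i ≡ 1 gives the Rasch variants (MLSRM, ULSRM), collapsing
D to 1 the unidimensional variants (ULS2PLM, ULSRM), and dropping the
space the CI baseline (MIRM). All reductions share the likelihood of the
parent model at the constrained parameter values, which the test suite
verifies to 1e−12.

## Priors and identification

Defaults (all configurable through `PriorConfig`):

| parameter | prior | default | note |
|---|---|---|---|
| β_i | Normal(μ_β, σ_β) | (0, 2) | weakly informative on the logit scale |
| log a_i | Normal(μ_a, σ_a) | (0, 1) | positive discriminations only |
| θ_p | MVN(0, Σ_θ) | — | mean fixed at 0; Σ_θ a correlation matrix |
| Σ_θ | LKJ(s) | s = 1 | uniform over correlation matrices |
| z_p, w_i | MVN(0, I_K) | fixed | unit scale identifies γ; not configurable |
| log γ (lognormal mode) | Normal | (0.5, 1) | the convention of earlier latent space IRT work |
| log γ (slab-and-spike) | w·N(0.5, 1) + (1−w)·N(−3, 1) | — | slab / spike |
| w | Beta(a, b) | (1, 1) | slab proportion |

Identification: latent ability means are fixed at zero and Σ_θ has unit
diagonal in **every** variant, including the Rasch ones. Fixing the θ
scale in Rasch variants is deliberate: freeing per-factor scales lets the
Rasch model re-absorb the average discrimination, which empties the very
misfit the CD analysis is meant to expose — with free scales the Rasch
reduction no longer detects larger CD than the full model, reversing the
relativity pattern the family is designed to study. A free-scale mode
(`theta_scale_mode="free"`, half-normal(1) scale priors) remains
available for users who want a conventional Rasch scaling.

Position priors are standard normal and not configurable: their fixed
scale is what separates γ from an arbitrary rescaling of the space, and
Procrustes matching (below) removes the remaining rigid-motion freedom.

## Testing conditional dependence

Under the slab-and-spike mode the mixture over log γ is marginalized (no
discrete indicator is sampled). The posterior inclusion probability of
the slab is the Monte-Carlo average of

    w f_slab(log γ) / (w f_slab(log γ) + (1 − w) f_spike(log γ))

over retained draws, with both normal densities evaluated on the log-γ
scale so each component is proper on γ > 0. PIP > 0.5 selects the slab
(substantial CD); the spike (mean exp(−3) ≈ 0.05 on the γ scale)
effectively removes the distance term. Calibration at the generator's
default conditions: PIP < 0.5 on all of 10 no-CD replicates and
PIP > 0.5 on all of 10 strong-CD replicates (recomputed by
`scripts/acceptance.py`).

## Inference

Sampling is plain adaptive Hamiltonian Monte Carlo written against an
unconstrained reparameterization with fully analytic gradients:

* log transforms for a, γ and free θ scales; logit for the slab
  proportion; the canonical-partial-correlation (tanh/Cholesky) transform
  for Σ_θ with an exact forward-mode gradient recurrence over the
  D(D−1)/2 coordinates. All change-of-variables terms are included.
* Leapfrog integration with the number of steps jittered uniformly over
  the upper half of `max_leapfrog` (default 20) to break resonances
  without wasting gradient work on very short paths.
* Dual averaging of the step size toward a 0.8 acceptance rate; a
  diagonal mass matrix estimated from the 30–70% warmup window, after
  which step-size adaptation restarts under the new metric.
* Burn-in defaults to the first half of the iterations.
* Initialization is data-informed and jittered: intercepts at the logit
  of observed item means, abilities at standardized per-factor person
  scores, discriminations near 1, γ near 1. Starting γ inside the slab
  matters: shrinking into the spike is easy for the sampler, but escaping
  a collapsed-positions spike state is entropically hard. Non-finite
  starting densities trigger bounded re-initialization.

Convergence is judged by the split-chain potential scale reduction factor
(R̂) with a 1.1 cutoff (configurable). The pipeline gates on the main
model parameters (a, β, γ, w, Σ_θ): individual latent coordinates are
weakly identified at the chain lengths the desk-scale harnesses use and
enter every downstream summary only through distances; full per-scalar
R̂ tables remain available. Point estimates are posterior means (EAP),
with the mean correlation matrix projected back to the nearest valid
correlation matrix (eigenvalue clipping plus diagonal rescaling).

## Alignment

The likelihood is invariant to translations, rotations and reflections of
the latent positions, so raw draws of (Z, W) wander over rigid-motion
orbits. The draw with the highest log posterior density (ties broken in
chain-major order) provides the reference configuration; every other draw
is matched to it by the rigid motion minimizing squared discrepancy —
persons and items stacked and moved **jointly**, since separate
transforms would break person–item distances. The orthogonal factor comes
from the SVD closed form and may reflect; no scaling is applied (scale
belongs to γ). Matching is pooled across chains against one global
reference. Distances, similarities and the PIP are unchanged by
alignment to 1e−10 (tested).

## Synthetic data generator

`DGPConfig` emulates a fully specified generating process:
discriminations are I values evenly dividing [0.5, 2.0] assigned in item
order; difficulties evenly divide [−2, 2] and are randomly permuted;
abilities are equicorrelated MVN with unit variances and ρ = 0.3;
positions are standard normal in K = 2; γ = 1.0. Items are blocked:
the first I/D items load on factor 1, and so on.

What the generator does **not** emulate: missing responses (the reader
supports them; the generator produces complete matrices), guessing or
slipping asymptotes, cross-loadings, clustered or otherwise structured
latent positions, and local dependence mechanisms other than the distance
effect. Passing recovery tests therefore demonstrate internal consistency
of model + sampler under the model's own assumptions, not robustness to
real-data violations of them.

## Recovery metrics and study harnesses

Per replication and parameter block: MSE = mean squared error, bias =
mean **absolute** difference (so MSE ≥ bias² need not hold), SE = the
standard deviation of the errors. Aggregation is over items (a, β),
persons × factors (θ), persons or items × the K dimensions (Z, W), and
matrix elements (Σ_θ). Estimated positions are Procrustes-matched to the
**true** configuration before comparison — without this, rigid-motion
indeterminacy contaminates position errors. Study harnesses exclude (and
count) replicates whose gated R̂ reaches the cutoff rather than re-running
them.

Desk-scale problem sizes used by the shipped studies and
`scripts/acceptance.py` (chosen once as the package's default study
conditions): recovery at P = 200, D = 2, five items per factor, 10
replications; relativity and impact at P = 250, D = 2, ten items per
factor, 10 replications; CD-detection calibration at P = 120. Two chains
of 600–1000 iterations, half discarded. The full factorial at
publication-scale replication counts is exposed through the same
functions and a YAML grid.

## Known limitations

* The impact comparison (full model vs MIRM on data with CD) does not
  show a consistent full-model advantage at the default generator
  conditions and desk-scale sizes: with γ = 1 the CI model's
  omitted-distance attenuation on discriminations is ≈ 0.10 —
  smaller than the posterior noise of either model below a few thousand
  persons — while the full model carries extra variance from the
  a ↔ γ·distance trade-off. The harness reports the honest win
  fractions; expect them near 50% at these sizes.
* Plain HMC with a diagonal metric mixes slowly along the global
  β ↔ γ·(mean distance) and a ↔ γ ridges for P ≳ 500; chain lengths well
  beyond the desk-scale defaults are needed there (a converged P = 800
  fit took ~4000 iterations during development).
* Model selection for K, WAIC/LOO comparisons, polytomous responses,
  response times, probit links and non-Euclidean distances are out of
  scope.
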