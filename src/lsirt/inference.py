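"""Posterior sampling, convergence diagnostics, point estimation, and the
slab-and-spike posterior inclusion probability.

The sampler targets the unconstrained posterior of
:class:`~lsirt.model.ModelSpec` models via Hamiltonian Monte Carlo and
stores draws per chain.  Convergence is judged by the split-chain
potential scale reduction factor (R-hat); point estimates are posterior
means (EAP), with latent positions averaged only after Procrustes
alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._posterior import UnconstrainedPosterior
from .data import ItemResponseData
from .hmc import HMCOptions, hmc_chain
from .model import ModelSpec, ParameterState, PriorConfig, log_posterior

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorDraws",
    "ConvergenceReport",
    "run_mcmc",
    "rhat",
    "rhat_report",
    "point_estimates",
    "compute_pip",
]


@dataclass
class PosteriorDraws:
    """Retained posterior draws: chains x iterations of every parameter.

    ``params`` maps a parameter name to an array whose two leading axes are
    (chain, iteration); e.g. ``params["theta"]`` has shape (C, T, P, D).
    ``log_post`` holds the constrained-scale log posterior density of each
    draw (used to pick the Procrustes reference configuration).
    """

    params: dict
    log_post: np.ndarray  # (C, T)
    spec: ModelSpec
    data: ItemResponseData
    seed: int
    aligned: bool = False
    accept_rate: tuple = ()
    item_factor: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.item_factor is None:
            self.item_factor = self.data.item_factor

    @property
    def n_chains(self) -> int:
        return self.log_post.shape[0]

    @property
    def n_draws(self) -> int:
        return self.log_post.shape[1]

    def state_at(self, chain: int, iteration: int) -> ParameterState:
        p = self.params
        kw = dict(
            theta=p["theta"][chain, iteration],
            a=p["a"][chain, iteration],
            beta=p["beta"][chain, iteration],
            Z=p["Z"][chain, iteration],
            W=p["W"][chain, iteration],
            gamma=float(p["gamma"][chain, iteration]),
            theta_corr=p["theta_corr"][chain, iteration],
            theta_scale=p["theta_scale"][chain, iteration],
        )
        if "mix_w" in p:
            kw["mix_w"] = float(p["mix_w"][chain, iteration])
        return ParameterState(**kw)

    def iter_states(self):
        for c in range(self.n_chains):
            for t in range(self.n_draws):
                yield c, t, self.state_at(c, t)

    def scalar_columns(self) -> dict:
        """Flatten every parameter to named scalar chains, (C, T) each."""
        cols = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                cols[name] = arr
                continue
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            tail = arr.shape[2:]
            for j in range(flat.shape[2]):
                idx = np.unravel_index(j, tail)
                cols[name + "[" + ",".join(str(k) for k in idx) + "]"] = flat[:, :, j]
        return cols

    def to_frame(self):
        """One row per chain x iteration, one column per scalar, plus log_post."""
        import pandas as pd

        cols = self.scalar_columns()
        C, T = self.log_post.shape
        out = {"chain": np.repeat(np.arange(C), T), "iteration": np.tile(np.arange(T), C)}
        for name, arr in cols.items():
            out[name] = arr.reshape(-1)
        out["log_post"] = self.log_post.reshape(-1)
        return pd.DataFrame(out)


@dataclass(frozen=True)
class ConvergenceReport:
    rhat: dict        # scalar parameter name -> split R-hat
    max_rhat: float
    cutoff: float

    @property
    def passed(self) -> bool:
        return self.max_rhat < self.cutoff


# ---------------------------------------------------------------------------


def run_mcmc(data: ItemResponseData, spec: ModelSpec, n_chains: int = 3,
             n_iter: int = 2000, burn_in: int = None, seed: int = 0,
             options: HMCOptions = HMCOptions(), max_init_retries: int = 20,
             ) -> PosteriorDraws:
    """Sample the joint posterior with HMC.

    ``burn_in`` defaults to the first half of ``n_iter``.  Chains are
    seeded independently from ``seed``; rerunning with identical inputs
    reproduces the draws bitwise.  A non-finite log posterior at the start
    triggers re-initialization up to ``max_init_retries`` times.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if burn_in is None:
        burn_in = n_iter // 2
    if not 0 <= burn_in < n_iter:
        raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")

    post = UnconstrainedPosterior(data, spec)
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains, logps, rates = [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        x0 = None
        for attempt in range(max_init_retries):
            cand = post.initial_vector(rng)
            if np.isfinite(post.value(cand)):
                x0 = cand
                break
        if x0 is None:
            raise FloatingPointError(
                f"could not find a finite initial point for chain {c} "
                f"after {max_init_retries} attempts")
        draws, lp, rate = hmc_chain(post.value_and_grad, x0, n_iter, burn_in, rng, options)
        chains.append(draws)
        logps.append(lp)
        rates.append(rate)
        logger.info("chain %d: acceptance %.2f", c, rate)

    T = n_iter - burn_in
    # unpack to parameter blocks
    proto = post.unpack(chains[0][0])
    names = ["theta", "a", "beta", "Z", "W", "gamma", "theta_corr", "theta_scale"]
    if proto.mix_w is not None:
        names.append("mix_w")
    params = {}
    for name in names:
        val = getattr(proto, name)
        shape = np.shape(val)
        params[name] = np.empty((n_chains, T) + shape)
    log_post = np.empty((n_chains, T))
    for c in range(n_chains):
        for t in range(T):
            st = post.unpack(chains[c][t])
            for name in names:
                params[name][c, t] = getattr(st, name)
            log_post[c, t] = log_posterior(st, data, spec)
    return PosteriorDraws(params=params, log_post=log_post, spec=spec, data=data,
                          seed=seed, aligned=not spec.latent_space,
                          accept_rate=tuple(rates))


# ---------------------------------------------------------------------------


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of one scalar parameter.

    ``draws`` has shape (chains, iterations).  Each chain is split in half,
    so mixing failures within a chain are detected as well.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("expected a (chains, iterations) array")
    C, T = draws.shape
    if C < 2:
        raise ValueError("R-hat needs at least 2 chains (split-chain fallback "
                         "for a single chain is not applied)")
    if T < 4:
        raise ValueError("R-hat needs at least 4 retained iterations")
    half = T // 2
    split = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W <= 1e-300:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def rhat_report(draws: PosteriorDraws, cutoff: float = 1.1,
                include: tuple = None) -> ConvergenceReport:
    """Split R-hat for every scalar parameter of a fit.

    With a latent space, positions should be aligned first; their chains
    are otherwise rigid-motion multimodal by construction.
    """
    cols = draws.scalar_columns()
    if include is not None:
        cols = {k: v for k, v in cols.items() if any(k.startswith(p) for p in include)}
    values = {}
    for name, arr in cols.items():
        if np.ptp(arr) < 1e-12:  # constants (e.g. fixed unit scales)
            continue
        values[name] = rhat(arr)
    max_rhat = max(values.values()) if values else 1.0
    return ConvergenceReport(rhat=values, max_rhat=max_rhat, cutoff=cutoff)


# ---------------------------------------------------------------------------


def _nearest_correlation(M: np.ndarray) -> np.ndarray:
    """Symmetrize, clip eigenvalues away from zero, rescale to unit diagonal."""
    R = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() <= 1e-10:
        vals = np.clip(vals, 1e-10, None)
        R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def point_estimates(draws: PosteriorDraws) -> ParameterState:
    """Posterior-mean (EAP) point estimates.

    Latent positions are averaged only after Procrustes alignment; the
    mean correlation matrix is projected back to the nearest valid
    correlation matrix.
    """
    if draws.spec.latent_space and not draws.aligned:
        raise RuntimeError("latent positions are unaligned; run "
                           "lsirt.alignment.align_all before point_estimates")
    p = draws.params
    mean = {k: v.mean(axis=(0, 1)) for k, v in p.items()}
    kw = dict(
        theta=mean["theta"], a=mean["a"], beta=mean["beta"],
        Z=mean["Z"], W=mean["W"], gamma=float(mean["gamma"]),
        theta_corr=_nearest_correlation(mean["theta_corr"]),
        theta_scale=mean["theta_scale"],
    )
    if "mix_w" in mean:
        kw["mix_w"] = float(mean["mix_w"])
    return ParameterState(**kw)


# ---------------------------------------------------------------------------


def compute_pip(draws: PosteriorDraws, prior: PriorConfig = None) -> float:
    """Posterior inclusion probability of the slab component.

    Averages, over retained draws, the conditional probability that
    log(gamma) came from the slab rather than the spike:

        w f_slab(log g) / (w f_slab(log g) + (1 - w) f_spike(log g))

    with both densities evaluated on the log-gamma scale.  PIP > 0.5
    signals substantial conditional dependence (the slab is selected).
    """
    prior = prior or draws.spec.prior
    if prior.gamma_prior_mode != "slab_spike":
        raise ValueError("PIP is defined only under the slab_spike prior mode")
    if "mix_w" not in draws.params:
        raise ValueError("draws carry no mixing proportion; refit with slab_spike prior")
    lg = np.log(np.maximum(draws.params["gamma"], 1e-300)).reshape(-1)
    w = np.asarray(draws.params["mix_w"], dtype=float).reshape(-1)
    log_slab = np.log(np.clip(w, 1e-300, None)) + norm.logpdf(lg, prior.slab_mean, prior.slab_sd)
    log_spike = np.log(np.clip(1 - w, 1e-300, None)) + norm.logpdf(lg, prior.spike_mean, prior.spike_sd)
    denom = np.logaddexp(log_slab, log_spike)
    return float(np.exp(log_slab - denom).mean())
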