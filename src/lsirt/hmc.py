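"""Adaptive Hamiltonian Monte Carlo.

A compact HMC implementation used as the default sampler backend: leapfrog
integration with a jittered number of steps (breaking resonances), dual
averaging of the step size toward a target acceptance rate during warmup,
and a diagonal mass matrix estimated from a mid-warmup window.  The
interface is a plain ``logp_and_grad`` callable, so any other
gradient-based sampler satisfying the stationarity contract can be swapped
in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCOptions", "hmc_chain"]


@dataclass(frozen=True)
class HMCOptions:
    target_accept: float = 0.8
    max_leapfrog: int = 20
    init_step_size: float = 0.1
    max_energy_error: float = 1000.0


def _leapfrog(logp_and_grad, x, p, grad, step, n_steps, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * step * grad
        for s in range(n_steps):
            x = x + step * inv_mass * p
            val, grad = logp_and_grad(x)
            if not np.isfinite(val):
                return x, p, -np.inf, grad
            p = p + (step if s < n_steps - 1 else 0.5 * step) * grad
    return x, p, val, grad


def hmc_chain(logp_and_grad, x0, n_iter, warmup, rng, options: HMCOptions = HMCOptions()):
    """Run one HMC chain; returns (draws after warmup, logp values, accept rate).

    ``draws`` has shape (n_iter - warmup, dim); ``logp`` holds the target
    value at each retained draw.
    """
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    val, grad = logp_and_grad(x)
    if not np.isfinite(val):
        raise FloatingPointError("non-finite log density at the initial point")

    inv_mass = np.ones(dim)
    sqrt_mass = np.ones(dim)
    step = _find_initial_step(logp_and_grad, x, val, grad, inv_mass, rng,
                              options.init_step_size)
    # dual averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * step)
    log_step_bar, h_bar = 0.0, 0.0
    da_gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-matrix estimation window inside warmup; dual averaging restarts after it
    w_lo, w_hi = int(0.3 * warmup), int(0.7 * warmup)
    window = []
    da_iter = 0

    kept = np.empty((n_iter - warmup, dim))
    kept_logp = np.empty(n_iter - warmup)
    n_accept = 0

    for it in range(n_iter):
        p0 = rng.normal(size=dim) * sqrt_mass
        h0 = val - 0.5 * float(inv_mass @ (p0 * p0))
        # jitter trajectory length over the upper half to break resonances
        # without wasting gradient work on very short paths
        lo = max(1, options.max_leapfrog // 2)
        n_steps = int(rng.integers(lo, options.max_leapfrog + 1))
        x1, p1, val1, grad1 = _leapfrog(logp_and_grad, x, p0, grad, step, n_steps, inv_mass)
        if np.isfinite(val1) and np.isfinite(p1).all():
            with np.errstate(over="ignore"):
                h1 = val1 - 0.5 * float(inv_mass @ (p1 * p1))
            energy_err = h1 - h0 if np.isfinite(h1) else -np.inf
        else:
            energy_err = -np.inf
        accept_prob = min(1.0, np.exp(min(energy_err, 0.0))) if np.isfinite(energy_err) else 0.0
        if energy_err < -options.max_energy_error:
            accept_prob = 0.0
        if rng.random() < accept_prob:
            x, val, grad = x1, val1, grad1
            if it >= warmup:
                n_accept += 1

        if it < warmup:
            # dual averaging toward the target acceptance rate
            da_iter += 1
            h_bar = ((1 - 1 / (da_iter + t0)) * h_bar
                     + (options.target_accept - accept_prob) / (da_iter + t0))
            log_step = mu - np.sqrt(da_iter) / da_gamma * h_bar
            eta = da_iter ** (-kappa)
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if w_lo <= it < w_hi:
                window.append(x.copy())
            if it == w_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                var = np.clip(var, 1e-6, None)
                inv_mass = var
                sqrt_mass = 1.0 / np.sqrt(var)
                # restart step-size adaptation under the new metric
                step = _find_initial_step(logp_and_grad, x, val, grad, inv_mass, rng, step)
                mu = np.log(10.0 * step)
                log_step_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == warmup - 1:
                step = float(np.exp(log_step_bar))
        else:
            kept[it - warmup] = x
            kept_logp[it - warmup] = val

    return kept, kept_logp, n_accept / max(n_iter - warmup, 1)


def _find_initial_step(logp_and_grad, x, val, grad, inv_mass, rng, step):
    """Crude doubling/halving search for a step size with ~50% acceptance."""
    sqrt_mass = 1.0 / np.sqrt(inv_mass)
    p0 = rng.normal(size=x.size) * sqrt_mass
    h0 = val - 0.5 * float(inv_mass @ (p0 * p0))

    def energy_err(s):
        x1, p1, v1, _ = _leapfrog(logp_and_grad, x, p0, grad, s, 1, inv_mass)
        if not np.isfinite(v1):
            return -np.inf
        return (v1 - 0.5 * float(inv_mass @ (p1 * p1))) - h0

    err = energy_err(step)
    direction = 1 if err > np.log(0.5) else -1
    for _ in range(50):
        candidate = step * (2.0 ** direction)
        err = energy_err(candidate)
        if (direction == 1 and err <= np.log(0.5)) or (direction == -1 and err >= np.log(0.5)):
            break
        step = candidate
    return step
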