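"""Unconstrained log-posterior with analytic gradients.

The sampler works on a flat real vector.  Positivity constraints are
handled by log transforms (discriminations, gamma, ability scales), the
mixing proportion by a logit transform, and the ability correlation matrix
by the canonical-partial-correlation Cholesky transform (tanh of
unconstrained coordinates, rows filling a lower-triangular factor of unit
row norm).  All change-of-variables terms are included, so the target
density is the posterior pushed forward to the unconstrained space, and
every gradient is exact (the correlation block uses a forward-mode
recurrence over at most D(D-1)/2 coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import betaln, expit, log_expit, logit

from .data import ItemResponseData
from .model import LOG_2PI, ModelSpec, ParameterState

_T_FLOOR = 1e-12


def _chol_corr_forward(y: np.ndarray, D: int):
    """Map unconstrained y (length D(D-1)/2) to a correlation Cholesky factor.

    Returns ``L`` (D, D) lower triangular with unit row norms, the
    derivative tensor ``dL`` with ``dL[i, j, m] = dL[i,j]/dy[m]``, the
    log-Jacobian of the map and its gradient with respect to y.
    """
    m = D * (D - 1) // 2
    L = np.zeros((D, D))
    L[0, 0] = 1.0
    dL = np.zeros((D, D, m))
    logJ = 0.0
    dlogJ = np.zeros(m)
    z = np.clip(np.tanh(y), -1.0 + _T_FLOOR, 1.0 - _T_FLOOR)
    pos = 0
    for i in range(1, D):
        idx = np.arange(pos, pos + i)  # this row's coordinates
        zr = z[idx]
        dzdy = 1.0 - zr ** 2
        t = 1.0
        dt = np.zeros(i)  # d t / d y[row coords]
        for j in range(i):
            c = np.sqrt(max(t, _T_FLOOR))
            dc = dt / (2.0 * c)
            L[i, j] = zr[j] * c
            g = zr[j] * dc
            g[j] += c * dzdy[j]
            dL[i, j, idx] = g
            # |dL_ij/dz_ij| = c, |dz/dy| = 1 - z^2
            logJ += np.log(c) + np.log1p(-zr[j] ** 2)
            dlogJ[idx] += dc / c
            dlogJ[idx[j]] += -2.0 * zr[j]
            t = t - L[i, j] ** 2
            dt = dt - 2.0 * L[i, j] * dL[i, j, idx]
        c = np.sqrt(max(t, _T_FLOOR))
        L[i, i] = c
        dL[i, i, idx] = dt / (2.0 * c)
        pos += i
    return L, dL, logJ, dlogJ


def _chol_corr_inverse(corr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_chol_corr_forward` (correlation matrix -> y)."""
    D = corr.shape[0]
    L = np.linalg.cholesky(corr)
    y = []
    for i in range(1, D):
        t = 1.0
        for j in range(i):
            zij = L[i, j] / np.sqrt(max(t, _T_FLOOR))
            y.append(np.arctanh(np.clip(zij, -1 + 1e-12, 1 - 1e-12)))
            t -= L[i, j] ** 2
    return np.asarray(y)


@dataclass
class _Layout:
    slices: dict
    size: int


class UnconstrainedPosterior:
    """Flat-vector view of the model posterior for gradient-based MCMC."""

    def __init__(self, data: ItemResponseData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        P, I, D, K = data.n_persons, data.n_items, spec.D, spec.K
        self.P, self.I, self.D, self.K = P, I, D, K
        self._d0 = data.factor_index0
        self._mask = data.mask
        self._all_observed = bool(self._mask.all())
        self._maskf = self._mask.astype(float)
        self._y = np.where(self._mask, data.responses, 0.0)
        self._sign = 2.0 * self._y - 1.0  # +1 where y=1, -1 elsewhere
        # item -> factor one-hot (I, D) for the theta gradient
        self._onehot = np.zeros((I, D))
        self._onehot[np.arange(I), self._d0] = 1.0
        self._tril_mask = np.tril(np.ones((D, D)))

        sl, pos = {}, 0

        def add(name, n):
            nonlocal pos
            sl[name] = slice(pos, pos + n)
            pos += n

        add("theta", P * D)
        add("beta", I)
        if spec.discrimination_free:
            add("log_a", I)
        if spec.latent_space:
            add("Z", P * K)
            add("W", I * K)
            add("log_gamma", 1)
            if spec.prior.gamma_prior_mode == "slab_spike":
                add("logit_w", 1)
        if D > 1:
            add("corr_y", D * (D - 1) // 2)
        if spec.prior.theta_scale_mode == "free":
            add("log_sigma", D)
        self.layout = _Layout(sl, pos)

    @property
    def size(self) -> int:
        return self.layout.size

    # ------------------------------------------------------------------
    def pack(self, state: ParameterState) -> np.ndarray:
        sl = self.layout.slices
        x = np.zeros(self.size)
        x[sl["theta"]] = state.theta.ravel()
        x[sl["beta"]] = state.beta
        if "log_a" in sl:
            x[sl["log_a"]] = np.log(state.a)
        if "Z" in sl:
            x[sl["Z"]] = state.Z.ravel()
            x[sl["W"]] = state.W.ravel()
            x[sl["log_gamma"]] = np.log(max(state.gamma, 1e-300))
            if "logit_w" in sl:
                w = 0.5 if state.mix_w is None else state.mix_w
                x[sl["logit_w"]] = logit(np.clip(w, 1e-12, 1 - 1e-12))
        if "corr_y" in sl:
            x[sl["corr_y"]] = _chol_corr_inverse(state.theta_corr)
        if "log_sigma" in sl:
            x[sl["log_sigma"]] = np.log(state.theta_scale)
        return x

    def unpack(self, x: np.ndarray) -> ParameterState:
        sl = self.layout.slices
        P, I, D, K = self.P, self.I, self.D, self.K
        theta = x[sl["theta"]].reshape(P, D)
        beta = x[sl["beta"]].copy()
        a = np.exp(x[sl["log_a"]]) if "log_a" in sl else np.ones(I)
        if "Z" in sl:
            Z = x[sl["Z"]].reshape(P, K)
            W = x[sl["W"]].reshape(I, K)
            gamma = float(np.exp(x[sl["log_gamma"]][0]))
            mix_w = float(expit(x[sl["logit_w"]][0])) if "logit_w" in sl else None
        else:
            Z, W = np.zeros((P, K)), np.zeros((I, K))
            gamma, mix_w = 0.0, None
        if "corr_y" in sl:
            L, _, _, _ = _chol_corr_forward(x[sl["corr_y"]], D)
            corr = L @ L.T
            corr = 0.5 * (corr + corr.T)
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.eye(D)
        scale = np.exp(x[sl["log_sigma"]]) if "log_sigma" in sl else np.ones(D)
        return ParameterState(theta=theta, a=a, beta=beta, Z=Z, W=W, gamma=gamma,
                              theta_corr=corr, theta_scale=scale, mix_w=mix_w)

    # ------------------------------------------------------------------
    def initial_vector(self, rng: np.random.Generator, jitter: float = 0.25) -> np.ndarray:
        """Data-informed, jittered starting point.

        Intercepts start at the logit of the observed item means, abilities
        at standardized per-factor person scores, discriminations at 1 and
        gamma small; everything is jittered so chains start apart.  This
        keeps warmup away from the degenerate large-discrimination /
        flat-ability basin that random prior draws can fall into.
        """
        sl = self.layout.slices
        x = rng.normal(scale=jitter, size=self.size)
        with np.errstate(invalid="ignore"):
            item_mean = np.clip(np.nansum(self._y, axis=0)
                                / np.maximum(self._mask.sum(axis=0), 1), 0.02, 0.98)
        x[sl["beta"]] += logit(item_mean)
        # crude ability scores: mean response on the factor's items, standardized
        scores = np.empty((self.P, self.D))
        for d in range(self.D):
            items = np.flatnonzero(self._d0 == d)
            cnt = np.maximum(self._mask[:, items].sum(axis=1), 1)
            s = self._y[:, items].sum(axis=1) / cnt
            sd = s.std()
            scores[:, d] = (s - s.mean()) / (sd if sd > 1e-8 else 1.0)
        x[sl["theta"]] += scores.ravel()
        if "log_a" in sl:
            x[sl["log_a"]] = rng.normal(0.0, 0.1, self.I)
        if "Z" in sl:
            # start inside the slab basin (gamma near 1): shrinking toward the
            # spike is easy for the sampler, escaping the collapsed-positions
            # spike basin upward is not
            x[sl["log_gamma"]] = rng.normal(0.0, 0.2)
        if "corr_y" in sl:
            x[sl["corr_y"]] = rng.normal(scale=0.1, size=sl["corr_y"].stop - sl["corr_y"].start)
        if "log_sigma" in sl:
            x[sl["log_sigma"]] = rng.normal(scale=0.1, size=self.D)
        return x

    # ------------------------------------------------------------------
    def value_and_grad(self, x: np.ndarray):
        """Log target density and its exact gradient at ``x``.

        Returns ``(-inf, garbage)`` semantics only through non-finite
        values, which the sampler rejects; overflow during exploratory
        leapfrog steps is therefore silenced here.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._value_and_grad(x)

    def _value_and_grad(self, x: np.ndarray):
        sl = self.layout.slices
        spec, pc = self.spec, self.spec.prior
        P, I, D, K = self.P, self.I, self.D, self.K
        g = np.zeros_like(x)

        theta = x[sl["theta"]].reshape(P, D)
        beta = x[sl["beta"]]
        if "log_a" in sl:
            log_a = x[sl["log_a"]]
            a = np.exp(log_a)
        else:
            a = np.ones(I)
        latent = "Z" in sl
        if latent:
            Z = x[sl["Z"]].reshape(P, K)
            W = x[sl["W"]].reshape(I, K)
            log_gamma = x[sl["log_gamma"]][0]
            gamma = np.exp(log_gamma)

        # ----- likelihood ------------------------------------------------
        theta_cell = theta[:, self._d0]                       # (P, I)
        eta = a[None, :] * theta_cell + beta[None, :]
        if latent:
            diff = Z[:, None, :] - W[None, :, :]              # (P, I, K)
            dist = np.sqrt(np.einsum("pik,pik->pi", diff, diff))
            eta = eta - gamma * dist
        cell = log_expit(self._sign * eta)
        p = expit(eta)
        if self._all_observed:
            val = float(cell.sum())
            r = self._y - p                                   # dloglik/deta
        else:
            val = float((cell * self._maskf).sum())
            r = (self._y - p) * self._maskf

        g[sl["beta"]] += r.sum(axis=0)
        grad_theta = r @ (self._onehot * a[:, None])          # (P, D)
        if "log_a" in sl:
            g[sl["log_a"]] += np.einsum("pi,pi->i", r, theta_cell) * a
        if latent:
            # unit vectors (z_p - w_i)/d_pi; coincident points get 0 (subgradient)
            rd = r / np.maximum(dist, 1e-12)
            g[sl["Z"]] += (-gamma * np.einsum("pi,pik->pk", rd, diff)).ravel()
            g[sl["W"]] += (gamma * np.einsum("pi,pik->ik", rd, diff)).ravel()
            g[sl["log_gamma"]] += -gamma * float(np.einsum("pi,pi->", r, dist))

        # ----- ability prior (MVN through scaled correlation Cholesky) ---
        if "corr_y" in sl:
            y_corr = x[sl["corr_y"]]
            L_R, dL, logJ, dlogJ = _chol_corr_forward(y_corr, D)
        else:
            L_R = np.eye(D)
        if "log_sigma" in sl:
            log_sigma = x[sl["log_sigma"]]
            sigma = np.exp(log_sigma)
        else:
            sigma = np.ones(D)
        L_full = sigma[:, None] * L_R
        diagL = np.diagonal(L_full)
        if not np.isfinite(L_full).all() or (diagL <= 0).any():
            return -np.inf, g  # overflowed exploration step; sampler rejects
        # small D: explicit triangular inverse beats LAPACK call overhead
        L_inv = solve_triangular(L_full, np.eye(D), lower=True) if D > 1 else 1.0 / L_full
        U = L_inv @ theta.T                                    # (D, P)
        val += (-0.5 * P * D * LOG_2PI - P * np.log(diagL).sum() - 0.5 * float((U * U).sum()))
        V = L_inv.T @ U                                        # Sigma^{-1} theta^T
        grad_theta += -V.T
        G_L = ((V @ V.T) @ L_full) * self._tril_mask           # d/dL of -0.5 tr(Sigma^{-1} S)
        G_L[np.diag_indices(D)] -= P / diagL

        if "corr_y" in sl:
            # LKJ density over the Cholesky factor + transform Jacobian
            eta_s = pc.lkj_shape
            coef = np.array([D - k + 2.0 * eta_s - 3.0 for k in range(D)])
            dr = np.diag(L_R)
            val += float((coef[1:] * np.log(dr[1:])).sum()) + logJ
            G_LR = G_L * sigma[:, None]
            G_LR[np.diag_indices(D)] += np.where(np.arange(D) > 0, coef / dr, 0.0)
            g[sl["corr_y"]] += np.einsum("ij,ijm->m", G_LR, dL) + dlogJ
        if "log_sigma" in sl:
            g[sl["log_sigma"]] += (G_L * L_full).sum(axis=1)
            s = pc.theta_scale_sd
            val += float((0.5 * np.log(2.0 / np.pi) - np.log(s)
                          - 0.5 * (sigma / s) ** 2 + log_sigma).sum())
            g[sl["log_sigma"]] += 1.0 - (sigma / s) ** 2
        g[sl["theta"]] += grad_theta.ravel()

        # ----- item parameter priors -------------------------------------
        val += float((-0.5 * LOG_2PI - np.log(pc.beta_sd)
                      - 0.5 * ((beta - pc.beta_mean) / pc.beta_sd) ** 2).sum())
        g[sl["beta"]] += -(beta - pc.beta_mean) / pc.beta_sd ** 2
        if "log_a" in sl:
            val += float((-0.5 * LOG_2PI - np.log(pc.log_a_sd)
                          - 0.5 * ((log_a - pc.log_a_mean) / pc.log_a_sd) ** 2).sum())
            g[sl["log_a"]] += -(log_a - pc.log_a_mean) / pc.log_a_sd ** 2

        # ----- latent positions and gamma --------------------------------
        if latent:
            val += float(-0.5 * (P + I) * K * LOG_2PI - 0.5 * (Z ** 2).sum() - 0.5 * (W ** 2).sum())
            g[sl["Z"]] += -Z.ravel()
            g[sl["W"]] += -W.ravel()
            if pc.gamma_prior_mode == "lognormal":
                val += float(-0.5 * LOG_2PI - np.log(pc.log_gamma_sd)
                             - 0.5 * ((log_gamma - pc.log_gamma_mean) / pc.log_gamma_sd) ** 2)
                g[sl["log_gamma"]] += -(log_gamma - pc.log_gamma_mean) / pc.log_gamma_sd ** 2
            else:
                v_w = x[sl["logit_w"]][0]
                w = expit(v_w)
                ls = (-0.5 * LOG_2PI - np.log(pc.slab_sd)
                      - 0.5 * ((log_gamma - pc.slab_mean) / pc.slab_sd) ** 2)
                lsp = (-0.5 * LOG_2PI - np.log(pc.spike_sd)
                       - 0.5 * ((log_gamma - pc.spike_mean) / pc.spike_sd) ** 2)
                lmix = np.logaddexp(np.log(w) + ls, np.log1p(-w) + lsp)
                val += float(lmix)
                r_slab = np.exp(np.log(w) + ls - lmix)
                g[sl["log_gamma"]] += (r_slab * (-(log_gamma - pc.slab_mean) / pc.slab_sd ** 2)
                                       + (1 - r_slab) * (-(log_gamma - pc.spike_mean) / pc.spike_sd ** 2))
                g[sl["logit_w"]] += r_slab - w
                # Beta prior on w plus the logit Jacobian
                val += float(pc.mix_beta_a * np.log(w) + pc.mix_beta_b * np.log1p(-w)
                             - betaln(pc.mix_beta_a, pc.mix_beta_b))
                g[sl["logit_w"]] += pc.mix_beta_a * (1 - w) - pc.mix_beta_b * w

        return val, g

    def value(self, x: np.ndarray) -> float:
        return self.value_and_grad(x)[0]
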