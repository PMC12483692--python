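"""Model family: latent space item response models and their nested reductions.

The full model (MLS2PLM) puts the logit of a correct/endorsed response at

    logit P(y_pi = 1) = a_i * theta_{p, d(i)} + beta_i - gamma * ||z_p - w_i||

where theta_p is a D-vector of abilities (between-item simple structure:
item i loads only on factor d(i)), a_i > 0 a discrimination, beta_i an
intercept (easiness), and z_p, w_i positions of person p and item i in a
shared K-dimensional Euclidean latent space.  The nonnegative distance
tuning parameter gamma scales the distance effect; gamma = 0 recovers a
conditionally independent multidimensional IRT model (MIRM).

Constrained reductions (fixing a_i = 1 and/or D = 1) give the MLSRM,
ULS2PLM and ULSRM (= LSIRM) variants; see :func:`reduce_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, log_expit
from scipy.spatial.distance import cdist

from .data import DimensionError, ItemResponseData

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "ParameterState",
    "euclidean_distance",
    "person_item_distances",
    "similarity",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "reduce_model",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters.

    Latent positions are not configurable: rows of Z and W are standard
    normal (mean 0, sd 1) per the identifiability convention.  The
    distance-tuning parameter gamma gets either a lognormal prior or a
    slab-and-spike mixture of normals on log(gamma); the spike concentrates
    near gamma = 0 (no conditional dependence) and the slab is diffuse.
    """

    beta_mean: float = 0.0
    beta_sd: float = 2.0
    log_a_mean: float = 0.0
    log_a_sd: float = 1.0
    lkj_shape: float = 1.0
    theta_scale_mode: str = "fixed_unit"  # or "free"
    theta_scale_sd: float = 1.0  # half-normal scale when free
    gamma_prior_mode: str = "lognormal"  # or "slab_spike"
    log_gamma_mean: float = 0.5
    log_gamma_sd: float = 1.0
    spike_mean: float = -3.0
    spike_sd: float = 1.0
    slab_mean: float = 0.5
    slab_sd: float = 1.0
    mix_beta_a: float = 1.0
    mix_beta_b: float = 1.0

    def __post_init__(self):
        for name in ("beta_sd", "log_a_sd", "lkj_shape", "theta_scale_sd",
                     "log_gamma_sd", "spike_sd", "slab_sd", "mix_beta_a", "mix_beta_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.theta_scale_mode not in ("fixed_unit", "free"):
            raise ValueError(f"unknown theta_scale_mode {self.theta_scale_mode!r}")
        if self.gamma_prior_mode not in ("lognormal", "slab_spike"):
            raise ValueError(f"unknown gamma_prior_mode {self.gamma_prior_mode!r}")
        if self.spike_sd > self.slab_sd:
            raise ValueError("spike_sd must not exceed slab_sd")
        if self.spike_mean >= self.slab_mean:
            raise ValueError("spike_mean must lie below slab_mean")


@dataclass(frozen=True)
class ModelSpec:
    """Which member of the model family to fit.

    ``discrimination_free=False`` fixes all a_i = 1 (Rasch-type);
    ``latent_space=False`` drops the distance term (gamma = 0, plain IRT).
    """

    D: int
    K: int = 2
    discrimination_free: bool = True
    latent_space: bool = True
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.D < 1:
            raise ValueError("factor dimension D must be >= 1")
        if self.K < 1:
            raise ValueError("latent space dimension K must be >= 1")

    # ---- Taxonomy constructors -------------------------------------------------
    @classmethod
    def mls2plm(cls, D: int, K: int = 2, prior: PriorConfig = None) -> "ModelSpec":
        """Multidimensional latent space 2PLM (the full model)."""
        return cls(D=D, K=K, discrimination_free=True, latent_space=True,
                   prior=prior or PriorConfig())

    @classmethod
    def mlsrm(cls, D: int, K: int = 2, prior: PriorConfig = None) -> "ModelSpec":
        """Multidimensional latent space Rasch model (a_i fixed at 1)."""
        return cls(D=D, K=K, discrimination_free=False, latent_space=True,
                   prior=prior or PriorConfig())

    @classmethod
    def uls2plm(cls, K: int = 2, prior: PriorConfig = None) -> "ModelSpec":
        """Unidimensional latent space 2PLM."""
        return cls(D=1, K=K, discrimination_free=True, latent_space=True,
                   prior=prior or PriorConfig())

    @classmethod
    def ulsrm(cls, K: int = 2, prior: PriorConfig = None) -> "ModelSpec":
        """Unidimensional latent space Rasch model (the LSIRM)."""
        return cls(D=1, K=K, discrimination_free=False, latent_space=True,
                   prior=prior or PriorConfig())

    @classmethod
    def mirm(cls, D: int, prior: PriorConfig = None) -> "ModelSpec":
        """Multidimensional IRT model without a latent space (CI baseline)."""
        return cls(D=D, K=2, discrimination_free=True, latent_space=False,
                   prior=prior or PriorConfig())


@dataclass(frozen=True)
class ParameterState:
    """One complete draw (or point estimate) of all model parameters."""

    theta: np.ndarray            # (P, D)
    a: np.ndarray                # (I,) strictly positive; all 1 for Rasch variants
    beta: np.ndarray             # (I,)
    Z: np.ndarray                # (P, K)
    W: np.ndarray                # (I, K)
    gamma: float                 # >= 0; 0 when latent_space=False; None if absent
    theta_corr: np.ndarray = None    # (D, D) correlation matrix
    theta_scale: np.ndarray = None   # (D,) positive scales (unit when fixed)
    mix_w: float = None              # slab mixing proportion (slab_spike mode)

    def __post_init__(self):
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        P, D = theta.shape
        a = np.asarray(self.a, dtype=float).ravel()
        beta = np.asarray(self.beta, dtype=float).ravel()
        I = beta.shape[0]
        if a.shape != (I,):
            raise DimensionError("a", (I,), a.shape)
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if Z.shape[0] != P:
            raise DimensionError("Z rows", P, Z.shape[0])
        if W.shape[0] != I:
            raise DimensionError("W rows", I, W.shape[0])
        if Z.shape[1] != W.shape[1]:
            raise DimensionError("latent space K", Z.shape[1], W.shape[1])
        if (a <= 0).any():
            raise ValueError("discriminations must be strictly positive")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        corr = self.theta_corr
        if corr is None:
            corr = np.eye(D)
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (D, D):
            raise DimensionError("theta_corr", (D, D), corr.shape)
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("theta_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
            raise ValueError("theta_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("theta_corr must be positive definite")
        scale = self.theta_scale
        if scale is None:
            scale = np.ones(D)
        scale = np.asarray(scale, dtype=float).ravel()
        if scale.shape != (D,):
            raise DimensionError("theta_scale", (D,), scale.shape)
        if (scale <= 0).any():
            raise ValueError("theta_scale must be strictly positive")
        if self.mix_w is not None and not (0.0 <= self.mix_w <= 1.0):
            raise ValueError("mix_w must lie in [0, 1]")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "theta_corr", corr)
        object.__setattr__(self, "theta_scale", scale)

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_items(self) -> int:
        return self.beta.shape[0]

    @property
    def n_factors(self) -> int:
        return self.theta.shape[1]

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    def replace(self, **kw) -> "ParameterState":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# distances & similarity
# ---------------------------------------------------------------------------

def euclidean_distance(z: np.ndarray, w: np.ndarray) -> float:
    """Euclidean distance between two K-vectors."""
    z = np.asarray(z, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if z.shape != w.shape:
        raise DimensionError("position length", z.shape, w.shape)
    return float(np.linalg.norm(z - w))


def person_item_distances(Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """All pairwise person-item Euclidean distances, shape (P, I)."""
    Z, W = np.atleast_2d(Z), np.atleast_2d(W)
    if Z.shape[1] != W.shape[1]:
        raise DimensionError("latent space K", Z.shape[1], W.shape[1])
    return cdist(Z, W)


def similarity(distance, gamma):
    """exp(-gamma * distance): person-item similarity in (0, 1].

    Equals the multiplicative change of the odds of a correct response
    relative to a zero-distance configuration, which makes it a scaled
    measure of unexplained person-item affinity.
    """
    distance = np.asarray(distance, dtype=float)
    if (distance < 0).any():
        raise ValueError("distance must be nonnegative")
    if np.any(np.asarray(gamma) < 0):
        raise ValueError("gamma must be nonnegative")
    out = np.exp(-gamma * distance)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# likelihood / prior / posterior on the constrained scale
# ---------------------------------------------------------------------------

def _check_state_against(state: ParameterState, data: ItemResponseData, spec: ModelSpec):
    if state.n_persons != data.n_persons:
        raise DimensionError("persons P", data.n_persons, state.n_persons)
    if state.n_items != data.n_items:
        raise DimensionError("items I", data.n_items, state.n_items)
    if state.n_factors != spec.D:
        raise DimensionError("factors D", spec.D, state.n_factors)
    if data.n_factors > spec.D:
        raise DimensionError("item_factor max", f"<= D = {spec.D}", data.n_factors)
    if spec.latent_space and state.K != spec.K:
        raise DimensionError("latent space K", spec.K, state.K)


def linear_predictor(state: ParameterState, data: ItemResponseData,
                     spec: ModelSpec) -> np.ndarray:
    """(P, I) matrix of logits: a_i theta_{p,d(i)} + beta_i - gamma * d(z_p, w_i)."""
    _check_state_against(state, data, spec)
    d0 = data.factor_index0
    eta = state.a[None, :] * state.theta[:, d0] + state.beta[None, :]
    if spec.latent_space and state.gamma:
        eta = eta - state.gamma * person_item_distances(state.Z, state.W)
    if not np.isfinite(eta).all():
        raise FloatingPointError("non-finite linear predictor")
    return eta


def log_likelihood(state: ParameterState, data: ItemResponseData,
                   spec: ModelSpec) -> float:
    """Bernoulli-logit log likelihood summed over observed cells.

    Missing cells contribute zero (ignorable missingness).
    """
    eta = linear_predictor(state, data, spec)
    mask = data.mask
    y = np.where(mask, data.responses, 0.0)
    # y*log p + (1-y)*log(1-p) = log_expit((2y-1) * eta)
    cell = log_expit(np.where(y == 1.0, eta, -eta))
    return float(cell[mask].sum())


def _normal_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * LOG_2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def lkj_logpdf_unnorm(corr: np.ndarray, shape: float) -> float:
    """LKJ density of a correlation matrix, up to its normalizing constant."""
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    return float((shape - 1.0) * logdet)


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log prior density of a parameter state (constrained scale).

    Terms: theta rows ~ MVN(0, Sigma_theta); beta ~ N; a ~ lognormal (2PL
    variants only); Z, W rows ~ standard normal; correlation ~ LKJ (up to
    its constant); free scales ~ half-normal; gamma ~ lognormal or the
    marginalized slab-and-spike mixture with mix_w ~ Beta.
    """
    pc = spec.prior
    D = spec.D
    scale = state.theta_scale if pc.theta_scale_mode == "free" else np.ones(D)
    cov = state.theta_corr * np.outer(scale, scale)
    chol = np.linalg.cholesky(cov)  # raises on non-PD
    sol = np.linalg.solve(chol, state.theta.T)
    lp = (-0.5 * state.n_persons * D * LOG_2PI
          - state.n_persons * np.log(np.diag(chol)).sum()
          - 0.5 * (sol ** 2).sum())
    lp += _normal_logpdf(state.beta, pc.beta_mean, pc.beta_sd).sum()
    if spec.discrimination_free:
        # lognormal density of a
        la = np.log(state.a)
        lp += (_normal_logpdf(la, pc.log_a_mean, pc.log_a_sd) - la).sum()
    if D > 1:
        lp += lkj_logpdf_unnorm(state.theta_corr, pc.lkj_shape)
    if pc.theta_scale_mode == "free":
        s = pc.theta_scale_sd
        lp += (0.5 * np.log(2.0 / np.pi) - np.log(s)
               - 0.5 * (scale / s) ** 2).sum()
    if spec.latent_space:
        lp += _normal_logpdf(state.Z, 0.0, 1.0).sum()
        lp += _normal_logpdf(state.W, 0.0, 1.0).sum()
        lg = np.log(state.gamma)
        if pc.gamma_prior_mode == "lognormal":
            lp += float(_normal_logpdf(lg, pc.log_gamma_mean, pc.log_gamma_sd) - lg)
        else:
            if state.mix_w is None:
                raise ValueError("slab_spike mode requires mix_w in the state")
            w = state.mix_w
            comp = np.array([
                np.log(w) + _normal_logpdf(lg, pc.slab_mean, pc.slab_sd),
                np.log1p(-w) + _normal_logpdf(lg, pc.spike_mean, pc.spike_sd),
            ])
            m = comp.max()
            lp += float(m + np.log(np.exp(comp - m).sum()) - lg)
            from scipy.special import betaln
            lp += float((pc.mix_beta_a - 1) * np.log(w)
                        + (pc.mix_beta_b - 1) * np.log1p(-w)
                        - betaln(pc.mix_beta_a, pc.mix_beta_b))
    return float(lp)


def log_posterior(state: ParameterState, data: ItemResponseData,
                  spec: ModelSpec) -> float:
    """Unnormalized log posterior density on the constrained scale."""
    return log_likelihood(state, data, spec) + log_prior(state, spec)


# ---------------------------------------------------------------------------
# model reductions
# ---------------------------------------------------------------------------

_CONSTRAINTS = ("fix_discrimination", "unidimensional", "drop_space")


def reduce_model(spec: ModelSpec, constraint: str) -> ModelSpec:
    """Apply one parameter constraint to obtain a nested, simpler model.

    ``fix_discrimination`` sets all a_i = 1 (2PL -> Rasch),
    ``unidimensional`` collapses D to 1, and ``drop_space`` removes the
    distance term (gamma = 0, CI model).  The ability covariance stays a
    correlation matrix in every variant (one identification convention
    across the family), so reductions change no other prior settings.
    """
    if constraint == "fix_discrimination":
        return replace(spec, discrimination_free=False)
    if constraint == "unidimensional":
        return replace(spec, D=1)
    if constraint == "drop_space":
        return replace(spec, latent_space=False)
    raise ValueError(f"unknown constraint {constraint!r}; one of {_CONSTRAINTS}")


def response_probability(state: ParameterState, data: ItemResponseData,
                         spec: ModelSpec) -> np.ndarray:
    """(P, I) matrix of Bernoulli success probabilities."""
    return expit(linear_predictor(state, data, spec))
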