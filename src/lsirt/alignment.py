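"""Procrustes alignment of latent-space configurations across draws.

Euclidean distances are invariant to translation, rotation and reflection
of the latent positions, so posterior draws of (Z, W) wander over an orbit
of rigid motions.  Alignment picks the draw with the highest log posterior
density as the reference configuration and maps every other draw onto it
with the rigid motion (translation plus orthogonal matrix, determinant
+/-1, no scaling) minimizing the squared discrepancy.  Persons and items
are stacked and matched jointly with a single motion per draw, which
preserves every person-item distance exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .inference import PosteriorDraws

logger = logging.getLogger(__name__)

__all__ = ["Configuration", "select_reference", "procrustes_match", "align_all"]


@dataclass(frozen=True)
class Configuration:
    """Stacked person-atop-item positions, (P + I) x K, with the partition."""

    stacked: np.ndarray
    n_persons: int

    def __post_init__(self):
        stacked = np.atleast_2d(np.asarray(self.stacked, dtype=float))
        if not np.isfinite(stacked).all():
            raise ValueError("configuration contains non-finite positions")
        if not 0 < self.n_persons < stacked.shape[0]:
            raise ValueError("partition index inconsistent with the stacked matrix")
        object.__setattr__(self, "stacked", stacked)

    @property
    def Z(self) -> np.ndarray:
        return self.stacked[: self.n_persons]

    @property
    def W(self) -> np.ndarray:
        return self.stacked[self.n_persons:]


def select_reference(draws: PosteriorDraws) -> Configuration:
    """Configuration of the draw with the highest log posterior density.

    Ties break toward the earliest (chain, iteration) in chain-major order.
    """
    if draws.log_post.size == 0:
        raise ValueError("no retained draws")
    flat = np.argmax(draws.log_post)  # argmax returns the first maximum in C order
    c, t = np.unravel_index(flat, draws.log_post.shape)
    stacked = np.vstack([draws.params["Z"][c, t], draws.params["W"][c, t]])
    return Configuration(stacked=stacked, n_persons=draws.params["Z"].shape[2])


def procrustes_match(config: Configuration, reference: Configuration) -> Configuration:
    """Rigid-motion match of ``config`` onto ``reference``.

    Solves the orthogonal Procrustes problem on the centered stacked
    matrices via the SVD closed form; the orthogonal factor may include a
    reflection.  No scaling is applied: scale is identified by the unit
    position priors and gamma.
    """
    if config.stacked.shape != reference.stacked.shape:
        raise ValueError(f"shape mismatch: {config.stacked.shape} vs "
                         f"{reference.stacked.shape}")
    if config.n_persons != reference.n_persons:
        raise ValueError("partition mismatch between configurations")
    X, Y = config.stacked, reference.stacked
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    A, B = X - cx, Y - cy
    U, _, Vt = np.linalg.svd(A.T @ B)
    Q = U @ Vt
    return Configuration(stacked=A @ Q + cy, n_persons=config.n_persons)


def align_all(draws: PosteriorDraws) -> PosteriorDraws:
    """Match every retained draw's (Z, W) to the reference configuration.

    Returns a new :class:`PosteriorDraws` with the aligned flag set; all
    distance-derived quantities are unchanged (rigid motions preserve the
    likelihood).  Aligning an already-aligned object is a logged no-op.
    """
    if not draws.spec.latent_space:
        raise ValueError("model has no latent space; nothing to align")
    if draws.aligned:
        logger.info("draws already aligned; returning them unchanged")
        return draws
    ref = select_reference(draws)
    P = ref.n_persons
    Z = draws.params["Z"].copy()
    W = draws.params["W"].copy()
    for c in range(draws.n_chains):
        for t in range(draws.n_draws):
            cfg = Configuration(stacked=np.vstack([Z[c, t], W[c, t]]), n_persons=P)
            matched = procrustes_match(cfg, ref)
            Z[c, t] = matched.Z
            W[c, t] = matched.W
    params = dict(draws.params)
    params["Z"] = Z
    params["W"] = W
    return replace(draws, params=params, aligned=True)
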