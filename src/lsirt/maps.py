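"""Interaction-map analytics of a fitted latent space.

Once positions are aligned and point-estimated, the latent space yields
person-item distances, inter-item distances, average distance effects
(gamma times distance, the quantity entering the logit), and per-person
similarity profiles exp(-gamma * d) used for individualized diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import ParameterState, person_item_distances, similarity

__all__ = [
    "InteractionSummary",
    "summarize",
    "similarity_profile",
    "cross_model_effect_table",
    "plot_latent_space",
    "MODEL_COMPLEXITY_ORDER",
]

# simpler models first (fewer main-effect parameters)
MODEL_COMPLEXITY_ORDER = ("ULSRM", "ULS2PLM", "MLSRM", "MLS2PLM")


@dataclass(frozen=True)
class InteractionSummary:
    """Distance- and similarity-based summaries of one fitted latent space."""

    person_item_distance: np.ndarray   # (P, I)
    inter_item_distance: np.ndarray    # (I, I), symmetric, zero diagonal
    person_avg_effect: np.ndarray      # (P,) mean over items of gamma * d
    item_avg_effect: np.ndarray        # (I,) mean over persons of gamma * d
    similarity: np.ndarray             # (P, I) exp(-gamma * d)
    gamma: float
    person_ids: tuple
    item_ids: tuple


def summarize(point_state: ParameterState, person_ids=None,
              item_ids=None) -> InteractionSummary:
    """All interaction-map summaries from posterior-mean positions and gamma.

    Positions should come from aligned draws; a per-draw mode (mapping
    this function over draws) yields posterior intervals of distances.
    """
    if point_state.gamma is None:
        raise ValueError("state has no distance-tuning parameter gamma")
    Z, W, gamma = point_state.Z, point_state.W, float(point_state.gamma)
    dist = person_item_distances(Z, W)
    inter = cdist(W, W)
    inter = 0.5 * (inter + inter.T)
    np.fill_diagonal(inter, 0.0)
    pids = tuple(person_ids) if person_ids is not None else tuple(
        f"P{p + 1}" for p in range(Z.shape[0]))
    iids = tuple(item_ids) if item_ids is not None else tuple(
        f"I{i + 1}" for i in range(W.shape[0]))
    return InteractionSummary(
        person_item_distance=dist,
        inter_item_distance=inter,
        person_avg_effect=(gamma * dist).mean(axis=1),
        item_avg_effect=(gamma * dist).mean(axis=0),
        similarity=similarity(dist, gamma),
        gamma=gamma,
        person_ids=pids,
        item_ids=iids,
    )


def similarity_profile(summary: InteractionSummary, person_id,
                       reference_person=None) -> pd.DataFrame:
    """Per-item similarities of one person, ordered by a reference person.

    Items are sorted by nonincreasing similarity to ``reference_person``
    (default: the person themselves), so profiles of several respondents
    can be compared on a common item ordering.
    """
    person_id = str(person_id)
    if person_id not in summary.person_ids:
        raise KeyError(f"unknown person id {person_id!r}")
    ref = str(reference_person) if reference_person is not None else person_id
    if ref not in summary.person_ids:
        raise KeyError(f"unknown reference person id {ref!r}")
    p = summary.person_ids.index(person_id)
    r = summary.person_ids.index(ref)
    order = np.argsort(-summary.similarity[r])
    return pd.DataFrame({
        "item_id": [summary.item_ids[i] for i in order],
        "similarity": summary.similarity[p, order],
        "distance": summary.person_item_distance[p, order],
    })


def cross_model_effect_table(fits) -> pd.DataFrame:
    """Long table of per-person and per-item average distance effects by model.

    ``fits`` is a sequence of ``(model_name, InteractionSummary)`` pairs on
    the same data; rows are keyed by entity x model and models are ordered
    by complexity (ULSRM, ULS2PLM, MLSRM, MLS2PLM, then anything else).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    pids, iids = fits[0][1].person_ids, fits[0][1].item_ids
    for name, summ in fits[1:]:
        if summ.person_ids != pids or summ.item_ids != iids:
            raise ValueError(f"fit {name!r} has a different entity set")

    def complexity(name):
        name = str(name)
        return (MODEL_COMPLEXITY_ORDER.index(name)
                if name in MODEL_COMPLEXITY_ORDER else len(MODEL_COMPLEXITY_ORDER))

    rows = []
    for name, summ in sorted(fits, key=lambda f: complexity(f[0])):
        for p, pid in enumerate(pids):
            rows.append(dict(entity_type="person", entity_id=pid,
                             model=str(name), avg_effect=float(summ.person_avg_effect[p])))
        for i, iid in enumerate(iids):
            rows.append(dict(entity_type="item", entity_id=iid,
                             model=str(name), avg_effect=float(summ.item_avg_effect[i])))
    return pd.DataFrame(rows)


def distance_intervals(draws, prob: float = 0.95):
    """Posterior quantiles of every person-item distance, over aligned draws.

    Returns (lower, median, upper) arrays of shape (P, I).  Distances are
    rigid-motion invariant, so alignment does not change them, but the
    draws must carry a latent space.
    """
    if not draws.spec.latent_space:
        raise ValueError("model has no latent space")
    if not 0 < prob < 1:
        raise ValueError("prob must lie in (0, 1)")
    Z, W = draws.params["Z"], draws.params["W"]
    C, T = Z.shape[:2]
    dist = np.empty((C * T,) + (Z.shape[2], W.shape[2]))
    k = 0
    for c in range(C):
        for t in range(T):
            dist[k] = person_item_distances(Z[c, t], W[c, t])
            k += 1
    alpha = 0.5 * (1 - prob)
    lo, med, hi = np.quantile(dist, [alpha, 0.5, 1 - alpha], axis=0)
    return lo, med, hi


def position_spreads(point_state: ParameterState) -> dict:
    """SDs of estimated latent positions, separately for persons and items."""
    return {"person_sd": float(point_state.Z.std()),
            "item_sd": float(point_state.W.std())}


def plot_latent_space(point_state: ParameterState, data, path,
                      shared_limits=None, title=None):
    """Planar interaction map: gray dots for persons, colored item numbers.

    Items measuring the same factor share a color.  ``shared_limits``
    (xlim, ylim) enforces common axes across models for comparing the
    extent of conditional dependence; ``None`` fits each configuration.
    Only K = 2 spaces can be drawn.
    """
    if point_state.K != 2:
        raise ValueError("visualization supports planar (K = 2) spaces only")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(point_state.Z[:, 0], point_state.Z[:, 1], s=12, c="0.6",
               alpha=0.6, linewidths=0, label="persons")
    cmap = plt.get_cmap("tab10")
    for i in range(point_state.n_items):
        fac = int(data.item_factor[i]) - 1
        ax.text(point_state.W[i, 0], point_state.W[i, 1], str(i + 1),
                color=cmap(fac % 10), fontsize=10, fontweight="bold",
                ha="center", va="center")
    if shared_limits is not None:
        xlim, ylim = shared_limits
        ax.set_xlim(*xlim)
        ax.set_ylim(*ylim)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
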