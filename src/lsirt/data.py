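"""Binary item response data with a between-item factor structure.

A response matrix holds persons in rows and items in columns, entries in
{0, 1} or missing (NaN).  Each item is assigned to exactly one of D factors
(simple structure, no cross loadings), which is how between-item
multidimensional IRT models index the single discrimination per item.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class DimensionError(ValueError):
    """Raised when an array's shape is inconsistent with the data; names the axis."""

    def __init__(self, axis: str, expected, got):
        self.axis = axis
        super().__init__(f"dimension mismatch on axis {axis!r}: expected {expected}, got {got}")


@dataclass(frozen=True)
class ItemResponseData:
    """P x I binary responses plus the item -> factor assignment.

    Parameters
    ----------
    responses : (P, I) float array
        Entries 0.0, 1.0 or NaN (missing).
    item_factor : (I,) int array
        1-based factor index of each item, in ``1..D``.
    person_ids, item_ids : sequences of str, optional
        Defaults to ``P1..`` / ``I1..``.
    """

    responses: np.ndarray
    item_factor: np.ndarray
    person_ids: tuple = field(default=None)
    item_ids: tuple = field(default=None)

    def __post_init__(self):
        resp = np.asarray(self.responses, dtype=float)
        if resp.ndim != 2:
            raise DimensionError("responses", "2-d (P, I)", f"{resp.ndim}-d")
        P, I = resp.shape
        if P < 2:
            raise ValueError(f"need at least 2 persons, got {P}")
        if I < 2:
            raise ValueError(f"need at least 2 items, got {I}")
        observed = resp[~np.isnan(resp)]
        if not np.isin(observed, (0.0, 1.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0))]
            raise ValueError(f"non-binary response values: {np.unique(bad)[:5]}")
        fac = np.asarray(self.item_factor, dtype=int)
        if fac.shape != (I,):
            raise DimensionError("item_factor", (I,), fac.shape)
        if fac.min(initial=1) < 1:
            raise ValueError("factor indices are 1-based and must be >= 1")
        D = int(fac.max())
        present = np.unique(fac)
        if not np.array_equal(present, np.arange(1, D + 1)):
            missing = sorted(set(range(1, D + 1)) - set(present.tolist()))
            raise ValueError(f"every factor in 1..{D} needs at least one item; missing {missing}")
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "item_factor", fac)
        pids = self.person_ids
        iids = self.item_ids
        if pids is None:
            pids = tuple(f"P{p + 1}" for p in range(P))
        if iids is None:
            iids = tuple(f"I{i + 1}" for i in range(I))
        pids, iids = tuple(map(str, pids)), tuple(map(str, iids))
        if len(pids) != P:
            raise DimensionError("person_ids", P, len(pids))
        if len(iids) != I:
            raise DimensionError("item_ids", I, len(iids))
        if len(set(pids)) != P:
            raise ValueError("duplicate person ids")
        if len(set(iids)) != I:
            raise ValueError("duplicate item ids")
        object.__setattr__(self, "person_ids", pids)
        object.__setattr__(self, "item_ids", iids)
        # degenerate rows/columns are allowed (priors regularize) but flagged
        mask = ~np.isnan(resp)
        filled = np.where(mask, resp, 0.0)
        for axis in (0, 1):
            n_obs = mask.sum(axis=axis)
            s = filled.sum(axis=axis)
            degenerate = (n_obs > 0) & ((s == 0) | (s == n_obs))
            if degenerate.any():
                logger.warning("data contain all-0 or all-1 rows/columns; "
                               "priors will regularize them")
                break

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_factors(self) -> int:
        return int(self.item_factor.max())

    @property
    def mask(self) -> np.ndarray:
        """Boolean (P, I) array, True where a response was observed."""
        return ~np.isnan(self.responses)

    @property
    def factor_index0(self) -> np.ndarray:
        """0-based d(i) used for array indexing."""
        return self.item_factor - 1

    def with_unidimensional_factor(self) -> "ItemResponseData":
        """Remap every item to factor 1 (for unidimensional reductions)."""
        return ItemResponseData(
            responses=self.responses,
            item_factor=np.ones(self.n_items, dtype=int),
            person_ids=self.person_ids,
            item_ids=self.item_ids,
        )
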