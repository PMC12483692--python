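"""Readers and writers for the package's file formats.

Responses travel as wide CSV (first column person id, remaining columns
item ids, cells 0/1/empty-for-missing); the item map as a two-column CSV
``item_id,factor`` with 1-based factor indices; posterior draws as a
columnar table (one row per chain x iteration) with a JSON sidecar
recording shapes so the table round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ItemResponseData
from .inference import PosteriorDraws

__all__ = ["read_response_csv", "write_response_csv", "read_item_map",
           "write_item_map", "write_draws", "read_draws_table"]


def read_item_map(path) -> pd.DataFrame:
    """Read ``item_id,factor`` CSV; validates 1-based contiguous factors."""
    table = pd.read_csv(path, dtype={"item_id": str})
    if list(table.columns[:2]) != ["item_id", "factor"]:
        raise ValueError(f"item map must have columns item_id,factor; got {list(table.columns)}")
    if table.item_id.duplicated().any():
        dup = table.item_id[table.item_id.duplicated()].iloc[0]
        raise ValueError(f"duplicate item id {dup!r} in item map")
    fac = table.factor.to_numpy()
    if not np.issubdtype(fac.dtype, np.integer):
        raise ValueError("factor column must be integer (1-based)")
    if fac.min() < 1:
        raise ValueError(f"factor index out of range: {fac.min()} (must be >= 1)")
    return table


def write_item_map(item_factor, item_ids, path):
    pd.DataFrame({"item_id": list(item_ids),
                  "factor": np.asarray(item_factor, dtype=int)}).to_csv(path, index=False)


def read_response_csv(path, item_map_path=None) -> ItemResponseData:
    """Read a wide response CSV (plus item map) into ItemResponseData.

    Cells must be 0, 1 or empty; offending cells are reported with their
    row and column.  Without an item map all items load on factor 1.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if table.shape[1] < 3:
        raise ValueError("response CSV needs a person-id column and >= 2 item columns")
    person_ids = table.iloc[:, 0].astype(str).tolist()
    if len(set(person_ids)) != len(person_ids):
        dup = pd.Series(person_ids)[pd.Series(person_ids).duplicated()].iloc[0]
        raise ValueError(f"duplicate person id {dup!r}")
    item_ids = [str(c) for c in table.columns[1:]]
    raw = table.iloc[:, 1:].to_numpy()
    resp = np.empty(raw.shape, dtype=float)
    for (r, c), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell == "" or cell.upper() in ("NA", "NAN"):
            resp[r, c] = np.nan
        elif cell in ("0", "1"):
            resp[r, c] = float(cell)
        else:
            raise ValueError(
                f"non-binary cell {cell!r} at row {r + 2} (person {person_ids[r]!r}), "
                f"column {item_ids[c]!r}")
    if item_map_path is not None:
        imap = read_item_map(item_map_path)
        lookup = dict(zip(imap.item_id, imap.factor))
        missing = [i for i in item_ids if i not in lookup]
        if missing:
            raise ValueError(f"item map lacks entries for items {missing[:5]}")
        item_factor = np.array([lookup[i] for i in item_ids], dtype=int)
    else:
        item_factor = np.ones(len(item_ids), dtype=int)
    return ItemResponseData(responses=resp, item_factor=item_factor,
                            person_ids=person_ids, item_ids=item_ids)


def write_response_csv(data: ItemResponseData, path):
    """Inverse of :func:`read_response_csv` (missing cells become empty)."""
    cells = np.empty(data.responses.shape, dtype=object)
    cells[:] = ""
    obs = data.mask
    cells[obs] = data.responses[obs].astype(int).astype(str)
    table = pd.DataFrame(cells, columns=list(data.item_ids))
    table.insert(0, "person_id", list(data.person_ids))
    table.to_csv(path, index=False)


def write_draws(draws: PosteriorDraws, path):
    """Serialize draws to ``<path>`` (CSV) plus ``<path>.meta.json``.

    Aligned draws serialize identically to unaligned ones apart from the
    position values and the flag in the sidecar.
    """
    path = Path(path)
    draws.to_frame().to_csv(path, index=False)
    meta = {
        "shapes": {k: list(v.shape[2:]) for k, v in draws.params.items()},
        "n_chains": draws.n_chains,
        "n_draws": draws.n_draws,
        "aligned": bool(draws.aligned),
        "seed": int(draws.seed),
        "spec": {
            "D": draws.spec.D, "K": draws.spec.K,
            "discrimination_free": draws.spec.discrimination_free,
            "latent_space": draws.spec.latent_space,
            "gamma_prior_mode": draws.spec.prior.gamma_prior_mode,
        },
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_draws_table(path):
    """Read a serialized draws table and its sidecar; returns (frame, meta)."""
    path = Path(path)
    frame = pd.read_csv(path)
    with open(path.with_suffix(path.suffix + ".meta.json")) as fh:
        meta = json.load(fh)
    return frame, meta
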