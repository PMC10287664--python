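"""Rescaling, weighting and aggregation of the forest condition index.

Variables are rescaled to indicators in [0, 1] by clamped min-max between
the lower and upper reference levels,

    I = (V - V_L) / (V_H - V_L),

with values at or below V_L mapping to 0 and at or above V_H mapping to 1.
Indicator weights derive from rank sums over five conceptual criteria and
sum to one; the condition index of a cell is the weighted sum of its
indicators, and the per-type index is the mean over the type's cells.
When a variable is structurally absent for a type (e.g. no soil-carbon
coverage), its weight is redistributed proportionally over the remaining
indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_WEIGHTS, VARIABLES
from .typology import TypologyGrid

log = logging.getLogger(__name__)


def rescale(V, V_L, V_H):
    """Clamped min-max rescale of variable values to [0, 1].

    Degenerate levels (``V_H == V_L``) yield 0 — an uninformative
    indicator is reported as degraded rather than silently granted top
    condition — and are logged by the callers that detect them type-wise.
    """
    V = np.asarray(V, dtype=float)
    V_L = np.asarray(V_L, dtype=float)
    V_H = np.asarray(V_H, dtype=float)
    if np.any(V_H < V_L):
        raise ValueError("upper reference level below lower reference level")
    span = V_H - V_L
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(span > 0, (V - V_L) / np.where(span > 0, span, 1.0), 0.0)
    out = np.clip(out, 0.0, 1.0)
    out = np.where(np.isnan(V) | np.isnan(V_L) | np.isnan(V_H), np.nan, out)
    return out if out.shape else float(out)


@dataclass
class WeightTable:
    """Indicator weights summing to one, with optional rank provenance."""

    weights: pd.Series            # index: indicator names
    rank_sums: pd.Series | None = None

    def __post_init__(self):
        w = self.weights
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights sum to {w.sum()}, expected 1")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")


def default_weights() -> WeightTable:
    return WeightTable(pd.Series(DEFAULT_WEIGHTS, index=VARIABLES, dtype=float))


def weights_from_ranks(rank_matrix: pd.DataFrame) -> WeightTable:
    """Convert an indicators x criteria rank matrix into weights.

    Each criterion column ranks the indicators 1 (lowest) .. k (highest);
    mid-rank ties are allowed. ``w_j`` is the rank sum of indicator j as a
    share of the total rank sum.
    """
    k = len(rank_matrix)
    vals = rank_matrix.to_numpy(dtype=float)
    if np.any(vals < 1) or np.any(vals > k):
        raise ValueError(f"ranks must lie in 1..{k}")
    rank_sums = rank_matrix.sum(axis=1)
    weights = rank_sums / rank_sums.sum()
    return WeightTable(weights=weights.astype(float), rank_sums=rank_sums)


def redistribute_missing(weights: WeightTable, missing) -> WeightTable:
    """Redistribute the weight of missing indicators over the rest.

    ``w'_j = w_j / (1 - sum of missing weights)`` for remaining j, which
    preserves the relative proportions and restores a unit sum.
    """
    missing = set(missing)
    if not missing:
        return weights
    w = weights.weights
    unknown = missing - set(w.index)
    if unknown:
        raise KeyError(f"unknown indicators: {sorted(unknown)}")
    if missing >= set(w.index):
        raise ValueError("cannot redistribute: all indicators missing")
    keep = w.drop(index=sorted(missing))
    return WeightTable(weights=keep / keep.sum())


def indicator_stack(variables: dict, levels: pd.DataFrame,
                    typology: TypologyGrid) -> dict:
    """Rescale each variable grid to its indicator grid, type by type.

    Cells outside the typology, or of a type lacking a (finite) level row
    for the variable, are NaN.
    """
    lv = levels.set_index(["type_id", "variable"])
    out = {}
    for var, grid in variables.items():
        grid = np.asarray(grid, dtype=float)
        ind = np.full(grid.shape, np.nan)
        for rec in typology.catalogue.itertuples():
            try:
                row = lv.loc[(rec.type_id, var)]
            except KeyError:
                continue
            v_l, v_h = float(row["V_L"]), float(row["V_H"])
            if np.isnan(v_l) or np.isnan(v_h):
                continue
            if v_h == v_l:
                log.info("degenerate levels for type %s variable %s "
                         "(V_L == V_H == %g); indicator set to 0",
                         rec.type_id, var, v_l)
            cells = typology.cells_of(rec.type_id)
            ind[cells] = rescale(grid[cells], v_l, v_h)
        out[var] = ind
    return out


@dataclass
class ConditionIndexGrid:
    index: np.ndarray          # [0,1], NaN off-domain
    per_type_mean: pd.Series   # index: type_id
    type_weights: dict         # type_id -> effective weight Series


def aggregate_index(indicators: dict, weights: WeightTable,
                    typology: TypologyGrid) -> ConditionIndexGrid:
    """Weighted aggregation of indicators into the condition index.

    A variable that is NaN on *every* cell of a type is treated as
    structurally absent for that type and its weight redistributed over
    the present indicators (the soil-carbon rule). Cell-sporadic gaps in
    otherwise-present indicators produce no-data cells instead.
    """
    names = list(indicators)
    stack = np.stack([np.asarray(indicators[v], dtype=float) for v in names])
    index = np.full(stack.shape[1:], np.nan)
    per_type, type_weights = {}, {}
    for rec in typology.catalogue.itertuples():
        cells = typology.cells_of(rec.type_id)
        sub = stack[:, cells]                      # vars x n_cells
        structurally_missing = {names[i] for i in range(len(names))
                                if np.all(np.isnan(sub[i]))}
        # weight entries without a supplied indicator grid are absent too
        structurally_missing |= set(weights.weights.index) - set(names)
        if len(structurally_missing) >= len(weights.weights):
            per_type[rec.type_id] = np.nan
            type_weights[rec.type_id] = pd.Series(dtype=float)
            continue
        w = redistribute_missing(weights, structurally_missing).weights
        present = [v for v in names if v not in structurally_missing]
        w = w.reindex(present)
        sub_p = stack[[names.index(v) for v in present]][:, cells]
        vals = np.einsum("j,jc->c", w.to_numpy(), sub_p)  # NaN-propagating
        index[cells] = vals
        finite = vals[~np.isnan(vals)]
        per_type[rec.type_id] = float(finite.mean()) if finite.size else np.nan
        type_weights[rec.type_id] = w
    return ConditionIndexGrid(index=index,
                              per_type_mean=pd.Series(per_type, dtype=float),
                              type_weights=type_weights)
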