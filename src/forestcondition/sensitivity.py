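"""One-at-a-time parameter sensitivity of the condition index.

Per forest type the index depends on 21 parameters: the lower level V_L,
the upper level V_H and the weight w_j of each of the seven indicators.
Each parameter is perturbed by 10% on its own — V_L is only increased
(most lower levels sit at a natural floor) and V_H only decreased, while
a perturbed weight is renormalized by scaling the remaining weights
proportionally so their sum stays 1 — and the per-type index is
recomputed and reported as percentage deviation from the nominal value.
Perturbations are multiplicative, so zero-valued parameters are fixed
points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .condition import WeightTable, rescale
from .typology import TypologyGrid


def perturb_weight(weights: WeightTable, indicator: str,
                   factor: float = 1.1) -> WeightTable:
    """Scale one weight by ``factor`` and renormalize the others
    proportionally: ``w_j' = w_j (1 - f w_k) / (1 - w_k)`` for j != k."""
    w = weights.weights.copy()
    wk = float(w[indicator])
    new_wk = factor * wk
    if new_wk >= 1.0:
        raise ValueError(f"perturbed weight {new_wk} >= 1")
    if wk == 0.0:
        return WeightTable(w)
    if wk == 1.0:
        raise ValueError("cannot renormalize: single indicator carries all weight")
    scale = (1.0 - new_wk) / (1.0 - wk)
    w *= scale
    w[indicator] = new_wk
    return WeightTable(w)


def perturb_reference_level(levels: pd.DataFrame, type_id: int, variable: str,
                            which: str) -> pd.DataFrame:
    """Return a copy of the level table with one (type, variable) row
    perturbed: ``which='lower'`` sets V_L' = 1.1 V_L, ``which='upper'``
    sets V_H' = 0.9 V_H. If the perturbed pair degenerates
    (V_H' < V_L'), the upper level is clipped to the lower and the row
    flagged in a ``degenerate`` column."""
    out = levels.copy()
    sel = (out["type_id"] == type_id) & (out["variable"] == variable)
    if not sel.any():
        raise KeyError(f"no level row for type {type_id}, variable {variable}")
    if which == "lower":
        out.loc[sel, "V_L"] = 1.1 * out.loc[sel, "V_L"]
    elif which == "upper":
        out.loc[sel, "V_H"] = 0.9 * out.loc[sel, "V_H"]
    else:
        raise ValueError("which must be 'lower' or 'upper'")
    bad = sel & (out["V_H"] < out["V_L"])
    if "degenerate" not in out.columns:
        out["degenerate"] = False
    if bad.any():
        out.loc[bad, "V_H"] = out.loc[bad, "V_L"]
        out.loc[bad, "degenerate"] = True
    return out


def _type_index(values: dict, levels_idx, weights: pd.Series,
                overrides: dict | None = None) -> float:
    """Per-type mean index from raw per-cell values and (possibly
    overridden) levels. ``overrides`` maps variable -> (V_L, V_H)."""
    overrides = overrides or {}
    total = 0.0
    for var, w in weights.items():
        v_l, v_h = overrides.get(var, levels_idx[var])
        if v_h < v_l:
            v_h = v_l
        total += w * np.mean(rescale(values[var], v_l, v_h))
    return float(total)


def run_oat(variables: dict, typology: TypologyGrid, levels: pd.DataFrame,
            weights: WeightTable, perturbation: float = 0.10) -> pd.DataFrame:
    """Full one-at-a-time sensitivity table.

    For every forest type and every indicator present for it, three rows
    are produced (lower level +10%, upper level -10%, weight +10%
    renormalized), each recomputing the rescaling and aggregation with
    exactly that parameter changed. Deviation is a percentage of the
    nominal per-type index; for types with nominal index 0 the absolute
    change is reported instead and flagged.
    """
    lv = levels.set_index(["type_id", "variable"])
    up, down = 1.0 + perturbation, 1.0 - perturbation
    rows = []
    for rec in typology.catalogue.itertuples():
        cells = typology.cells_of(rec.type_id)
        levels_idx, values = {}, {}
        for var in weights.weights.index:
            try:
                lrow = lv.loc[(rec.type_id, var)]
            except KeyError:
                continue
            v_l, v_h = float(lrow["V_L"]), float(lrow["V_H"])
            if np.isnan(v_l) or np.isnan(v_h):
                continue
            vals = np.asarray(variables[var], dtype=float)[cells]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            levels_idx[var] = (v_l, v_h)
            values[var] = vals
        if not levels_idx:
            continue
        w = weights.weights.reindex(sorted(levels_idx))
        w = w / w.sum()  # redistribute over present indicators
        nominal = _type_index(values, levels_idx, w)

        def emit(parameter, var, perturbed):
            if nominal != 0:
                dev = 100.0 * (perturbed - nominal) / nominal
                absolute = False
            else:
                dev = perturbed - nominal
                absolute = True
            rows.append({"type_id": rec.type_id, "parameter": parameter,
                         "indicator": var, "index_nominal": nominal,
                         "index_perturbed": perturbed,
                         "pct_deviation": dev, "absolute_deviation": absolute})

        for var in w.index:
            v_l, v_h = levels_idx[var]
            emit("lower+10%", var, _type_index(
                values, levels_idx, w, {var: (up * v_l, v_h)}))
            emit("upper-10%", var, _type_index(
                values, levels_idx, w, {var: (v_l, down * v_h)}))
            emit("weight+10%", var, _type_index(
                values, levels_idx,
                perturb_weight(WeightTable(w), var, up).weights))
    return pd.DataFrame(rows)


def summarize_oat(result: pd.DataFrame) -> pd.DataFrame:
    """Average percentage deviation over types per (parameter, indicator)."""
    rel = result[~result["absolute_deviation"]]
    return (rel.groupby(["parameter", "indicator"])["pct_deviation"]
            .agg(["mean", "std", "min", "max"]).reset_index())
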