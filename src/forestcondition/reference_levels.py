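"""Lower and upper reference levels per forest type and condition variable.

The lower level ``V_L`` is the minimum of the variable over the ambient
distribution of the type (a degraded state); the upper level ``V_H`` is
the maximum observed inside reference sites of the type (the natural
state). Both are measured on the reference-year (year 2000) grids and
applied to every accounting year. Types in regions without reference
sites borrow ``V_H`` from the same forest class in a fallback region.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .typology import TypologyGrid

log = logging.getLogger(__name__)


def lower_levels(variables_year0: dict, typology: TypologyGrid,
                 percentile: float | None = None) -> pd.DataFrame:
    """Ambient lower level V_L per (type, variable).

    Default is the absolute minimum over the type's cells; a robust floor
    (``percentile``, e.g. 0.5 for the 0.5th percentile) is available to
    guard against single-cell artefacts.
    """
    rows = []
    for rec in typology.catalogue.itertuples():
        cells = typology.cells_of(rec.type_id)
        for var, grid in variables_year0.items():
            vals = np.asarray(grid)[cells]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            v_l = (np.min(vals) if percentile is None
                   else np.percentile(vals, percentile))
            rows.append({"type_id": rec.type_id, "variable": var,
                         "V_L": float(v_l)})
    return pd.DataFrame(rows, columns=["type_id", "variable", "V_L"])


def upper_levels(variables_year0: dict, typology: TypologyGrid,
                 reference_mask, fallback_assignment: dict,
                 percentile: float | None = None) -> pd.DataFrame:
    """Reference-site upper level V_H per (type, variable).

    ``fallback_assignment`` maps each region name to the region whose sites
    supply V_H (itself when it has own sites, ``None`` when unresolvable).
    For a type whose own region x class has no reference cells, V_H is
    taken over the same forest class in the fallback region and flagged.
    Types with no resolvable source get ``V_H = NaN`` (missing, scored as
    highest uncertainty downstream).
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    cat = typology.catalogue
    # reference cells per (region, class) pair
    rows = []
    for rec in cat.itertuples():
        own = typology.cells_of(rec.type_id) & reference_mask
        fallback_used = False
        source_region = rec.region
        cells = own
        if not own.any():
            target = fallback_assignment.get(rec.region)
            if target is not None and target != rec.region:
                match = cat[(cat["region"] == target)
                            & (cat["forest_class"] == rec.forest_class)]
                if len(match):
                    cells = (typology.cells_of(int(match["type_id"].iloc[0]))
                             & reference_mask)
                    fallback_used = True
                    source_region = target
        for var, grid in variables_year0.items():
            vals = np.asarray(grid)[cells] if cells.any() else np.array([])
            vals = vals[~np.isnan(vals)] if vals.size else vals
            if vals.size == 0:
                v_h = np.nan
            else:
                v_h = (np.max(vals) if percentile is None
                       else np.percentile(vals, percentile))
            rows.append({"type_id": rec.type_id, "variable": var,
                         "V_H": float(v_h), "source_region": source_region,
                         "fallback_used": fallback_used})
    return pd.DataFrame(rows, columns=["type_id", "variable", "V_H",
                                       "source_region", "fallback_used"])


def reference_level_table(lower: pd.DataFrame, upper: pd.DataFrame) -> pd.DataFrame:
    """Merge lower and upper levels into the reference-level table.

    With fallback-sourced upper levels, ``V_H < V_L`` can occur; such rows
    are clipped to ``V_H = V_L`` (indicator 0 everywhere) and logged, which
    keeps the rescaling well-defined.
    """
    table = lower.merge(upper, on=["type_id", "variable"], how="outer")
    bad = table["V_H"] < table["V_L"]
    if bad.any():
        for rec in table[bad].itertuples():
            log.warning("V_H < V_L for type %s variable %s; clipping to V_L",
                        rec.type_id, rec.variable)
        table.loc[bad, "V_H"] = table.loc[bad, "V_L"]
    return table
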