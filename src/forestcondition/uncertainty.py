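"""Semi-quantitative uncertainty level (1-4) of the condition index per type.

Four criteria each score 1 (low) .. 4 (high uncertainty): (1) the extent
of reference sites, absolute (> 100 km2) and relative (> 2% of the type's
forest area); (2) environmental representativeness of the sites, as the
mean absolute z-score of their elevation, slope, temperature and rainfall
against the type's distribution; (3) the share of the type's forest area
whose class matches the potential natural vegetation; (4) the same share
inside reference sites. The final level is the mean of the four scores
rounded half away from zero (conservative ties).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .typology import TypologyGrid

#: z-score bin edges (left-closed, right-open) for scores 1..4.
Z_BINS = (0.3, 0.7, 1.2)
#: natural-share bin edges (%); exact 75/50/25 fall to the worse side.
SHARE_BINS = (75.0, 50.0, 25.0)

ENV_VARIABLES = ["elevation", "slope", "temperature", "rainfall"]


def score_area(ref_area_km2: float, ref_share_pct: float) -> int:
    """Reference-extent score: AND of both thresholds -> 1, one -> 2,
    neither (but sites exist) -> 3, no sites -> 4."""
    if ref_area_km2 <= 0:
        return 4
    big = ref_area_km2 > 100.0
    enough = ref_share_pct > 2.0
    if big and enough:
        return 1
    if big or enough:
        return 2
    return 3


def score_representativeness(mean_abs_z: float) -> int:
    """Environmental-representativeness score from the mean |z|-score."""
    if np.isnan(mean_abs_z):
        return 4
    for score, edge in enumerate(Z_BINS, start=1):
        if mean_abs_z < edge:
            return score
    return 4


def score_natural_share(share_pct: float) -> int:
    """Share of naturally occurring forest class: >75 -> 1, (50,75] -> 2,
    (25,50] -> 3, <=25 -> 4."""
    if np.isnan(share_pct):
        return 4
    for score, edge in enumerate(SHARE_BINS, start=1):
        if share_pct > edge:
            return score
    return 4


def classify_uncertainty(scores) -> int:
    """Mean of the four scores, rounded half away from zero (2.5 -> 3)."""
    m = float(np.mean(list(scores)))
    return int(np.floor(m + 0.5))


def natural_correspondence(typology: TypologyGrid, pnv, mask=None) -> pd.Series:
    """Per-type share (%) of cells whose forest class matches the expected
    (potential natural vegetation) class, optionally within a mask."""
    pnv = np.asarray(pnv)
    observed = typology.type_id % 10
    match = (observed == pnv) & typology.forest_mask
    domain = typology.forest_mask if mask is None \
        else typology.forest_mask & np.asarray(mask, dtype=bool)
    out = {}
    for rec in typology.catalogue.itertuples():
        cells = typology.cells_of(rec.type_id) & domain
        n = int(np.count_nonzero(cells))
        out[rec.type_id] = (100.0 * np.count_nonzero(match & cells) / n
                            if n else np.nan)
    return pd.Series(out, dtype=float)


def mean_abs_zscore(typology: TypologyGrid, reference_mask,
                    environment: dict, signed: bool = False) -> pd.Series:
    """Mean (absolute) z-score of reference-site environment per type.

    For each environmental variable the z-score compares the mean over the
    type's reference cells with the type's mean, in units of the type's
    population standard deviation; scores are averaged over the variables
    (absolute values by default, signed optionally).
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    out = {}
    for rec in typology.catalogue.itertuples():
        cells = typology.cells_of(rec.type_id)
        ref = cells & reference_mask
        if not ref.any():
            out[rec.type_id] = np.nan
            continue
        zs = []
        for var in ENV_VARIABLES:
            g = np.asarray(environment[var], dtype=float)
            sd = g[cells].std()  # population SD of the type
            if sd == 0:
                zs.append(0.0)
                continue
            z = (g[ref].mean() - g[cells].mean()) / sd
            zs.append(z if signed else abs(z))
        out[rec.type_id] = float(np.mean(zs))
    return pd.Series(out, dtype=float)


def assess_uncertainty(typology: TypologyGrid, reference_mask,
                       environment: dict, pnv,
                       cell_area_ha: float = 1.0,
                       signed_z: bool = False) -> pd.DataFrame:
    """Full per-type uncertainty record with the four scores and level."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    zscores = mean_abs_zscore(typology, reference_mask, environment,
                              signed=signed_z)
    share_type = natural_correspondence(typology, pnv)
    share_ref = natural_correspondence(typology, pnv, mask=reference_mask)
    rows = []
    for rec in typology.catalogue.itertuples():
        ref_cells = int(np.count_nonzero(
            typology.cells_of(rec.type_id) & reference_mask))
        ref_area_km2 = ref_cells * cell_area_ha / 100.0
        # share relative to the type's own forest area
        ref_share = (100.0 * ref_cells / rec.n_cells if rec.n_cells else 0.0)
        s = (score_area(ref_area_km2, ref_share),
             score_representativeness(zscores[rec.type_id]),
             score_natural_share(share_type[rec.type_id]),
             score_natural_share(share_ref[rec.type_id]))
        rows.append({
            "type_id": rec.type_id, "ref_area_km2": ref_area_km2,
            "ref_share_pct": ref_share,
            "mean_abs_z": zscores[rec.type_id],
            "natural_share_type_pct": share_type[rec.type_id],
            "natural_share_ref_pct": share_ref[rec.type_id],
            "score_area": s[0], "score_representativeness": s[1],
            "score_natural_type": s[2], "score_natural_ref": s[3],
            "level": classify_uncertainty(s),
        })
    return pd.DataFrame(rows, columns=[
        "type_id", "ref_area_km2", "ref_share_pct", "mean_abs_z",
        "natural_share_type_pct", "natural_share_ref_pct", "score_area",
        "score_representativeness", "score_natural_type",
        "score_natural_ref", "level"])
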