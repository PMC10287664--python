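"""Selection of undisturbed / least-disturbed reference forest sites.

Reference sites anchor the upper reference levels of the condition
variables. Candidate polygons come from a primary-forest inventory merged
with strictly protected areas (IUCN Ia/Ib/II); a polygon is retained when
it holds at least 7.5 ha of forest (the minimum treed area of a 25 ha
mapping unit at 30% canopy, see :func:`forestcondition.constants.min_treed_area_ha`)
and its cumulative tree-cover loss is at most 5% of that forest.

Cells belong to a polygon when their center falls inside it
(deterministic, resolution-consistent). Canopy threshold comparison is
strict (> 20%): 20% is read as the open-habitat limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .constants import (
    DEFAULT_ALLOWED_IUCN,
    DEFAULT_CANOPY_THRESHOLD,
    DEFAULT_FALLBACKS,
    DEFAULT_MAX_LOSS_FRACTION,
    min_treed_area_ha,
)
from .raster import cell_centers, check_registration

log = logging.getLogger(__name__)


def forest_mask_from_canopy(canopy_cover, threshold_pct: float = DEFAULT_CANOPY_THRESHOLD):
    """Forest/non-forest mask from canopy cover: forest where cover > threshold."""
    canopy = np.asarray(canopy_cover, dtype=float)
    if np.nanmin(canopy) < 0 or np.nanmax(canopy) > 100:
        raise ValueError("canopy cover must lie in [0, 100] %")
    return canopy > threshold_pct


def polygon_cell_mask(geometry, grid_shape) -> np.ndarray:
    """Cells whose centers fall inside the polygon (cell-center rule)."""
    rows, cols = grid_shape
    minx, miny, maxx, maxy = geometry.bounds
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), rows)
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), cols)
    mask = np.zeros(grid_shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    x, y = cell_centers((r1 - r0, c1 - c0))
    inside = shapely.contains_xy(geometry, x + c0, y + r0)
    mask[r0:r1, c0:c1] = inside
    return mask


def summarize_polygons(polygons, properties, forest_mask, loss_mask,
                       cell_area_ha: float = 1.0) -> pd.DataFrame:
    """Per-polygon forest area, tree-cover-loss area and loss fraction.

    The loss mask is the any-year summary of annual loss layers. Polygons
    falling outside the grid extent get zero-area stats with a warning.
    """
    forest_mask = np.asarray(forest_mask, dtype=bool)
    loss_mask = np.asarray(loss_mask, dtype=bool)
    check_registration(forest_mask, loss_mask)
    records = []
    for geom, props in zip(polygons, properties, strict=True):
        cells = polygon_cell_mask(geom, forest_mask.shape)
        if not cells.any():
            log.warning("polygon %s outside grid extent or covers no cell center",
                        props.get("polygon_id"))
        forest_cells = int(np.count_nonzero(cells & forest_mask))
        loss_cells = int(np.count_nonzero(cells & forest_mask & loss_mask))
        forest_area = forest_cells * cell_area_ha
        loss_area = loss_cells * cell_area_ha
        records.append({
            "polygon_id": props.get("polygon_id"),
            "origin": props.get("origin"),
            "iucn_category": props.get("iucn_category"),
            "forest_area_ha": forest_area,
            "loss_area_ha": loss_area,
            "loss_fraction": loss_area / forest_area if forest_area > 0 else 0.0,
        })
    return pd.DataFrame(records)


@dataclass
class ReferenceMask:
    """Accepted reference cells (union of accepted polygons x forest mask)."""

    mask: np.ndarray
    accepted_polygons: list = field(default_factory=list)


def select_reference_sites(stats: pd.DataFrame, polygons, properties,
                           forest_mask,
                           min_forest_ha: float = min_treed_area_ha(),
                           max_loss_fraction: float = DEFAULT_MAX_LOSS_FRACTION,
                           allowed_iucn=DEFAULT_ALLOWED_IUCN) -> ReferenceMask:
    """Filter candidate polygons into the set of reference sites.

    Accepts primary polygons and protected polygons in an allowed IUCN
    category, with forest area >= ``min_forest_ha`` ("below 7.5 ha"
    excluded, so exactly 7.5 ha passes) and loss fraction <=
    ``max_loss_fraction`` (equal-or-less than 5% passes).
    """
    forest_mask = np.asarray(forest_mask, dtype=bool)
    by_id = {p.get("polygon_id"): (g, p)
             for g, p in zip(polygons, properties, strict=True)}
    accepted = []
    mask = np.zeros(forest_mask.shape, dtype=bool)
    for rec in stats.itertuples():
        if rec.origin == "protected" and rec.iucn_category not in allowed_iucn:
            continue
        if rec.origin not in ("primary", "protected"):
            continue
        if rec.forest_area_ha < min_forest_ha:
            continue
        if rec.loss_fraction > max_loss_fraction:
            continue
        geom, _ = by_id[rec.polygon_id]
        mask |= polygon_cell_mask(geom, forest_mask.shape)
        accepted.append(rec.polygon_id)
    mask &= forest_mask
    return ReferenceMask(mask=mask, accepted_polygons=accepted)


def apply_region_fallbacks(regions_with_sites, all_regions,
                           fallback_map: dict | None = None) -> dict:
    """Assign each region a source region with reference sites.

    Regions with own sites map to themselves; regions without sites use the
    fallback map; regions whose fallback target is itself empty (or that
    have no fallback entry) map to ``None`` (unresolvable -> highest
    uncertainty downstream).
    """
    if fallback_map is None:
        fallback_map = dict(DEFAULT_FALLBACKS)
    with_sites = set(regions_with_sites)
    assignment = {}
    for region in all_regions:
        if region in with_sites:
            assignment[region] = region
        else:
            target = fallback_map.get(region)
            assignment[region] = target if target in with_sites else None
    return assignment
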