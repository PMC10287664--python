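"""Forest ecosystem typology: forest land-cover classes x biogeographic regions.

Crossing the four forest classes with up to eleven regions yields up to 44
forest ecosystem types. Type identifiers are assigned deterministically as
``region_code * 10 + class_code`` so they are stable, human-readable and
reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import FOREST_CLASSES, FOREST_CODES, REGION_NAMES
from .raster import check_registration

log = logging.getLogger(__name__)


@dataclass
class TypologyGrid:
    """Per-cell forest-type identifier with its catalogue.

    ``type_id`` is 0 on non-forest cells; the catalogue has one row per
    occurring (forest class, region) pair with its area.
    """

    type_id: np.ndarray
    catalogue: pd.DataFrame  # type_id, forest_class, region, region_code, n_cells, area_ha
    cell_area_ha: float = 1.0

    @property
    def forest_mask(self) -> np.ndarray:
        return self.type_id > 0

    def cells_of(self, type_id: int) -> np.ndarray:
        """Boolean mask of the cells belonging to one type."""
        return self.type_id == type_id


def type_id_for(region_code: int, class_code: int) -> int:
    return region_code * 10 + class_code


def build_typology(land_cover, regions, cell_area_ha: float = 1.0) -> TypologyGrid:
    """Intersect forest land-cover classes with regions into a typology.

    Forest cells lacking region coverage (region code 0) are dropped from
    the typology, mirroring the exclusion of unmapped regions from the
    accounting area.
    """
    land_cover = np.asarray(land_cover)
    regions = np.asarray(regions)
    check_registration(land_cover, regions)

    forest = np.isin(land_cover, list(FOREST_CODES))
    covered = regions > 0
    dropped = int(np.count_nonzero(forest & ~covered))
    if dropped:
        log.warning("dropping %d forest cells without region coverage", dropped)

    valid = forest & covered
    type_id = np.zeros(land_cover.shape, dtype=np.int32)
    type_id[valid] = regions[valid].astype(np.int32) * 10 + land_cover[valid]

    ids, counts = np.unique(type_id[valid], return_counts=True)
    catalogue = pd.DataFrame({
        "type_id": ids.astype(int),
        "forest_class": [FOREST_CLASSES[t % 10] for t in ids],
        "region_code": [int(t // 10) for t in ids],
        "region": [REGION_NAMES[t // 10 - 1] for t in ids],
        "n_cells": counts.astype(int),
    })
    catalogue["area_ha"] = catalogue["n_cells"] * cell_area_ha
    return TypologyGrid(type_id=type_id, catalogue=catalogue,
                        cell_area_ha=cell_area_ha)
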