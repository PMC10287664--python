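"""Landscape-level condition variables: forest connectivity and naturalness.

Forest area density (FAD) is the proportion of forest cells inside a
square moving window (default 23 x 23 cells, i.e. a 529 ha neighbourhood
of 1 ha cells) centered on each cell, classified into six connectivity
classes. Landscape naturalness reclassifies the land cover into a 3-way
agriculture/natural/developed mosaic and reports the windowed proportion
of natural cells, binned into twelve naturalness categories.

Window counting uses an integer summed-area table, so the result equals
exhaustive per-cell counting exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    MOSAIC_AGRICULTURE,
    MOSAIC_DEVELOPED,
    MOSAIC_NATURAL,
)

#: Six connectivity classes over FAD percent (GuidosToolbox-style edges):
#: rare [0,10), patchy [10,40), transitional [40,60), dominant [60,90),
#: interior [90,100), intact exactly 100.
FAD_CLASS_NAMES = ["rare", "patchy", "transitional", "dominant",
                   "interior", "intact"]
FAD_CLASS_EDGES = [10.0, 40.0, 60.0, 90.0, 100.0]

#: Twelve naturalness category labels (percent), assigned by nearest value.
NATURALNESS_LEVELS = np.array([0, 5, 15, 25, 35, 45, 55, 65, 75, 85, 95, 100],
                              dtype=float)


@dataclass
class WindowSpec:
    """Square moving window; edge windows either shrink to the in-bounds
    part (default) or keep full size with zero padding."""

    size: int = 23
    edge_rule: str = "shrink"  # or "pad-zero"

    def __post_init__(self):
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 1")
        if self.edge_rule not in ("shrink", "pad-zero"):
            raise ValueError(f"unknown edge_rule {self.edge_rule!r}")

    @property
    def area_ha(self) -> float:
        """Neighbourhood area for 1-ha cells (23 x 23 -> 529 ha)."""
        return float(self.size * self.size)


def _box_counts(mask: np.ndarray, size: int) -> np.ndarray:
    """Exact in-window true-cell counts via an integer summed-area table."""
    m = np.asarray(mask, dtype=np.int64)
    rows, cols = m.shape
    sat = np.zeros((rows + 1, cols + 1), dtype=np.int64)
    np.cumsum(np.cumsum(m, axis=0), axis=1, out=sat[1:, 1:])
    h = size // 2
    r = np.arange(rows)
    c = np.arange(cols)
    r0 = np.clip(r - h, 0, rows)[:, None]
    r1 = np.clip(r + h + 1, 0, rows)[:, None]
    c0 = np.clip(c - h, 0, cols)[None, :]
    c1 = np.clip(c + h + 1, 0, cols)[None, :]
    return (sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0])


def window_proportion(mask, window: WindowSpec, domain=None) -> np.ndarray:
    """Percent of true ``mask`` cells in the window around each cell.

    Under the ``shrink`` rule the denominator is the number of in-bounds
    window cells; under ``pad-zero`` it is always ``size**2``. If ``domain``
    is given, cells outside it are set to NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    counts = _box_counts(mask, window.size)
    if window.edge_rule == "shrink":
        denom = _box_counts(np.ones_like(mask), window.size)
    else:
        denom = np.full(mask.shape, window.size ** 2, dtype=np.int64)
    percent = 100.0 * counts / denom
    if domain is not None:
        percent = np.where(np.asarray(domain, dtype=bool), percent, np.nan)
    return percent


def classify_fad(percent) -> np.ndarray:
    """Map FAD percent onto the six connectivity classes (codes 1..6)."""
    p = np.asarray(percent, dtype=float)
    cls = np.searchsorted(FAD_CLASS_EDGES, p, side="right") + 1
    cls = np.where(p == 100.0, 6, cls)  # intact is exactly 100
    return np.where(np.isnan(p), 0, cls).astype(np.int8)


@dataclass
class FADGrid:
    percent: np.ndarray   # NaN off the forest domain
    fad_class: np.ndarray  # 0 = outside domain


def forest_area_density(forest_mask, window: WindowSpec | None = None) -> FADGrid:
    """Forest area density over forest cells, with its 6-class map."""
    window = window or WindowSpec()
    pct = window_proportion(forest_mask, window, domain=forest_mask)
    return FADGrid(percent=pct, fad_class=classify_fad(pct))


def naturalness_category(percent) -> np.ndarray:
    """Nearest of the twelve naturalness levels; ties go to the upper level."""
    p = np.asarray(percent, dtype=float)
    idx = np.searchsorted(NATURALNESS_LEVELS, p)
    idx = np.clip(idx, 1, len(NATURALNESS_LEVELS) - 1)
    lower = NATURALNESS_LEVELS[idx - 1]
    upper = NATURALNESS_LEVELS[idx]
    take_upper = (upper - p) <= (p - lower)
    out = np.where(take_upper, upper, lower)
    return np.where(np.isnan(p), np.nan, out)


@dataclass
class NaturalnessGrid:
    percent_natural: np.ndarray
    category: np.ndarray


def naturalness(land_cover, window: WindowSpec | None = None) -> NaturalnessGrid:
    """Windowed proportion of natural cells in the 3-way landscape mosaic."""
    window = window or WindowSpec()
    lc = np.asarray(land_cover)
    known = MOSAIC_NATURAL | MOSAIC_AGRICULTURE | MOSAIC_DEVELOPED
    unknown = np.unique(lc[~np.isin(lc, list(known))])
    if unknown.size:
        raise ValueError(
            f"land cover codes not mapped to the 3-way mosaic: {unknown.tolist()}")
    natural = np.isin(lc, list(MOSAIC_NATURAL))
    pct = window_proportion(natural, window)
    return NaturalnessGrid(percent_natural=pct,
                           category=naturalness_category(pct))
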