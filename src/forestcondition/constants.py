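"""Shared vocabulary of the forest condition account.

Land-cover codes, biogeographic regions, the seven condition variables with
their native measurement ranges, and the default indicator weights used to
aggregate rescaled indicators into the condition index.
"""

# Land-cover codes on the abstract grid. 1-4 are the four forest classes
# (the CLC-style forest classes); 5-7 form the 3-way landscape mosaic
# together with the forest classes (forest counts as "natural").
LC_BROADLEAVED = 1
LC_CONIFEROUS = 2
LC_MIXED = 3
LC_TRANSITIONAL = 4
LC_AGRICULTURE = 5
LC_NATURAL = 6  # non-forest (semi-)natural: grassland, wetland, water ...
LC_DEVELOPED = 7

FOREST_CLASSES = {
    LC_BROADLEAVED: "broadleaved",
    LC_CONIFEROUS: "coniferous",
    LC_MIXED: "mixed",
    LC_TRANSITIONAL: "transitional",
}
FOREST_CODES = frozenset(FOREST_CLASSES)

#: 3-way landscape mosaic reclassification (forest classes are natural).
MOSAIC_NATURAL = frozenset({LC_BROADLEAVED, LC_CONIFEROUS, LC_MIXED,
                            LC_TRANSITIONAL, LC_NATURAL})
MOSAIC_AGRICULTURE = frozenset({LC_AGRICULTURE})
MOSAIC_DEVELOPED = frozenset({LC_DEVELOPED})

# The eleven biogeographic regions crossed with the four forest classes to
# form (up to) 44 forest ecosystem types. Region code r is 1-based index
# into this list; code 0 means "not covered by a region".
REGION_NAMES = [
    "Alpine",
    "Alpine-Scandinavia",
    "Arctic",
    "Atlantic",
    "BlackSea",
    "Boreal",
    "Continental",
    "Macaronesian",
    "Mediterranean",
    "Pannonian",
    "Steppic",
]
N_REGIONS_MAX = len(REGION_NAMES)

#: Regions without own reference sites borrow upper reference levels from
#: a climatically analogous region.
DEFAULT_FALLBACKS = {
    "Arctic": "Alpine-Scandinavia",
    "BlackSea": "Pannonian",
    "Steppic": "Pannonian",
}

# The seven condition variables, ordered as in the account tables.
VARIABLES = ["ndwi", "soc", "birds", "trees", "ndvi", "fad", "lm"]

#: Native measurement range (lo, hi) per variable.
VARIABLE_RANGES = {
    "ndwi": (-1.0, 1.0),    # normalized difference water index
    "soc": (0.0, 1.0),      # soil organic carbon, normalised
    "birds": (0.0, 22.0),   # threatened forest bird richness, species
    "trees": (0.0, 100.0),  # tree cover density, %
    "ndvi": (-1.0, 1.0),    # normalized difference vegetation index
    "fad": (0.0, 100.0),    # forest area density, %
    "lm": (0.0, 100.0),     # landscape-mosaic naturalness, %
}

#: Default indicator weights (rank-derived); sum to 1.
DEFAULT_WEIGHTS = {
    "ndwi": 0.08,
    "soc": 0.12,
    "birds": 0.22,
    "trees": 0.21,
    "ndvi": 0.13,
    "fad": 0.13,
    "lm": 0.11,
}

#: IUCN protected-area categories admitting a polygon as reference site.
DEFAULT_ALLOWED_IUCN = frozenset({"Ia", "Ib", "II"})

#: Canopy-cover threshold (%) separating open habitat from woodland.
DEFAULT_CANOPY_THRESHOLD = 20.0

#: Minimum treed area (ha) for a reference polygon: the smallest treed area
#: inside a 25 ha minimum mapping unit at a 30% canopy-cover criterion.
MIN_MAPPING_UNIT_HA = 25.0
CANOPY_DELINEATION_FRACTION = 0.30


def min_treed_area_ha(mapping_unit_ha: float = MIN_MAPPING_UNIT_HA,
                      canopy_fraction: float = CANOPY_DELINEATION_FRACTION) -> float:
    """Minimum treed area qualifying a mapped unit as forest (default 7.5 ha)."""
    return mapping_unit_ha * canopy_fraction


#: Maximum tolerated tree-cover-loss share of a reference polygon's forest.
DEFAULT_MAX_LOSS_FRACTION = 0.05

#: Accounting years carried by a scene.
YEARS = (2000, 2018)
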