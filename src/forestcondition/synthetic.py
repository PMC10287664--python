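"""Synthetic scene generation.

Builds fully synthetic landscapes with the statistical structure the
accounting pipeline assumes: a categorical land cover with four forest
classes embedded in an agriculture/natural/developed mosaic, contiguous
biogeographic regions, spatially autocorrelated condition variables that
are stochastically higher inside designated reference sites, sparse
tree-cover-loss patches, environmental gradients correlated with
reference-site placement, and an over-dispersed bird-richness table driven
by a known log-linear model (kept alongside the scene for recovery tests).

Spatial autocorrelation is produced by Gaussian smoothing of white noise;
reference polygons are rasterized blobs vectorized back to polygons, which
guarantees polygon/raster consistency.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from . import raster
from .constants import (
    LC_AGRICULTURE,
    LC_DEVELOPED,
    LC_NATURAL,
    FOREST_CODES,
    N_REGIONS_MAX,
    VARIABLE_RANGES,
    YEARS,
)

#: Condition variables generated directly (connectivity and naturalness are
#: computed downstream from the land cover).
GENERATED_VARIABLES = ["ndwi", "soc", "birds", "trees", "ndvi"]

#: The 15 candidate predictors of the bird-richness model.
BIRD_PREDICTORS = [
    "mean_temperature",
    "temperature_seasonality",
    "annual_precipitation",
    "precipitation_seasonality",
    "altitude",
    "urban_share",
    "cropland_share",
    "forest_share",
    "shrubland_share",
    "rivers_share",
    "sparse_veg_share",
    "grassland_share",
    "landcover_shannon",
    "ndvi_summer_mean",
    "ndvi_summer_range",
]


@dataclass
class VariableParams:
    """Generating parameters of one condition variable on its native scale."""

    mean: float
    spread: float          # std. dev. of the spatial field
    corr_range: float = 4.0  # Gaussian smoothing sigma, in cells
    drift: float = 0.0     # mean additive change from year 0 to year 1
    drift_spread: float = 0.0


def _default_variable_params() -> dict:
    return {
        "ndwi": VariableParams(0.30, 0.15, 4.0, drift=0.02, drift_spread=0.02),
        "soc": VariableParams(0.25, 0.10, 5.0, drift=0.01, drift_spread=0.02),
        "birds": VariableParams(4.0, 2.0, 4.0, drift=0.3, drift_spread=0.3),
        "trees": VariableParams(55.0, 15.0, 3.0, drift=2.0, drift_spread=2.0),
        "ndvi": VariableParams(0.55, 0.12, 4.0, drift=0.02, drift_spread=0.02),
    }


def _default_uplift() -> dict:
    # Additive shift inside reference sites, ~10% of each native scale:
    # reference forests sit closer to the natural end of every variable.
    return {"ndwi": 0.10, "soc": 0.10, "birds": 3.0, "trees": 15.0, "ndvi": 0.10}


@dataclass
class SceneConfig:
    """Configuration of a synthetic scene (defaults are the study conditions)."""

    grid_shape: tuple = (96, 96)
    cell_area_ha: float = 1.0
    n_regions: int = 11
    forest_fraction: float = 0.6
    reference_fraction: float = 0.08
    loss_fraction: float = 0.02
    variable_params: dict = field(default_factory=_default_variable_params)
    reference_uplift: dict = field(default_factory=_default_uplift)
    n_bird_obs: int = 3000
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        for name in ("forest_fraction", "reference_fraction", "loss_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 1 <= self.n_regions <= N_REGIONS_MAX:
            raise ValueError(f"n_regions must be in 1..{N_REGIONS_MAX}")
        if self.cell_area_ha <= 0:
            raise ValueError("cell_area_ha must be positive")


@dataclass
class Scene:
    """A co-registered bundle of grids, polygons and tables.

    All grids share shape and registration; ``variables[name][year]`` holds
    one grid per generated condition variable and accounting year.
    """

    config: SceneConfig
    land_cover: np.ndarray
    regions: np.ndarray
    variables: dict
    canopy_cover: np.ndarray
    loss_mask: np.ndarray
    elevation: np.ndarray
    slope: np.ndarray
    temperature: np.ndarray
    rainfall: np.ndarray
    pnv: np.ndarray
    reference_polygons: list          # shapely geometries
    reference_polygon_props: list     # dicts: polygon_id, origin, iucn_category
    bird_obs: pd.DataFrame
    bird_truth: dict                  # {"coefficients": {...}, "dispersion": f}
    reference_cell_mask: np.ndarray = None  # generator-truth reference cells

    @property
    def forest_mask_lc(self) -> np.ndarray:
        """Forest cells according to the land cover."""
        return np.isin(self.land_cover, list(FOREST_CODES))

    @property
    def environment(self) -> dict:
        return {"elevation": self.elevation, "slope": self.slope,
                "temperature": self.temperature, "rainfall": self.rainfall}

    # ---- persistence -----------------------------------------------------

    def save(self, directory) -> None:
        """Write the scene as a directory of TIFFs, GeoJSON, CSV + manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        grids = {
            "land_cover": self.land_cover, "regions": self.regions,
            "canopy_cover": self.canopy_cover, "loss_mask": self.loss_mask,
            "elevation": self.elevation, "slope": self.slope,
            "temperature": self.temperature, "rainfall": self.rainfall,
            "pnv": self.pnv, "reference_cell_mask": self.reference_cell_mask,
        }
        for name, g in grids.items():
            raster.write_grid(d / f"{name}.tif", g)
        for name, by_year in self.variables.items():
            for year, g in by_year.items():
                raster.write_grid(d / f"{name}_{year}.tif", g)
        raster.write_polygons(d / "reference_polygons.geojson",
                              self.reference_polygons,
                              self.reference_polygon_props)
        self.bird_obs.to_csv(d / "bird_obs.csv", index=False)
        cfg = dataclasses.asdict(self.config)  # recurses into VariableParams
        manifest = {"config": cfg, "bird_truth": self.bird_truth,
                    "years": list(YEARS),
                    "variables": sorted(self.variables)}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "Scene":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        cfg = manifest["config"]
        cfg["grid_shape"] = tuple(cfg["grid_shape"])
        cfg["variable_params"] = {k: VariableParams(**v)
                                  for k, v in cfg["variable_params"].items()}
        config = SceneConfig(**cfg)
        g = lambda name, dt: raster.read_grid(d / f"{name}.tif", dt)
        variables = {
            name: {year: g(f"{name}_{year}", float) for year in manifest["years"]}
            for name in manifest["variables"]
        }
        geoms, props = raster.read_polygons(d / "reference_polygons.geojson")
        return cls(
            config=config,
            land_cover=g("land_cover", np.int16),
            regions=g("regions", np.int16),
            variables=variables,
            canopy_cover=g("canopy_cover", float),
            loss_mask=g("loss_mask", None).astype(bool),
            elevation=g("elevation", float),
            slope=g("slope", float),
            temperature=g("temperature", float),
            rainfall=g("rainfall", float),
            pnv=g("pnv", np.int16),
            reference_polygons=geoms,
            reference_polygon_props=props,
            bird_obs=pd.read_csv(d / "bird_obs.csv"),
            bird_truth=manifest["bird_truth"],
            reference_cell_mask=g("reference_cell_mask", None).astype(bool),
        )


# ---------------------------------------------------------------------------
# field helpers


def correlated_field(rng, shape_, corr_range) -> np.ndarray:
    """Standardized spatially autocorrelated field (smoothed white noise)."""
    white = rng.standard_normal(shape_)
    if corr_range and corr_range > 0:
        f = ndimage.gaussian_filter(white, sigma=corr_range, mode="reflect")
    else:
        f = white
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def _quantile_split(values, fractions):
    """Assign 1..k labels by quantile bins of `values` (fractions sum to 1)."""
    qs = np.cumsum(fractions)[:-1]
    edges = np.quantile(values, qs)
    return np.searchsorted(edges, values, side="right") + 1


# ---------------------------------------------------------------------------
# bird model truth & simulation


def generate_bird_truth(config: SceneConfig | None = None) -> tuple[dict, float]:
    """True generating model of threatened-bird richness.

    Returns ``(coefficients, dispersion)``: a log-linear predictor on three
    of the 15 candidate predictors, with one quadratic term, and a
    quasi-Poisson dispersion > 1. Quadratic terms act on the centered
    predictor (predictors are generated standardized).
    """
    coefficients = {
        "(Intercept)": float(np.log(4.0)),
        "forest_share": 0.45,
        "ndvi_summer_mean": 0.30,
        "mean_temperature": 0.35,
        "mean_temperature^2": -0.20,
    }
    dispersion = 2.0
    return coefficients, dispersion


def simulate_quasipoisson(rng, mu, dispersion):
    """Draw counts with mean ``mu`` and variance ``dispersion * mu``.

    Uses the gamma-Poisson (NB1) mixture: lambda ~ Gamma(mu/(phi-1), phi-1),
    X | lambda ~ Poisson(lambda). For phi == 1 this is plain Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    if dispersion == 1.0:
        return rng.poisson(mu)
    shape_par = mu / (dispersion - 1.0)
    lam = rng.gamma(shape_par, dispersion - 1.0)
    return rng.poisson(lam)


def generate_bird_table(n, rng, coefficients=None, dispersion=None,
                        include_lonlat=False) -> pd.DataFrame:
    """Simulate the gridded bird-observation table.

    Predictors are standardized with mild cross-correlation; counts are
    over-dispersed draws from the log-linear truth. With
    ``include_lonlat=True`` two coordinate columns nearly collinear with the
    climate predictors are appended (17 predictors), mirroring raw survey
    tables before collinearity pruning.
    """
    if coefficients is None or dispersion is None:
        coefficients, dispersion = generate_bird_truth()
    X = pd.DataFrame(rng.standard_normal((n, len(BIRD_PREDICTORS))),
                     columns=BIRD_PREDICTORS)
    # mild realistic correlation among land-shares, kept below the point
    # where an inactive share would outrank an active predictor marginally
    X["cropland_share"] -= 0.25 * X["forest_share"]
    X["grassland_share"] += 0.3 * X["cropland_share"]
    X = (X - X.mean()) / X.std(ddof=0)
    lp = np.full(n, coefficients["(Intercept)"])
    for term, beta in coefficients.items():
        if term == "(Intercept)":
            continue
        if term.endswith("^2"):
            lp += beta * X[term[:-2]].to_numpy() ** 2
        else:
            lp += beta * X[term].to_numpy()
    mu = np.exp(lp)
    threatened = simulate_quasipoisson(rng, mu, dispersion)
    total = threatened + rng.poisson(10.0, size=n)
    out = pd.DataFrame({"cell_id": np.arange(n),
                        "total_richness": total,
                        "threatened_richness": threatened})
    out = pd.concat([out, X], axis=1)
    if include_lonlat:
        out["longitude"] = (X["temperature_seasonality"]
                            + 0.3 * rng.standard_normal(n))
        out["latitude"] = (-X["mean_temperature"]
                           + 0.3 * rng.standard_normal(n))
    return out


# ---------------------------------------------------------------------------
# scene generation


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a deterministic synthetic scene from its configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape_ = tuple(config.grid_shape)
    rows, cols = shape_
    n_cells = rows * cols

    # --- regions: nearest-seed tessellation (contiguous) ---
    seeds_rc = rng.uniform(0, [rows, cols], size=(config.n_regions, 2))
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = ((rr[None] - seeds_rc[:, 0, None, None]) ** 2
          + (cc[None] - seeds_rc[:, 1, None, None]) ** 2)
    regions = (np.argmin(d2, axis=0) + 1).astype(np.int16)

    # --- environmental gradients ---
    elevation = np.clip(800 + 600 * correlated_field(rng, shape_, 8), 0, None)
    slope = np.abs(correlated_field(rng, shape_, 3)) * 8.0
    temperature = (9.0 - 0.006 * elevation
                   + 1.5 * correlated_field(rng, shape_, 8))
    rainfall = np.clip(700 + 300 * correlated_field(rng, shape_, 8)
                       + 0.2 * elevation, 50, None)

    # --- land cover ---
    land_cover = np.empty(shape_, dtype=np.int16)
    forest_field = correlated_field(rng, shape_, 5)
    if config.forest_fraction >= 1.0:
        forest = np.ones(shape_, bool)
    elif config.forest_fraction <= 0.0:
        forest = np.zeros(shape_, bool)
    else:
        thr = np.quantile(forest_field, 1 - config.forest_fraction)
        forest = forest_field > thr
    class_field = correlated_field(rng, shape_, 4)
    if forest.any():
        labels = _quantile_split(class_field[forest], [0.3, 0.3, 0.2, 0.2])
        land_cover[forest] = labels
    nonforest = ~forest
    if nonforest.any():
        nf_field = correlated_field(rng, shape_, 4)
        nf_labels = _quantile_split(nf_field[nonforest], [0.45, 0.45, 0.10])
        land_cover[nonforest] = np.array(
            [LC_AGRICULTURE, LC_NATURAL, LC_DEVELOPED])[nf_labels - 1]

    # --- potential natural vegetation: noisy replica of the class pattern ---
    pnv = np.zeros(shape_, dtype=np.int16)
    pnv_field = class_field + 0.6 * correlated_field(rng, shape_, 4)
    pnv_labels = _quantile_split(pnv_field.ravel(), [0.3, 0.3, 0.2, 0.2])
    pnv[:] = pnv_labels.reshape(shape_)

    # --- reference sites: blobs in forest, biased uphill/colder ---
    z_elev = (elevation - elevation.mean()) / (elevation.std() or 1.0)
    # long-range score concentrates each stratum's top tail into a few
    # cohesive blobs large enough to behave like real protected sites
    ref_score = correlated_field(rng, shape_, 8) + 0.6 * z_elev
    ref_cells = np.zeros(shape_, bool)
    if forest.any() and config.reference_fraction > 0:
        # per-stratum selection: remnant natural forest exists in most
        # region x class strata, and a real site has a minimum viable
        # extent — strata too small to host one get none, exercising the
        # downstream area filter and fallback machinery
        min_site_cells = 9
        for code in range(1, config.n_regions + 1):
            for cls in range(1, 5):
                sel_idx = np.flatnonzero(
                    ((regions == code) & (land_cover == cls)).ravel())
                n = sel_idx.size
                k = max(int(round(config.reference_fraction * n)),
                        min_site_cells)
                if n < 2 * min_site_cells:
                    continue
                top = sel_idx[np.argsort(ref_score.ravel()[sel_idx])[-k:]]
                ref_cells.ravel()[top] = True
        ref_cells &= forest
    polygons, props = _vectorize_reference_blobs(ref_cells, rng)

    # --- canopy cover & loss ---
    canopy = np.where(
        forest,
        60 + 20 * correlated_field(rng, shape_, 3),
        8 + 8 * correlated_field(rng, shape_, 3),
    )
    canopy = np.clip(canopy, 0, 100)
    loss_mask = np.zeros(shape_, bool)
    if forest.any() and config.loss_fraction > 0:
        # disturbance concentrates outside remnant natural sites (their
        # having escaped loss is what qualifies them as reference sites)
        loss_field = correlated_field(rng, shape_, 1.5) - 1.5 * ref_cells
        thr = np.quantile(loss_field[forest], 1 - config.loss_fraction)
        loss_mask = forest & (loss_field > thr)

    # --- condition variables, two accounting years ---
    variables = {}
    for name, p in config.variable_params.items():
        lo, hi = VARIABLE_RANGES[name]
        base = p.mean + p.spread * correlated_field(rng, shape_, p.corr_range)
        base = base + config.reference_uplift.get(name, 0.0) * ref_cells
        y0 = np.clip(base, lo, hi)
        drift = p.drift + p.drift_spread * correlated_field(
            rng, shape_, p.corr_range)
        y1 = np.clip(y0 + drift, lo, hi)
        variables[name] = {YEARS[0]: y0, YEARS[1]: y1}

    # --- bird observations with known truth ---
    coefficients, dispersion = generate_bird_truth(config)
    bird_obs = generate_bird_table(config.n_bird_obs, rng,
                                   coefficients, dispersion)

    return Scene(
        config=config, land_cover=land_cover, regions=regions,
        variables=variables, canopy_cover=canopy, loss_mask=loss_mask,
        elevation=elevation, slope=slope, temperature=temperature,
        rainfall=rainfall, pnv=pnv,
        reference_polygons=polygons, reference_polygon_props=props,
        bird_obs=bird_obs,
        bird_truth={"coefficients": coefficients, "dispersion": dispersion},
        reference_cell_mask=ref_cells,
    )


def _vectorize_reference_blobs(ref_cells, rng):
    """Vectorize connected reference blobs into attributed polygons.

    Components alternate between primary-forest and protected-area origin;
    protected polygons draw an IUCN category with most in the strict
    classes (Ia/Ib/II) so that scenes contain admissible reference sites.
    """
    labels, n = ndimage.label(ref_cells, structure=np.ones((3, 3)))
    polygons, props = [], []
    iucn_cats = np.array(["Ia", "Ib", "II", "IV", "V"])
    iucn_p = np.array([0.25, 0.2, 0.35, 0.1, 0.1])
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        geom = unary_union([box(c, r, c + 1, r + 1) for r, c in cells])
        origin = "primary" if rng.random() < 0.5 else "protected"
        iucn = str(rng.choice(iucn_cats, p=iucn_p)) if origin == "protected" else None
        polygons.append(geom)
        props.append({"polygon_id": int(lab), "origin": origin,
                      "iucn_category": iucn})
    return polygons, props
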