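"""Facade model for the full condition-accounting pipeline.

`ForestConditionModel` wraps a `Scene` together with the accounting
parameters (canopy threshold, reference-site filters, moving-window size,
indicator weights, region fallbacks); `fit()` runs typology, reference
site selection, reference levels, landscape metrics, rescaling and
aggregation for both accounting years and returns a
`ForestConditionResults` that carries the account table, change
statistics and uncertainty assessment, and offers the significance test,
the sensitivity analysis, a text `summary()` and quick-look plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounts, condition, raster, reference_levels, reference_sites
from .accounts import ChangeSummary
from .condition import ConditionIndexGrid, WeightTable, default_weights
from .constants import (
    DEFAULT_ALLOWED_IUCN,
    DEFAULT_CANOPY_THRESHOLD,
    DEFAULT_MAX_LOSS_FRACTION,
    min_treed_area_ha,
)
from .landscape import WindowSpec, forest_area_density, naturalness
from .synthetic import Scene
from .typology import TypologyGrid, build_typology
from .uncertainty import assess_uncertainty


class ForestConditionModel:
    """Condition-accounting model over a scene.

    Parameters default to the standard account configuration: 20% canopy
    threshold, 7.5 ha minimum treed area, 5% maximum loss share, IUCN
    Ia/Ib/II, a 23-cell (529 ha) window and the rank-derived weights.
    """

    def __init__(self, scene: Scene, weights: WeightTable | None = None,
                 canopy_threshold: float = DEFAULT_CANOPY_THRESHOLD,
                 min_forest_ha: float | None = None,
                 max_loss_fraction: float = DEFAULT_MAX_LOSS_FRACTION,
                 allowed_iucn=DEFAULT_ALLOWED_IUCN,
                 window: WindowSpec | None = None,
                 fallback_map: dict | None = None):
        self.scene = scene
        self.weights = weights or default_weights()
        self.canopy_threshold = canopy_threshold
        self.min_forest_ha = (min_treed_area_ha() if min_forest_ha is None
                              else min_forest_ha)
        self.max_loss_fraction = max_loss_fraction
        self.allowed_iucn = allowed_iucn
        self.window = window or WindowSpec()
        self.fallback_map = fallback_map

    @classmethod
    def from_directory(cls, path, **kwargs) -> "ForestConditionModel":
        return cls(Scene.load(path), **kwargs)

    def fit(self) -> "ForestConditionResults":
        scene = self.scene
        cell_area = scene.config.cell_area_ha
        years = sorted(next(iter(scene.variables.values())))
        ref_year = years[0]

        typology = build_typology(scene.land_cover, scene.regions, cell_area)

        # reference sites
        canopy_forest = reference_sites.forest_mask_from_canopy(
            scene.canopy_cover, self.canopy_threshold)
        stats = reference_sites.summarize_polygons(
            scene.reference_polygons, scene.reference_polygon_props,
            canopy_forest, scene.loss_mask, cell_area)
        refmask = reference_sites.select_reference_sites(
            stats, scene.reference_polygons, scene.reference_polygon_props,
            canopy_forest & typology.forest_mask,
            min_forest_ha=self.min_forest_ha,
            max_loss_fraction=self.max_loss_fraction,
            allowed_iucn=self.allowed_iucn)

        # landscape metrics per year (land cover is static across years here,
        # so the metrics are shared; recomputed per year if that changes)
        fad = forest_area_density(typology.forest_mask, self.window)
        nat = naturalness(scene.land_cover, self.window)
        variables_by_year = {}
        for year in years:
            v = {name: by_year[year] for name, by_year in scene.variables.items()}
            v["fad"] = fad.percent
            v["lm"] = nat.category
            variables_by_year[year] = v

        # reference levels on the reference year
        regions_present = typology.catalogue["region"].unique()
        regions_with_sites = typology.catalogue.loc[
            [bool((typology.cells_of(t) & refmask.mask).any())
             for t in typology.catalogue["type_id"]], "region"].unique()
        fallbacks = reference_sites.apply_region_fallbacks(
            regions_with_sites, regions_present, self.fallback_map)
        lower = reference_levels.lower_levels(
            variables_by_year[ref_year], typology)
        upper = reference_levels.upper_levels(
            variables_by_year[ref_year], typology, refmask.mask, fallbacks)
        levels = reference_levels.reference_level_table(lower, upper)

        # indicators and index per year
        indicators_by_year = {
            year: condition.indicator_stack(variables_by_year[year], levels,
                                            typology)
            for year in years
        }
        index_by_year = {
            year: condition.aggregate_index(indicators_by_year[year],
                                            self.weights, typology)
            for year in years
        }

        account = accounts.build_account(typology, variables_by_year, levels,
                                         indicators_by_year, index_by_year)
        change = accounts.change_stats(index_by_year[years[0]].index,
                                       index_by_year[years[-1]].index) \
            if len(years) > 1 else None
        unc = assess_uncertainty(typology, refmask.mask, scene.environment,
                                 scene.pnv, cell_area)

        return ForestConditionResults(
            model=self, typology=typology, reference_mask=refmask,
            polygon_stats=stats, fallbacks=fallbacks, levels=levels,
            weights=self.weights, variables_by_year=variables_by_year,
            indicators_by_year=indicators_by_year,
            index_by_year=index_by_year, account=account, change=change,
            uncertainty=unc, years=years,
        )


@dataclass
class ForestConditionResults:
    """Outputs of a fitted condition account."""

    model: ForestConditionModel
    typology: TypologyGrid
    reference_mask: reference_sites.ReferenceMask
    polygon_stats: pd.DataFrame
    fallbacks: dict
    levels: pd.DataFrame
    weights: WeightTable
    variables_by_year: dict
    indicators_by_year: dict
    index_by_year: dict[int, ConditionIndexGrid]
    account: pd.DataFrame
    change: ChangeSummary | None
    uncertainty: pd.DataFrame
    years: list = field(default_factory=list)

    # -- derived analyses --------------------------------------------------

    def mwu_test(self, n_samples: int = 1000,
                 min_separation_cells: float | None = None,
                 seed: int = 0, independent_samples: bool = True) -> pd.DataFrame:
        if min_separation_cells is None:
            min_separation_cells = float(self.model.window.size)
        y0, y1 = self.years[0], self.years[-1]
        return accounts.mwu_change_test(
            self.index_by_year[y0].index, self.index_by_year[y1].index,
            self.typology, n_samples=n_samples,
            min_separation_cells=min_separation_cells, seed=seed,
            independent_samples=independent_samples)

    def sensitivity(self, year: int | None = None) -> pd.DataFrame:
        from .sensitivity import run_oat
        year = self.years[0] if year is None else year
        return run_oat(self.variables_by_year[year], self.typology,
                       self.levels, self.weights)

    def index_mean(self, year: int) -> float:
        grid = self.index_by_year[year].index
        if not np.any(~np.isnan(grid)):
            return np.nan
        return float(np.nanmean(grid))

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = ["Forest condition account",
                 "========================",
                 f"forest types: {len(self.typology.catalogue)}",
                 f"forest area (ha): {self.typology.catalogue['area_ha'].sum():.0f}",
                 f"reference polygons accepted: "
                 f"{len(self.reference_mask.accepted_polygons)} / "
                 f"{len(self.polygon_stats)}",
                 f"reference cells: {int(self.reference_mask.mask.sum())}"]
        for year in self.years:
            per_type = self.index_by_year[year].per_type_mean
            lines.append(f"condition index {year}: "
                         f"area mean {self.index_mean(year):.3f}, "
                         f"type-average {per_type.mean():.3f}")
        if self.change is not None:
            c = self.change
            lines += [
                f"change {self.years[0]}->{self.years[-1]}: "
                f"{c.mean_change_pts:+.1f} points x100",
                f"  area increasing {c.share_increasing_pct:.1f}% "
                f"(mean {c.mean_change_increasing_pts:+.1f}), "
                f"decreasing {c.share_decreasing_pct:.1f}% "
                f"(mean {c.mean_change_decreasing_pts:+.1f})",
                f"  loss > 10 points in {c.share_loss_gt_threshold_pct:.1f}% of area",
            ]
        counts = self.uncertainty["level"].value_counts().sort_index()
        lines.append("uncertainty levels (types): "
                     + ", ".join(f"L{k}: {v}" for k, v in counts.items()))
        return "\n".join(lines)

    def plot_index(self, year: int | None = None, ax=None):
        """Quick-look map of the condition index."""
        import matplotlib.pyplot as plt
        year = self.years[-1] if year is None else year
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.index_by_year[year].index, vmin=0, vmax=1,
                       cmap="viridis")
        ax.set_title(f"Forest condition index {year}")
        plt.colorbar(im, ax=ax, label="index")
        return ax

    def plot_change(self, ax=None):
        import matplotlib.pyplot as plt
        y0, y1 = self.years[0], self.years[-1]
        ch = accounts.change_points(self.index_by_year[y0].index,
                                    self.index_by_year[y1].index)
        if ax is None:
            _, ax = plt.subplots()
        lim = np.nanmax(np.abs(ch)) if np.isfinite(ch).any() else 1.0
        im = ax.imshow(ch, cmap="RdBu", vmin=-lim, vmax=lim)
        ax.set_title(f"Condition change {y0}-{y1} (points x100)")
        import matplotlib.pyplot as _plt
        _plt.colorbar(im, ax=ax, label="points x100")
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, outdir) -> None:
        """Write account artifacts: CSV tables and TIFF maps."""
        d = Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        raster.write_grid(d / "typology.tif", self.typology.type_id)
        self.typology.catalogue.to_csv(d / "typology_catalogue.csv", index=False)
        raster.write_grid(d / "reference_mask.tif", self.reference_mask.mask)
        self.polygon_stats.to_csv(d / "polygon_stats.csv", index=False)
        self.levels.to_csv(d / "reference_levels.csv", index=False)
        self.weights.weights.rename("weight").to_csv(d / "weights.csv")
        for year in self.years:
            raster.write_grid(d / f"index_{year}.tif",
                              self.index_by_year[year].index)
        if len(self.years) > 1:
            ch = accounts.change_points(
                self.index_by_year[self.years[0]].index,
                self.index_by_year[self.years[-1]].index)
            raster.write_grid(d / "change_points.tif", ch)
        self.account.to_csv(d / "account.csv", index=False)
        self.uncertainty.to_csv(d / "uncertainty.csv", index=False)
        (d / "summary.txt").write_text(self.summary() + "\n")
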