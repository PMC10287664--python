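"""Reference-site selection: canopy threshold, polygon statistics, the
admission filters and their boundary behaviour, and region fallbacks."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from forestcondition.reference_sites import (
    apply_region_fallbacks,
    forest_mask_from_canopy,
    polygon_cell_mask,
    select_reference_sites,
    summarize_polygons,
)


class TestCanopyMask:
    def test_boundary_is_open_habitat(self):
        # exactly 20% canopy is the open-habitat limit -> non-forest
        assert not forest_mask_from_canopy(np.array([[20.0]]))[0, 0]
        assert forest_mask_from_canopy(np.array([[20.0001]]))[0, 0]
        assert forest_mask_from_canopy(np.array([[100.0]]))[0, 0]

    def test_uniform_cover(self):
        assert forest_mask_from_canopy(np.full((10, 10), 50.0)).sum() == 100

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            forest_mask_from_canopy(np.array([[101.0]]))
        with pytest.raises(ValueError):
            forest_mask_from_canopy(np.array([[-1.0]]))


def _stats_for(forest, loss, geoms, props, cell_area=1.0):
    return summarize_polygons(geoms, props, forest, loss, cell_area)


class TestPolygonStats:
    def test_counting_oracle(self):
        forest = np.zeros((10, 10), bool)
        forest[0:4, 0:5] = True          # 20 forest cells
        loss = np.zeros((10, 10), bool)
        loss[0, 0] = True                # 1 of them lost
        geom = box(0, 0, 5, 4)
        st = _stats_for(forest, loss, [geom], [{"polygon_id": 1,
                                                "origin": "primary",
                                                "iucn_category": None}])
        assert st.loc[0, "forest_area_ha"] == 20
        assert st.loc[0, "loss_fraction"] == pytest.approx(0.05)

    def test_no_loss_and_no_forest(self):
        forest = np.zeros((6, 6), bool)
        forest[:2] = True
        loss = np.zeros((6, 6), bool)
        st = _stats_for(forest, loss,
                        [box(0, 0, 6, 2), box(0, 3, 6, 6)],
                        [{"polygon_id": 1, "origin": "primary"},
                         {"polygon_id": 2, "origin": "primary"}])
        assert st.loc[0, "loss_fraction"] == 0.0
        assert st.loc[1, "forest_area_ha"] == 0.0

    def test_polygon_outside_extent_zero_stats(self):
        forest = np.ones((5, 5), bool)
        st = _stats_for(forest, np.zeros((5, 5), bool),
                        [box(100, 100, 110, 110)],
                        [{"polygon_id": 9, "origin": "primary"}])
        assert st.loc[0, "forest_area_ha"] == 0.0

    def test_cell_center_rule_matches_pointwise_oracle(self):
        """Vectorized membership equals per-cell shapely containment."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            x0, y0 = rng.uniform(0, 20, 2)
            w, h = rng.uniform(1, 10, 2)
            geom = box(x0, y0, x0 + w, y0 + h).union(
                Point(*rng.uniform(0, 30, 2)).buffer(rng.uniform(1, 6)))
            mask = polygon_cell_mask(geom, (30, 30))
            for r in range(30):
                for c in range(30):
                    assert mask[r, c] == geom.contains(Point(c + 0.5, r + 0.5))


def _run_selection(stats_rows, forest=None, **kwargs):
    geoms, props, records = [], [], []
    for i, row in enumerate(stats_rows, start=1):
        geoms.append(box(0, 0, 1, 1))
        props.append({"polygon_id": i, "origin": row.get("origin", "primary"),
                      "iucn_category": row.get("iucn_category")})
        records.append({"polygon_id": i, "origin": props[-1]["origin"],
                        "iucn_category": props[-1]["iucn_category"],
                        "forest_area_ha": row["forest_area_ha"],
                        "loss_area_ha": row.get("loss_area_ha", 0.0),
                        "loss_fraction": row.get("loss_fraction", 0.0)})
    forest = np.ones((3, 3), bool) if forest is None else forest
    return select_reference_sites(pd.DataFrame(records), geoms, props,
                                  forest, **kwargs)


class TestSelectionFilters:
    def test_area_boundary_inclusive(self):
        # "below 7.5 ha" excluded, so exactly 7.5 ha passes
        r = _run_selection([{"forest_area_ha": 7.5},
                            {"forest_area_ha": 7.4999}])
        assert r.accepted_polygons == [1]

    def test_iucn_category_gate(self):
        r = _run_selection([
            {"origin": "protected", "iucn_category": "IV",
             "forest_area_ha": 100.0},
            {"origin": "protected", "iucn_category": "II",
             "forest_area_ha": 100.0},
            {"origin": "primary", "forest_area_ha": 100.0},
        ])
        assert r.accepted_polygons == [2, 3]

    def test_loss_boundary_equal_or_less(self):
        r = _run_selection([{"forest_area_ha": 100, "loss_fraction": 0.05},
                            {"forest_area_ha": 100, "loss_fraction": 0.0501}])
        assert r.accepted_polygons == [1]

    def test_mask_subset_of_forest_mask(self, small_scene):
        from forestcondition.reference_sites import forest_mask_from_canopy
        forest = forest_mask_from_canopy(small_scene.canopy_cover)
        st = summarize_polygons(small_scene.reference_polygons,
                                small_scene.reference_polygon_props,
                                forest, small_scene.loss_mask)
        r = select_reference_sites(st, small_scene.reference_polygons,
                                   small_scene.reference_polygon_props, forest)
        assert not (r.mask & ~forest).any()

    @pytest.mark.parametrize("tighter", [
        dict(min_forest_ha=20.0), dict(max_loss_fraction=0.01),
        dict(allowed_iucn=frozenset({"Ia"}))])
    def test_tightening_filters_is_monotone(self, small_scene, tighter):
        forest = forest_mask_from_canopy(small_scene.canopy_cover)
        st = summarize_polygons(small_scene.reference_polygons,
                                small_scene.reference_polygon_props,
                                forest, small_scene.loss_mask)
        base = select_reference_sites(
            st, small_scene.reference_polygons,
            small_scene.reference_polygon_props, forest, min_forest_ha=2.0)
        tight = select_reference_sites(
            st, small_scene.reference_polygons,
            small_scene.reference_polygon_props, forest,
            **{"min_forest_ha": 2.0, **tighter})
        assert set(tight.accepted_polygons) <= set(base.accepted_polygons)


class TestFallbacks:
    def test_default_map(self):
        a = apply_region_fallbacks(
            ["Alpine-Scandinavia", "Pannonian", "Boreal"],
            ["Arctic", "BlackSea", "Steppic", "Boreal", "Mediterranean"])
        assert a["Arctic"] == "Alpine-Scandinavia"
        assert a["BlackSea"] == a["Steppic"] == "Pannonian"
        assert a["Boreal"] == "Boreal"          # own sites -> itself
        assert a["Mediterranean"] is None       # no sites, no fallback

    def test_empty_fallback_target_unresolvable(self):
        a = apply_region_fallbacks([], ["Arctic"])
        assert a["Arctic"] is None
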