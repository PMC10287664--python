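"""One-at-a-time sensitivity: perturbation mechanics and the OAT table."""

import numpy as np
import pandas as pd
import pytest

from forestcondition.condition import WeightTable, default_weights, rescale
from forestcondition.constants import VARIABLES
from forestcondition.sensitivity import (
    perturb_reference_level,
    perturb_weight,
    run_oat,
    summarize_oat,
)
from forestcondition.typology import build_typology


class TestPerturbWeight:
    def test_two_weight_example(self):
        w = WeightTable(pd.Series({"a": 0.5, "b": 0.5}))
        out = perturb_weight(w, "a").weights
        assert out["a"] == pytest.approx(0.55)
        assert out["b"] == pytest.approx(0.45)

    @pytest.mark.parametrize("k", VARIABLES)
    def test_sum_preserved_for_default_weights(self, k):
        out = perturb_weight(default_weights(), k).weights
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out[k] == pytest.approx(1.1 * default_weights().weights[k])

    def test_zero_weight_is_fixed_point(self):
        w = WeightTable(pd.Series({"a": 0.0, "b": 1.0}))
        out = perturb_weight(w, "a").weights
        pd.testing.assert_series_equal(out, w.weights)

    def test_overflow_rejected(self):
        w = WeightTable(pd.Series({"a": 0.95, "b": 0.05}))
        with pytest.raises(ValueError):
            perturb_weight(w, "a")

    def test_others_keep_relative_ratios(self):
        out = perturb_weight(default_weights(), "soc").weights
        base = default_weights().weights
        ratios = (out / base).drop("soc")
        assert ratios.max() - ratios.min() < 1e-12


class TestPerturbLevels:
    def _levels(self):
        return pd.DataFrame({
            "type_id": [11, 11, 12], "variable": ["soc", "ndvi", "soc"],
            "V_L": [0.0, 0.2, 0.1], "V_H": [10.0, 0.8, 0.9]})

    def test_upper_decreased(self):
        out = perturb_reference_level(self._levels(), 11, "soc", "upper")
        assert out.loc[0, "V_H"] == pytest.approx(9.0)

    def test_zero_lower_fixed_point_and_locality(self):
        out = perturb_reference_level(self._levels(), 11, "soc", "lower")
        assert out.loc[0, "V_L"] == 0.0
        pd.testing.assert_frame_equal(
            out.drop(columns="degenerate").iloc[1:], self._levels().iloc[1:])

    def test_degenerate_flagged_and_clipped(self):
        levels = pd.DataFrame({"type_id": [11], "variable": ["soc"],
                               "V_L": [0.85], "V_H": [0.9]})
        out = perturb_reference_level(levels, 11, "soc", "lower")
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "V_H"] == out.loc[0, "V_L"]

    def test_missing_row_raises(self):
        with pytest.raises(KeyError):
            perturb_reference_level(self._levels(), 99, "soc", "upper")


def _oat_inputs(shape=(10, 10), seed=0):
    rng = np.random.default_rng(seed)
    lc = rng.choice([1, 2], shape).astype(np.int16)
    rg = np.ones(shape, np.int16)
    t = build_typology(lc, rg)
    variables = {v: rng.random(shape) for v in VARIABLES}
    levels = pd.DataFrame([
        {"type_id": tid, "variable": v, "V_L": 0.1, "V_H": 0.9}
        for tid in t.catalogue["type_id"] for v in VARIABLES])
    return variables, t, levels


class TestRunOAT:
    def test_21_rows_per_type(self):
        variables, t, levels = _oat_inputs()
        out = run_oat(variables, t, levels, default_weights())
        assert (out.groupby("type_id").size() == 21).all()
        assert set(out["parameter"]) == {"lower+10%", "upper-10%",
                                         "weight+10%"}

    def test_consensus_null_for_weight_perturbations(self):
        rng = np.random.default_rng(1)
        lc = np.ones((6, 6), np.int16)
        t = build_typology(lc, np.ones((6, 6), np.int16))
        variables = {v: np.full((6, 6), 0.5) for v in VARIABLES}
        levels = pd.DataFrame([{"type_id": 11, "variable": v,
                                "V_L": 0.0, "V_H": 1.0} for v in VARIABLES])
        out = run_oat(variables, t, levels, default_weights())
        wrows = out[out["parameter"] == "weight+10%"]
        np.testing.assert_allclose(wrows["pct_deviation"], 0.0, atol=1e-10)

    def test_saturated_indicator_immune_to_lower_perturbation(self):
        lc = np.ones((4, 4), np.int16)
        t = build_typology(lc, np.ones((4, 4), np.int16))
        variables = {v: np.full((4, 4), 5.0) for v in VARIABLES}
        levels = pd.DataFrame([{"type_id": 11, "variable": v,
                                "V_L": 1.0, "V_H": 2.0} for v in VARIABLES])
        out = run_oat(variables, t, levels, default_weights())
        low = out[out["parameter"] == "lower+10%"]
        np.testing.assert_allclose(low["pct_deviation"], 0.0, atol=1e-12)

    def test_matches_independent_recompute(self):
        """Every OAT row equals a from-scratch rescale+aggregate with the
        perturbed parameter (independent double-loop recomputation)."""
        variables, t, levels = _oat_inputs((20, 20), seed=3)
        w = default_weights().weights
        out = run_oat(variables, t, levels, default_weights())
        for row in out.itertuples():
            cells = np.argwhere(t.type_id == row.type_id)
            vl = {v: 0.1 for v in VARIABLES}
            vh = {v: 0.9 for v in VARIABLES}
            ww = dict(w)
            if row.parameter == "lower+10%":
                vl[row.indicator] *= 1.1
            elif row.parameter == "upper-10%":
                vh[row.indicator] *= 0.9
            else:
                wk = ww[row.indicator]
                for v in VARIABLES:
                    ww[v] = ww[v] * (1 - 1.1 * wk) / (1 - wk)
                ww[row.indicator] = 1.1 * wk
            total = 0.0
            for r, c in cells:
                total += sum(ww[v] * rescale(variables[v][r, c], vl[v], vh[v])
                             for v in VARIABLES)
            expected = total / len(cells)
            assert row.index_perturbed == pytest.approx(expected, abs=1e-10)

    def test_direction_of_weight_perturbation(self):
        """Raising w_k moves the index toward the k-th indicator mean."""
        variables, t, levels = _oat_inputs(seed=4)
        out = run_oat(variables, t, levels, default_weights())
        lv = levels.set_index(["type_id", "variable"])
        for row in out[out["parameter"] == "weight+10%"].itertuples():
            cells = t.type_id == row.type_id
            xk = np.mean(rescale(variables[row.indicator][cells], 0.1, 0.9))
            expected_sign = np.sign(xk - row.index_nominal)
            got = np.sign(row.index_perturbed - row.index_nominal)
            if abs(xk - row.index_nominal) > 1e-9:
                assert got == expected_sign

    def test_summary_aggregates_over_types(self):
        variables, t, levels = _oat_inputs()
        out = run_oat(variables, t, levels, default_weights())
        summ = summarize_oat(out)
        assert len(summ) == 21
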