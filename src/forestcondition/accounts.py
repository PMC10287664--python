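"""SEEA-style condition account tables, change statistics and significance.

The account records, per forest type and accounting year, the area, the
mean of each condition variable on its native scale, the reference
levels, the mean rescaled indicators and the mean condition index.
Change between years is expressed in absolute index points x 100 (an
index moving from 0.648 to 0.682 is reported as +3.4); relative change is
available behind a flag. Significance of per-type change is assessed with
a two-sided Mann-Whitney U test on spatially thinned random cell samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .typology import TypologyGrid


def build_account(typology: TypologyGrid, variables_by_year: dict,
                  levels: pd.DataFrame, indicators_by_year: dict,
                  index_by_year: dict) -> pd.DataFrame:
    """Assemble the condition account: one row per (type, year)."""
    if len(typology.catalogue) == 0 or len(levels) == 0:
        return pd.DataFrame(columns=["type_id", "year", "forest_class",
                                     "region", "area_ha", "index_mean"])
    lv = levels.set_index(["type_id", "variable"])
    var_names = sorted({v for _, v in lv.index})
    rows = []
    for year in sorted(variables_by_year):
        variables = variables_by_year[year]
        indicators = indicators_by_year[year]
        idx = index_by_year[year]
        for rec in typology.catalogue.itertuples():
            cells = typology.cells_of(rec.type_id)
            row = {"type_id": rec.type_id, "year": year,
                   "forest_class": rec.forest_class, "region": rec.region,
                   "area_ha": rec.area_ha}
            for var in var_names:
                if var in variables:
                    row[f"{var}_mean"] = float(np.nanmean(
                        np.asarray(variables[var], dtype=float)[cells]))
                try:
                    lrow = lv.loc[(rec.type_id, var)]
                    row[f"{var}_VL"] = float(lrow["V_L"])
                    row[f"{var}_VH"] = float(lrow["V_H"])
                except KeyError:
                    pass
                if var in indicators:
                    vals = np.asarray(indicators[var], dtype=float)[cells]
                    row[f"{var}_indicator"] = (float(np.nanmean(vals))
                                               if np.any(~np.isnan(vals))
                                               else np.nan)
            vals = np.asarray(idx.index, dtype=float)[cells]
            row["index_mean"] = (float(np.nanmean(vals))
                                 if np.any(~np.isnan(vals)) else np.nan)
            rows.append(row)
    account = pd.DataFrame(rows)
    if len(account):
        wide = account.pivot(index="type_id", columns="year",
                             values="index_mean")
        years = sorted(variables_by_year)
        if len(years) == 2:
            change = (wide[years[1]] - wide[years[0]]) * 100.0
            account = account.merge(
                change.rename("index_change_points").reset_index(),
                on="type_id", how="left")
    return account


@dataclass
class ChangeSummary:
    share_increasing_pct: float
    share_decreasing_pct: float
    share_unchanged_pct: float
    mean_change_increasing_pts: float
    mean_change_decreasing_pts: float
    share_loss_gt_threshold_pct: float
    mean_change_pts: float


def change_points(index_t0, index_t1, relative: bool = False) -> np.ndarray:
    """Per-cell change in index points x 100 (or percent if relative)."""
    t0 = np.asarray(index_t0, dtype=float)
    t1 = np.asarray(index_t1, dtype=float)
    if relative:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 100.0 * (t1 - t0) / t0
    return 100.0 * (t1 - t0)


def change_stats(index_t0, index_t1, loss_threshold_pts: float = 10.0,
                 relative: bool = False) -> ChangeSummary:
    """Area shares and mean magnitudes of condition change.

    Shares are computed over cells with a defined index in both years, so
    they are invariant to surrounding non-forest area.
    """
    ch = change_points(index_t0, index_t1, relative=relative)
    valid = ch[~np.isnan(ch)]
    n = valid.size
    if n == 0:
        return ChangeSummary(0.0, 0.0, 100.0, np.nan, np.nan, 0.0, np.nan)
    inc, dec = valid[valid > 0], valid[valid < 0]
    return ChangeSummary(
        share_increasing_pct=100.0 * inc.size / n,
        share_decreasing_pct=100.0 * dec.size / n,
        share_unchanged_pct=100.0 * np.count_nonzero(valid == 0) / n,
        mean_change_increasing_pts=float(inc.mean()) if inc.size else np.nan,
        mean_change_decreasing_pts=float(dec.mean()) if dec.size else np.nan,
        share_loss_gt_threshold_pct=100.0 * np.count_nonzero(
            valid < -loss_threshold_pts) / n,
        mean_change_pts=float(valid.mean()),
    )


def thin_sample(cells_rc: np.ndarray, n_samples: int,
                min_separation_cells: float, rng) -> np.ndarray:
    """Greedy random spatial thinning: candidate cells are visited in
    random order and accepted while at least ``min_separation_cells`` from
    every already-accepted cell. Returns indices into ``cells_rc``."""
    order = rng.permutation(len(cells_rc))
    min2 = float(min_separation_cells) ** 2
    accepted: list[int] = []
    pts = cells_rc.astype(float)
    acc_pts = np.empty((0, 2))
    for i in order:
        p = pts[i]
        if acc_pts.size:
            d2 = np.sum((acc_pts - p) ** 2, axis=1)
            if d2.min() < min2:
                continue
        accepted.append(i)
        acc_pts = np.vstack([acc_pts, p])
        if len(accepted) >= n_samples:
            break
    return np.asarray(accepted, dtype=int)


def mwu_change_test(index_t0, index_t1, typology: TypologyGrid,
                    n_samples: int = 1000, min_separation_cells: float = 23.0,
                    seed: int = 0, independent_samples: bool = True) -> pd.DataFrame:
    """Per-type Mann-Whitney U test of condition change on thinned samples.

    For each forest type, random grid cells are sampled subject to a
    pairwise minimum distance (to avoid spatial autocorrelation) and the
    year-0 and year-1 index values are compared with a two-sided rank-sum
    test. By default the two years are sampled independently (so the test
    is correctly calibrated when the grids are identical); with
    ``independent_samples=False`` both years use the same cells. When
    fewer than ``n_samples`` cells survive thinning, all surviving cells
    are used and the row is flagged.
    """
    t0 = np.asarray(index_t0, dtype=float)
    t1 = np.asarray(index_t1, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rec in typology.catalogue.itertuples():
        cells = typology.cells_of(rec.type_id)
        eligible = cells & ~np.isnan(t0) & ~np.isnan(t1)
        rc = np.argwhere(eligible)
        if len(rc) == 0:
            continue
        idx0 = thin_sample(rc, n_samples, min_separation_cells, rng)
        s0 = t0[rc[idx0, 0], rc[idx0, 1]]
        if independent_samples:
            idx1 = thin_sample(rc, n_samples, min_separation_cells, rng)
            s1 = t1[rc[idx1, 0], rc[idx1, 1]]
        else:
            s1 = t1[rc[idx0, 0], rc[idx0, 1]]
        reduced = min(len(s0), len(s1)) < n_samples
        u, p = sps.mannwhitneyu(s1, s0, alternative="two-sided",
                                method="asymptotic")
        direction = ("increase" if np.median(s1) > np.median(s0)
                     else "decrease" if np.median(s1) < np.median(s0)
                     else "none")
        rows.append({"type_id": rec.type_id, "n0": len(s0), "n1": len(s1),
                     "U": float(u), "p": float(p), "direction": direction,
                     "reduced_sample": reduced})
    return pd.DataFrame(rows, columns=["type_id", "n0", "n1", "U", "p",
                                       "direction", "reduced_sample"])
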