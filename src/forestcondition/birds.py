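"""Threatened forest-bird richness modelling.

Survey tables of per-cell bird richness are filtered for data quality,
pruned for collinear predictors, and fitted with a forward stepwise
quasi-Poisson GLM (log link, variance proportional to the mean) in which
candidate predictors enter in order of their absolute correlation with
richness and quadratic companions are admitted when significant. The
fitted model projects expected richness onto predictor grids per
accounting year (dynamic land-cover/NDVI predictors vary; climate is held
constant).

`BirdRichnessModel.fit()` returns a `BirdRichnessResults` carrying the
selected terms, coefficients and their standard errors, the dispersion,
deviance-based pseudo-R2, and validation metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm


#: The 27 threatened forest bird species considered (forest specialists of
#: the European breeding-bird lists that are Annex-I or red-listed).
THREATENED_FOREST_BIRDS = [
    "Phylloscopus borealis", "Dryocopus martius", "Fringilla montifringilla",
    "Ficedula albicollis", "Sitta whiteheadi", "Bubo bubo",
    "Glaucidium passerinum", "Picoides tridactylus", "Pernis apivorus",
    "Turdus pilaris", "Strix nebulosa", "Picus canus", "Bonasa bonasia",
    "Dendrocopos medius", "Surnia ulula", "Milvus milvus", "Ficedula parva",
    "Turdus iliacus", "Emberiza rustica", "Ficedula semitorquata",
    "Aegolius funereus", "Strix uralensis", "Tetrao urogallus",
    "Dendrocopos leucotos", "Loxia scotica", "Pyrrhula murina",
    "Sitta krueperi",
]

#: Species of the list without any occurrence record in the survey period.
UNOBSERVED_SPECIES = frozenset(
    {"Loxia scotica", "Pyrrhula murina", "Sitta krueperi"})


def filter_observed_species(species=None, unobserved=None) -> list:
    """Drop species without occurrence records from the species list."""
    species = THREATENED_FOREST_BIRDS if species is None else species
    unobserved = UNOBSERVED_SPECIES if unobserved is None else set(unobserved)
    return [s for s in species if s not in unobserved]


@dataclass
class BirdDataset:
    """Prepared richness table: response counts plus named predictors."""

    df: pd.DataFrame
    predictors: list
    response: str = "threatened_richness"
    dropped_fraction: float = 0.0

    def __len__(self):
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df[self.response].to_numpy(dtype=float)


def prepare_bird_data(raw: pd.DataFrame, predictors=None,
                      min_total_richness: int = 3,
                      excluded_strata=None, stratum_col: str | None = None,
                      response: str = "threatened_richness") -> BirdDataset:
    """Quality-filter the raw survey table.

    Rows with a total reported richness below ``min_total_richness`` are
    dropped (low sampling effort), as are rows in explicitly excluded
    strata (e.g. countries with incomplete coverage).
    """
    if predictors is None:
        predictors = [c for c in raw.columns
                      if c not in ("cell_id", "total_richness", response)]
    n0 = len(raw)
    if n0 == 0:
        raise ValueError("empty bird table")
    keep = raw["total_richness"] >= min_total_richness
    if excluded_strata and stratum_col:
        keep &= ~raw[stratum_col].isin(set(excluded_strata))
    df = raw.loc[keep].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("all observations filtered out")
    df = df.dropna(subset=list(predictors) + [response]).reset_index(drop=True)
    return BirdDataset(df=df, predictors=list(predictors), response=response,
                       dropped_fraction=1.0 - len(df) / n0)


def prune_collinear(data: BirdDataset, threshold: float = 0.7) -> BirdDataset:
    """Greedily remove one predictor of each highly correlated pair.

    While any pair has |Pearson r| > threshold, the member with the lower
    absolute correlation to the response is dropped (generalizing the
    manual choice of dropping coordinates in favour of climate).
    """
    preds = list(data.predictors)
    resp_corr = {p: abs(data.df[p].corr(data.df[data.response]))
                 for p in preds}
    while len(preds) > 1:
        corr = data.df[preds].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        drop = preds[i] if resp_corr[preds[i]] <= resp_corr[preds[j]] else preds[j]
        preds.remove(drop)
    return BirdDataset(df=data.df, predictors=preds, response=data.response,
                       dropped_fraction=data.dropped_fraction)


def train_test_split(data: BirdDataset, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[BirdDataset, BirdDataset]:
    """Deterministic random split into calibration and validation sets."""
    rng = np.random.default_rng(seed)
    n = len(data)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    make = lambda idx: BirdDataset(df=data.df.iloc[idx].reset_index(drop=True),
                                   predictors=data.predictors,
                                   response=data.response)
    return make(tr), make(te)


# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, terms, centers) -> np.ndarray:
    """Design matrix for intercept + terms; quadratics are centered squares."""
    cols = [np.ones(len(df))]
    for t in terms:
        if t.endswith("^2"):
            base = t[:-2]
            cols.append((df[base].to_numpy(dtype=float) - centers[base]) ** 2)
        else:
            cols.append(df[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def _fit_glm(y, X):
    return sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")


@dataclass
class BirdRichnessResults:
    """Fitted quasi-Poisson richness model."""

    selected_terms: list
    params: pd.Series
    bse: pd.Series
    dispersion: float
    pseudo_r2: float
    rmse_train: float
    centers: dict
    train_size: int
    step_trace: pd.DataFrame | None = None
    metrics: dict = field(default_factory=dict)

    # -- prediction --------------------------------------------------------

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        X = _design(df, self.selected_terms, self.centers)
        return np.exp(X @ self.params.to_numpy())

    def project(self, predictor_grids: dict) -> np.ndarray:
        """Expected richness grid from per-predictor grids (log link).

        ``predictor_grids`` must contain every selected base predictor;
        a missing grid raises an error naming it.
        """
        base_needed = {t[:-2] if t.endswith("^2") else t
                       for t in self.selected_terms}
        missing = base_needed - set(predictor_grids)
        if missing:
            raise KeyError(f"missing predictor grids: {sorted(missing)}")
        shp = next(iter(predictor_grids.values())).shape if predictor_grids \
            else (1, 1)
        lp = np.full(shp, self.params.iloc[0])
        for t, beta in zip(self.selected_terms, self.params.iloc[1:]):
            if t.endswith("^2"):
                g = np.asarray(predictor_grids[t[:-2]], dtype=float)
                lp = lp + beta * (g - self.centers[t[:-2]]) ** 2
            else:
                lp = lp + beta * np.asarray(predictor_grids[t], dtype=float)
        return np.exp(lp)

    # -- validation --------------------------------------------------------

    def validate(self, test: BirdDataset, cv_data: BirdDataset | None = None,
                 cv_folds: int = 10, cv_repeats: int = 100,
                 seed: int = 0) -> dict:
        """Hold-out metrics plus optional repeated k-fold cross-validation.

        The cross-validation refits the selected terms on each training
        fold and scores the held-out fold, reporting mean and SD of RMSE
        and pseudo-R2 across folds x repeats.
        """
        pred = self.predict_frame(test.df)
        obs = test.y
        out = {
            "rmse_test": float(np.sqrt(np.mean((obs - pred) ** 2))),
            "cor_test": float(np.corrcoef(obs, pred)[0, 1]),
        }
        if cv_data is not None:
            rng = np.random.default_rng(seed)
            rmses, r2s = [], []
            n = len(cv_data)
            y_all = cv_data.y
            X_all = _design(cv_data.df, self.selected_terms, self.centers)
            for _ in range(cv_repeats):
                order = rng.permutation(n)
                folds = np.array_split(order, cv_folds)
                for hold in folds:
                    tr = np.setdiff1d(order, hold, assume_unique=False)
                    res = _fit_glm(y_all[tr], X_all[tr])
                    mu = np.exp(X_all[hold] @ res.params)
                    rmses.append(np.sqrt(np.mean((y_all[hold] - mu) ** 2)))
                    r2s.append(_pseudo_r2(y_all[hold], mu))
            out.update(cv_rmse_mean=float(np.mean(rmses)),
                       cv_rmse_sd=float(np.std(rmses)),
                       cv_pseudo_r2_mean=float(np.mean(r2s)),
                       cv_pseudo_r2_sd=float(np.std(r2s)))
        self.metrics.update(out)
        return out

    def summary(self) -> str:
        lines = ["Quasi-Poisson threatened-bird richness model",
                 f"  n (train) = {self.train_size}",
                 f"  dispersion = {self.dispersion:.3f}",
                 f"  pseudo-R2 = {self.pseudo_r2:.3f}",
                 f"  RMSE (train) = {self.rmse_train:.3f}",
                 "  terms:"]
        for name, b, se in zip(["(Intercept)"] + self.selected_terms,
                               self.params, self.bse):
            lines.append(f"    {name:<28s} {b:+.4f} (se {se:.4f})")
        for k, v in self.metrics.items():
            lines.append(f"  {k} = {v:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        doc = {
            "selected_terms": self.selected_terms,
            "coefficients": dict(zip(["(Intercept)"] + self.selected_terms,
                                     map(float, self.params))),
            "bse": list(map(float, self.bse)),
            "dispersion": self.dispersion,
            "pseudo_r2": self.pseudo_r2,
            "rmse_train": self.rmse_train,
            "centers": self.centers,
            "train_size": self.train_size,
            "metrics": self.metrics,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def _pseudo_r2(y, mu) -> float:
    """Deviance-based pseudo-R2: 1 - residual deviance / null deviance."""
    def dev(yy, mm):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(yy > 0, yy * np.log(yy / mm), 0.0)
        return 2.0 * np.sum(term - (yy - mm))
    ybar = np.mean(y)
    d0 = dev(y, np.full_like(y, ybar, dtype=float))
    return 1.0 - dev(y, mu) / d0 if d0 > 0 else 0.0


class BirdRichnessModel:
    """Forward stepwise quasi-Poisson GLM of threatened-bird richness.

    Candidates enter in descending order of |Pearson correlation| with the
    response. Each step adds the linear term, then tests its quadratic
    companion (centered before squaring for conditioning); a term is kept
    when its Wald p-value is below ``alpha`` *and* it improves the
    deviance pseudo-R2 by more than ``improvement_tol``. By default the
    search stops at the first candidate whose linear term fails;
    ``scan_all=True`` keeps scanning the remaining candidates instead.
    """

    def __init__(self, data: BirdDataset):
        self.data = data

    def fit(self, improvement_tol: float = 0.005, alpha: float = 0.05,
            scan_all: bool = False, quadratic: bool = True) -> BirdRichnessResults:
        df, preds, y = self.data.df, self.data.predictors, self.data.y
        centers = {p: float(df[p].mean()) for p in preds}
        order = sorted(preds, key=lambda p: -abs(df[p].corr(df[self.data.response])))

        terms: list = []
        best = _fit_glm(y, _design(df, terms, centers))
        best_r2 = _pseudo_r2(y, best.fittedvalues)
        trace = []

        for cand in order:
            accepted_linear, res = self._try_term(
                y, df, centers, terms, cand, best_r2, improvement_tol, alpha)
            if accepted_linear:
                terms.append(cand)
                best, best_r2 = res, _pseudo_r2(y, res.fittedvalues)
                if quadratic:
                    ok_q, res_q = self._try_term(
                        y, df, centers, terms, cand + "^2",
                        best_r2, improvement_tol, alpha)
                    if ok_q:
                        terms.append(cand + "^2")
                        best, best_r2 = res_q, _pseudo_r2(y, res_q.fittedvalues)
            trace.append({"candidate": cand, "accepted": accepted_linear,
                          "pseudo_r2": best_r2})
            if not accepted_linear and not scan_all:
                break

        mu = best.fittedvalues
        names = ["(Intercept)"] + terms
        return BirdRichnessResults(
            selected_terms=terms,
            params=pd.Series(np.asarray(best.params), index=names),
            bse=pd.Series(np.asarray(best.bse), index=names),
            dispersion=float(best.scale),
            pseudo_r2=best_r2,
            rmse_train=float(np.sqrt(np.mean((y - mu) ** 2))),
            centers=centers,
            train_size=len(df),
            step_trace=pd.DataFrame(trace),
        )

    @staticmethod
    def _try_term(y, df, centers, terms, new_term, best_r2,
                  improvement_tol, alpha):
        X = _design(df, terms + [new_term], centers)
        try:
            res = _fit_glm(y, X)
        except Exception:   # non-convergence: skip the step
            return False, None
        r2 = _pseudo_r2(y, res.fittedvalues)
        p = res.pvalues[-1]
        if p < alpha and (r2 - best_r2) > improvement_tol:
            return True, res
        return False, None
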