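"""County-level livestock density modelling.

The response is the natural log of county livestock density,

    y_c = ln(SSU_c / A_c),

where SSU_c is the county's census total in standard sheep units
(1 cattle = 5 SSU, 1 sheep = 1 SSU) and A_c the area (km^2) of its suitable
pasture mask. Predictors are county zonal means over the mask. Highly
correlated predictor pairs (|Pearson r| > 0.7) are screened before fitting;
a ten-fold stratified random forest is then fitted and each fold model
predicts a density for every masked pixel. The across-fold mean exp(y_hat)
becomes the dasymetric weight surface and the across-fold coefficient of
variation (SD/mean) the published uncertainty layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

from .geodata import GridMismatchError, Raster, area_raster, zonal_table

logger = logging.getLogger(__name__)

#: SSUs per head of cattle; sheep count 1.
SSU_PER_CATTLE = 5.0

#: Default density predictor set (the final-model roster).
DENSITY_PREDICTORS = ("DEM", "Tmp", "Wpre", "SnowDays", "NDVI", "TravelTime")

CORRELATION_THRESHOLD = 0.7


def to_ssu(cattle_head, sheep_head, ssu_per_cattle: float = SSU_PER_CATTLE) -> float | np.ndarray:
    """Standard sheep units: 5 per cattle, 1 per sheep (factor configurable)."""
    cattle = np.asarray(cattle_head, dtype=float)
    sheep = np.asarray(sheep_head, dtype=float)
    if np.any(cattle < 0) or np.any(sheep < 0):
        raise ValueError("head counts must be nonnegative")
    if ssu_per_cattle <= 0:
        raise ValueError("ssu_per_cattle must be positive")
    out = ssu_per_cattle * cattle + sheep
    return float(out) if out.ndim == 0 else out


@dataclass
class DensitySamples:
    """County training table: response y = ln(SSU/km^2) + predictor means."""

    table: pd.DataFrame  # columns: county_id, ssu, area_km2, y, <predictors...>
    predictor_names: tuple[str, ...]
    excluded: dict[str, str]  # county_id -> reason

    @property
    def X(self) -> np.ndarray:
        return self.table[list(self.predictor_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=float)


def county_response(
    census: pd.DataFrame,
    mask: Raster,
    county_raster: Raster,
    county_codes: dict[str, int],
    predictors: dict[str, Raster],
    predictor_names: tuple[str, ...] = DENSITY_PREDICTORS,
) -> DensitySamples:
    """Build county ln-density responses and zonal-mean predictor features.

    ``census`` needs columns unit_id, cattle_head, sheep_head and optionally
    is_agricultural. Counties flagged agricultural, with zero masked area or
    zero stock are excluded with a logged reason.
    """
    areas = area_raster(mask.spec)
    area_tab = zonal_table({"area": areas}, county_raster, mask, stat="sum",
                           zone_codes=county_codes)
    pred_tab = zonal_table({n: predictors[n] for n in predictor_names},
                           county_raster, mask, stat="mean", zone_codes=county_codes)

    rows, excluded = [], {}
    for rec in census.itertuples(index=False):
        cid = rec.unit_id
        if getattr(rec, "is_agricultural", False):
            excluded[cid] = "agricultural county"
            continue
        if cid not in area_tab.data or area_tab.counts.get(cid, 0) == 0:
            excluded[cid] = "no masked pasture pixels"
            continue
        ssu = to_ssu(rec.cattle_head, rec.sheep_head)
        if ssu <= 0:
            excluded[cid] = "zero livestock"
            continue
        area = area_tab.data[cid]["area"]
        row = {"county_id": cid, "ssu": ssu, "area_km2": area,
               "y": float(np.log(ssu / area))}
        row.update({n: pred_tab.data[cid][n] for n in predictor_names})
        rows.append(row)
    for cid, why in excluded.items():
        logger.info("county %s excluded from density model: %s", cid, why)
    table = pd.DataFrame(rows, columns=["county_id", "ssu", "area_km2", "y",
                                        *predictor_names])
    return DensitySamples(table, tuple(predictor_names), excluded)


def screen_correlated(
    predictor_table: pd.DataFrame,
    response: np.ndarray,
    threshold: float = CORRELATION_THRESHOLD,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one of each predictor pair with |Pearson r| above the threshold.

    While any pair exceeds the threshold, the member with the weaker absolute
    univariate correlation to the response is dropped (ties alphabetically).
    Constant predictors (undefined r) are dropped first with a warning.
    Returns (retained names, dropped (kept, dropped, r) pairs).
    """
    names = sorted(predictor_table.columns)
    dropped_pairs: list[tuple[str, str, float]] = []
    kept = []
    for n in names:
        if predictor_table[n].std(ddof=0) == 0:
            logger.warning("predictor %s is constant; dropped (undefined correlation)", n)
            dropped_pairs.append((n, n, np.nan))
        else:
            kept.append(n)
    names = kept

    y = np.asarray(response, dtype=float)

    def r_to_response(n: str) -> float:
        return abs(float(np.corrcoef(predictor_table[n], y)[0, 1]))

    while True:
        if len(names) < 2:
            break
        corr = predictor_table[names].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        ra, rb = r_to_response(a), r_to_response(b)
        if ra > rb:
            keep, drop = a, b
        elif rb > ra:
            keep, drop = b, a
        else:  # tie -> alphabetical keep
            keep, drop = sorted((a, b))
        names.remove(drop)
        dropped_pairs.append((keep, drop, float(worst)))
        logger.info("collinearity screen: dropped %s (|r|=%.3f with %s)", drop, worst, keep)
    return names, dropped_pairs


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    resid = y_true - y_pred
    ss_res = float((resid**2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return r2, float(np.abs(resid).mean()), float((resid**2).mean())


@dataclass
class DensityModel:
    """Fitted ten-fold ensemble with cross-validation metrics.

    The headline metrics (``oof_r2`` etc.) are computed once over the pooled
    out-of-fold predictions of all counties — per-fold R^2 on the 2-3
    held-out counties a small region yields per fold is dominated by noise,
    whereas the pooled form remains well defined at any sample size. The
    per-fold lists are retained for diagnostics.
    """

    fold_models: list[RandomForestRegressor]
    predictor_names: tuple[str, ...]
    oof_r2: float
    oof_mae: float
    oof_mse: float
    fold_r2: list[float]
    fold_mae: list[float]
    fold_mse: list[float]
    importances: dict[str, float]
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    def metrics_dict(self) -> dict:
        return {
            "predictors": list(self.predictor_names),
            "oof_r2": self.oof_r2,
            "oof_mae": self.oof_mae,
            "oof_mse": self.oof_mse,
            "fold_r2": self.fold_r2,
            "fold_mae": self.fold_mae,
            "fold_mse": self.fold_mse,
            "importances": self.importances,
            "seed": self.seed,
        }


def _response_strata(y: np.ndarray, n_folds: int) -> np.ndarray:
    """Quantile-bin a continuous response for stratified K-fold splitting.

    Every stratum must hold at least ``n_folds`` members, so the bin count
    is capped at n_samples // n_folds (and at 10, i.e. deciles).
    """
    n_bins = max(2, min(10, len(y) // n_folds))
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, y, side="left")


def fit_density_model(
    samples: DensitySamples,
    seed: int = 0,
    n_folds: int = 10,
    n_estimators: int = 200,
    predictor_names: tuple[str, ...] | None = None,
) -> DensityModel:
    """Ten-fold stratified random-forest fit of county ln-density.

    Strata are response quantile bins. Out-of-fold R^2 (1 - SS_res/SS_tot),
    MAE and MSE are computed per fold on the ln scale.
    """
    names = tuple(predictor_names or samples.predictor_names)
    X = samples.table[list(names)].to_numpy(dtype=float)
    y = samples.y
    if len(y) < n_folds:
        raise ValueError(f"{len(y)} counties cannot support {n_folds} folds")
    strata = _response_strata(y, n_folds)
    if np.bincount(strata).min() >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, strata)
    else:
        # too few samples per stratum to stratify; plain shuffled K-fold
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)
    models, r2s, maes, mses = [], [], [], []
    importances = np.zeros(len(names))
    oof = np.empty_like(y)
    for k, (tr, te) in enumerate(splits):
        m = RandomForestRegressor(n_estimators=n_estimators,
                                  random_state=seed * 1000 + k, n_jobs=1)
        m.fit(X[tr], y[tr])
        pred = m.predict(X[te])
        oof[te] = pred
        r2, mae, mse = _metrics(y[te], pred)
        models.append(m)
        r2s.append(r2)
        maes.append(mae)
        mses.append(mse)
        importances += m.feature_importances_
    importances /= n_folds
    oof_r2, oof_mae, oof_mse = _metrics(y, oof)
    model = DensityModel(models, names, oof_r2, oof_mae, oof_mse,
                         r2s, maes, mses, dict(zip(names, importances)), seed)
    logger.info("density model: pooled out-of-fold R2 %.3f, MAE %.3f, MSE %.3f",
                oof_r2, oof_mae, oof_mse)
    return model


def prune_by_importance(
    samples: DensitySamples,
    seed: int = 0,
    n_folds: int = 10,
    n_estimators: int = 200,
) -> list[DensityModel]:
    """Backward-elimination ladder: refit after dropping the least important
    predictor each round, down to a single predictor."""
    names = list(samples.predictor_names)
    ladder = []
    while names:
        model = fit_density_model(samples, seed=seed, n_folds=n_folds,
                                  n_estimators=n_estimators,
                                  predictor_names=tuple(names))
        ladder.append(model)
        if len(names) == 1:
            break
        weakest = min(model.importances, key=model.importances.get)
        names.remove(weakest)
    return ladder


@dataclass
class PixelPrediction:
    mean_density: Raster  # SSU/km^2 on the mask, nodata elsewhere
    cv: Raster  # unitless SD/mean across folds, nodata off-mask


def predict_pixel_density(
    model: DensityModel,
    predictors: dict[str, Raster],
    mask: Raster,
) -> PixelPrediction:
    """Per-pixel fold-mean density exp(y_hat) and its across-fold CV.

    Each fold model predicts ln-density for every masked pixel; predictions
    are exponentiated to the density scale, then averaged. CV is the sample
    SD (ddof=1) across folds divided by the mean, defined as 0 where the
    mean is 0.
    """
    spec = mask.spec
    for n in model.predictor_names:
        if not predictors[n].spec.same_grid(spec):
            raise GridMismatchError(f"predictor {n} grid differs from mask grid")
    masked = mask.values == 1
    for n in model.predictor_names:
        masked &= predictors[n].valid_mask()
    idx = np.flatnonzero(masked.ravel())
    mean = np.full(spec.shape, spec.nodata).ravel()
    cv = np.full(spec.shape, spec.nodata).ravel()
    if idx.size:
        X = np.column_stack(
            [predictors[n].values.ravel()[idx] for n in model.predictor_names]
        )
        preds = np.stack([np.exp(m.predict(X)) for m in model.fold_models])
        mu = preds.mean(axis=0)
        sd = preds.std(axis=0, ddof=1) if preds.shape[0] > 1 else np.zeros_like(mu)
        mean[idx] = mu
        with np.errstate(divide="ignore", invalid="ignore"):
            cv[idx] = np.where(mu > 0, sd / mu, 0.0)
    return PixelPrediction(Raster(spec, mean.reshape(spec.shape)),
                           Raster(spec, cv.reshape(spec.shape)))


def partial_dependence(
    model: DensityModel,
    samples: DensitySamples,
    predictor: str,
    n_grid: int = 20,
) -> pd.DataFrame:
    """Partial-dependence curve of the fold-mean prediction on one predictor.

    The grid spans the observed min..max of the predictor; at each grid value
    the predictor column is replaced wholesale and predictions are averaged
    over counties and folds (ln-density scale).
    """
    if predictor not in model.predictor_names:
        raise ValueError(f"predictor {predictor!r} not in the model")
    X = samples.table[list(model.predictor_names)].to_numpy(dtype=float)
    j = model.predictor_names.index(predictor)
    grid = np.linspace(X[:, j].min(), X[:, j].max(), n_grid)
    means = []
    for g in grid:
        Xg = X.copy()
        Xg[:, j] = g
        means.append(float(np.mean([m.predict(Xg).mean() for m in model.fold_models])))
    return pd.DataFrame({predictor: grid, "mean_prediction": means})
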