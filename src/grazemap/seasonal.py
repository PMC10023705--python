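"""Warm/cold-season pasture classification.

Predictors are first expressed as *relative values* within each township,

    RV = (X_ij - Xbar_i) / Xbar_i,

where X_ij is the raw predictor at pixel j of township i and Xbar_i the
township mean over masked pixels. The transform makes, e.g., "higher than
this township's average elevation" comparable across townships, matching how
seasonal pastures are allocated within township boundaries. A ten-fold
stratified random-forest classifier is then fitted to labelled warm(1)/
cold(0) samples; each fold model classifies every masked pixel and the final
class is the mode of the ten predictions (5-5 ties go to warm iff the mean
warm probability is >= 0.5). Performance is scored by the rank-based AUC of
each held-out fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .geodata import GridMismatchError, Raster

logger = logging.getLogger(__name__)

#: RV is forced to 0 (with a warning) in townships whose mean predictor
#: magnitude is below this, to keep near-zero means (winter temperature in
#: deg C) from producing unbounded features.
MEAN_EPSILON = 1e-6

#: Season-map codes
WARM, COLD, NON_PASTURE = 1, 0, 255

#: Default classification predictor set.
CLASSIFIER_PREDICTORS = ("DEM", "GStem", "Wtem", "GSpre", "Wpre", "NDVI", "TravelTime")

#: Qualitative AUC bands, lower bound inclusive.
AUC_BANDS = (
    (0.9, "excellent"),
    (0.8, "very good"),
    (0.7, "good"),
    (0.6, "average"),
    (0.5, "poor"),
)


def relative_transform(predictor: Raster, township_raster: Raster, mask: Raster) -> Raster:
    """Within-township relative value RV = (X - Xbar) / Xbar of a predictor.

    Township means are taken over masked pixels only. Pixels of townships
    whose |mean| < MEAN_EPSILON get RV = 0 (warned); pixels of townships with
    no masked pixels are nodata. Off-mask pixels are nodata.
    """
    spec = predictor.spec
    if not (spec.same_grid(township_raster.spec) and spec.same_grid(mask.spec)):
        raise GridMismatchError("predictor, township and mask grids differ")
    x = predictor.values.astype(np.float64)
    masked = (mask.values == 1) & predictor.valid_mask() & township_raster.valid_mask()
    out = np.full(spec.shape, spec.nodata)
    tw = township_raster.values
    for code in np.unique(tw[township_raster.valid_mask()]):
        in_town = masked & (tw == code)
        if not in_town.any():
            continue
        m = x[in_town].mean()
        if abs(m) < MEAN_EPSILON:
            warnings.warn(
                f"township code {int(code)}: |mean| < {MEAN_EPSILON:g}; RV forced to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            out[in_town] = 0.0
        else:
            out[in_town] = (x[in_town] - m) / m
    return Raster(spec, out)


def relative_stack(
    predictors: dict[str, Raster],
    township_raster: Raster,
    mask: Raster,
    names: tuple[str, ...] = CLASSIFIER_PREDICTORS,
) -> dict[str, Raster]:
    """Relative-value rasters for the named predictors."""
    return {n: relative_transform(predictors[n], township_raster, mask) for n in names}


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve, rank-statistic (Mann-Whitney) form.

    Equivalent to the probability that a random positive outscores a random
    negative, with ties counting 1/2. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both a positive and a negative class")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_band(value: float) -> str:
    """Qualitative label for an AUC value (lower band edge inclusive)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {value}")
    for lo, name in AUC_BANDS:
        if value >= lo:
            return name
    return "no discrimination"


@dataclass
class ClassifierReport:
    fold_auc: list[float]
    importances: dict[str, float]
    predictor_names: tuple[str, ...]
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def band(self) -> str:
        return auc_band(self.mean_auc)

    def to_dict(self) -> dict:
        return {
            "fold_auc": self.fold_auc,
            "mean_auc": self.mean_auc,
            "band": self.band,
            "importances": self.importances,
            "predictors": list(self.predictor_names),
            "seed": self.seed,
        }


def _sample_matrix(
    samples: pd.DataFrame, stack: dict[str, Raster]
) -> tuple[np.ndarray, np.ndarray]:
    names = tuple(stack)
    rows = samples["row"].to_numpy()
    cols = samples["col"].to_numpy()
    X = np.column_stack([stack[n].values[rows, cols] for n in names])
    y = samples["label"].to_numpy().astype(int)
    ok = np.all([stack[n].valid_mask()[rows, cols] for n in names], axis=0)
    return X[ok], y[ok]


def fit_season_classifier(
    samples: pd.DataFrame,
    stack: dict[str, Raster],
    seed: int = 0,
    n_folds: int = 10,
    n_estimators: int = 100,
) -> tuple[list[RandomForestClassifier], ClassifierReport]:
    """Fit the ten-fold warm/cold random-forest classifier.

    ``samples`` needs columns row, col, label. Folds are stratified by label;
    each fold model trains on 9/10 of the samples and is scored (AUC) on its
    held-out tenth. Returns the fold models and the report.
    """
    X, y = _sample_matrix(samples, stack)
    if len(np.unique(y)) < 2:
        raise ValueError("training samples contain a single class")
    if np.bincount(y).min() < 2:
        raise ValueError("need at least 2 samples of each class")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    models: list[RandomForestClassifier] = []
    fold_auc: list[float] = []
    importances = np.zeros(X.shape[1])
    for k, (tr, te) in enumerate(skf.split(X, y)):
        model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed * 1000 + k, n_jobs=1
        )
        model.fit(X[tr], y[tr])
        warm_col = list(model.classes_).index(1)
        fold_auc.append(compute_auc(model.predict_proba(X[te])[:, warm_col], y[te]))
        importances += model.feature_importances_
        models.append(model)
    importances /= n_folds
    report = ClassifierReport(
        fold_auc=fold_auc,
        importances=dict(zip(tuple(stack), importances)),
        predictor_names=tuple(stack),
        seed=seed,
    )
    logger.info("season classifier: mean AUC %.3f (%s)", report.mean_auc, report.band)
    return models, report


def predict_season_map(
    models: list[RandomForestClassifier],
    stack: dict[str, Raster],
    mask: Raster,
) -> Raster:
    """Classify every masked pixel; final class = mode of the fold predictions.

    Even warm/cold splits are broken by the mean warm-class probability
    (warm iff >= 0.5). Off-mask pixels get the NON_PASTURE code.
    """
    spec = mask.spec
    for r in stack.values():
        if not r.spec.same_grid(spec):
            raise GridMismatchError("stack and mask grids differ")
    masked = mask.values == 1
    for r in stack.values():
        masked &= r.valid_mask()
    idx = np.flatnonzero(masked.ravel())
    out = np.full(spec.shape, NON_PASTURE, dtype=np.uint8).ravel()
    if idx.size:
        X = np.column_stack([r.values.ravel()[idx] for r in stack.values()])
        votes = np.zeros(idx.size, dtype=np.int32)
        prob = np.zeros(idx.size)
        for model in models:
            votes += model.predict(X).astype(np.int32)
            warm_col = list(model.classes_).index(1)
            prob += model.predict_proba(X)[:, warm_col]
        n = len(models)
        prob /= n
        cls = np.where(votes * 2 > n, WARM, COLD)
        even = votes * 2 == n
        cls[even] = np.where(prob[even] >= 0.5, WARM, COLD)
        out[idx] = cls.astype(np.uint8)
    return Raster(spec, out.reshape(spec.shape))
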