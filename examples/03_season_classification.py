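"""Classify warm- vs cold-season pastures with township-relative predictors.

Each predictor X is turned into its relative value RV = (X - Xbar)/Xbar
within its township, then a ten-fold random forest is trained on labelled
samples and every masked pixel gets the mode of the ten fold predictions.
"""

from grazemap import GridSpec, LandscapeConfig, build_mask, generate_landscape
from grazemap.seasonal import fit_season_classifier, predict_season_map, relative_stack
from grazemap.synth import generate_season_samples

truth = generate_landscape(LandscapeConfig(
    seed=42, n_county_rows=2, n_county_cols=2,
    spec=GridSpec(92.0, 35.0, 15.0 / 3600.0, 96, 96)))
mask = build_mask(truth.landcover).raster
samples = generate_season_samples(truth, 1000)

stack = relative_stack(truth.predictors, truth.township_raster, mask)
models, report = fit_season_classifier(samples, stack, seed=0)
print(f"fold AUCs: {[round(a, 3) for a in report.fold_auc]}")
print(f"mean AUC {report.mean_auc:.3f} -> {report.band}")
top = sorted(report.importances.items(), key=lambda kv: -kv[1])[:3]
print("top predictors:", ", ".join(f"{k} ({v:.2f})" for k, v in top))

season_map = predict_season_map(models, stack, mask)
defined = truth.true_season.valid_mask()
agree = (season_map.values[defined] == truth.true_season.values[defined]).mean()
print(f"pixelwise agreement with planted truth: {100 * agree:.1f}%")
# DEM dominates because the planted rule is an elevation quantile split;
# agreement is imperfect because 5% of training labels are flipped.
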