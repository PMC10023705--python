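"""Fit the county ln-density model and derive the pixel weight/CV layers.

County census totals (standard sheep units: 1 cattle = 5 SSU) are divided by
masked pasture area to give densities; ln-density is regressed on county
zonal means of the predictors after screening |r| > 0.7 pairs. Each of the
ten fold models then predicts every masked pixel; the fold-mean exp(y_hat)
is the dasymetric weight surface and the fold CV the uncertainty layer.
"""

import numpy as np

from grazemap import LandscapeConfig, build_mask, generate_landscape
from grazemap.density import (
    county_response,
    fit_density_model,
    predict_pixel_density,
    screen_correlated,
)
from grazemap.synth import generate_census

truth = generate_landscape(LandscapeConfig(seed=42))  # 200x200, 24 counties
mask = build_mask(truth.landcover).raster
census = generate_census(truth, level="county")
print(f"counties: {len(census)}, total stock {census['ssu'].sum():,} SSU")

samples = county_response(census, mask, truth.county_raster,
                          truth.county_codes, truth.predictors)
retained, dropped = screen_correlated(
    samples.table[list(samples.predictor_names)], samples.y)
for kept, gone, r in dropped:
    print(f"screened out {gone} (|r|={r:.2f} with {kept})")

model = fit_density_model(samples, seed=0, predictor_names=tuple(retained))
print(f"pooled out-of-fold R2 {model.oof_r2:.3f}, MAE {model.oof_mae:.3f} (ln scale)")

pred = predict_pixel_density(model, truth.predictors, mask)
sel = pred.mean_density.valid_mask()
print(f"predicted density: mean {pred.mean_density.values[sel].mean():.1f} SSU/km^2")
print(f"fold CV: median {np.median(pred.cv.values[sel]):.3f} "
      f"(low CV = fold models agree)")
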