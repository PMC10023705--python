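"""Generate a synthetic study region and inspect its planted structure.

The landscape emulates a high-plateau transhumance region: elevation-driven
climate, a grazable land-cover mosaic, nested county/township tiles, a
planted warm/cold season rule (warm above each township's median elevation)
and a planted log-linear livestock density surface.
"""

import numpy as np

from grazemap import GridSpec, LandscapeConfig, generate_landscape

config = LandscapeConfig(
    seed=42,
    n_county_rows=2,
    n_county_cols=2,
    townships_per_county=4,
    spec=GridSpec(92.0, 35.0, 15.0 / 3600.0, 96, 96),
)
truth = generate_landscape(config)

suitable = truth.suitable_mask()
print(f"grid: {config.spec.n_rows}x{config.spec.n_cols} at 15 arc-seconds")
print(f"counties: {len(truth.counties)}, townships: {len(truth.townships)}")
print(f"suitable pasture fraction: {suitable.mean():.2f}")
dem = truth.predictors['DEM'].values
print(f"elevation range: {dem.min():.0f}-{dem.max():.0f} m")
dens = truth.true_density.values[suitable]
print(f"planted density (SSU/km^2): mean {dens.mean():.1f}, "
      f"p5-p95 {np.percentile(dens, 5):.1f}-{np.percentile(dens, 95):.1f}")
warm = truth.true_season.values[suitable] == 1
print(f"warm-season share of suitable pixels: {warm.mean():.2f}")
# The warm share sits near 0.5 because warm pastures are defined as the
# upper half of each township's elevation distribution.
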