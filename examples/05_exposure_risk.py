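"""Convert a concentration surface into population-exposure risk and
classify it into low/moderate/high natural-breaks tiers."""

import numpy as np

from pm25risk import ann
from pm25risk import exposure as ex
from pm25risk import spatial as sp
from pm25risk import synthetic as sy
from pm25risk.pipeline import FEATURES, monthly_means

df = sy.generate_stations(sy.SyntheticSpec(n_days=730, seed=5))
monthly = monthly_means(df)
fit = ann.fit(monthly[FEATURES].to_numpy(), monthly["pm25"].to_numpy(),
              ann.TrainConfig(max_epochs=80, seed=6), optimizer="trainlm")
jan = monthly[monthly["month"] == 1].copy()
jan["pm25_pred"] = ann.predict(fit, jan[FEATURES].to_numpy())

grid = sp.grid_from_points(jan["x"].to_numpy(), jan["y"].to_numpy(),
                           n_cols=60, n_rows=60)
conc = sp.idw_interpolate(jan["x"].to_numpy(), jan["y"].to_numpy(),
                          jan["pm25_pred"].to_numpy(), grid)
dens = sp.idw_interpolate(jan["x"].to_numpy(), jan["y"].to_numpy(),
                          jan["pop_density"].to_numpy(), grid)

params = ex.ExposureParams()  # IR=11.7 m3/day, UR=0.008 per ug/m3, BW=57 kg
print(f"inhalation slope factor SFI = UR*BW*IR = {ex.slope_factor(params):.3f}")

surf = ex.population_risk(conc, dens, params, classify_k=3)
pr = surf.population.values
print(f"population risk range: {pr.min():.0f} - {pr.max():.0f} "
      "(risk x persons/km2)")
counts = {lab: int(np.sum(surf.classes.values == i))
          for i, lab in enumerate(surf.breaks.labels)}
print("natural-breaks zoning:", counts)

# Risk is individual risk (C * IR^2 * UR under ED=AT) times the exposed
# population density, so the high tier concentrates where the January
# concentration surface and the density surface overlap.
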