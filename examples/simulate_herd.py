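"""Generate a synthetic regional herd-year and summarise its structure.

Nine sheds sampled monthly for a year: near-constant per-shed farm waters on
the regional water line, a seasonal temperature cycle, and milk whose
heavy-isotope enrichment over the farm water follows the temperature of the
two preceding weeks.  The summary lines show that the generated data carry
the statistical signatures the analysis relies on: waters on a slope-≈8.3
line, milk α rising from winter to summer, and a deuterium-excess gap that
tracks temperature.
"""

import numpy as np

import isomilk as im
from isomilk.synthetic import SyntheticHerdConfig, simulate_herd_year

config = SyntheticHerdConfig(seed=1, outdoor_sheds=("shed09",))
records = simulate_herd_year(config)
print(f"{len(records)} records from {config.n_sheds} sheds × 12 months "
      f"(seed {config.seed})")

fit = im.fit_water_line([(r.d18O_W, r.d2H_W) for r in records])
print(f"farm-water line: slope {fit.slope:.2f} ± {fit.slope_se:.2f}, "
      f"intercept {fit.intercept:.1f}‰, R² {fit.r2:.2f}")

alphas = {m: [im.compute_alpha(r.d18O_M, r.d18O_W).alpha
              for r in records if r.month == m] for m in (1, 7)}
print(f"mean alpha January {np.mean(alphas[1]):.6f} vs July {np.mean(alphas[7]):.6f} "
      "(summer metabolic enrichment)")

r_dex = im.dex_temperature_correlation(records)
print(f"d_ex,W − d_ex,M vs 2-week temperature: R = {r_dex:.2f} "
      "(evaporation-like response)")

im.write_samples(records, "synthetic_herd_year.csv")
print("wrote synthetic_herd_year.csv")
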