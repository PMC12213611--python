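"""Closed-loop check: generate grassland sites with a known FRC-SOC
coupling and recover the slope through the full pipeline.

The generator couples SOC_total = 8.5 + 15.5 * FRC_total + noise; after
profile construction, alignment, and aggregation, ordinary least squares
on the pipeline outputs should return ~15.5.
"""

from rootsoc import fit_model, io_tables, run_pipeline
from rootsoc.models import ModelSpec
from rootsoc.synth import GeneratorConfig, generate

cfg = GeneratorConfig(seed=42, outlier_tundra=0, n_sites={"grassland": 15})
ds = generate(cfg)
profiles = io_tables.profiles_from_frames(ds.sites, ds.horizons, ds.roots)
agg = run_pipeline(profiles).aggregate_frame

fit = fit_model(ModelSpec("soc_total", ("frc_total",)), agg)
b = fit.coefficients["frc_total"]
a = fit.coefficients["const"]
print(f"recovered SOC = {a:.2f} + {b:.2f} * FRC  (adj r^2 = {fit.adj_r2:.2f})")
print("Truth was SOC = 8.50 + 15.50 * FRC with site-level noise sd 2; the "
      "estimate differs only by sampling error at n = 15.")
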