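"""Quantify a simulated 7-point 3-fold dilution series.

Starting at 5,832 template copies against a 1,500-copy reference
background, the series bottoms out at 8 expected copies.  The example
pools triplicates, converts droplet counts to copies/ul via the Poisson
model, fits per-assay linearity, and reports the lowest quantity detected
by every assay in all three replicates.
"""

from methplex import (
    WellSimConfig,
    linearity_fit,
    lowest_detected_quantity,
    poisson_concentration,
    simulate_dilution_series,
)

cfg = WellSimConfig(seed=0)
wells, series = simulate_dilution_series(5832, cfg, points=7, factor=3, replicates=3)
print(f"{len(wells)} wells over {series['point'].nunique()} dilution points")

for target, sub in series.groupby("target"):
    pooled = sub.groupby("expected_copies")["positives"].sum()
    conc = [poisson_concentration(int(p), 3 * cfg.total_droplets).conc_per_ul
            for p in pooled]
    fit = linearity_fit(pooled.index.to_numpy(), conc)
    print(f"{target:8s} slope={fit.slope:.4f} copies/ul per copy, "
          f"R^2={fit.r_squared:.4f}")

res = lowest_detected_quantity(series)
print(f"\nlowest fully detected quantity: {res.copies} copies "
      f"(non-monotone run: {res.non_monotone})")
print("R^2 near 1 means droplet counting is linear down the series; the\n"
      "lowest detected quantity is the technical sensitivity in genomic copies.")
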