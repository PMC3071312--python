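"""Fit maximum specific growth rates for a simulated microplate.

Generates a small plate of three-phase OD600 curves with known growth
rates, fits every well, aggregates replicates, and derives the scalar
fitness statistics used to compare strains.
"""

import pandas as pd

from evotol import growth, synth

truth = pd.DataFrame({
    "well": ["A1", "A2", "B1", "B2"],
    "strain": ["ancestor", "ancestor", "evolved", "evolved"],
    "condition": ["stress"] * 4,
    "mu": [0.30, 0.30, 0.55, 0.55],
    "lag_h": [2.0, 2.2, 1.5, 1.7],
    "od0": [0.005] * 4,
    "capacity": [1.2] * 4,
})
plate, plate_map = synth.gen_growth_plate(truth, synth.SimConfig(seed=1, noise_sd=0.002))

fits = growth.fit_plate(plate, plate_map, growth.GrowthFitConfig(noise_sd=0.002))
print(fits[["well", "strain", "mu_max", "r_squared", "no_growth"]])

records = {(r.strain, r.condition): r for r in growth.aggregate_fitness(fits)}
anc = records[("ancestor", "stress")]
evo = records[("evolved", "stress")]
print(f"\nancestor mu = {anc.mu_max:.3f} +/- {anc.se:.3f}")
print(f"evolved  mu = {evo.mu_max:.3f} +/- {evo.se:.3f}")
print(f"relative fitness (evolved / ancestor) = "
      f"{growth.relative_fitness(evo.mu_max, anc.mu_max):.2f}")
print(f"percent relative inhibition of the ancestor = "
      f"{growth.percent_relative_inhibition(anc.mu_max, evo.mu_max):.0f}%")
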