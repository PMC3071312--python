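# evotol

Quantitative analysis toolkit for microbial stress-tolerance evolution
experiments.  It covers the full analysis arc of a laboratory-evolution
study of a solvent-tolerant bacterium:

| module | what it does |
| --- | --- |
| `evotol.growth` | maximum specific growth rates from OD600 curves; relative fitness, inhibition, tolerance and enzyme-activity statistics |
| `evotol.epistasis` | epistasis decomposition of combination-mutant fitness against the multiplicative null, with delta-method and bootstrap CIs |
| `evotol.genotype` | mutation catalogs, parallel-evolution tallies, mutation ordering from allele trajectories, resequencing variant triage |
| `evotol.expression` | microarray preprocessing (background adjust, glog + quantile normalization, replicate collapse, probe selection, gene filter) and moderated-t differential expression with BH FDR control |
| `evotol.nca` | network component analysis: TF activities from expression via a known connectivity, identifiability checks, and a subset-consensus procedure for condition-limited designs |
| `evotol.qpcr` | mechanistic MAK2 quantification of qPCR amplification curves |
| `evotol.synth` | synthetic-data generators with planted ground truth for every pipeline |
| `evotol.validation` | seeded end-to-end recovery studies used by the acceptance tests |

## Worked example: growth rates and relative fitness

```python
import pandas as pd
from evotol import growth, synth

# simulate a small plate with known rates (ancestor 0.30/h, evolved 0.55/h)
truth = pd.DataFrame({
    "well": ["A1", "A2", "B1", "B2"],
    "strain": ["ancestor", "ancestor", "evolved", "evolved"],
    "condition": ["stress"] * 4,
    "mu": [0.30, 0.30, 0.55, 0.55],
    "lag_h": [2.0, 2.2, 1.5, 1.7],
    "od0": [0.005] * 4, "capacity": [1.2] * 4,
})
plate, plate_map = synth.gen_growth_plate(truth, synth.SimConfig(seed=1, noise_sd=0.002))

fits = growth.fit_plate(plate, plate_map, growth.GrowthFitConfig(noise_sd=0.002))
recs = {(r.strain, r.condition): r for r in growth.aggregate_fitness(fits)}
anc, evo = recs[("ancestor", "stress")], recs[("evolved", "stress")]
print(round(anc.mu_max, 3), round(evo.mu_max, 3))
# 0.301 0.554
print(round(growth.relative_fitness(evo.mu_max, anc.mu_max), 2))
# 1.84
```

The fitter scans every contiguous window of the blank-corrected ln(OD)
series and selects the best-qualifying window by a noise-penalized slope
score; see `docs/methods.md` for the model and the calibration study.

## Other entry points

Each script in `examples/` is a short, self-contained walk-through of one
capability and can be run directly:

```sh
python examples/growth_rates.py
python examples/epistasis_scan.py
python examples/mutation_catalog.py
python examples/differential_expression.py
python examples/tf_activities.py
python examples/qpcr_quantification.py
```

Packaged reference tables (mutation catalogs, parallel-evolution tallies,
an allele-state trajectory) load via `evotol.genotype.load_table1()` and
friends.

## Validation

`python scripts/acceptance.py --seed 1234 --out results.json` reruns every
recovery study (planted growth rates, null epistasis false-positive rate,
NCA activity recovery and subset-consensus selection, null-FDR of the
differential-expression pipeline, MAK2 recovery, variant-triage
separation) and writes a JSON summary.  The same studies back
`tests/test_acceptance.py`:

```sh
python -m pytest -q tests/
```

## Layout

- `src/evotol/` — the library (plus packaged TSV fixtures in `evotol/data/`)
- `tests/` — unit, property, and acceptance tests
- `examples/` — runnable narrative walk-throughs
- `docs/methods.md` — statistical methods, parameter rationale, design notes
- `scripts/acceptance.py` — end-to-end validation summary
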