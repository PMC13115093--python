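# teacolloid

Computational pipeline for optimising the isolation of **white-tea
micro-nanoparticles (WTMPs)** from microfiltered tea infusion colloids
(WTCs), and for explaining why the isolated fraction is more stable than its
parent colloid.

Tea infusions carry colloidal protein–polysaccharide–polyphenol particles.
Isolating a clean nanoparticle fraction by ultrafiltration–centrifugation
means choosing a membrane molecular-weight cut-off (MWCO), a centrifugal
force and a spin time — a multi-criteria trade-off between particle
retention, dispersion uniformity, electrostatic stability and purification.
This package implements every computation of that workflow:

- **`topsis`** — the six-step TOPSIS ranking of separation conditions on
  five DLS criteria (Z-average, count rate, PDI, |zeta potential|,
  conductivity). Criteria are vector-normalised
  (Z<sub>ij</sub> = X<sub>ij</sub>/√ΣX<sub>ij</sub>²), weighted
  (w = 0.15, 0.20, 0.25, 0.15, 0.25), compared with per-criterion
  benefit/cost ideal vectors, and scored by closeness
  C = d⁻/(d⁺ + d⁻). A validator checks printed closeness tables for
  internal consistency.
- **`binding`** — Stern–Volmer (F₀/F = 1 + K<sub>SV</sub>[Q]) and
  double-logarithmic (lg(F₀/F − 1) = lg K<sub>a</sub> + n·lg[Q]) fits to
  fluorescence titrations of the BSA–pectin complex with gallic acid or
  caffeine.
- **`mmgbsa`** — MM/GBSA bookkeeping: frame aggregation, the additivity
  identities ΔE<sub>gas</sub> = ΔE<sub>vdw</sub> + ΔE<sub>ele</sub>,
  ΔG<sub>solv</sub> = ΔG<sub>GB</sub> + ΔG<sub>SA</sub>,
  ΔG<sub>bind</sub> = ΔE<sub>gas</sub> + ΔG<sub>solv</sub>, the nonpolar
  term ΔG<sub>SA</sub> = 0.0072·ΔSASA, and a decomposition-table validator.
- **`group_compare`** — Welch's unequal-variance t-test from summary
  statistics (mean ± SD, n), reproducing the reported WTC-vs-WTMP
  composition p-values.
- **`stability`** — delta/range metrics over temperature, pH, storage and
  freeze–thaw sweeps, and two-system comparisons.
- **`synthetic_data`** — seeded generators for all five input tables, so the
  full pipeline runs and is tested without any instrument data.

## Worked example

Rank a synthetic 2 × 5 × 3 factorial campaign (30 conditions) and fit a
quenching constant:

```python
from teacolloid import synthetic_data, topsis, binding
from teacolloid.synthetic_data import TitrationDesign

records = synthetic_data.gen_condition_table(seed=42)   # 30 conditions
result = topsis.run_topsis(records)
print(result.to_frame().sort_values("rank").head(3))

series = synthetic_data.gen_titration(TitrationDesign(ksv_true=7.6e6),
                                      law="stern_volmer")
fit = binding.stern_volmer_fit(series)
print(f"K_SV = {fit.ksv:.3e} L/mol, intercept = {fit.intercept:.3f}")
```

```
 mwco_kda  time_min  force_g  d_pos  d_neg  closeness  rank
    100.0      10.0   5000.0 0.0062 0.0285     0.8205     1
    100.0      10.0   4000.0 0.0065 0.0284     0.8129     2
    100.0      30.0   6000.0 0.0071 0.0307     0.8129     3
K_SV = 7.600e+06 L/mol, intercept = 1.000
```

The 100 kDa membrane conditions dominate the ranking (the generator plants
the trends the campaign observed: the looser membrane retains smaller, more
uniform, better-purified particles), and the noiseless Stern–Volmer fit
returns exactly the constant that generated the titration, with the
theoretical intercept of 1.

The same stages are exposed as a CLI:

```bash
teacolloid simulate conditions --seed 42 --out conditions.csv
teacolloid topsis --conditions conditions.csv --out ranking.csv
teacolloid binding --titration titration.csv --f0 8608 --model sv --out fit.json
```

Welch comparison of the bundled composition summaries (μg/mg, n = 3):

```python
from teacolloid import group_compare, reference
print(group_compare.compare_composition_table(reference.composition_summaries()))
```

```
     component  t_stat    df  p_two_sided
       protein    -3.1 3.909      0.03737
polysaccharide   1.608 2.624       0.2189
tea_polyphenol    19.7 3.485    0.0001069
      caffeine   355.2     4     3.77e-10
   gallic_acid  -224.6 2.941    2.537e-07
```

All five components except polysaccharide differ significantly between the
parent colloid and the isolated fraction — gallic acid is enriched about
fourfold while caffeine drops, the compositional remodelling the binding and
MM/GBSA analyses then rationalise.

## Layout

```
src/teacolloid/
  tabular_io.py      CSV schemas + JSON run configuration
  synthetic_data.py  seeded generators for all input tables
  topsis.py          six-step ranking + closeness-table validator
  binding.py         Stern–Volmer and double-log quenching fits
  mmgbsa.py          energy decomposition and table validator
  group_compare.py   Welch t-tests from summaries or replicates
  stability.py       sweep metrics and comparisons
  reference.py       bundled reported tables (ranking, composition, energies)
  cli.py             `teacolloid` command-line entry point
```

See `docs/methods.md` for the models, assumptions and design choices.
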