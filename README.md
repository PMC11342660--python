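# forestmit

Factorial simulation framework for quantifying the carbon-mitigation
potential of managed temperate forests. A reduced-form, patch-replicated
stand emulator (logistic cohort growth, stochastic stand-replacing
disturbances with temperature-dependent probabilities, staggered partial
harvests, salvage logging) feeds a harvested-wood-product chain
(fixed allocation fractions, Gamma-survival decay with 3/18/93-year
medians, usage ramp and cascading scenarios) and a substitution module
(displacement factors 1.5 / 0.67 tC/tC with exponential decarbonization
schedules). The full 9-factor design (3456 scenarios) is simulated with
common random numbers and analyzed through exact pairwise-difference
attribution.

## CLI

```bash
# simulate an ensemble (full Table-style design by default)
forestmit run --config configs/example.yaml --out results.csv --patches 10 --seed 1

# pairwise attribution of one factor (a minus b), exponential subset
forestmit compare --results results.csv --factor salvage --a true --b false \
    --metric total_mitigation --horizon 2050

# effect summaries for all canonical contrasts
forestmit summarize --results results.csv --out summary.csv
```

The results CSV has one row per (scenario, horizon) with every factor
level plus `combined_sink`, `cumulative_avoided` and `total_mitigation`
(kgC/m2). The YAML config can restrict factor levels and override stand,
harvest, forcing and substitution parameters (see `configs/example.yaml`).

## Package layout

| module | contents |
| --- | --- |
| `forestmit.scenarios` | 9-factor design, `ScenarioConfig`, enumeration |
| `forestmit.forcing` | synthetic anomaly trajectories, disturbance-probability responses |
| `forestmit.stand` | patch/cohort stand emulator (growth, mortality, disturbance, harvest, dead-pool decay) |
| `forestmit.harvest` | fresh-cut and salvage carbon partitioning |
| `forestmit.products` | product allocation, Gamma decay ledger, usage ramp, cascading |
| `forestmit.substitution` | displacement factors and decarbonization multipliers |
| `forestmit.accounting` | combined sink and total mitigation metrics |
| `forestmit.experiment` | ensemble driver with staged memoization, pairwise differences, summaries |
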