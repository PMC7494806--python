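# droughtmem

Drought **stress-memory** analysis for plant phenotyping panels.

Priming experiments expose plants to repeated sub-lethal drought episodes
(water restriction followed by recovery) and ask whether that exposure
"trains" the plant: do primed plants senesce more slowly, keep more leaf
area, cool their leaves harder, or discriminate more strongly against
<sup>13</sup>C than never-stressed controls of the same accession?
`droughtmem` turns the raw repeated measurements of such an experiment into
per-accession memory indices, biomass-based tolerance scores, and a
multivariate classification of the panel — and ships a synthetic-experiment
generator with known ground truth so the whole chain is testable by
parameter recovery. It is aimed at crop ecophysiologists and pre-breeding
programs screening germplasm panels (e.g. crop wild relatives) for drought
tolerance.

## The indices

For each accession, primed (pr) and non-primed (npr) plants are summarised
and contrasted:

| Quantity | Per-plant summary | Memory index | Occurrence |
|---|---|---|---|
| Senescence *S* (SPAD/day) | OLS slope of SPAD vs time, from peak greenness to harvest | STM_S = S_pr − S_npr | STM_S > 0 |
| Foliar area FA (cm²) | maximum over assessments | STM_FA = FA_max_pr / FA_max_npr | STM_FA > 1 |
| Leaf−air temperature dT (°C) | minimum over events | STM_dT = dT_min_pr / dT_min_npr (both minima < 0) | STM_dT > 1 |
| ¹³C discrimination Δ (‰) | max over occasions of the event-mean Δ, with Δ = (δₐ − δₚ)/(1 + δₚ/1000), δₐ = −8‰ | STM_Δ = Δ_max_pr / Δ_max_npr | STM_Δ > 1 |

Harvest dry biomass Y feeds two tolerance indices across the population:
the stress susceptibility index SSI = (1 − Y_pr/Y_npr)/(1 − Ȳ_pr/Ȳ_npr)
(lower = more resilient) and the geometric mean productivity
GMP = √(Y_pr·Y_npr). Both are converted to 1–10 decile scores — the
resilience capacity index (RCI, from SSI inverted) and the production
capacity index (PCI, from GMP) — and each accession is placed in a
Fernandez group (A: good under stress and non-stress, B: productive only,
C: resilient only, D: poor in both) against the population medians.
Population structure is explored with Pearson correlations, standardized
PCA and Ward clustering on the leading component scores.

## Worked example

```python
from droughtmem import SimConfig, generate_experiment, run_analysis

cfg = SimConfig(n_accessions=59, seed=42)   # 59 accessions x 2 treatments x 4 replicates
exp = generate_experiment(cfg)
result = run_analysis(exp.tables)

for name, info in result.occurrence.items():
    print(f"{name:10s} occurrence {info['percent']:5.1f}%  ({info['n_true']}/59)")
print(result.tolerance_scores.head(3).round(2).to_string(index=False))
```

prints

```
stm_s      occurrence  81.4%  (48/59)
stm_fa     occurrence  15.3%  (9/59)
stm_dt     occurrence  30.5%  (18/59)
stm_delta  occurrence  52.5%  (31/59)
accession_id  SSI   GMP  RCI  PCI group
     SIM-001 0.58 18.55  8.0  4.0     C
     SIM-002 1.49 18.10  3.0  4.0     D
     SIM-003 1.96 21.31  1.0  5.0     B
```

The occurrence lines say what fraction of the panel shows each memory
response under strict inequalities (here 48 of 59 accessions senesce more
slowly after priming). The score table reads per accession: SIM-001 loses
relatively little biomass under priming (SSI 0.58, scored RCI 8) but is an
average producer (PCI 4), so it lands in group C — resilient but not
productive.

The same pipeline runs from the shell:

```sh
droughtmem simulate --out data/ --seed 42
droughtmem analyze --data data/ --out results/ --k-clusters 3
droughtmem recover --n-seeds 20        # parameter-recovery report
droughtmem fixtures --out table1.csv   # the 59-accession panel metadata
```

`analyze` accepts any directory of long-format CSVs with the same schemas
(one row per plant, measurement day and value), so real exports can be
analysed identically.

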