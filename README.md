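# greenscape

Multi-scenario simulation and optimization of urban green-space landscape
patterns from categorical land-cover rasters.

Cities that want to plan green space (cultivated land, forest, grassland,
wetland, water) against competing economic pressure need three things: a
quantitative account of how the landscape has been changing, a spatial
simulation of where it will change next under alternative policies, and an
optimal target structure that balances ecological and economic benefit.
`greenscape` implements that full chain for 100 m categorical rasters
(Globeland30-coded by default) and ships a seeded synthetic-landscape
generator so everything runs and is tested entirely offline.

## What it computes

**Change dynamics.** From two dates the package cross-tabulates the
transition matrix ΔLU<sub>ij</sub> and reports the single dynamic degree
per class, K = (U_b − U_a)/U_a · (1/T) · 100 %/yr, and the comprehensive
degree L<sub>c</sub> = [Σ<sub>i≠j</sub> ΔLU<sub>ij</sub> / (2 Σ<sub>i</sub>
LU<sub>i</sub>)] · (1/T) · 100 %/yr.

**Suitability + CA simulation.** A single-hidden-layer neural network
(12 logistic units, trained on a 2% uniform cell sample) maps normalized
driver layers to per-class occurrence probabilities p(p,k) with
Σ<sub>k</sub> p(p,k) = 1 per cell. Future demand per class comes from
powering the empirical Markov transition matrix; named scenarios rescale
selected transition probabilities (e.g. forest→artificial × 0.5 under
ecological protection) with the mass change absorbed by the stay
probability. A cellular automaton then allocates cells by roulette over
TP<sub>k</sub> = suitability × neighborhood × inertia, under a binary
conversion-cost matrix and a restriction mask, until every class is
within tolerance of its demand. Map agreement is scored with overall
accuracy and Cohen's kappa.

**Landscape pattern metrics.** Class-level NP, ED (m/ha), LPI (%), AI (%)
and landscape-level SHDI, SHEI, CONTAG (%), DIVISION, with the standard
raster conventions (8-connected patches by default, rook adjacencies for
AI/CONTAG).

**Structure optimization.** A weighted ecological–economic linear program
max α·E<sub>d</sub>(x) + β·E<sub>p</sub>(x) over the seven class areas
x₁..x₇, subject to per-class box bounds and a fixed total area. The
box-plus-one-equality structure admits an exact greedy solution (slack
above the lower bounds goes to variables in descending weighted
coefficient), cross-checked against a simplex solve. The `harbin2030`
preset ships the published coefficients, bounds and weights (α=0.60,
β=0.40).

## Worked example

```bash
python examples/06_structure_optimization.py
```

prints

```
optimal land-cover structure (km²):
    cultivated:     22299.88
        forest:     19379.10
     grassland:      4271.00
       wetland:       920.74
         water:      4648.54
    artificial:      2453.68
          bare:        17.24
Ep = 194,732.26  Ed = 602,823.30  comprehensive = 797,555.56 (CNY million)
```

Cultivated land sits at its food-security floor, artificial surface fills
its 10%-growth cap (the highest economic coefficient), and the remaining
~3,806 km² of slack goes to water, the uncapped class with the highest
ecological coefficient — the sustainable-development structure. The other
examples (`examples/01`–`05`) generate a synthetic scene, compute its
dynamic degrees, train the suitability network, run the three named
scenarios through the CA, and report the pattern metrics; each prints a
closing comment on how to read its numbers. The same stages are available
as a thin CLI (`greenscape synth|change|suitability|simulate|metrics|
optimize|run`).

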