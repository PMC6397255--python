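# dhtpoly

Quantitative machinery for **living chain-growth copolymerization of DNA
hairpin tiles (DHTs)** — metastable double-crossover tiles that polymerize
into 1D nanofilaments only when an initiator strand opens the first hairpin
by toehold-mediated strand displacement.

The package is aimed at people modeling structural DNA nanotechnology: it
lets you design and validate tile/initiator systems at the strand level,
simulate the polymerization statistics that distinguish living (chain-growth)
from step-growth assembly, analyze label-count and photobleaching data the
way single-molecule experiments are analyzed, and estimate the mechanical
compliance of the resulting filaments.

## What it computes

**Activation cascade** (`tile_model`, `synthetic`). Tiles are four annotated
strands; design rules (sticky-pair complementarity, stem self-consistency,
single-stranded toeholds) are validated, and the strand-displacement cascade
is replayed symbolically: the initiator invades the toehold `TGTCAC`,
exposing the loop `TGAACC`, which invades `GGTTCA`, exposing `GTGACA` — the
initiator's own active segment, closing the self-propagating cycle.

**Polymerization statistics** (`chain_growth`, `dispersity`). With
initiation and propagation sharing identical toehold kinetics, the
fast-mixing limit puts k ~ Poisson(μ) repeat units on each initiator site,
μ = [M]₀/[I]₀. Number- and weight-averaged lengths follow

    Ln = ΣNᵢLᵢ/ΣNᵢ,  Lw = ΣNᵢLᵢ²/ΣNᵢLᵢ,  PDI = Lw/Ln = (1+μ)/μ,

so dispersity narrows toward 1 as μ grows, while the no-initiator thermal
control follows Flory step-growth statistics with PDI → 1 + p. Label counts
over detected filaments are zero-truncated Poisson, fitted by maximum
likelihood. Monomer re-feeding resumes growth linearly in the cumulative
ratio (the living signature).

**Photobleaching step counting** (`photobleach`). Staircase traces at the
camera's 3.88 Hz are segmented by an exact penalized least-squares
change-point program, blinking is merged, and level drops are quantized by a
(batch-pooled) unit step height — ≥ 95% exact recovery up to 10 fluorophores
at SNR ≥ 5.

**Mechanics** (`mechanics`). Filaments are 1D elastic rods (duplex
230 pN·nm², DX regions 2×, nicked junctions ÷100, soft single-stranded
ends); normal-mode analysis at 298 K gives per-node RMSF, and compliance is
reported relative to a 24-bp duplex.

## Worked example

```python
from dhtpoly import (SimParams, simulate_living, label_counts, fit_poisson,
                     LengthSample, dispersity_summary, chain_contour_lengths)
from dhtpoly.chain_growth import tile_counts

pop = simulate_living(SimParams(ratio_MI=10, n_initiators=10_000, seed=42))
t = tile_counts(pop, include_uninitiated=True)
print(dispersity_summary(LengthSample(t, allow_zero=True)).PDI)
# 1.100558   — closed form (1+10)/10 = 1.1

print(chain_contour_lengths(pop, tile_length_nm=16.0).mean())
# 320.0      — nm; 20 tiles x 16 nm, matching the AFM-scale mean

pop1 = simulate_living(SimParams(ratio_MI=1, n_initiators=10_000, seed=42))
hist = label_counts(pop1, labeling_efficiency=1.0, truncated=True)
print(100 * hist.counts[1] / hist.n, fit_poisson(hist).lambda_hat)
# 58.71385684942329 0.9970529089447873
#   — % singly-labeled detected filaments (closed form 58.2%, measured 62%)
#     and the zero-truncated Poisson mean
```

The PDI of 1.1 at ratio 10 versus ~2 for the thermal control, the Poisson
label statistics, and linear regrowth on re-feeding are the three fingerprints
of living chain-growth assembly.

A command-line interface mirrors the library:

```bash
dht fixtures tiles --seed 1 --out system.json --fasta strands.fa
dht validate --system system.json --fasta strands.fa
dht simulate --ratio 10 --n-init 10000 --seed 42 --out lengths.csv --population pop.json
dht extend --population pop.json --to-ratio 20 --out lengths2.csv
dht stats lengths.csv
dht bleach synth --steps 5 --snr 5 --n 200 --seed 7 --out traces.csv
dht bleach count traces.csv --out calls.csv
dht mech --design filament --n-ab 10 --out rmsf.csv
dht run --config run.yaml
```

The numbered scripts under `analysis/` run the full story — tile design,
dispersity across ratios, label statistics, photobleaching recovery,
mechanics — and write their tables to `results/`.

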