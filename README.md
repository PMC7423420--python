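# wordage

Word-age distributions for centre–periphery cultural diffusion on population
networks.

Some dialect words turn up in geographically distant regions while missing in
between — the classic concentric pattern around an old cultural capital such
as Kyoto. `wordage` is for quantitative linguists and cultural-evolution
researchers who want to model that pattern mechanistically: a single central
population `P0` invents one new variant per time step, learners in peripheral
populations `P1..Pn` copy role models across a network of transmission rates
`a_ij` (rows summing to one), and every variant is tracked by its **age** ρ —
steps since invention — which stands in for its identity.

In the large-population limit the dynamics are exactly linear. The package
computes, per population:

- the transient and equilibrium age distributions
  `f(ρ) = A^(ρ−1) a_·0` (with `A` the periphery transmission matrix and
  `a_·0` the rates of copying from the centre),
- the equilibrium mean age from `(E − A) r = 1` and its SD from the moment
  system `(E − A) m = 2Ar + 1`,
- the heterozygosity `H_k = 1 − Σ_ρ f_k(ρ)²`,

together with builders for the analysed topologies (uni/bidirectional
chains with closed-form moments `r_k = k/a` and `r_k = k(2n−k+1)/(2a)`,
rectangular lattices, chain and lattice barriers), a gravity-model builder
for geographic node tables (`φ_ij = π_i π_j / (1 + d_ij²/γ²)`, row-normalized)
with a bundled 46-prefecture Japanese table, and a finite-population
agent-based simulator for cultural drift.

## Worked example

```python
import wordage as w

# two-way chain of 9 populations, neighbour rate 0.1
net = w.build_bidirectional_chain(9, 0.1)
print(w.equilibrium_mean(net)[[0, 4, 8]])   # [ 90. 350. 450.]
print(w.bi_chain_moments(9, 0.1)[0][[0, 4, 8]])  # same, analytically

# heterozygosity needs the full distribution up to a cut-off
dist = w.equilibrium_age_distribution(net, rho_max=10_000)
print(w.heterozygosity(dist)[[0, 8]])       # [0.96744 0.99879]

# Japanese prefectures, gravity-weighted, Kyoto central
geo = w.build_geo_network(w.japan_prefectures(),
                          w.GravityConfig(gamma=10.0))
ages = dict(zip(geo.labels, w.equilibrium_mean(geo)))
print(round(ages["Osaka"]), round(ages["Tokyo"]), round(ages["Aomori"]))
# 239 571 577
```

The chain numbers say that with two-way diffusion the population nine steps
from the centre holds words 450 steps old on average (versus 90 under one-way
diffusion), and that nearly every pair of speakers there uses different
variants. On the prefecture network, words reach nearby Osaka quickly (mean
age 239) but the populous Tokyo area retains its own learners and stays as
old (571) as remote northern Tohoku (577) — the east–west asymmetry that
population weighting creates.

The `examples/` directory holds one short script per capability (chain
profiles, age distributions, barriers, the prefecture network, drift
simulation); each prints its numbers with a line of interpretation. A thin
CLI mirrors the builders:

```
wordage chain --mode uni -n 9 -a 0.1 --closed-form
wordage geo --gamma 10 --mode pop --out ages.csv
wordage simulate --network net.csv --sizes 1000 --steps 5000 --reps 10 --seed 42
```

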