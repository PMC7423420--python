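# Methods

## The model

`wordage` implements a neutral-transmission model of cultural variants
spreading from a single inventing centre over a network of populations. One
central population `P0` invents exactly one new variant (a word form, a
pronunciation, any polychotomous trait) per time step and always carries only
the newest one. Each of `n` peripheral populations `P1..Pn` consists of
learners who, every step, first choose a source population — `Pj` with
probability `a_kj`, `j = 0..n`, for a learner in `Pk` — and then copy a
uniformly chosen role model from that population's previous-step state. All
updates are synchronous. Transmission is unbiased: rates do not depend on a
variant's age or frequency (novelty and conformity biases are deliberately
out of scope).

Because every variant is born in the centre, variant identity reduces to
**age** ρ (steps since invention), and the system state is the per-population
age-frequency vector `f_k(ρ, t)`. With populations large enough for sampling
noise to vanish, the dynamics are linear:

    f_k(ρ, t) = Σ_j a_kj f_j(ρ − 1, t − 1),   f_0(0, t) = 1.

Collecting the periphery-to-periphery rates into the matrix `A` (the centre's
column becomes the source-rate vector `a_k0`; the centre has no row — it
learns from nobody), the transient solution is `A^(ρ−1) a_·0` for ages
`1 ≤ ρ ≤ t`, plus `A^t f(ρ − t, 0)` for pre-existing variants (defined for
ages ≥ 1 only; age-0 initial mass is not representable, so when no initial
distribution is supplied the unaccounted share `A^t·1` is reported as tail
mass rather than invented). At equilibrium:

- mean age: `(E − A) r = 1`, solved by sparse LU (never explicit inversion);
- second moment: `(E − A) m = 2 A r + 1`, from the fact that a copied
  variant is one step older than its role model's; SD `= sqrt(m − r²)`;
- heterozygosity: `H_k = 1 − Σ_ρ f_k(ρ)²`, the chance two random speakers
  differ, summed to a finite cut-off.

Validity of a network means: all rates in `[0, 1]`, every row summing to one
(tolerance 1e−12), and every peripheral population reachable from the centre
along positive-rate edges (checked by BFS on the directed transmission graph;
equivalent to spectral radius of `A` below one, hence `(E − A)` invertible).

## Closed forms for chains

For a chain with a single neighbour rate `a` the moments are analytic. With
`k` the distance from the centre:

- unidirectional (`P0 → P1 → …`): `r_k = k/a`,
  `σ_k² = (k/a)(1/a − 1)` — a sum of `k` geometric waiting times.
- bidirectional: `r_k = k(2n − k + 1)/(2a)` and
  `σ_k² = k(2n − k + 1)(2n² − 2nk + k² + 2n − k + 1)/(6a²) − r_k`.

The subtracted term in the bidirectional variance is the *mean*, not its
square; printed renderings of this formula elsewhere are ambiguous, so the
form shipped here was validated symbolically at small `n` (where it reduces
to the geometric variance `(1 − a)/a²` at `n = k = 1`) and numerically
against the moment solve across `n ≤ 50` and several rates — the test suite
re-runs that cross-check. The moment solve, not the formula, is the
authority; the closed form is a convenience and an oracle.

## Cut-off policy

Distributions over age are infinite; sums are truncated at a cut-off chosen
so the ignored tail is negligible. Default policy: grow the cut-off until
every population's tail mass is below `tail_tol = 1e−9` (hard ceiling 1e7,
raising `CutoffError`). Fixed cut-offs (e.g. 1000 for the one-way chain,
10000 for the two-way chain and barrier analyses) can be requested explicitly
and are what the chain heterozygosity runs use. Heterozygosity warns when the
tail exceeds 1e−6, since it is the only reported statistic that is
cut-off-sensitive (mean and SD always come from exact solves).

## Topology builders

- **Chains** as above; `n = 1` makes the two builders coincide.
- **Lattice**: `m × l` rectangle, von Neumann neighbourhoods, rate `a` per
  edge, self-rate `1 − a·degree` (requiring `a ≤ 1/4` on interior nodes).
  Coordinates are 1-based `(x=column, y=row)`; the centre may sit anywhere.
  A single-row lattice equals the bidirectional chain (tested).
- **Chain barrier**: the two rates across one edge drop to `b < a`; the
  freed probability `a − b` is returned to the two affected self-rates, the
  only reading consistent with rows summing to one.
- **Lattice barrier**: one node whose every incident edge is crossed at `b`
  in both directions, self-rates adjusted likewise. Since the construction
  fixes only the crossing rate, the same self-rate absorption rule is
  applied; this is a modelling choice documented here rather than a derived
  fact.

## Gravity (interaction-density) networks

For geographic node tables the transmission rates come from a modified
gravity model. The interaction density between nodes `i` and `j` is
`φ_ij = π_i π_j / (1 + d_ij²/γ²)` (population-dependent) or
`1/(1 + d_ij²/γ²)` (population-independent), with `d_ij` the great-circle
distance (haversine, sphere radius 6371.0 km, configurable) and `γ` the
half-decay distance in km. Rates are `a_ij = φ_ij / Σ_l φ_il`, the sum
running over *all* nodes including the learner's own (`φ_ii` with `d = 0`):
dropping self-interaction would be wrong — it is exactly what makes populous
nodes retain their own learners and act as conservative barriers. Only
population *ratios* matter after normalization (uniform rescaling leaves the
network bit-identical), so any population unit works.

The bundled table covers the 46 Japanese prefectures other than Okinawa
(historically isolated), with prefectural-office coordinates and 2018
population estimates in thousands, and Kyoto — the historical source of
innovations in the concentric-dialect account — as the centre.
`scripts/build_prefecture_fixture.py` regenerates the CSV from its raw table.
At `γ = 10 km` the population-dependent network puts the Tokyo area and
northern Tohoku (we read those as the Tokyo and Aomori prefectures; nearby
prefectures behave alike) between 550 and 600 steps of mean word age, with
westward diffusion visibly faster than eastward; the population-independent
mode is near-symmetric east/west. Raising `γ` to 20 or 50 km shrinks all
ages (words travel farther per step) without changing the qualitative
picture. Population-vintage differences of a few percent move prefecture
means by only a few steps.

## Agent-based simulator

The ABM replays the exact copying mechanism with finite agent counts `N_k`:
per step and population, each agent draws a source population by inverse-CDF
lookup on its rate row, then a uniform role model from that population's
previous state; the copied age is incremented by one; the centre contributes
a permanent age-0 role model. Variant identity is the invention step, so two
agents share a variant iff their ages match. Updates are synchronous; only
the current state is kept (no per-agent history). Replicate `r` uses the
`r`-th child of `SeedSequence(seed)`, making runs bit-reproducible and
replicates independent.

Expected mean ages are *exactly* the deterministic recursion's regardless of
`N` (the update is linear in ages), so the simulator is an unbiased
stochastic check of the solver; heterozygosity, by contrast, is depressed to
at most `1 − 1/N_k`. Summaries discard a burn-in (default judgement: 500 of
3000 steps for the convergence runs, far beyond the chain's relaxation time)
and report time-averaged per-replicate statistics with across-replicate
standard errors. The convergence criterion used in the tests — time-averaged
means within 3 SE of the deterministic values at `N = 10⁴`, 5 replicates —
is this package's own; with 5 replicates a 3-SE band is roughly a 96%
interval per population, so the check is pinned to the package's default
seed.

## Problem sizes and numerics

All linear algebra is sparse (`scipy.sparse`); the largest routinely solved
system here is the 15×15 lattice (224 unknowns) and the 45-node prefecture
network — far below any performance ceiling, chosen to match the study
settings rather than to stress the solver. Equilibrium distributions iterate
`v ← A v` column by column; for the two-way chain at `a = 0.1` the 1e−9 tail
tolerance is met near age 400 for `n = 9`. Variances within `[−1e−9, 0]`
from the moment solve are clamped to zero; anything lower raises
`NegativeVarianceError`. Test comparisons use absolute tolerance 1e−8 unless
a tighter identity (1e−10, 1e−12) is being asserted.

## Limitations

- One inventing centre, constant invention rate, no mutation en route;
  multiple centres or peripheral innovation need a different framework.
- No novelty/prestige/conformity bias; the unidirectional chain is the only
  stand-in for strongly novelty-biased diffusion.
- Age measures variant *identity*, not linguistic distance between variants.
- The gravity mode ships great-circle distances only (no travel-time or
  railway metrics) and a single static population per node.
- The synthetic study networks (chains, lattices) idealize geography; the
  prefecture network adds realistic distances and populations but still
  ignores within-prefecture structure, so agreement there shows consistency
  of the mechanism, not a fit to dialect atlas data.
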