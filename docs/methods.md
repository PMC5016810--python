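# Methods

## Landscape model

Habitat is a two-type (`suitable`/`unsuitable`) square lattice of side `L`
(default 100) with periodic boundaries and von Neumann neighbourhoods
(z = 4). Two statistics summarise it: availability `s` (fraction suitable)
and connectivity `q_s/s = ρ_ss/s`, the conditional probability that a
neighbour of a suitable patch is suitable. Pair densities are counted over
all `4L²` ordered neighbour slots, so each unordered pair counts twice and
`ρ_ss + 2ρ_su + ρ_uu = 1`.

Non-negativity of the mixed pair density bounds the attainable
connectivity: `ρ_su = s(1 − q_s/s) ≤ 1 − s`, i.e. `q_s/s ≥ (2s−1)/s`.
Dense habitat cannot be arbitrarily fragmented; the generator rejects
targets outside this range.

### Generation

Exactly `round(s·L²)` cells are suitable, so availability carries no
sampling error. Connectivity is then steered to within `tol_q`
(default 0.01) of its target:

1. *Seeding.* Cells are visited in random order and assigned suitable with
   probability proportional to `s·∏ q_{t/s}` over already-assigned
   neighbours (the pair-level conditional), which keeps the landscape
   statistically typical for its `(s, q)`. If the refinement below cannot
   close the remaining gap — which happens only for strongly
   over-dispersed targets, where descending into anti-correlated states by
   local swaps jams (greedy search gets trapped the way it does in
   anti-ferromagnets) — the attempt restarts from one checkerboard parity
   class: orthogonal neighbours always differ in parity, so that seed
   starts near the minimal pair count and refinement only has to *climb*,
   which is unfrustrated.
2. *Refinement.* Annealed Metropolis swaps of one suitable with one
   unsuitable cell, mixing uniform proposals with directional ones (lowest/
   highest suitable-neighbour-count candidates), with cost
   `|ρ_ss − target|`. The loop steers to a quarter of `tol_q` while the
   iteration budget lasts so the reported statistic is not biased toward
   the tolerance edge, and fails loudly rather than returning a near-miss.

Reported `s_meas`/`q_meas` are always re-measured from the final grid by
the same `measure_statistics` used everywhere else. Cluster labels come
from connected-component labelling (scipy) with components merged across
the periodic seam by default (`wrap=False` available), since dispersal uses
the torus topology; `mean_cluster_size` reports both the arithmetic and the
occupancy-weighted mean (the expected cluster size seen by a random
suitable cell, the mean-crowding reading of connectivity).

## Extended patch-dynamic model

State (fractions of **all** patches): `ρ₁` (patches with the basal
species), `ρ₁,₂` (patches with the 1→2 link), `ρ₂,₃` (full chains), and
the ordered pair densities `ρ₁₁`, `ρ₁ᵤ` carrying the basal species'
spatial correlation. Occupancies are nested (`ρ₂ = ρ₁,₂`, `ρ₃ = ρ₂,₃`,
`ρ₂,₃ ≤ ρ₁,₂ ≤ ρ₁ ≤ s`) because local chains collapse bottom-up.

Tri-trophic system (the bi-trophic one drops the last equation and the
`q_s/s` factor, its consumer dispersing globally):

    dρ₁/dt   = c₁ ρ₁ (1 − q_1/1 − q_u/1) − e₁ ρ₁ − μ₂₁ ρ₁,₂
    dρ₁,₂/dt = c₂ q_s/s ρ₁,₂ (ρ₁ − ρ₁,₂) − (e₁+e₂+μ₂₁) ρ₁,₂ − μ₃₂ ρ₂,₃
    dρ₂,₃/dt = c₃ ρ₂,₃ (ρ₁,₂ − ρ₂,₃) − (e₁+e₂+e₃+μ₂₁+μ₃₂) ρ₂,₃

* Basal colonization is neighbour-limited: `1 − q_1/1 − q_u/1 = q_s/1` is
  the chance a neighbour of an occupied patch is empty-but-suitable.
* Consumer colonization is damped by `q_s/s`, the within-cluster dispersal
  restriction: at `q_s/s ≈ 1` consumers behave like global dispersers, at
  `q_s/s ≈ 0` they cannot spread at all.
* A link dies when any member dies (summed `e_i`) or when predation inside
  it removes a prey (`μ_ji`); `μ₂₁ ρ₂,₃` appears in the `ρ₂,₃` loss because
  every full chain contains a 1→2 link whose basal member may be eaten.

Pair dynamics (ordinary pair approximation, z = 4, `(z−1)/z` closure,
`q_1/0 = ρ₁₀/ρ₀` with `ρ₁₀ = ρ₁ − ρ₁₁ − ρ₁ᵤ`, `ρ₀ = s − ρ₁`):

    dρ₁₁/dt = 2 c₁ ρ₁₀ [1/z + ((z−1)/z) q_1/0] − 2 m₁ ρ₁₁
    dρ₁ᵤ/dt = c₁ ρ₀ᵤ ((z−1)/z) q_1/0 − m₁ ρ₁ᵤ

with `m₁ = e₁ + μ₂₁ ρ₁,₂/ρ₁`: consumers are treated as randomly spread
over basal patches when accounting pair losses. Integrating pair
*densities* rather than conditional densities avoids 0/0 at low occupancy;
the conditionals are exposed read-only. The singlet and pair colonization
fluxes agree identically (`c₁ ρ₁ q_s/1 = c₁ ρ₁₀`), which the tests check
pointwise along trajectories.

Numerical choices: LSODA with `rtol 1e−8 / atol 1e−10`, `t_max` 10000,
early termination when the sup-norm of the derivative falls below 1e−9
(both criteria reported); extinction threshold `ρ_i < 1e−4`; ratio guards
floor denominators at 1e−12 and cap `ρ₁,₂/ρ₁` at its nesting bound 1;
colonization shuts off when `ρ₀ ≤` floor (saturated habitat). A state
leaving its invariant polytope by more than integrator-scale slack raises
instead of being clipped. Default initial conditions seed within-suitable
densities (0.1, 0.05, 0.025) down the chain with Bernoulli pairs
(`ρ₁₁ = θ²ρ_ss`, `ρ₁ᵤ = θρ_su`), mirroring the CA initializer.

The mean-field baseline (all levels global, no pair variables) is solved in
closed form — Levins occupancy `s − e₁/c₁`; bi-trophic from the quadratic
`c₁ρ₁² − (c₁s−e₁−μ₂₁)ρ₁ − μ₂₁(e₁+e₂+μ₂₁)/c₂ = 0` with gap
`ρ₁−ρ₁,₂ = (e₁+e₂+μ₂₁)/c₂` — and by a bracketed 1-D root-solve for the
tri-trophic interior equilibrium, falling back to boundary equilibria when
a level cannot invade.

## Cellular automaton

Discrete-time, same landscapes, chain height `k ∈ {0..3}` per cell (nested
by construction). Per step, three event families are drawn from the
start-of-step configuration: colonization with probability
`1 − (1 − c/A)^n` (A = z, cluster size, or lattice size for neighbour /
cluster / global dispersal; n = the matching source count), intrinsic death
`e_i`, and predation death `μ_ji` for prey inside a link. The
independent-trials form uses exactly the source counts each dispersal mode
can draw on and linearizes to the ODE rate terms. Deaths are drawn only for
species present at the step start, all events apply together, and the
cascade rule then removes species stacked above a vanished one — so a cell
colonized and struck in the same step ends post-extinction. A sequential
variant (colonize, then die) is available behind a flag for sensitivity
checks; global-dispersal denominators default to `L²` (all patches,
matching the ODE normalization) with the suitable-only variant documented
in code.

Replicated runs regenerate a fresh landscape per replicate (same `s, q`),
re-seed populations, and time-average occupancy over a trailing window;
the cross-replicate mean and SD are the steady-state estimate. The
full-scale reference protocol is `L=100`, 100000 steps, 10000-step window,
100 replicates; routine checks and the acceptance script use a scaled-down
profile (`L=50`, 20000 steps, 2000-step window, 10 replicates), which
resolves the same contrasts at a few seconds per replicate.

## What the validation does and does not show

The CA validates the ODEs where the approximations behind them hold:

* *All-global, full availability.* The CA is a discrete-time process; its
  per-step event probabilities equal continuous-time rates only to first
  order, so the mean-field consistency check runs at small per-step rates
  (c = 0.025, e = 0.00125, μ = 0.000625 — the standard symmetric ratios
  scaled down; equilibria depend only on rate ratios, so the mean-field
  values are unchanged). At c = 1 the discretization alone shifts CA
  equilibria by a few percent, which would confound the limit being
  checked.
* *Spatial contrasts* (clustered-vs-shredded occupancy ordering, pair-
  approximation bias) are checked at the standard rates c = 1, e = 0.05,
  μ = 0.025, where the EPDM systematically overestimates CA occupancy and
  more so at low availability — the expected direction and ordering of the
  pair-approximation error, which both the bias sign and its decrease with
  `s` confirm.

Synthetic landscapes are statistically controlled in `(s, q_s/s)` only;
real landscapes have gradients, anisotropy and multi-scale structure that
a two-point correlation does not capture, so passing tests show fidelity
of the *models to each other* under the stated assumptions, not fidelity
to any particular empirical landscape.

## Design choices made where the design was open

* Cluster labelling wraps the torus by default (consistency with
  dispersal); a no-wrap flag exists for flat-lattice replication.
* The coexistence classifier enforces bottom-up nesting: a level counts as
  present only if all lower levels are.
* The EPDM-vs-CA bias contrast is run at fixed `q = 0.5` with
  `s ∈ {0.3, 0.6}`: 2/3 is the largest availability for which `q = 0.5`
  is feasible, so 0.6 is the high-availability end of that slice.
* Sweep grids default to `s ∈ {0.05, …, 0.95}` with 20 evenly spaced
  connectivity points, masked per-`s` by feasibility; masked cells are
  absent from outputs, never zero-filled.
* Seeding is counter-based (master seed plus a stable label hash), so
  adding runs to a study never perturbs existing ones.

## Known limitations

* The pair approximation carries spatial correlation only for the basal
  species; consumer and predator correlations enter solely through the
  `q_s/s` damping and global mixing, which is why bias grows in
  highly fragmented, low-availability landscapes.
* Chains are limited to three levels with strictly nested diets — no
  omnivory, intraguild predation, competition or mutualism.
* Dispersal modes are the three idealized scales (neighbour, within-
  cluster, global); no kernels in between.
* The landscape generator controls first- and second-order statistics
  only; two landscapes with equal `(s, q_s/s)` can differ in higher-order
  structure.
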