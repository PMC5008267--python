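# Methods

## The model

`trophodyn` simulates the carbon dynamics of quantitative food webs whose
nodes fall into four categories — producers, consumers (herbivores and
predators), decomposers and non-living detritus — and asks which
node-importance index best identifies the species whose loss destabilises the
community.

The state variable is the carbon standing stock `B_i` (g C m⁻²) of each node.
The governing equations are

* producers: `dB_i/dt = r_i B_i G − Σ_j Φ_ij B_j − d_i B_i`, with the shared
  logistic term `G = 1 − Σ_pro B / K`;
* consumers and decomposers: `dB_i/dt = a_i Σ_j Φ_ji B_i − Σ_j Φ_ij B_j − x_i B_i`;
* detritus: dead producer matter (`d_j B_j`) and the unassimilated fraction of
  every feeder's intake (`(1 − a_j) · intake_j`), both routed by the
  proportions `p`, plus donor-linear detritus-to-detritus conversion `c`,
  minus consumption by detritivores and outgoing conversion.

Boundary imports and exports are assumed to be in balance and do not enter the
dynamics.  Decomposer egestion is routed into detritus exactly like consumer
egestion: without it the detrital budget cannot close and the equilibrium
property below fails.  For the same reason the detritus equation subtracts
consumption by *any* living feeder on detritus, so webs with detritivorous
consumers remain consistent.

Every rate constant is derived from the web's energy budget, not from
allometry: `r_i = (GPP_i − R_i)/B_i/(1 − 10^(−k0))`, `K = 10^(k0) Σ_pro B`,
`d_i` and `a_i` from the detrital outflows, `x_i = R_i/B_i`, `p` and `c` from
the flux shares.  Feeding follows either a saturating response

    Φ_ij = y_j ω_ij B_i^h / (H_j^h + q B_j H_j^h + Σ_k ω_kj B_k^h)

with preferences `ω_ij ∝ F_ij/B_i^h` (column-stochastic), half-saturation
`H_j = 10^b · mean(B)` over the living community, and `y_j` solved so that
`Φ_ij(B⁰) B⁰_j = F_ij`, or a linear response `Φ_ij = f_ij B_i` with
`f_ij = F_ij/(B_i B_j)`.  Both calibrations reproduce the empirical flux
matrix exactly at the initial stocks.

**Central correctness oracle.**  For a mass-balanced web with zero boundary
flows, the empirical state is an exact fixed point of the system under either
response form: each producer's `r B G` collapses to `GPP − R` at `t = 0`, each
feeder's assimilated intake minus respiration equals its predation and
detrital losses, and the detrital routing returns exactly the recorded flows.
The test-suite asserts this to 1e−9 relative across generated webs of 10–40
nodes; it chains the balancing, parameter derivation and right-hand side into
one algebraic identity and is the strongest single check in the package.

## Free parameters

Four scalars are not identified by the budget and are drawn per Monte-Carlo
replicate, shared by all consumers within a replicate:

| symbol | meaning                        | support     |
|--------|--------------------------------|-------------|
| `h`    | hill exponent (type II → III)  | U[1, 2]     |
| `k0`   | carrying-capacity coefficient  | U[0.01, 3]  |
| `b`    | half-saturation coefficient    | U[−1, 1]    |
| `q`    | predator interference          | U[0, 100]   |

`k0` is floored at 0.01 because the growth-rate formula is singular at
`k0 = 0` (the uniform support has zero mass at the point).  The mean stock
defining `H_j` is taken over living nodes only; a flag includes detritus.
Where a single canonical run is wanted (examples, the equilibrium acceptance
check) the package uses the central point of the supports,
`(h, k0, b, q) = (1.5, 1.5, 0, 50)`, exposed as `CENTRAL_DRAW`.

## Numerical integration

Windows of 1000 days are integrated with an adaptive Dormand–Prince 5(4)
Runge–Kutta stepper (jit-compiled), relative tolerance 1e−8 and absolute
tolerance 1e−12 times the median initial stock.  The step is capped at one
day so the extinction threshold — 1e−30 g C m⁻², far below every tolerance
scale — is monitored at least daily; the precision of the crossing time is
immaterial at that magnitude, so no root-finding is attempted.  A living node
crossing the threshold is zeroed and masked out of every interaction term
(zeros are not denormal, so no slow-float penalty); detrital stocks are
floored at zero but never go extinct.  Functional-response parameters are
fitted once at the pre-burn-in stocks and are not re-derived after
extinctions (a config flag enables re-fitting).  A per-window budget of 2e6
accepted steps converts a pathological window into a flagged replicate
failure instead of a hang; typical windows take 1e3–4e4 steps.  An
independent cross-check against `scipy.integrate.solve_ivp` on the same
right-hand side is part of the test-suite.

## Deletion experiments and stability metrics

After a 1000-day burn-in, nodes are removed one at a time: the top-ranked
living non-detrital node under the chosen index is deleted, 1000 days are
simulated, secondary extinctions are logged, and the ranking is recomputed on
the surviving web — weighted indices from the realized carbon flows at the
current state (which at the first step equal the empirical matrix exactly),
unweighted indices from the surviving topology.  Ties break lexicographically
by node id.  Detrital nodes are scored (they participate in effect
propagation) but never removed, so recycling persists until no living node
remains.

Losses during burn-in are counted as pre-experiment losses and reduce the
living pool `S_l` (configurable); robustness `R50` is the number of primary
removals needed for cumulative losses to reach `⌈S_l/2⌉`, divided by `S_l`;
survival area is `SA = Σ_p N_p / S_l²` over the survivor counts `N_p`, with
`SA + EA = 1` against the extinction area computed independently from the
loss log.  Each secondary extinction is classified against the web as it
stood at the start of its window: bottom-up if the extinct node lies
downstream of the removed node's outgoing energy, top-down if upstream, mixed
if both or neither; direct if the two were trophic neighbours.  Connectivity
and link-weight log-ratios compare the extinct node with the window's
survivors on the post-removal flux snapshot.

## Synthetic webs

The generator emulates the structure of empirical aquatic carbon-flow
networks without copying any particular one: 10–125 nodes split roughly into
a fifth producers, a tenth decomposers, one detrital pool per ~12 nodes and
the rest consumers; log-normal stocks (σ of log₁₀ = 1, spanning more than
three orders of magnitude per web); a target binary connectance hit by
constrained random attachment honouring the category rules (producers
prey-free, decomposers feeding only on detritus, every consumer anchored to a
lower trophic level, detritus fed by all living categories).

Diet shares scale with prey standing stock times a log-normal skew, consumer
intake is a mass-specific turnover in [0.05, 0.5] day⁻¹, egestion fractions
lie in [0.15, 0.5], and specific predation losses are capped at 0.5 day⁻¹ of
the prey's stock and 60% of the predator's assimilated intake.  Balance is
achieved by construction rather than by AVG2: respiration and gross primary
production absorb each living node's residual, and the detrital budgets are
closed by a short contraction iteration (egestion feeds back into detritus
with factor < 1 per round).  Detrital pools hold at least one day's
throughflow and decomposer stocks are floored so their imposed intake stays
within the same turnover bound as consumers' — without these floors the
balance can force a tiny pool to turn over orders of magnitude faster than
anything biological, which both stiffens the ODEs and creates spurious
unstable detritus–decomposer modes.  Generated webs pass the balance check at
1e−9 and are exact fixed points of the dynamics; the AVG2 balancer is
exercised separately on perturbed fixtures.

**What the generator does not emulate.**  Degree distributions are close to
uniform-random under the category constraints; empirical webs have skewed,
structured topologies (hubs, sediment bacteria with far-reaching indirect
pathways).  Consequences observed in the directional experiments: orderings
by link weight are clearly more destructive than degree orderings, and the
linear response is clearly less stable than the saturating one, exactly as on
empirical webs; but the *unweighted* direct-plus-indirect ranking is so
rank-correlated with plain degree on this family that it shows no extra
destructiveness (its mean R50/SA fall within a point of the degree
ordering's, slightly above rather than below).  Passing the weighted and
response-form contrasts on synthetic webs therefore says nothing about the
unweighted-indirect contrast on real webs, which appears to require
empirically structured indirect pathways.  The DI score computation itself is
verified against exhaustive walk enumeration to 1e−12.

## Design choices on open points

* Connectance counts all S nodes (detritus included) and all internal flows,
  detritus-to-detritus conversion included; boundary flows are excluded from
  L.  The weighted variant is the Bersier/Banašek-Richter quantitative link
  density: per-node base-2 entropies of in/out flux shares, exponentiated to
  effective link counts and averaged with throughflow weights, divided by S.
* AVG2 is realised as simultaneous input-based and output-based proportional
  corrections averaged per sweep, iterated to 1e−9 with a 1e5-sweep cap.
* `q` is one shared scalar per replicate (per-consumer values available via
  the API); effect-matrix rows with no consumers or no resources contribute
  zero through that channel.
* Monte-Carlo replicates draw independent `(h, k0, b, q)` per (index,
  replicate) from `SeedSequence([base_seed, kind, replicate])`, so tables are
  reproducible from one integer and replicates are uncorrelated.  The
  directional acceptance study instead pairs draws across indices (same draw,
  four orderings) to compare means at lower variance; it uses 10 webs of
  S = 30 with 13 paired draws per web and response form (~50 sequences per
  web and form, ~1000 total), which resolves the observed contrasts well
  within a few standard errors.

## Known limitations

* Empirical flow-network exports (e.g. from the `enaR` archive) are read via
  the CSV exchange format, but no downloader or R bridge is shipped; the
  catalogue-exactness test is red unless an export is supplied locally.
* No allometric parameterisation, no stochastic dynamics, no spatial
  structure, and no statistical post-processing (the long-form result tables
  are the interface to mixed-effects models and post-hoc tests).
* Linear-response equilibria of strongly cyclic webs can be genuinely
  unstable; the experiment then measures stability of whatever attractor the
  burn-in reaches, exactly as the protocol prescribes.
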