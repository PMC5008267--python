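# trophodyn

Bioenergetic food-web dynamics for identifying keystone nodes: parameterise a
mass-balanced consumer–resource ODE model from quantitative carbon-flow data,
rank nodes by four direct/indirect, (un)weighted centrality indices, simulate
sequential species deletions, and quantify network stability through
robustness and survival area.

## Who this is for

Ecologists working with quantitative flow networks (carbon budgets of
lakes, estuaries, coastal seas) who want to go beyond binary "hub" analysis:
does removing the node with the most links really cause the largest cascade
of secondary extinctions, or do link weights and indirect effects matter
more?  The package is used from Python; `examples/` holds one short script
per capability.

## The model in brief

Nodes carry carbon stocks `B_i` (g C m⁻²) in four categories.  Producers grow
logistically against a community carrying capacity `K = 10^k0 Σ_pro B`,
consumers and decomposers assimilate a fraction `a_i` of their intake and
respire at `x_i = R_i/B_i`, and detritus collects dead matter and egestion,
feeding decomposers in turn:

    producers:   dB_i/dt = r_i B_i (1 − Σ_pro B / K) − Σ_j Φ_ij B_j − d_i B_i
    feeders:     dB_i/dt = a_i Σ_j Φ_ji B_i − Σ_j Φ_ij B_j − x_i B_i
    detritus:    dB_i/dt = Σ_j p_ji d_j B_j + Σ_j p_ji (1−a_j)·intake_j
                           + Σ_j c_ji B_j − Σ_j Φ_ij B_j − Σ_j c_ij B_i

The functional response Φ is either saturating (Holling II–III with predator
interference) or linear, and both are calibrated so that `Φ_ij(B⁰)·B⁰_j`
reproduces the measured flux matrix exactly — a balanced web therefore starts
at a dynamical fixed point, which is the package's central correctness check.
Deletion experiments remove the top node under Max.D (degree), Max.DI
(direct+indirect effects), Max.wD (total carbon flux) or Max.wDI (weighted
direct+indirect), simulate 1000 days, log secondary extinctions (anything
falling below 1e−30 g C m⁻²), re-rank and repeat.  Stability of a sequence is
`R50` (fraction of primaries needed for 50% total loss) and the survival area
`SA = Σ_p N_p / S_l²`.

## Worked example

```python
import trophodyn as td

net = td.generate_web(td.GeneratorSpec(S=24, target_connectance=0.2, seed=42))
print(td.describe(net))
res = td.run_deletion_sequence(net, "max_wd", "nonlinear", td.CENTRAL_DRAW)
print(res.r50, res.sa)
```

Running `examples/01_generate_and_describe.py` prints

```
nodes (S)                 : 24
internal links (L)        : 115
binary connectance (C)    : 0.200
weighted connectance (Cw) : 0.106
mass balanced             : True (worst residual 0.00e+00)
```

— a 24-node web hitting the requested binary connectance, whose
entropy-weighted connectance is roughly half of it because flows are
unevenly spread, and whose every node budget closes exactly.
`examples/04_rank_and_delete.py` then runs a full deletion experiment on a
16-node web and ends with

```
robustness R50 = 0.400   survival area SA = 0.373
```

meaning 40% of the living nodes had to be removed before half the community
was lost, and the survivors-vs-removals curve retained 37% of its maximal
area — the flux-weighted ordering found removals whose cascades (two
top-down, indirect secondary extinctions appear in the step log) cut the web
down faster than one-per-step attrition would.

Empirical webs are read from a two-CSV exchange format (nodes:
`id,name,category,biomass,gpp,respiration,import,export`; flows:
`source,target,flux`) via `td.read_network`, with `td.balance_avg2` available
to close small budget imbalances before parameterisation.

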