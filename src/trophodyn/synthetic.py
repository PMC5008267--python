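"""Balanced synthetic food webs and tiny hand-checkable fixtures.

The generator emulates the structure of empirical aquatic carbon-flow webs:
a dozen to ~100 nodes in four trophic categories, standing stocks spanning
several orders of magnitude, strongly skewed link weights, detrital recycling
loops, and exact mass balance at every node.  Balance is achieved by
construction: gross primary production and respiration absorb each living
node's budget residual (predation losses are scaled down where a residual
would go negative), and detrital outflows are matched to detrital inflows by a
short fixed-point iteration, so generated webs have zero boundary flows and
pass :func:`trophodyn.network.check_balance` at 1e-9.  Every generated web is
therefore an exact fixed point of the dynamics at its initial stocks.

Topology is sampled by constrained random attachment honouring the category
rules (producers are prey-free; decomposers feed only on detritus; every
consumer has at least one resource; detritus receives dead matter from all
living categories).  Consumers feed on living nodes only; detritivory is the
decomposers' role here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .network import (CONSUMER, DECOMPOSER, DETRITUS, PRODUCER, TrophicNetwork,
                      check_balance, make_network)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic web.

    Category counts default to roughly the empirical mix (about a fifth
    producers, a tenth decomposers, one detrital compartment per ~12 nodes,
    the rest consumers).  ``biomass_sigma`` is the standard deviation of
    log10 standing stock, so the default 1.0 spans well over three orders of
    magnitude across a web; ``flux_sigma`` (ln-space) skews diet shares so
    most consumers have one or two dominant resources.  ``turnover_range``
    bounds the mass-specific daily intake of consumers and sets the pace of
    starvation after resource loss.
    """

    S: int
    target_connectance: float = 0.2
    n_producers: int | None = None
    n_consumers: int | None = None
    n_decomposers: int | None = None
    n_detritus: int | None = None
    biomass_sigma: float = 1.0
    flux_sigma: float = 1.0
    turnover_range: tuple = (0.05, 0.5)
    egestion_range: tuple = (0.15, 0.5)
    seed: int = 0

    def counts(self) -> tuple:
        n_det = self.n_detritus if self.n_detritus is not None else max(1, round(0.08 * self.S))
        n_dec = self.n_decomposers if self.n_decomposers is not None else max(1, round(0.10 * self.S))
        n_pro = self.n_producers if self.n_producers is not None else max(1, round(0.22 * self.S))
        n_con = (self.n_consumers if self.n_consumers is not None
                 else self.S - n_pro - n_dec - n_det)
        return n_pro, n_con, n_dec, n_det

    def validate(self) -> None:
        n_pro, n_con, n_dec, n_det = self.counts()
        if n_pro + n_con + n_dec + n_det != self.S:
            raise ValidationError("category counts do not sum to S")
        if n_pro < 1 or n_det < 1:
            raise ValidationError("need at least one producer and one detrital node")
        if n_dec < 1:
            raise ValidationError(
                "need at least one decomposer: without one the detrital pool cannot be "
                "drained and the web cannot balance")
        if n_con < 0:
            raise ValidationError("negative consumer count")
        if not (0.0 < self.target_connectance <= 0.4):
            raise ValidationError("target connectance must lie in (0, 0.4]")


def generate_web(spec: GeneratorSpec) -> TrophicNetwork:
    """Sample one mass-balanced web; identical spec and seed give an identical web."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_pro, n_con, n_dec, n_det = spec.counts()
    S = spec.S

    cats = np.concatenate([
        np.full(n_pro, PRODUCER), np.full(n_con, CONSUMER),
        np.full(n_dec, DECOMPOSER), np.full(n_det, DETRITUS)]).astype(np.int8)
    ids = ([f"pro{k:02d}" for k in range(n_pro)] + [f"con{k:02d}" for k in range(n_con)]
           + [f"dec{k:02d}" for k in range(n_dec)] + [f"det{k:02d}" for k in range(n_det)])
    pro = np.flatnonzero(cats == PRODUCER)
    con = np.flatnonzero(cats == CONSUMER)
    dec = np.flatnonzero(cats == DECOMPOSER)
    det = np.flatnonzero(cats == DETRITUS)
    living = np.flatnonzero(cats != DETRITUS)

    B = 10.0 ** rng.normal(0.0, spec.biomass_sigma, size=S)

    # --- topology ----------------------------------------------------------
    # consumers get a loose trophic level; the mandatory first prey comes from
    # strictly lower levels so every consumer is anchored to primary production
    level = {int(j): int(rng.integers(1, 4)) for j in con}
    adj = np.zeros((S, S), dtype=bool)  # adj[i, j]: flow i -> j exists

    for j in con:
        pool = list(pro) + [k for k in con if level[int(k)] < level[int(j)]]
        adj[int(rng.choice(pool)), j] = True
    for j in dec:
        adj[int(rng.choice(det)), j] = True
    for i in det:  # every detrital pool is drained by some decomposer
        adj[i, int(rng.choice(dec))] = True
    for i in pro:  # natural death routes to detritus
        adj[i, int(rng.choice(det))] = True
    for j in np.concatenate([con, dec]):  # one egestion route each
        adj[j, int(rng.choice(det))] = True
    if n_det >= 2:
        for i in det:
            if rng.random() < 0.5:
                others = det[det != i]
                adj[i, int(rng.choice(others))] = True

    # extra feeding links up to the target link count
    l_target = int(round(spec.target_connectance * S * S))
    candidates = [(int(i), int(j)) for j in con for i in living if i != j and not adj[i, j]]
    candidates += [(int(i), int(j)) for j in dec for i in det if not adj[i, j]]
    n_extra = l_target - int(adj.sum())
    if n_extra > 0 and candidates:
        take = rng.choice(len(candidates), size=min(n_extra, len(candidates)), replace=False)
        for t in np.sort(take):
            i, j = candidates[int(t)]
            adj[i, j] = True

    feeding = adj.copy()
    feeding[:, det] = False       # flows into detritus are not feeding links
    egestion = adj.copy()
    egestion[:] = False
    egestion[np.ix_(living, det)] = adj[np.ix_(living, det)]
    egestion[np.ix_(pro, det)] = False
    death = np.zeros_like(adj)
    death[np.ix_(pro, det)] = adj[np.ix_(pro, det)]
    detdet = np.zeros_like(adj)
    detdet[np.ix_(det, det)] = adj[np.ix_(det, det)]

    # --- weights -----------------------------------------------------------
    # diet shares scale with prey standing stock (encounter-rate logic) times a
    # lognormal skew, so specific losses stay of order the consumers' turnover
    F = np.zeros((S, S))
    lo, hi = np.log10(spec.turnover_range[0]), np.log10(spec.turnover_range[1])
    for j in np.concatenate([con, dec]):
        # decomposer fluxes are an initial guess, overwritten by the detrital
        # balance below
        prey = np.flatnonzero(feeding[:, j])
        w = B[prey] * rng.lognormal(0.0, spec.flux_sigma, size=prey.size)
        F[prey, j] = B[j] * 10.0 ** rng.uniform(lo, hi) * w / w.sum()

    delta = 10.0 ** rng.uniform(-2.3, -1.3, size=S)  # producer death rates
    for i in pro:
        targets = np.flatnonzero(death[i])
        w = rng.lognormal(0.0, spec.flux_sigma, size=targets.size)
        F[i, targets] = delta[i] * B[i] * w / w.sum()

    e = np.zeros(S)
    e[np.concatenate([con, dec])] = rng.uniform(*spec.egestion_range,
                                                size=n_con + n_dec)
    egest_w = {}
    for j in np.concatenate([con, dec]):
        targets = np.flatnonzero(egestion[j])
        w = rng.lognormal(0.0, spec.flux_sigma, size=targets.size)
        egest_w[int(j)] = (targets, w / w.sum())
    dec_w = {}
    for i in det:
        feeders = np.flatnonzero(feeding[i])
        w = rng.lognormal(0.0, spec.flux_sigma, size=feeders.size)
        dec_w[int(i)] = (feeders, w / w.sum())
    detdet_share = {}
    for i in det:
        targets = np.flatnonzero(detdet[i])
        if targets.size:
            sh = rng.uniform(0.03, 0.1, size=targets.size)
            detdet_share[int(i)] = (targets, sh)

    # --- balance by construction -------------------------------------------
    # respiration absorbs each living node's surplus, so only the detrital
    # budgets are hard constraints; they are closed by a contraction mapping
    # (egestion feeds back into detritus with a factor < 1 per round trip)
    pred_cap = 0.6   # predation may claim at most this share of assimilated intake
    max_loss = 0.5   # and at most this specific daily loss of the prey's stock
    consdec = np.concatenate([con, dec])
    for _ in range(500):
        for i in living:
            out_liv = F[i, living].sum()
            if out_liv > max_loss * B[i]:
                F[i, living] *= max_loss * B[i] / out_liv
        intake = F.sum(axis=0)
        for j in consdec:
            out_pred = F[j, living].sum()
            cap = pred_cap * (1.0 - e[j]) * intake[j]
            if out_pred > cap and out_pred > 0:
                F[j, living] *= cap / out_pred
        intake = F.sum(axis=0)
        for j in consdec:
            targets, w = egest_w[int(j)]
            F[j, targets] = e[j] * intake[j] * w
        inflow = F.sum(axis=0)
        resid = 0.0
        for i in det:
            out_conv = 0.0
            if int(i) in detdet_share:
                targets, sh = detdet_share[int(i)]
                F[i, targets] = sh * inflow[i]
                out_conv = float(F[i, targets].sum())
            feeders, w = dec_w[int(i)]
            avail = inflow[i] - out_conv
            old = F[i, feeders].copy()
            F[i, feeders] = avail * w
            denom = max(avail, 1e-300)
            resid = max(resid, float(np.max(np.abs(F[i, feeders] - old))) / denom)
        if resid < 1e-14:
            break

    # --- boundary terms as budget residuals ---------------------------------
    GPP = np.zeros(S)
    R = np.zeros(S)
    intake = F.sum(axis=0)
    outflow = F.sum(axis=1)
    # detrital pools hold at least a day's throughflow of carbon, and
    # decomposer stocks are large enough that their imposed intake stays
    # within the same mass-specific turnover bound as consumers'
    B[det] = np.maximum(B[det], intake[det])
    B[dec] = np.maximum(B[dec], intake[dec] / spec.turnover_range[1])
    for i in pro:
        R[i] = 0.4 * outflow[i]
        GPP[i] = outflow[i] + R[i]
    for j in consdec:
        R[j] = intake[j] - outflow[j]
        if R[j] <= 0:
            raise ValidationError(
                f"generator produced non-positive respiration at node {ids[j]!r}")

    net = make_network(ids, ids, cats, B, GPP, R, np.zeros(S), np.zeros(S), F)
    report = check_balance(net, tol=1e-9)
    if not report.passed:
        worst = max(report.residuals.values(), key=abs)
        raise ValidationError(f"generated web failed balance check (worst residual {worst:.2e})")
    return net


# ---------------------------------------------------------------------------
# Hand-checkable fixtures
# ---------------------------------------------------------------------------

#: Hand-computed energy-budget parameters of the "chain" fixture at k0 = 1,
#: kept adjacent to the fixture so tests can assert against worked arithmetic.
FIXTURE_CHAIN_EXPECTED = {
    "k0": 1.0,
    "K": 100.0,                 # 10^1 * B_prod
    "r": {"prod": 1.2 / 9.0},   # (GPP - R)/B/(1 - 10^-1) = (2.0 - 0.8)/10/0.9
    "d": {"prod": 0.02},        # 0.2 / 10
    "a": {"cons1": 0.8, "cons2": 0.8},   # 1 - det outflow / intake
    "e": {"cons1": 0.2, "cons2": 0.2},
    "x": {"cons1": 0.1, "cons2": 0.4},   # R / B
    "p": {"prod": {"det": 1.0}, "cons1": {"det": 1.0}, "cons2": {"det": 1.0}},
}

#: Documented node pair of the "cycle" fixture: removing con_A lets con_C be
#: reached downstream (A->B->C) and upstream (C->E->A), both paths of length
#: two and no direct link, so a loss of C classifies as mixed / indirect.
FIXTURE_CYCLE_MIXED_PAIR = ("con_A", "con_C")


def fixture_webs() -> dict:
    """Three tiny named networks used throughout the test-suite.

    ``chain``: producer -> consumer -> consumer plus one detrital pool, with
    every budget parameter hand-computed in :data:`FIXTURE_CHAIN_EXPECTED`
    (boundary exports close the detrital budget, so it is *not* a dynamical
    fixed point).  ``cycle``: five living nodes containing the feeding cycle
    A -> B -> C -> E -> A used for cascade classification.  ``equilibrium``:
    a generated balanced web with zero boundary flows whose initial state is
    an exact fixed point of the dynamics.
    """
    webs = {}

    S = 4
    F = np.zeros((S, S))
    ids = ["prod", "cons1", "cons2", "det"]
    ix = {n: k for k, n in enumerate(ids)}
    F[ix["prod"], ix["cons1"]] = 1.0
    F[ix["prod"], ix["det"]] = 0.2
    F[ix["cons1"], ix["cons2"]] = 0.5
    F[ix["cons1"], ix["det"]] = 0.2
    F[ix["cons2"], ix["det"]] = 0.1
    webs["chain"] = make_network(
        ids, ids, ["producer", "consumer", "consumer", "detritus"],
        B=[10.0, 3.0, 1.0, 5.0], GPP=[2.0, 0, 0, 0], R=[0.8, 0.3, 0.4, 0],
        imports=[0, 0, 0, 0], exports=[0, 0, 0, 0.5], F=F)

    S = 6
    ids = ["pro_P", "con_A", "con_B", "con_C", "con_E", "det_D"]
    ix = {n: k for k, n in enumerate(ids)}
    F = np.zeros((S, S))
    F[ix["pro_P"], ix["con_A"]] = 1.0
    F[ix["con_A"], ix["con_B"]] = 0.4
    F[ix["con_B"], ix["con_C"]] = 0.3
    F[ix["con_C"], ix["con_E"]] = 0.2
    F[ix["con_E"], ix["con_A"]] = 0.1
    F[ix["pro_P"], ix["det_D"]] = 0.1
    F[ix["con_A"], ix["det_D"]] = 0.1
    F[ix["con_B"], ix["det_D"]] = 0.05
    F[ix["con_C"], ix["det_D"]] = 0.05
    F[ix["con_E"], ix["det_D"]] = 0.02
    webs["cycle"] = make_network(
        ids, ids, ["producer", "consumer", "consumer", "consumer", "consumer", "detritus"],
        B=[10.0, 5.0, 2.0, 1.0, 0.5, 20.0],
        GPP=[1.5, 0, 0, 0, 0, 0], R=[0.4, 0.6, 0.05, 0.05, 0.08, 0],
        imports=[0] * 6, exports=[0, 0, 0, 0, 0, 0.32], F=F)

    webs["equilibrium"] = generate_web(
        GeneratorSpec(S=8, target_connectance=0.25, seed=20160627))
    return webs
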