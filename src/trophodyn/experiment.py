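"""Sequential-deletion experiments, cascade bookkeeping and stability metrics.

One experiment on a balanced web proceeds as in the dynamical attack-tolerance
protocol: a 1000-day burn-in lets transients settle, then nodes are removed
one at a time, always the currently top-ranked living non-detrital node under
the chosen centrality index (weighted indices are re-scored from the realized
carbon flows at the current state, unweighted ones from the surviving
topology), with 1000 simulated days after each removal during which secondary
extinctions are recorded, classified (bottom-up / top-down / mixed, direct /
indirect) and compared against the surviving community.  The experiment ends
when only detrital nodes remain.

Stability of a run is summarised by robustness R50 — the fraction of nodes
removed as primaries before cumulative losses reach half the initial living
community — and survival area SA = sum_p N_p / S_l^2, the normalised area
under the survivors-versus-removals curve (SA + EA = 1 with EA the analogous
extinction area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .centrality import DEFAULT_STEPS, normalize_kind, rank_for_deletion
from .dynamics import DynamicalModel, IntegratorConfig, SimulationState
from .errors import FoodWebError
from .network import DETRITUS, TrophicNetwork
from .parameters import (CENTRAL_DRAW, FreeParameterDraw, derive_parameters,
                         draw_free_parameters, fit_linear_fr, fit_nonlinear_fr)
from .synthetic import GeneratorSpec  # noqa: F401  (re-exported convenience)

FR_FORMS = ("nonlinear", "linear")


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol settings for deletion experiments."""

    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    n_steps: int = DEFAULT_STEPS       # walk length for DI indices
    burnin_reduces_sl: bool = True     # burn-in losses shrink the initial living pool
    refit_fr: bool = False             # re-fit FR parameters after each deletion


@dataclass(frozen=True)
class CascadeClass:
    """Direction and proximity of one secondary extinction."""

    direction: str  # bottom-up | top-down | mixed
    proximity: str  # direct | indirect


@dataclass(frozen=True)
class SecondaryExtinction:
    node_id: str
    day_in_window: float
    cascade: CascadeClass
    log10_degree_ratio: float
    log10_weight_ratio: float


@dataclass(frozen=True)
class DeletionStep:
    step: int
    removed: str
    ranking: tuple  # ranking snapshot (ids, best first) before the removal
    secondary: tuple  # SecondaryExtinction records, in event order
    n_survivors: int  # living nodes alive at the end of the window (N_p)


@dataclass(frozen=True)
class ExperimentResult:
    steps: tuple
    s_initial_living: int          # living nodes before burn-in
    burnin_extinctions: tuple      # (node_id, day) lost during burn-in
    s_l: int                       # living pool the metrics are scaled by
    r50: float
    sa: float
    draw: FreeParameterDraw
    kind: str
    fr_form: str
    collapsed_in_burnin: bool = False
    label: str = ""


# ---------------------------------------------------------------------------
# Stability metrics
# ---------------------------------------------------------------------------

def r50(result: ExperimentResult) -> float:
    """Robustness: primaries needed for >= 50% total loss, as a fraction of S_l.

    The 50% threshold is the ceiling of S_l / 2 on odd pools."""
    s_l = result.s_l
    if s_l <= 0:
        return math.nan
    need = math.ceil(s_l / 2)
    for step in result.steps:
        if s_l - step.n_survivors >= need:
            return step.step / s_l
    return math.nan


def survival_area(result: ExperimentResult) -> float:
    """SA = sum over primary deletions p of N_p, divided by S_l^2.

    Steps past total collapse contribute zero survivors."""
    s_l = result.s_l
    if s_l <= 0:
        return math.nan
    return sum(step.n_survivors for step in result.steps) / s_l**2


def extinction_area(result: ExperimentResult) -> float:
    """EA computed from the loss log (primary + secondary counts per step).

    Padded with total loss for the unreached steps p..S_l; SA + EA = 1 when
    the survivor and loss bookkeeping agree."""
    s_l = result.s_l
    if s_l <= 0:
        return math.nan
    cum = 0
    total = 0
    for step in result.steps:
        cum += 1 + len(step.secondary)
        total += cum
    total += (s_l - len(result.steps)) * s_l  # every later step has full loss
    return total / s_l**2


# ---------------------------------------------------------------------------
# Cascade classification and diagnostics
# ---------------------------------------------------------------------------

def _reachable(adj: np.ndarray, src: int) -> np.ndarray:
    """Nodes reachable from src along directed edges (src excluded unless cyclic)."""
    S = adj.shape[0]
    seen = np.zeros(S, dtype=bool)
    frontier = adj[src].copy()
    while frontier.any():
        seen |= frontier
        frontier = (adj[frontier].any(axis=0)) & ~seen
    return seen


def classify_cascade(pre_removal_net, removed, extinct) -> CascadeClass:
    """Classify one secondary extinction against the pre-removal web.

    ``pre_removal_net`` may be a TrophicNetwork or a flux/adjacency matrix;
    ``removed``/``extinct`` are node ids (for a network) or indices.  The
    extinct node lying downstream of the removed node's outgoing energy is a
    bottom-up cascade, upstream a top-down one; both or neither is mixed.
    A path of length one either way makes it direct.
    """
    if isinstance(pre_removal_net, TrophicNetwork):
        adj = pre_removal_net.F > 0
        removed = pre_removal_net.index(removed) if isinstance(removed, str) else removed
        extinct = pre_removal_net.index(extinct) if isinstance(extinct, str) else extinct
    else:
        adj = np.asarray(pre_removal_net) > 0
    down = bool(_reachable(adj, removed)[extinct])
    up = bool(_reachable(adj, extinct)[removed])
    if down and not up:
        direction = "bottom-up"
    elif up and not down:
        direction = "top-down"
    else:
        direction = "mixed"
    direct = bool(adj[removed, extinct] or adj[extinct, removed])
    return CascadeClass(direction=direction, proximity="direct" if direct else "indirect")


def extinct_vs_survivor_ratios(flux_snapshot: np.ndarray, extinct: int,
                               survivors) -> tuple:
    """Log10 ratios of the extinct node's connectivity and link weight to the
    survivor means, on the given realized-flux snapshot.

    Degree is the distinct-neighbour count, link weight the total inward plus
    outward flux.  Returns (log10 degree ratio, log10 weight ratio); a zero
    numerator or denominator yields -inf/inf respectively.
    """
    F = np.asarray(flux_snapshot, dtype=float)
    adj = (F > 0) | (F.T > 0)
    np.fill_diagonal(adj, False)
    deg = adj.sum(axis=1).astype(float)
    wt = F.sum(axis=0) + F.sum(axis=1)
    survivors = np.asarray(list(survivors), dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        dratio = float(np.log10(deg[extinct]) - np.log10(deg[survivors].mean()))
        wratio = float(np.log10(wt[extinct]) - np.log10(wt[survivors].mean()))
    return dratio, wratio


# ---------------------------------------------------------------------------
# The deletion experiment
# ---------------------------------------------------------------------------

def _build_model(net, draw, fr_form, cfg):
    params = derive_parameters(net, draw.k0)
    if fr_form == "nonlinear":
        fr = fit_nonlinear_fr(net, h=draw.h, b=draw.b, q=draw.q)
    else:
        fr = fit_linear_fr(net)
    return DynamicalModel(net, params, fr, cfg.integrator)


def run_deletion_sequence(net: TrophicNetwork, kind: str, fr_form: str = "nonlinear",
                          draw: FreeParameterDraw = CENTRAL_DRAW,
                          cfg: ExperimentConfig | None = None,
                          label: str = "") -> ExperimentResult:
    """Run one full burn-in + sequential-deletion experiment.

    Deterministic: the same web, index kind, functional-response form and
    parameter draw give bit-identical step logs.
    """
    kind = normalize_kind(kind)
    if fr_form not in FR_FORMS:
        raise ValueError(f"fr_form must be one of {FR_FORMS}")
    cfg = cfg or ExperimentConfig()
    model = _build_model(net, draw, fr_form, cfg)
    cats = net.categories

    state = model.simulate_window(model.initial_state())
    burnin = tuple((net.node_ids[i], t) for i, t in state.extinctions)
    s_initial = int(np.count_nonzero(cats != DETRITUS))
    s_l = state.n_living_alive(cats) if cfg.burnin_reduces_sl else s_initial

    steps = []
    if s_l > 0 and state.n_living_alive(cats) > 0:
        p = 0
        while state.n_living_alive(cats) > 0:
            p += 1
            flux_now = model.realized_fluxes(state.B, state.alive)
            ranking = rank_for_deletion(net, kind, flux_now, alive=state.alive,
                                        n_steps=cfg.n_steps)
            removed = ranking.order[0]
            ridx = net.index(removed)
            pre_adj = np.where(np.outer(state.alive, state.alive), flux_now, 0.0)

            B = state.B.copy()
            alive = state.alive.copy()
            B[ridx] = 0.0
            alive[ridx] = False
            state = SimulationState(time=state.time, B=B, alive=alive,
                                    extinctions=state.extinctions)
            if cfg.refit_fr:
                model = _rebuild_with_refit(net, model, state, draw, fr_form, cfg)
            snapshot = model.realized_fluxes(state.B, state.alive)

            n_before = len(state.extinctions)
            state = model.simulate_window(state)
            new_events = state.extinctions[n_before:]

            survivors = np.flatnonzero(state.alive & (cats != DETRITUS))
            secondary = []
            for idx, t_abs in new_events:
                cascade = classify_cascade(pre_adj, ridx, idx)
                dr, wr = extinct_vs_survivor_ratios(snapshot, idx, survivors) \
                    if survivors.size else (math.nan, math.nan)
                secondary.append(SecondaryExtinction(
                    node_id=net.node_ids[idx],
                    day_in_window=t_abs - (state.time - cfg.integrator.window),
                    cascade=cascade,
                    log10_degree_ratio=dr, log10_weight_ratio=wr))
            steps.append(DeletionStep(step=p, removed=removed, ranking=ranking.order,
                                      secondary=tuple(secondary),
                                      n_survivors=int(survivors.size)))

    result = ExperimentResult(
        steps=tuple(steps), s_initial_living=s_initial, burnin_extinctions=burnin,
        s_l=s_l, r50=math.nan, sa=math.nan, draw=draw, kind=kind, fr_form=fr_form,
        collapsed_in_burnin=(s_l == 0 or not steps), label=label)
    return replace(result, r50=r50(result), sa=survival_area(result))


def _rebuild_with_refit(net, model, state, draw, fr_form, cfg):
    """Re-fit functional-response parameters at the current stocks (optional).

    Budget-derived rates (r, d, a, x, p, c) stay fixed; only the feeding
    calibration is refreshed from the realized flows among survivors."""
    from dataclasses import replace as drep
    flux = model.realized_fluxes(state.B, state.alive)
    B = np.where(state.B > 0, state.B, net.B)  # extinct stocks are irrelevant
    pseudo = drep(net, F=flux, B=B)
    try:
        if fr_form == "nonlinear":
            fr = fit_nonlinear_fr(pseudo, h=draw.h, b=draw.b, q=draw.q)
        else:
            fr = fit_linear_fr(pseudo)
    except FoodWebError:
        return model
    return DynamicalModel(net, model.params, fr, cfg.integrator)


# ---------------------------------------------------------------------------
# Monte-Carlo design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonteCarloResult:
    """Long-form per-replicate table, the secondary-extinction event table and
    the per-replicate failures (kind, replicate, message)."""

    results: pd.DataFrame
    events: pd.DataFrame
    failures: tuple


def monte_carlo(net: TrophicNetwork, kinds, fr_form: str, n_reps: int,
                base_seed: int, cfg: ExperimentConfig | None = None,
                label: str = "") -> MonteCarloResult:
    """Replicated deletion experiments with random free-parameter draws.

    Each (kind, replicate) gets an independent (h, k0, b, q) draw from its own
    seed stream derived from ``base_seed``, so the whole table is reproducible
    from the base seed alone and replicates are uncorrelated.
    """
    kinds = [normalize_kind(k) for k in (kinds if not isinstance(kinds, str) else [kinds])]
    rows, events, failures = [], [], []
    for ki, kind in enumerate(kinds):
        for rep in range(n_reps):
            rng = np.random.default_rng(np.random.SeedSequence([base_seed, ki, rep]))
            draw = draw_free_parameters(rng)
            try:
                res = run_deletion_sequence(net, kind, fr_form, draw, cfg, label=label)
            except FoodWebError as exc:
                failures.append((kind, rep, str(exc)))
                continue
            rows.append({
                "web": label, "kind": kind, "fr_form": fr_form, "replicate": rep,
                "r50": res.r50, "sa": res.sa, "s_l": res.s_l,
                "burnin_losses": len(res.burnin_extinctions),
                "collapsed": res.collapsed_in_burnin,
                "h": draw.h, "k0": draw.k0, "b": draw.b, "q": draw.q,
            })
            for step in res.steps:
                for sec in step.secondary:
                    events.append({
                        "web": label, "kind": kind, "fr_form": fr_form,
                        "replicate": rep, "step": step.step, "removed": step.removed,
                        "node": sec.node_id, "day_in_window": sec.day_in_window,
                        "direction": sec.cascade.direction,
                        "proximity": sec.cascade.proximity,
                        "log10_degree_ratio": sec.log10_degree_ratio,
                        "log10_weight_ratio": sec.log10_weight_ratio,
                    })
    return MonteCarloResult(results=pd.DataFrame(rows), events=pd.DataFrame(events),
                            failures=tuple(failures))
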