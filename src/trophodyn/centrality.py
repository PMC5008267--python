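"""Node-importance indices for deletion orderings.

Four indices are implemented.  Direct indices score a node by its
neighbourhood alone: Max.D is the number of distinct trophic neighbours
(resources and consumers pooled) and Max.wD is the node's total inward plus
outward carbon flux.  The direct-plus-indirect indices (Max.DI, Max.wDI)
propagate normalised one-step effects through the network: the one-step effect
of a consumer on its resource is the reciprocal of the resource's consumer
count (or the flux share, in the weighted variant) and symmetrically for
resources on consumers; multi-step effects are matrix powers of the one-step
matrix, and a node's score is the mean over 1..n steps of the total effect it
originates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DETRITUS, TrophicNetwork

KINDS = ("max_d", "max_di", "max_wd", "max_wdi")
_ALIASES = {"max.d": "max_d", "max.di": "max_di", "max.wd": "max_wd", "max.wdi": "max_wdi",
            "maxd": "max_d", "maxdi": "max_di", "maxwd": "max_wd", "maxwdi": "max_wdi"}

DEFAULT_STEPS = 5  # indirect effects decay quickly with distance; five steps suffice


def normalize_kind(kind: str) -> str:
    k = kind.strip().lower()
    k = _ALIASES.get(k, k)
    if k not in KINDS:
        raise ValueError(f"unknown index kind {kind!r}; expected one of {KINDS}")
    return k


def _as_matrix(net_or_matrix) -> np.ndarray:
    if isinstance(net_or_matrix, TrophicNetwork):
        return net_or_matrix.F
    return np.asarray(net_or_matrix, dtype=float)


@dataclass(frozen=True)
class EffectMatrix:
    """One-step effect matrix: ``a1[i, j]`` is the effect of node j on node i.

    Rows are normalised per channel: over node i's consumers the entries sum
    to 1, and over its resources they sum to 1.  A node that is both resource
    and consumer of i contributes through both channels.
    """

    a1: np.ndarray
    weighted: bool
    b: np.ndarray  # underlying feeding matrix (binary or flux)


def one_step_effects(net_or_matrix, weighted: bool = False) -> EffectMatrix:
    """Build the one-step effect matrix from a flux (or binary feeding) matrix.

    Unweighted: effect of consumer j on resource i is 1/D_i,out and of
    resource j on consumer i is 1/D_i,in.  Weighted: the same construction
    with flux shares, F_ij / sum_k F_ik over i's consumers and
    F_ji / sum_k F_ki over i's resources.  Rows with no consumers (or no
    resources) contribute zero through that channel.
    """
    F = _as_matrix(net_or_matrix)
    b = F.copy() if weighted else (F > 0).astype(float)
    S = b.shape[0]
    a1 = np.zeros((S, S))
    out_tot = b.sum(axis=1)   # over i's consumers
    in_tot = b.sum(axis=0)    # over i's resources
    for i in range(S):
        if out_tot[i] > 0:
            a1[i, :] += b[i, :] / out_tot[i]
        if in_tot[i] > 0:
            a1[i, :] += b[:, i] / in_tot[i]
    return EffectMatrix(a1=a1, weighted=weighted, b=b)


def di_scores(effects: EffectMatrix, n: int = DEFAULT_STEPS) -> np.ndarray:
    """Direct-plus-indirect scores DI_i^n = (sum_{m=1..n} sigma_m,i) / n.

    sigma_m,i is the column sum of the m-step effect matrix (the m-fold
    product of the one-step matrix), i.e. the total effect originating from
    node i over exactly m steps, self-effects through cycles included.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    A = effects.a1
    M = A.copy()
    total = M.sum(axis=0)
    for _ in range(n - 1):
        M = M @ A
        total = total + M.sum(axis=0)
    return total / n


def degree_scores(net_or_matrix, count_links: bool = False) -> np.ndarray:
    """Max.D scores: number of distinct trophic neighbours of each node.

    A node that is both resource and consumer of i counts once; set
    ``count_links`` to count directed links (in plus out) instead."""
    F = _as_matrix(net_or_matrix)
    if count_links:
        return ((F > 0).sum(axis=0) + (F > 0).sum(axis=1)).astype(float)
    adj = (F > 0) | (F.T > 0)
    np.fill_diagonal(adj, False)
    return adj.sum(axis=1).astype(float)


def weighted_degree_scores(net_or_matrix) -> np.ndarray:
    """Max.wD scores: total inward plus outward carbon flux (g C m^-2 day^-1)."""
    F = _as_matrix(net_or_matrix)
    return F.sum(axis=0) + F.sum(axis=1)


@dataclass(frozen=True)
class CentralityRanking:
    """Scores and a deterministic deletion ordering for one index kind.

    The ordering covers living, non-detrital nodes only (detritus participates
    in effect propagation but is never removed); ties break lexicographically
    by node id.
    """

    kind: str
    scores: dict
    order: tuple
    n_steps: int = DEFAULT_STEPS


def rank_for_deletion(net: TrophicNetwork, kind: str, realized_fluxes: np.ndarray,
                      alive: np.ndarray | None = None,
                      n_steps: int = DEFAULT_STEPS) -> CentralityRanking:
    """Rank living non-detrital nodes for primary deletion, best first.

    ``realized_fluxes`` is the current carbon-flow matrix; weighted kinds use
    it directly, unweighted kinds use only its surviving topology (nonzero
    pattern).  Extinct nodes are excluded from the effect propagation and from
    the ordering.
    """
    kind = normalize_kind(kind)
    S = net.S
    alive = np.ones(S, dtype=bool) if alive is None else np.asarray(alive, bool)
    F = np.where(np.outer(alive, alive), realized_fluxes, 0.0)

    if kind == "max_d":
        scores = degree_scores(F)
    elif kind == "max_wd":
        scores = weighted_degree_scores(F)
    else:
        weighted = kind == "max_wdi"
        scores = di_scores(one_step_effects(F, weighted=weighted), n=n_steps)

    eligible = alive & (net.categories != DETRITUS)
    order = sorted((net.node_ids[i] for i in np.flatnonzero(eligible)),
                   key=lambda nid: (-scores[net.index(nid)], nid))
    score_map = {net.node_ids[i]: float(scores[i]) for i in range(S)}
    return CentralityRanking(kind=kind, scores=score_map, order=tuple(order),
                             n_steps=n_steps)
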