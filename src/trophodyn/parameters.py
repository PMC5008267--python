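"""Derive dynamical rate constants and functional-response fits from energy budgets.

Every rate constant of the bioenergetic model is read off the mass-balanced
energy budget of the web:

====================  =======================================================
symbol                derivation (per node, at the empirical stocks)
====================  =======================================================
r_i  (day^-1)         (GPP_i - R_i) / B_i / (1 - 10^-k0)    producers
K    (g C m^-2)       10^k0 * sum of producer stocks
d_i  (day^-1)         detrital outflow / B_i                producers
a_i  (proportion)     1 - detrital outflow / intake         consumers, decomposers
e_i  (proportion)     1 - a_i                               (egestion)
x_i  (day^-1)         R_i / B_i                             consumers, decomposers
p_ji (proportion)     share of j's detrital outflow routed to detritus i
c_ji (day^-1)         F_ji / B_j                            detritus -> detritus
====================  =======================================================

Both functional-response forms are calibrated so that the feeding term
reproduces the empirical flux matrix exactly at the initial stocks:
Phi_ij(B0) * B0_j == F_ij for every trophic link.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .network import CONSUMER, DECOMPOSER, DETRITUS, PRODUCER, TrophicNetwork

#: lower floor on the carrying-capacity coefficient; r_i is singular at k0 = 0
K0_FLOOR = 0.01


def feeding_mask(net: TrophicNetwork) -> np.ndarray:
    """Boolean S x S mask of trophic links: flows whose target is a consumer
    or decomposer.  Flows into detritus (death, egestion, conversion) are not
    feeding links."""
    feeds = (net.categories == CONSUMER) | (net.categories == DECOMPOSER)
    return (net.F > 0) & feeds[np.newaxis, :]


def carrying_capacity(net: TrophicNetwork, k0: float) -> float:
    """Community carrying capacity K = 10^k0 * total producer stock.

    Valid for any k0 >= 0 (at k0 = 0, K equals the total producer biomass)."""
    return float(10.0 ** k0 * net.B[net.categories == PRODUCER].sum())


@dataclass(frozen=True)
class DerivedParameters:
    """All energy-budget rate constants (full-length arrays, zero where a
    quantity does not apply to a node's category)."""

    r: np.ndarray    # producer intrinsic growth rate, day^-1
    K: float         # community carrying capacity, g C m^-2
    k0: float        # carrying-capacity coefficient (free draw)
    d: np.ndarray    # producer natural death rate, day^-1
    a: np.ndarray    # assimilation efficiency, consumers/decomposers
    e: np.ndarray    # egestion rate = 1 - a
    x: np.ndarray    # respiration rate, day^-1
    p: np.ndarray    # S x S detritus routing proportions (rows sum to 1 where defined)
    c: np.ndarray    # S x S detritus-to-detritus conversion coefficients, day^-1


def derive_parameters(net: TrophicNetwork, k0: float) -> DerivedParameters:
    """Derive every rate constant from a balanced web's energy budget.

    Raises
    ------
    ParameterError
        If k0 is outside [K0_FLOOR, 3], a producer has GPP < R (negative
        growth rate), or a consumer/decomposer has zero intake.
    """
    if not (K0_FLOOR <= k0 <= 3.0):
        raise ParameterError(
            f"k0={k0} outside [{K0_FLOOR}, 3]; r is singular at k0=0, so draws are "
            "floored at K0_FLOOR")
    S = net.S
    cats = net.categories
    det = cats == DETRITUS
    r = np.zeros(S)
    d = np.zeros(S)
    a = np.zeros(S)
    x = np.zeros(S)
    p = np.zeros((S, S))
    c = np.zeros((S, S))

    det_out = net.F[:, det].sum(axis=1)  # per-node outflow into detritus
    for i in range(S):
        cat = cats[i]
        if cat == PRODUCER:
            if net.GPP[i] < net.R[i]:
                raise ParameterError(
                    f"producer {net.node_ids[i]!r} has GPP < R: negative growth rate")
            r[i] = (net.GPP[i] - net.R[i]) / net.B[i] / (1.0 - 10.0 ** (-k0))
            d[i] = det_out[i] / net.B[i]
        elif cat in (CONSUMER, DECOMPOSER):
            intake = net.F[:, i].sum()
            if intake <= 0:
                raise ParameterError(
                    f"{net.node_ids[i]!r} is a {'consumer' if cat == CONSUMER else 'decomposer'} "
                    "with zero intake")
            a[i] = 1.0 - det_out[i] / intake
            if a[i] < -1e-12 or a[i] > 1 + 1e-12:
                raise ParameterError(
                    f"node {net.node_ids[i]!r}: assimilation efficiency {a[i]:.6g} outside "
                    "[0, 1]; is the web balanced?")
            a[i] = min(max(a[i], 0.0), 1.0)
            x[i] = net.R[i] / net.B[i]
        if cat != DETRITUS and det_out[i] > 0:
            p[i, det] = net.F[i, det] / det_out[i]
        if cat == DETRITUS:
            c[i, det] = net.F[i, det] / net.B[i]

    return DerivedParameters(r=r, K=carrying_capacity(net, k0), k0=float(k0),
                             d=d, a=a, e=1.0 - a, x=x, p=p, c=c)


# ---------------------------------------------------------------------------
# Functional responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonlinearFR:
    """Saturating (Holling II-III) functional-response parameter set.

    Phi_ij = y_j * omega_ij * B_i^h / (H_j^h + q * B_j * H_j^h + sum_k omega_kj * B_k^h)

    omega columns are stochastic over each consumer's resources; H_j is
    10^b times the mean living stock; y_j is calibrated so the feeding term
    reproduces the empirical fluxes at the initial stocks.
    """

    omega: np.ndarray  # S x S preference of consumer j (column) for resource i (row)
    y: np.ndarray      # maximum consumption rate, day^-1
    H: np.ndarray      # half-saturation density, g C m^-2
    q: np.ndarray      # predator-interference coefficient, per consumer
    h: float           # hill exponent, 1 (type II) .. 2 (type III)
    b: float           # half-saturation coefficient, H = 10^b * mean(B)

    @property
    def form(self) -> str:
        return "nonlinear"


@dataclass(frozen=True)
class LinearFR:
    """Linear (Holling I) functional response Phi_ij = f_ij * B_i."""

    f: np.ndarray  # S x S feeding-rate coefficients, m^2 (g C)^-1 day^-1

    @property
    def form(self) -> str:
        return "linear"


def fit_nonlinear_fr(net: TrophicNetwork, h: float, b: float, q: float,
                     params: DerivedParameters | None = None,
                     include_detritus_in_mean: bool = False) -> NonlinearFR:
    """Calibrate the saturating functional response to the empirical fluxes.

    omega_ij = (F_ij / B_i^h) / sum_k (F_kj / B_k^h) over consumer j's
    resources; H_j = 10^b * mean initial stock of the biotic community
    (set ``include_detritus_in_mean`` to average over detrital stocks too);
    y_j is solved from any one resource so that Phi_ij(B0) * B0_j = F_ij.
    ``q`` is one shared scalar by default but accepts a per-consumer array.
    """
    if not (1.0 <= h <= 2.0):
        raise ParameterError(f"hill exponent h={h} outside [1, 2]")
    if not (-1.0 <= b <= 1.0):
        raise ParameterError(f"half-saturation coefficient b={b} outside [-1, 1]")
    q = np.broadcast_to(np.asarray(q, dtype=float), (net.S,)).copy()
    if np.any((q < 0.0) | (q > 100.0)):
        raise ParameterError("interference coefficient q outside [0, 100]")

    S = net.S
    B = net.B
    mask = feeding_mask(net)
    mean_b = B.mean() if include_detritus_in_mean else B[net.living].mean()
    H = np.full(S, 10.0 ** b * mean_b)
    omega = np.zeros((S, S))
    y = np.zeros(S)
    Hh = H ** h

    for j in range(S):
        res = np.flatnonzero(mask[:, j])
        if net.categories[j] in (CONSUMER, DECOMPOSER) and res.size == 0:
            warnings.warn(f"node {net.node_ids[j]!r} feeds on nothing; skipped in FR fit")
            continue
        if res.size == 0:
            continue
        if np.any(B[res] <= 0):
            raise ParameterError(f"zero resource stock feeding node {net.node_ids[j]!r}")
        w = net.F[res, j] / B[res] ** h
        omega[res, j] = w / w.sum()
        denom = Hh[j] + q[j] * B[j] * Hh[j] + (omega[res, j] * B[res] ** h).sum()
        i = res[0]  # Eq-7 identity: any resource gives the same y_j
        y[j] = net.F[i, j] * denom / (omega[i, j] * B[i] ** h * B[j])

    return NonlinearFR(omega=omega, y=y, H=H, q=q, h=float(h), b=float(b))


def fit_linear_fr(net: TrophicNetwork) -> LinearFR:
    """Calibrate the linear response: f_ij = F_ij / (B_i * B_j) on trophic links."""
    mask = feeding_mask(net)
    f = np.zeros_like(net.F)
    i, j = np.nonzero(mask)
    f[i, j] = net.F[i, j] / (net.B[i] * net.B[j])
    return LinearFR(f=f)


def fr_flux_matrix(fr, B: np.ndarray, alive: np.ndarray | None = None) -> np.ndarray:
    """Realized feeding flows Phi_ij * B_j (g C m^-2 day^-1) at stocks ``B``.

    Extinct nodes (``alive`` False) neither feed nor are fed upon.  At the
    calibration stocks this reproduces the trophic part of the empirical flux
    matrix exactly, for either form.
    """
    B = np.asarray(B, dtype=float)
    Bp = np.maximum(B, 0.0)
    if alive is not None:
        Bp = np.where(alive, Bp, 0.0)
    if isinstance(fr, LinearFR):
        return fr.f * np.outer(Bp, Bp)
    Bh = Bp ** fr.h
    denom = fr.H ** fr.h * (1.0 + fr.q * Bp) + fr.omega.T.dot(Bh)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = fr.y * fr.omega * Bh[:, np.newaxis] / np.where(denom > 0, denom, 1.0)
    return phi * Bp[np.newaxis, :]


# ---------------------------------------------------------------------------
# Free-parameter draws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeParameterDraw:
    """One Monte-Carlo draw of the four free model parameters."""

    h: float   # hill exponent ~ U[1, 2]
    k0: float  # carrying-capacity coefficient ~ U[K0_FLOOR, 3]
    b: float   # half-saturation coefficient ~ U[-1, 1]
    q: float   # predator interference ~ U[0, 100]


def draw_free_parameters(seed) -> FreeParameterDraw:
    """Draw (h, k0, b, q) for one simulation replicate.

    ``seed`` may be an int, a SeedSequence, or a Generator.  All consumers
    share the same scalar draw within a replicate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return FreeParameterDraw(
        h=float(rng.uniform(1.0, 2.0)),
        k0=float(rng.uniform(K0_FLOOR, 3.0)),
        b=float(rng.uniform(-1.0, 1.0)),
        q=float(rng.uniform(0.0, 100.0)),
    )


#: central point of the free-parameter supports, used as the canonical
#: single-run parameterisation when no Monte-Carlo draw is wanted
CENTRAL_DRAW = FreeParameterDraw(h=1.5, k0=1.5, b=0.0, q=50.0)


def params_to_dict(obj) -> dict:
    """JSON-ready dict of a DerivedParameters, FreeParameterDraw or FR set,
    for replicate provenance."""
    out = {}
    for name, val in dataclasses.asdict(obj).items():
        out[name] = val.tolist() if isinstance(val, np.ndarray) else val
    return out
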