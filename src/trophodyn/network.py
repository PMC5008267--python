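"""Quantitative flow networks: reading, validation, balancing and descriptors.

A quantitative food web is stored as a :class:`TrophicNetwork`: per-node carbon
standing stocks (g C m^-2), boundary flows (gross primary production,
respiration, import, export; g C m^-2 day^-1) and an internal node x node
carbon-flux matrix ``F`` with ``F[i, j]`` the flow from node ``i`` to node
``j``.  Nodes belong to one of four trophic categories: producers, consumers,
decomposers and (non-living) detritus.

The exchange format is a pair of CSV files: a node table with columns
``id,name,category,biomass,gpp,respiration,import,export`` and a flux table in
long form with columns ``source,target,flux``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import BalanceError, FormatError, ValidationError

PRODUCER, CONSUMER, DECOMPOSER, DETRITUS = 0, 1, 2, 3

CATEGORY_NAMES = ("producer", "consumer", "decomposer", "detritus")
_CATEGORY_CODES = {name: code for code, name in enumerate(CATEGORY_NAMES)}

NODE_COLUMNS = ("id", "name", "category", "biomass", "gpp", "respiration", "import", "export")
FLUX_COLUMNS = ("source", "target", "flux")


def category_code(name: str) -> int:
    try:
        return _CATEGORY_CODES[name.strip().lower()]
    except KeyError:
        raise FormatError(f"unknown trophic category {name!r}; expected one of {CATEGORY_NAMES}")


@dataclass(frozen=True)
class TrophicNetwork:
    """A validated quantitative flow network.

    All flow quantities are in g C m^-2 day^-1 and stocks in g C m^-2.
    ``F[i, j]`` is the carbon flow from node ``i`` to node ``j``; the matrix
    includes non-feeding flows (producer death and egestion into detritus,
    detritus-to-detritus conversion) alongside trophic links.
    """

    node_ids: tuple
    names: tuple
    categories: np.ndarray  # int codes, see CATEGORY_NAMES
    B: np.ndarray
    GPP: np.ndarray
    R: np.ndarray
    imports: np.ndarray
    exports: np.ndarray
    F: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {nid: k for k, nid in enumerate(self.node_ids)})
        self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def S(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}")

    @property
    def living(self) -> np.ndarray:
        """Boolean mask over nodes: True for producers, consumers, decomposers."""
        return self.categories != DETRITUS

    def nodes_of(self, category: int) -> np.ndarray:
        return np.flatnonzero(self.categories == category)

    def with_fluxes(self, F: np.ndarray) -> "TrophicNetwork":
        return replace(self, F=np.asarray(F, dtype=float))

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        S = self.S
        if len(set(self.node_ids)) != S:
            raise ValidationError("duplicate node ids")
        for arr, name in ((self.B, "B"), (self.GPP, "GPP"), (self.R, "R"),
                          (self.imports, "imports"), (self.exports, "exports")):
            if arr.shape != (S,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({S},)")
        if self.F.shape != (S, S):
            raise ValidationError(f"F has shape {self.F.shape}, expected ({S}, {S})")
        cats = self.categories
        if np.any((cats < 0) | (cats > 3)):
            raise ValidationError("category codes out of range")

        def offender(mask):
            return self.node_ids[int(np.flatnonzero(mask)[0])]

        if np.any(self.B <= 0):
            raise ValidationError(
                f"node {offender(self.B <= 0)!r}: standing stock must be strictly positive")
        for arr, name in ((self.GPP, "GPP"), (self.R, "respiration"),
                          (self.imports, "import"), (self.exports, "export")):
            if np.any(arr < 0):
                raise ValidationError(f"node {offender(arr < 0)!r}: negative {name}")
        if np.any(self.F < 0):
            i, j = np.argwhere(self.F < 0)[0]
            raise ValidationError(
                f"negative flux {self.node_ids[i]!r} -> {self.node_ids[j]!r}")
        diag = np.diag(self.F)
        if np.any(diag > 0):
            raise ValidationError(f"node {offender(diag > 0)!r}: self-loop flux F[i][i] > 0")

        pro = cats == PRODUCER
        if np.any(self.F[:, pro] > 0):
            j = int(np.flatnonzero(pro)[np.flatnonzero(self.F[:, pro].sum(axis=0) > 0)[0]])
            raise ValidationError(
                f"node {self.node_ids[j]!r}: producer must not receive internal inflow")
        if np.any(self.GPP[~pro] > 0):
            raise ValidationError(
                f"node {offender((~pro) & (self.GPP > 0))!r}: GPP must be zero for non-producers")

        det = cats == DETRITUS
        dec = cats == DECOMPOSER
        bad = self.F[~det][:, dec] > 0
        if np.any(bad):
            rows = np.flatnonzero(~det)
            cols = np.flatnonzero(dec)
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"node {self.node_ids[cols[j]]!r}: decomposer may receive internal inflow "
                f"only from detritus (offending source {self.node_ids[rows[i]]!r})")
        if np.any(self.R[det] > 0):
            raise ValidationError(
                f"node {offender(det & (self.R > 0))!r}: detritus must have zero respiration")
        if not (np.any(pro) or np.any(det)):
            raise ValidationError("network needs at least one producer or one detrital node")


def make_network(node_ids, names, categories, B, GPP, R, imports, exports, F) -> TrophicNetwork:
    """Build a validated :class:`TrophicNetwork` from plain sequences.

    ``categories`` may be given as names ("producer", ...) or integer codes.
    """
    cats = np.array([category_code(c) if isinstance(c, str) else int(c) for c in categories],
                    dtype=np.int8)
    as_f = lambda a: np.ascontiguousarray(np.asarray(a, dtype=float))
    return TrophicNetwork(
        node_ids=tuple(str(i) for i in node_ids),
        names=tuple(str(n) for n in names),
        categories=cats,
        B=as_f(B), GPP=as_f(GPP), R=as_f(R),
        imports=as_f(imports), exports=as_f(exports),
        F=as_f(F),
    )


# ---------------------------------------------------------------------------
# Exchange format
# ---------------------------------------------------------------------------

def read_network(node_table, flux_table) -> TrophicNetwork:
    """Read the two-CSV exchange format and return a validated network.

    Parameters
    ----------
    node_table, flux_table : path-like
        Node CSV (``id,name,category,biomass,gpp,respiration,import,export``)
        and long-form flux CSV (``source,target,flux``).
    """
    nodes = pd.read_csv(node_table, dtype={"id": str})
    missing = [c for c in NODE_COLUMNS if c not in nodes.columns]
    if missing:
        raise FormatError(f"node table missing column(s): {', '.join(missing)}")
    fluxes = pd.read_csv(flux_table, dtype={"source": str, "target": str})
    missing = [c for c in FLUX_COLUMNS if c not in fluxes.columns]
    if missing:
        raise FormatError(f"flux table missing column(s): {', '.join(missing)}")

    ids = list(nodes["id"])
    known = set(ids)
    S = len(ids)
    idx = {nid: k for k, nid in enumerate(ids)}
    F = np.zeros((S, S))
    for _, row in fluxes.iterrows():
        s, t = row["source"], row["target"]
        for nid in (s, t):
            if nid not in known:
                raise FormatError(f"flux table references node {nid!r} missing from node table")
        if s == t and row["flux"] > 0:
            raise ValidationError(f"node {s!r}: self-loop flux F[i][i] > 0")
        F[idx[s], idx[t]] += float(row["flux"])

    return make_network(
        ids, nodes["name"], list(nodes["category"]),
        nodes["biomass"], nodes["gpp"], nodes["respiration"],
        nodes["import"], nodes["export"], F,
    )


def write_network(net: TrophicNetwork, node_table, flux_table) -> None:
    """Write a network in the two-CSV exchange format (inverse of read_network)."""
    pd.DataFrame({
        "id": net.node_ids,
        "name": net.names,
        "category": [CATEGORY_NAMES[c] for c in net.categories],
        "biomass": net.B,
        "gpp": net.GPP,
        "respiration": net.R,
        "import": net.imports,
        "export": net.exports,
    }).to_csv(node_table, index=False)
    src, tgt = np.nonzero(net.F)
    pd.DataFrame({
        "source": [net.node_ids[i] for i in src],
        "target": [net.node_ids[j] for j in tgt],
        "flux": net.F[src, tgt],
    }).to_csv(flux_table, index=False)


# ---------------------------------------------------------------------------
# Connectance descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectanceReport:
    """Structural descriptors of a flow network.

    S: node count (detritus included); L: number of nonzero internal fluxes;
    C: binary directed connectance L/S^2; Cw: weighted directed connectance
    (entropy-based effective link density over S), None if not computed.
    """
    S: int
    L: int
    C: float
    Cw: float | None = None


def binary_connectance(net: TrophicNetwork) -> ConnectanceReport:
    """Binary directed connectance C = L/S^2.

    L counts nonzero entries of the internal flux matrix over all S nodes,
    detrital compartments included; boundary flows are excluded.
    """
    L = int(np.count_nonzero(net.F))
    return ConnectanceReport(S=net.S, L=L, C=L / net.S**2)


def weighted_connectance(net: TrophicNetwork) -> ConnectanceReport:
    """Weighted directed connectance Cw = LDw / S.

    LDw is the quantitative link density of Bersier/Banasek-Richter: for each
    node the base-2 Shannon entropy of its inflow and outflow distributions is
    exponentiated to an effective number of resources/consumers, and the two
    effective counts are averaged over nodes weighted by each node's share of
    total system throughflow.
    """
    F = net.F
    total = F.sum()
    if total <= 0:
        raise ValidationError("weighted connectance undefined: total internal flux is zero")
    t_in = F.sum(axis=0)
    t_out = F.sum(axis=1)

    def effective(counts, tot):
        # 2**H with H the base-2 entropy of the positive flux shares
        if tot <= 0:
            return 0.0
        p = counts[counts > 0] / tot
        return float(2.0 ** (-(p * np.log2(p)).sum()))

    ld = 0.0
    for k in range(net.S):
        ld += 0.5 * (t_in[k] / total) * effective(F[:, k], t_in[k])
        ld += 0.5 * (t_out[k] / total) * effective(F[k, :], t_out[k])
    L = int(np.count_nonzero(F))
    return ConnectanceReport(S=net.S, L=L, C=L / net.S**2, Cw=ld / net.S)


def describe(net: TrophicNetwork) -> ConnectanceReport:
    """S, L, C and Cw in a single report."""
    return weighted_connectance(net)


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalanceReport:
    residuals: dict
    passed: bool
    tol: float


def _node_budgets(net: TrophicNetwork):
    inputs = net.F.sum(axis=0) + net.GPP + net.imports
    outputs = net.F.sum(axis=1) + net.R + net.exports
    return inputs, outputs


def check_balance(net: TrophicNetwork, tol: float = 1e-9) -> BalanceReport:
    """Per-node relative budget residuals.

    residual_i = (inputs_i - outputs_i) / max(inputs_i, outputs_i); a node with
    zero throughput has residual 0.  ``passed`` is True when every
    |residual| <= tol.
    """
    inputs, outputs = _node_budgets(net)
    scale = np.maximum(inputs, outputs)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = np.where(scale > 0, (inputs - outputs) / np.where(scale > 0, scale, 1.0), 0.0)
    residuals = {nid: float(r) for nid, r in zip(net.node_ids, res)}
    return BalanceReport(residuals=residuals, passed=bool(np.all(np.abs(res) <= tol)), tol=tol)


def balance_avg2(net: TrophicNetwork, tol: float = 1e-9, max_iter: int = 100_000) -> TrophicNetwork:
    """Balance a flow network by input/output averaging (AVG2).

    Each iteration scales every node's internal inflows to close its budget
    given its outputs (input correction) and its internal outflows to close
    the budget given its inputs (output correction), then averages the two
    corrected matrices.  Boundary flows (GPP, respiration, imports, exports)
    and standing stocks are untouched; flux signs are preserved.

    Raises
    ------
    BalanceError
        If a node has outputs but no possible input, or the iteration fails
        to reach ``tol`` within ``max_iter`` sweeps.
    """
    F = net.F.astype(float).copy()
    fixed_in = net.GPP + net.imports
    fixed_out = net.R + net.exports
    S = net.S

    for _ in range(max_iter):
        fin = F.sum(axis=0)
        fout = F.sum(axis=1)
        inputs = fin + fixed_in
        outputs = fout + fixed_out
        scale = np.maximum(inputs, outputs)
        res = np.where(scale > 0, (inputs - outputs) / np.where(scale > 0, scale, 1.0), 0.0)
        if np.all(np.abs(res) <= tol):
            return net.with_fluxes(F)

        infeasible = (outputs > 0) & (fin == 0) & (fixed_in == 0)
        if np.any(infeasible):
            nid = net.node_ids[int(np.flatnonzero(infeasible)[0])]
            raise BalanceError(
                f"node {nid!r} is structurally infeasible: it has outputs but no "
                "internal inflow, GPP or import to supply them")

        col_scale = np.ones(S)
        has_in = fin > 0
        target_in = np.maximum(outputs - fixed_in, 0.0)
        col_scale[has_in] = target_in[has_in] / fin[has_in]

        row_scale = np.ones(S)
        has_out = fout > 0
        target_out = np.maximum(inputs - fixed_out, 0.0)
        row_scale[has_out] = target_out[has_out] / fout[has_out]

        F = 0.5 * (F * col_scale[np.newaxis, :] + F * row_scale[:, np.newaxis])

    raise BalanceError(f"AVG2 did not converge to tol={tol} within {max_iter} iterations")
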