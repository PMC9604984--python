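"""Branch enumeration and synergism quantification.

A branch is a simple directed path on the (unsigned) interaction digraph
from an origin (TNFR1 or NFkB) to a terminus (pAKT or pJNK), re-annotated
with the original edge signs.  Signal processing along a branch is scored
by the relative capacity

    R = prod over consecutive edges (l -> k) of |J_{l->k}| * C_k

where J is the edge's reaction flux and C_k the relative flux-processing
capacity of the edge's end node, C_k = (sum of unsigned outbound edge
fluxes of k) / (sum of unsigned inbound edge fluxes of k).  The extent of
synergism between two stimuli is

    S = R_combined / (R_a + R_b) - 1

so S > 0 marks super-additive (positive) synergism, S < 0 sub-additive,
and S = -1 a branch silent under co-stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import NetworkSpec
from .flux import FluxTraces

__all__ = [
    "Branch",
    "CapacityTrace",
    "SynergismTrace",
    "enumerate_branches",
    "node_capacity",
    "branch_capacity",
    "synergism",
    "synergism_trace",
    "branch_table",
]

#: relative threshold under which a synergism denominator is flagged missing
DENOM_GUARD = 1e-12
MAX_LEN_DEFAULT = 8  # edges; the longest curated branch has 6


@dataclass(frozen=True)
class Branch:
    """Simple path from an origin to a terminus with per-edge signs."""

    id: str
    nodes: tuple[str, ...]
    signs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"branch {self.id}: path must be simple")
        if len(self.signs) != len(self.nodes) - 1:
            raise ValueError(f"branch {self.id}: need one sign per edge")

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes[:-1], self.nodes[1:]))

    def __str__(self) -> str:
        sym = {"activation": "->", "inhibition": "-|"}
        parts = [self.nodes[0]]
        for sign, node in zip(self.signs, self.nodes[1:]):
            parts.append(sym[sign] + node)
        return "".join(parts)


_ORIGIN_CODE = {"TNFR1": "t", "NFkB": "n"}
_TERMINUS_CODE = {"AKT": "a", "JNK": "j"}


def enumerate_branches(net: NetworkSpec, source: str, target: str,
                       max_len: int = MAX_LEN_DEFAULT) -> list[Branch]:
    """All simple directed paths source -> target with at most ``max_len``
    edges, in lexicographic order of their node sequences.

    Enumeration runs on the unsigned digraph; each path is re-annotated
    with the original edge signs.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for name in (source, target):
        if name not in net.entities:
            raise KeyError(f"unknown entity {name!r}")
    g = nx.DiGraph()
    g.add_nodes_from(net.entities)
    sign_of = {}
    for e in net.edges:
        g.add_edge(e.source, e.target)
        sign_of[(e.source, e.target)] = e.sign
    paths = sorted(
        nx.all_simple_paths(g, source, target, cutoff=max_len),
        key=lambda p: tuple(p),
    )
    prefix = "B_" + _ORIGIN_CODE.get(source, source[0].lower()) \
        + _TERMINUS_CODE.get(target, target[0].lower())
    return [
        Branch(
            id=f"{prefix}{i + 1}",
            nodes=tuple(p),
            signs=tuple(sign_of[(a, b)] for a, b in zip(p[:-1], p[1:])),
        )
        for i, p in enumerate(paths)
    ]


def branch_table(branches: Sequence[Branch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.id, ">".join(b.nodes), ";".join(b.signs)) for b in branches],
        columns=["id", "nodes", "signs"],
    )


@dataclass
class CapacityTrace:
    node: str
    time: np.ndarray
    capacity: np.ndarray  # NaN where inbound flux vanishes


def _edge_flux_arrays(fluxes: FluxTraces):
    ef = fluxes.edges_only()
    sources = np.array([t.edge.source for t in ef.terms])
    targets = np.array([t.edge.target for t in ef.terms])
    return ef, sources, targets


def node_capacity(node: str, fluxes: FluxTraces,
                  mode: str = "node") -> CapacityTrace:
    """Relative flux-processing capacity C_k of a node over time.

    ``mode="node"`` (default): unsigned outbound edge flux divided by
    unsigned inbound edge flux of the node.  ``mode="network"``: outbound
    flux divided by the total flux through all edges.  Times with zero
    denominator yield NaN (flagged missing), never infinity.
    """
    ef, sources, targets = _edge_flux_arrays(fluxes)
    out_flux = np.abs(ef.values[sources == node]).sum(axis=0)
    if mode == "network":
        denom = np.abs(ef.values).sum(axis=0)
    elif mode == "node":
        denom = np.abs(ef.values[targets == node]).sum(axis=0)
    else:
        raise ValueError(f"unknown capacity mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        cap = np.where(denom > 0, out_flux / np.where(denom > 0, denom, 1.0), np.nan)
    return CapacityTrace(node, ef.time, cap)


def branch_capacity(branch: Branch, fluxes: FluxTraces,
                    capacities: Mapping[str, CapacityTrace] | None = None,
                    mode: str = "node") -> np.ndarray:
    """Relative capacity R(t) of a branch: the product over its edges of
    |J_edge| x C_(end node).  NaN wherever any factor is undefined."""
    if capacities is None:
        capacities = {k: node_capacity(k, fluxes, mode) for _, k in branch.edges}
    r = np.ones_like(fluxes.time, dtype=float)
    for src, tgt in branch.edges:
        j = np.abs(fluxes.edge_flux(f"{src}>{tgt}"))
        r = r * j * capacities[tgt].capacity
    return r


def synergism(r_comb, r_a, r_b, guard: float | None = None):
    """Extent of synergism S = R_combined / (R_a + R_b) - 1.

    Scalar or elementwise on arrays.  Denominators smaller in magnitude
    than ``guard`` (default: DENOM_GUARD x the largest R supplied) yield
    NaN rather than raising or returning infinities.
    """
    r_comb = np.asarray(r_comb, dtype=float)
    denom = np.asarray(r_a, dtype=float) + np.asarray(r_b, dtype=float)
    scale = np.nanmax(np.abs(np.concatenate([
        np.atleast_1d(r_comb), np.atleast_1d(denom)])))
    g = guard if guard is not None else DENOM_GUARD * (scale if scale > 0 else 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(np.abs(denom) > g, r_comb / np.where(denom == 0, 1.0, denom) - 1.0,
                     np.nan)
    return s if s.ndim else float(s)


@dataclass
class SynergismTrace:
    branch: Branch
    time: np.ndarray
    r_single_a: np.ndarray
    r_single_b: np.ndarray
    r_combined: np.ndarray
    s: np.ndarray  # NaN-flagged gaps where the denominator vanishes
    conditions: tuple[str, str, str]  # (a, b, combined)


def synergism_trace(branch: Branch, fluxes_by_condition: Mapping[str, FluxTraces],
                    conditions: tuple[str, str, str] = ("TNFa", "TPL", "TNFa+TPL"),
                    mode: str = "node") -> SynergismTrace:
    """Time-resolved extent of synergism of one branch across the two
    single-stimulus conditions and their combination."""
    for c in conditions:
        if c not in fluxes_by_condition:
            raise KeyError(f"missing fluxes for condition {c!r}")
    cond_a, cond_b, cond_comb = conditions
    r = {}
    for c in conditions:
        fx = fluxes_by_condition[c]
        caps = {k: node_capacity(k, fx, mode) for _, k in branch.edges}
        r[c] = branch_capacity(branch, fx, caps, mode)
    s = synergism(r[cond_comb], r[cond_a], r[cond_b])
    return SynergismTrace(
        branch, fluxes_by_condition[cond_a].time,
        r[cond_a], r[cond_b], r[cond_comb], np.atleast_1d(s), conditions,
    )
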