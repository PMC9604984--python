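"""Reaction-flux trajectories and node decomposition.

Every additive term of the model RHS (interaction edges, basal
interconversion, stimulus coupling) is a flux; evaluating each term's rate
law along a simulated trajectory gives its reaction-flux trajectory.  The
time derivative of any species is then, exactly, the signed sum of its
terms — the decomposition carries no numerical-differentiation error
because fluxes are evaluated analytically from the stored rate callables.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .network import ODESystem, Term
from .simulate import TrajectorySet

__all__ = [
    "FluxTraces",
    "NodeDecomposition",
    "edge_fluxes",
    "decompose_node",
    "dominant_contributors",
]


@dataclass
class FluxTraces:
    """Per-term rate time series along one trajectory.

    ``values[i]`` is the unsigned (nonnegative) rate of ``terms[i]`` on
    ``time``; the sign with which a term enters its target's RHS is
    ``effects[i]``.
    """

    time: np.ndarray
    terms: tuple[Term, ...]
    values: np.ndarray  # (n_terms, n_times), attenuation applied
    effects: np.ndarray
    protocol_label: str

    def term_index(self, label: str) -> int:
        for i, t in enumerate(self.terms):
            if t.label == label:
                return i
        raise KeyError(f"no flux term {label!r}")

    def edge_flux(self, label: str) -> np.ndarray:
        return self.values[self.term_index(label)]

    def edges_only(self) -> "FluxTraces":
        keep = [i for i, t in enumerate(self.terms) if t.kind == "edge"]
        return FluxTraces(
            self.time, tuple(self.terms[i] for i in keep), self.values[keep],
            self.effects[keep], self.protocol_label,
        )

    def to_frame(self, condition: str | None = None) -> pd.DataFrame:
        rows = []
        cond = condition if condition is not None else self.protocol_label
        for i, term in enumerate(self.terms):
            for j, t in enumerate(self.time):
                rows.append((cond, term.label, term.kind, float(t),
                             float(self.values[i, j]), int(self.effects[i])))
        return pd.DataFrame(
            rows, columns=["condition", "edge", "kind", "time_h", "flux", "sign"]
        )


def edge_fluxes(sys: ODESystem, traj: TrajectorySet) -> FluxTraces:
    """Evaluate every rate term of the system along a stored trajectory.

    The trajectory must carry full species states (a marker-only export is
    not enough; rerun the simulation with full output).
    """
    if traj.states is None or traj.states.shape[0] != len(sys.species):
        raise ValueError(
            "trajectory lacks full species states; rerun the protocol with "
            "full state output before computing fluxes"
        )
    values = sys.term_rates(traj.states, traj.inputs)
    effects = np.array([t.effect for t in sys.terms], dtype=int)
    return FluxTraces(traj.time, sys.terms, values, effects, traj.protocol.label)


@dataclass
class NodeDecomposition:
    """Signed flux contributions to one entity's active form."""

    node: str
    time: np.ndarray
    contributions: list[tuple[Term, np.ndarray]]  # signed series
    derivative: np.ndarray  # d(active)/dt from the RHS
    residual: np.ndarray  # derivative - sum(contributions)


def decompose_node(node: str, sys: ODESystem, fluxes: FluxTraces,
                   traj: TrajectorySet) -> NodeDecomposition:
    """Decompose d(active node)/dt into signed per-term contributions.

    The residual against the full RHS is zero to rounding because both
    sides evaluate the same rate callables.
    """
    if node not in sys.net.entities:
        raise KeyError(f"unknown entity {node!r}")
    contribs = []
    total = np.zeros_like(fluxes.time, dtype=float)
    for i, term in enumerate(fluxes.terms):
        if term.target != node:
            continue
        signed = fluxes.effects[i] * fluxes.values[i]
        contribs.append((term, signed))
        total = total + signed
    rhs = sys.rhs(0.0, traj.states, traj.inputs)
    deriv = rhs[sys.active_index(node)]
    return NodeDecomposition(node, fluxes.time, contribs, deriv, deriv - total)


def dominant_contributors(dec: NodeDecomposition,
                          window: tuple[float, float] | None = None
                          ) -> list[tuple[str, float]]:
    """Terms ranked by time-integrated |contribution| over a window
    (trapezoidal); ties broken alphabetically by term label."""
    t = dec.time
    lo, hi = window if window is not None else (t[0], t[-1])
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window [{lo}, {hi}] contains fewer than 2 grid points")
    ranked = sorted(
        ((term.label, float(np.trapezoid(np.abs(series[mask]), t[mask])))
         for term, series in dec.contributions),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return ranked
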