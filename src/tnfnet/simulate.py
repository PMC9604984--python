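"""Integration of the signalling ODEs under stimulation protocols.

A protocol mirrors the experimental timing: TPL and/or a kinase inhibitor
are applied ``pretreat_offset`` hours before t = 0, TNFa is added at t = 0,
and the system is followed to the horizon.  Before any input is applied the
model is relaxed to its unstimulated steady state, so an unstimulated run
is a fixed point.

Inhibitors (Wortmannin, SP600125) enter as a phenomenological
multiplicative attenuation ``1 / (1 + K * dose)`` of each affected edge's
rate, with the inhibition constants K in nM^-1; the dose is held constant
(no inhibitor decay).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import DEFAULT_MARKERS, ODESystem

__all__ = [
    "StimulationProtocol",
    "InhibitorSpec",
    "TrajectorySet",
    "IntegrationError",
    "WORTMANNIN",
    "SP600125",
    "INHIBITORS",
    "steady_state",
    "run_protocol",
    "apply_inhibitor",
    "marker_fc",
    "default_protocols",
]

RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g} h)")
        self.last_time = last_time


@dataclass(frozen=True)
class StimulationProtocol:
    """Doses and timing of one experimental condition."""

    label: str
    tnf_dose: float = 0.0  # ng/ml, applied at t = 0
    tpl_dose: float = 0.0  # nM, applied at t = -pretreat_offset
    inhibitor: str = "none"  # none | Wort | SP6
    inhibitor_dose: float = 0.0  # nM, applied at t = -pretreat_offset
    pretreat_offset: float = 1.0  # h
    horizon: float = 24.0  # h

    def __post_init__(self) -> None:
        if min(self.tnf_dose, self.tpl_dose, self.inhibitor_dose) < 0:
            raise ValueError("doses must be nonnegative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.inhibitor not in ("none", "Wort", "SP6"):
            raise ValueError(f"unknown inhibitor {self.inhibitor!r}")


def default_protocols(tpl_dose: float = 60.0) -> dict[str, StimulationProtocol]:
    """The three study conditions: TNFa 100 ng/ml, TPL (60 nM by default,
    10 nM for the validation dose), and their combination with 1 h TPL
    pre-treatment."""
    return {
        "TNFa": StimulationProtocol("TNFa", tnf_dose=100.0),
        "TPL": StimulationProtocol("TPL", tpl_dose=tpl_dose),
        "TNFa+TPL": StimulationProtocol("TNFa+TPL", tnf_dose=100.0, tpl_dose=tpl_dose),
    }


@dataclass(frozen=True)
class InhibitorSpec:
    """Edges attenuated by a small-molecule inhibitor.

    ``constants`` maps edge label -> name of the inhibition constant
    (nM^-1) in the parameter set.
    """

    name: str
    constants: Mapping[str, str]


WORTMANNIN = InhibitorSpec(
    "Wort",
    {
        "PI3K>AKT": "Ki_wort_PI3K_AKT",
        "MKK47>JNK": "Ki_wort_MKK47_JNK",
        "NFkB>XG": "Ki_wort_NFkB_XG",
    },
)

SP600125 = InhibitorSpec(
    "SP6",
    {
        "Bcl2>AKT": "Ki_sp6_Bcl2_AKT",
        "MKK47>JNK": "Ki_sp6_MKK47_JNK",
    },
)

INHIBITORS = {"Wort": WORTMANNIN, "SP6": SP600125}


@dataclass
class TrajectorySet:
    """Time-resolved state and marker fold-change trajectories."""

    time: np.ndarray  # strictly increasing grid spanning [0, horizon]
    states: np.ndarray  # (n_species, n_times)
    species: tuple[str, ...]
    markers: dict[str, np.ndarray]  # marker -> FC series
    protocol: StimulationProtocol
    parameter_set_id: str = ""
    inputs: dict[str, float] = field(default_factory=dict)  # post t=0 doses

    def state(self, species_name: str) -> np.ndarray:
        return self.states[self.species.index(species_name)]


def apply_inhibitor(sys: ODESystem, inh: InhibitorSpec, dose: float) -> ODESystem:
    """System with each affected edge scaled by 1/(1 + K*dose); all other
    rate terms are untouched.  dose = 0 returns an identical RHS."""
    if dose < 0:
        raise ValueError("inhibitor dose must be nonnegative")
    factors = {
        label: 1.0 / (1.0 + sys.params[kname] * dose)
        for label, kname in inh.constants.items()
    }
    return sys.with_attenuation(factors)


def steady_state(sys: ODESystem, inputs: Mapping[str, float] | None = None,
                 t_relax: float = 500.0, tol: float = 1e-8,
                 guess: np.ndarray | None = None) -> np.ndarray:
    """Unstimulated (or fixed-input) steady state.

    Long relaxation from the all-inactive state followed by a Newton polish
    on the active fractions (the inactive ones follow from conservation);
    verified by an RHS norm below ``tol``.  A ``guess`` (e.g. the steady
    state of a nearby parameter set) short-circuits the relaxation when the
    Newton solve already converges from it.
    """
    u = dict(inputs or {})
    n_ent = len(sys.net.entities)
    totals = np.ones(n_ent)

    def _reduced(active):
        full = np.empty(2 * n_ent)
        full[1::2] = active
        full[0::2] = totals - active
        return sys.rhs(0.0, full, u)[1::2]

    def _expand(active):
        full = np.empty(2 * n_ent)
        full[1::2] = active
        full[0::2] = totals - active
        return full

    if guess is not None:
        polish = root(_reduced, np.asarray(guess)[1::2], method="hybr", tol=1e-12)
        if polish.success and np.all(polish.x >= 0) and np.all(polish.x <= totals):
            y = _expand(polish.x)
            if np.linalg.norm(sys.rhs(0.0, y, u)) <= tol:
                return y

    y0 = np.zeros(2 * n_ent)
    y0[0::2] = totals  # all mass in the inactive forms
    sol = solve_ivp(
        sys.rhs, (0.0, t_relax), y0, method="LSODA", rtol=RTOL, atol=ATOL, args=(u,)
    )
    if not sol.success:
        raise IntegrationError("pre-equilibration failed", sol.t[-1])
    y = sol.y[:, -1]
    polish = root(_reduced, y[1::2], method="hybr", tol=1e-12)
    if polish.success:
        y = _expand(polish.x)
    resid = np.linalg.norm(sys.rhs(0.0, y, u))
    if resid > tol:
        raise IntegrationError(f"steady state not converged (|RHS| = {resid:.2e})", t_relax)
    return y


def _integrate(sys: ODESystem, y0: np.ndarray, t_span: tuple[float, float],
               t_eval: np.ndarray | None, inputs: Mapping[str, float],
               rtol: float, atol: float):
    sol = solve_ivp(
        sys.rhs, t_span, y0, method="LSODA", rtol=rtol, atol=atol,
        t_eval=t_eval, args=(dict(inputs),), dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", sol.t[-1] if sol.t.size else t_span[0])
    if np.min(sol.y) < -100 * atol:
        raise IntegrationError("state went negative beyond tolerance", sol.t[-1])
    return sol


def run_protocol(sys: ODESystem, proto: StimulationProtocol,
                 grid: Sequence[float] | None = None,
                 rtol: float = RTOL, atol: float = ATOL,
                 y0: np.ndarray | None = None) -> TrajectorySet:
    """Two-phase integration of a stimulation protocol.

    Phase 1 runs from -pretreat_offset to 0 with TPL and any inhibitor on
    and TNFa off; phase 2 runs from 0 to the horizon with all inputs on.
    Marker fold change is scaling-constant x active level.  ``grid``
    defaults to an hourly grid over [0, horizon]; ``y0`` (the state before
    pre-treatment) defaults to the unstimulated steady state.
    """
    if grid is None:
        grid = np.linspace(0.0, proto.horizon, int(proto.horizon) + 1)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > proto.horizon:
        raise ValueError("time grid must lie within [0, horizon]")

    run_sys = sys
    if proto.inhibitor != "none" and proto.inhibitor_dose > 0:
        run_sys = apply_inhibitor(sys, INHIBITORS[proto.inhibitor], proto.inhibitor_dose)

    if y0 is None:
        # resting state of the untreated system (inhibitor acts only from
        # the pre-treatment phase onward)
        y0 = steady_state(sys)
    y = np.asarray(y0, dtype=float)

    if proto.pretreat_offset > 0 and (proto.tpl_dose > 0 or proto.inhibitor_dose > 0):
        pre_inputs = {"TNFa": 0.0, "TPL": proto.tpl_dose}
        sol = _integrate(run_sys, y, (-proto.pretreat_offset, 0.0), None,
                         pre_inputs, rtol, atol)
        y = sol.y[:, -1]

    inputs = {"TNFa": proto.tnf_dose, "TPL": proto.tpl_dose}
    t_eval = grid if grid[0] == 0.0 else np.concatenate([[0.0], grid])
    sol = _integrate(run_sys, y, (0.0, proto.horizon), t_eval, inputs, rtol, atol)
    states = sol.y[:, -len(grid):]

    markers = marker_fc_states(run_sys, states)
    return TrajectorySet(
        time=grid, states=states, species=run_sys.species, markers=markers,
        protocol=proto, parameter_set_id=sys.params_id, inputs=inputs,
    )


def marker_fc_states(sys: ODESystem, states: np.ndarray,
                     markers: Mapping[str, tuple[str, str]] | None = None
                     ) -> dict[str, np.ndarray]:
    out = {}
    for marker, (entity, s_name) in (markers or sys.net.markers or DEFAULT_MARKERS).items():
        if s_name not in sys.params:
            raise KeyError(f"missing scaling constant {s_name!r} for marker {marker}")
        out[marker] = sys.params[s_name] * states[sys.active_index(entity)]
    return out


def marker_fc(trajectory: np.ndarray, scaling: float) -> np.ndarray:
    """Fold change of a single active-species trajectory: FC = s * level."""
    if scaling <= 0:
        raise ValueError("scaling constant must be positive")
    return scaling * np.asarray(trajectory, dtype=float)
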