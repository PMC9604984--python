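"""Declarative TNFa signalling network and ODE assembly.

The model follows the activation-cycle convention used throughout kinetic
models of phospho-signalling: every entity X exists as an interconverting
(inactive, active) pair, so a network of ``n`` entities yields ``2n`` state
variables.  Activation edges convert the target's inactive form to its
active form at a rate modulated by the *active* level of the source;
inhibition edges do the converse.  Each entity additionally carries basal
activation/deactivation first-order terms so that an unstimulated cell
relaxes to a non-trivial resting state.

The default network describes TNFa signalling to the three measured
markers (pAKT, pJNK, activated Caspase3): receptor-proximal activation of
NFkB, PI3K, Ceramide, RAF and Caspase8 by TNFR1; the NFkB-controlled
survival arm (PTEN, XIAP/Gadd45b, Bcl2, direct Caspase3 repression); the
ceramide arm (C1P, CAPP); the MKK4/7-ROS-JNK positive feedback loop; and
the RAF-ERK1/2 repression of JNK.  It has 17 entities, 25 interactions,
34 species and an 81-entry parameter schema (including the 3 marker
scaling constants and 5 inhibitor constants).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "RateLaw",
    "Edge",
    "Input",
    "NetworkSpec",
    "ODESystem",
    "NetworkValidationError",
    "build_network",
    "assemble_odes",
    "rate_law_eval",
    "read_edge_list",
    "write_edge_list",
    "DEFAULT_MARKERS",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"

RATE_LAW_KINDS = ("mass_action", "michaelis_menten", "hill")

#: marker name -> (entity whose active form is read out, scaling parameter)
DEFAULT_MARKERS: dict[str, tuple[str, str]] = {
    "pAKT": ("AKT", "s_pAKT"),
    "pJNK": ("JNK", "s_pJNK"),
    "Casp3": ("Casp3", "s_Casp3"),
}


class NetworkValidationError(ValueError):
    """Raised when a network definition violates a structural constraint."""


@dataclass(frozen=True)
class RateLaw:
    """A bound rate law: kind plus its numeric constants.

    ``constants`` uses the keys ``k`` (mass action), ``vmax``/``km``
    (Michaelis-Menten) and additionally ``n`` (Hill).  A Hill law with
    n = 1 evaluates identically to Michaelis-Menten.
    """

    kind: str
    constants: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise NetworkValidationError(f"unknown rate-law kind {self.kind!r}")
        for name, value in self.constants.items():
            if not value > 0:
                raise NetworkValidationError(
                    f"rate-law constant {name!r} must be strictly positive, got {value}"
                )


def rate_law_eval(law: RateLaw, substrate: float, modulator: float = 1.0):
    """Evaluate a rate law for a substrate (species being converted) and a
    modulator (active level of the regulating species).

    Mass action is bilinear ``k * modulator * substrate``; saturating laws
    are Michaelian in the substrate and linear in the modulator.  Inputs
    must be nonnegative concentrations.
    """
    substrate = np.asarray(substrate, dtype=float)
    modulator = np.asarray(modulator, dtype=float)
    if np.any(substrate < 0) or np.any(modulator < 0):
        raise ValueError("concentrations must be nonnegative")
    c = law.constants
    if law.kind == "mass_action":
        out = c["k"] * modulator * substrate
    elif law.kind == "michaelis_menten":
        out = c["vmax"] * modulator * substrate / (c["km"] + substrate)
    else:  # hill
        n = c["n"]
        sn = substrate**n
        out = c["vmax"] * modulator * sn / (c["km"] ** n + sn)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Edge:
    """A signed, directed interaction with a rate-law kind.

    ``param_names`` maps rate-law constant slots (``k`` | ``vmax`` | ``km``
    | ``n``) to entries of the parameter schema.
    """

    source: str
    target: str
    sign: str  # activation | inhibition
    rate_law: str  # mass_action | michaelis_menten | hill
    param_names: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{self.source}>{self.target}"

    def constant_slots(self) -> tuple[str, ...]:
        if self.rate_law == "mass_action":
            return ("k",)
        if self.rate_law == "michaelis_menten":
            return ("vmax", "km")
        return ("vmax", "km", "n")


@dataclass(frozen=True)
class Input:
    """An external stimulus acting on one entity (dose held constant)."""

    name: str
    target: str
    sign: str
    param: str  # coupling constant, (dose unit)^-1 h^-1
    dose_unit: str


@dataclass(frozen=True)
class NetworkSpec:
    """Validated signed interaction network."""

    entities: tuple[str, ...]
    edges: tuple[Edge, ...]
    inputs: tuple[Input, ...] = ()
    markers: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.entities)) != len(self.entities):
            raise NetworkValidationError("entity names must be unique")
        known = set(self.entities)
        input_names = {u.name for u in self.inputs}
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in known and e.source not in input_names:
                raise NetworkValidationError(
                    f"edge {e.label}: unknown source entity {e.source!r}"
                )
            if e.target not in known:
                raise NetworkValidationError(
                    f"edge {e.label}: unknown target entity {e.target!r}"
                )
            if e.sign not in (ACTIVATION, INHIBITION):
                raise NetworkValidationError(f"edge {e.label}: invalid sign {e.sign!r}")
            if e.rate_law not in RATE_LAW_KINDS:
                raise NetworkValidationError(
                    f"edge {e.label}: unknown rate law {e.rate_law!r}"
                )
            key = (e.source, e.target)
            if key in seen:
                raise NetworkValidationError(f"duplicate edge {e.label}")
            seen.add(key)
        for u in self.inputs:
            if u.target not in known:
                raise NetworkValidationError(
                    f"input {u.name}: unknown target entity {u.target!r}"
                )

    @property
    def n_species(self) -> int:
        return 2 * len(self.entities)

    def edge(self, source: str, target: str) -> Edge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source}>{target}")

    def parameter_schema(self) -> list[str]:
        """Ordered parameter names the network's ODE system requires
        (basal rates, edge constants, stimulus couplings, marker scalings)."""
        names: list[str] = []
        for ent in self.entities:
            names.append(f"k_act_{ent}")
            names.append(f"k_inact_{ent}")
        for e in self.edges:
            names.extend(e.param_names)
        for u in self.inputs:
            names.append(u.param)
        for _, (_, s_name) in self.markers.items():
            names.append(s_name)
        return names


def _ma(src: str, tgt: str, sign: str) -> Edge:
    return Edge(src, tgt, sign, "mass_action", (f"k_{src}_{tgt}",))


def _mm(src: str, tgt: str, sign: str) -> Edge:
    return Edge(src, tgt, sign, "michaelis_menten", (f"V_{src}_{tgt}", f"Km_{src}_{tgt}"))


def _hill(src: str, tgt: str, sign: str) -> Edge:
    return Edge(
        src, tgt, sign, "hill", (f"V_{src}_{tgt}", f"Km_{src}_{tgt}", f"n_{src}_{tgt}")
    )


DEFAULT_ENTITIES = (
    "TNFR1",
    "NFkB",
    "PTEN",
    "PI3K",
    "AKT",
    "Bcl2",
    "XG",
    "Ceramide",
    "C1P",
    "CAPP",
    "MKK47",
    "ROS",
    "JNK",
    "RAF",
    "ERK12",
    "Casp8",
    "Casp3",
)

DEFAULT_EDGES = (
    # receptor-proximal activation (bilinear mass action)
    _ma("TNFR1", "NFkB", ACTIVATION),
    _ma("TNFR1", "PI3K", ACTIVATION),
    _ma("TNFR1", "Ceramide", ACTIVATION),
    _ma("TNFR1", "RAF", ACTIVATION),
    _ma("TNFR1", "Casp8", ACTIVATION),
    # NFkB-governed survival arm
    _mm("NFkB", "PTEN", INHIBITION),
    _mm("NFkB", "XG", ACTIVATION),
    _mm("NFkB", "Bcl2", INHIBITION),
    _mm("PTEN", "PI3K", INHIBITION),
    # pAKT regulators
    _mm("PI3K", "AKT", ACTIVATION),
    _mm("Bcl2", "AKT", ACTIVATION),
    _mm("JNK", "AKT", ACTIVATION),
    _mm("CAPP", "AKT", INHIBITION),
    _mm("AKT", "Casp3", INHIBITION),
    # ceramide arm
    _ma("Ceramide", "C1P", ACTIVATION),
    _ma("Ceramide", "CAPP", ACTIVATION),
    _ma("C1P", "JNK", ACTIVATION),
    # MKK4/7 - ROS - JNK positive feedback loop
    _mm("MKK47", "JNK", ACTIVATION),
    _ma("JNK", "ROS", ACTIVATION),
    _ma("ROS", "MKK47", ACTIVATION),
    # MAPK repression of JNK
    _ma("RAF", "ERK12", ACTIVATION),
    _ma("ERK12", "JNK", INHIBITION),
    _ma("XG", "JNK", INHIBITION),
    # apoptotic output
    _hill("JNK", "Casp3", ACTIVATION),
    _ma("Casp8", "Casp3", ACTIVATION),
)

DEFAULT_INPUTS = (
    Input("TNFa", "TNFR1", ACTIVATION, "k_stim_tnfa", "ng/ml"),
    Input("TPL", "NFkB", INHIBITION, "k_stim_tpl", "nM"),
)


def build_network(config: str | Mapping = "default") -> NetworkSpec:
    """Build and validate a :class:`NetworkSpec`.

    ``config`` is either the string ``"default"`` (the 17-entity / 25-edge
    TNFa network) or a mapping with keys ``entities``, ``edges`` and
    optionally ``inputs`` and ``markers`` in the JSON dialect of the edge
    list format (see :func:`read_edge_list`).
    """
    if config == "default":
        return NetworkSpec(
            entities=DEFAULT_ENTITIES,
            edges=DEFAULT_EDGES,
            inputs=DEFAULT_INPUTS,
            markers=dict(DEFAULT_MARKERS),
        )
    if isinstance(config, str):
        raise NetworkValidationError(f"unknown network config {config!r}")
    return _network_from_dict(config)


def _network_from_dict(d: Mapping) -> NetworkSpec:
    edges = []
    for ed in d["edges"]:
        if isinstance(ed, Edge):
            edges.append(ed)
        else:
            edges.append(
                Edge(
                    source=ed["source"],
                    target=ed["target"],
                    sign=ed["sign"],
                    rate_law=ed["rate_law"],
                    param_names=tuple(ed["params"]),
                )
            )
    inputs = []
    for u in d.get("inputs", ()):
        if isinstance(u, Input):
            inputs.append(u)
        else:
            inputs.append(
                Input(
                    name=u["name"],
                    target=u["target"],
                    sign=u["sign"],
                    param=u["param"],
                    dose_unit=u.get("dose_unit", ""),
                )
            )
    markers = {k: tuple(v) for k, v in d.get("markers", {}).items()}
    return NetworkSpec(
        entities=tuple(d["entities"]),
        edges=tuple(edges),
        inputs=tuple(inputs),
        markers=markers,
    )


# ---------------------------------------------------------------------------
# edge-list file round trip (TSV and JSON dialects)
# ---------------------------------------------------------------------------

_SIGN_TO_SYMBOL = {ACTIVATION: "+", INHIBITION: "-"}
_SYMBOL_TO_SIGN = {v: k for k, v in _SIGN_TO_SYMBOL.items()}


def write_edge_list(net: NetworkSpec, path: str) -> None:
    """Write a network to TSV (``.tsv``) or JSON (anything else)."""
    if str(path).endswith(".tsv"):
        lines = ["source\ttarget\tsign\trate_law\tparams"]
        for e in net.edges:
            lines.append(
                "\t".join(
                    [e.source, e.target, _SIGN_TO_SYMBOL[e.sign], e.rate_law,
                     ";".join(e.param_names)]
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    doc = {
        "entities": list(net.entities),
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "rate_law": e.rate_law,
                "params": list(e.param_names),
            }
            for e in net.edges
        ],
        "inputs": [
            {
                "name": u.name,
                "target": u.target,
                "sign": u.sign,
                "param": u.param,
                "dose_unit": u.dose_unit,
            }
            for u in net.inputs
        ],
        "markers": {k: list(v) for k, v in net.markers.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_edge_list(path: str, entities: Sequence[str] | None = None) -> NetworkSpec:
    """Read a network written by :func:`write_edge_list`.

    The TSV dialect stores edges only; ``entities`` defaults to the set of
    edge endpoints (in order of first appearance) when not given.
    """
    if str(path).endswith(".tsv"):
        edges = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            expected = ["source", "target", "sign", "rate_law", "params"]
            if header != expected:
                raise NetworkValidationError(
                    f"bad edge-list header {header!r}, expected {expected!r}"
                )
            for line in fh:
                if not line.strip():
                    continue
                src, tgt, sym, law, params = line.rstrip("\n").split("\t")
                edges.append(
                    Edge(src, tgt, _SYMBOL_TO_SIGN[sym], law, tuple(params.split(";")))
                )
        if entities is None:
            seen: list[str] = []
            for e in edges:
                for name in (e.source, e.target):
                    if name not in seen:
                        seen.append(name)
            entities = seen
        return NetworkSpec(entities=tuple(entities), edges=tuple(edges))
    with open(path) as fh:
        return _network_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# ODE assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One additive contribution to the RHS of a single entity.

    ``effect`` is +1 when the term converts inactive -> active of the
    target entity and -1 for the converse; ``kind`` distinguishes network
    interactions from basal interconversion and stimulus coupling terms.
    """

    label: str
    kind: str  # "edge" | "basal" | "input"
    target: str
    effect: int
    rate: Callable  # (y, inputs) -> rate (scalar or vectorised along axis 1)
    edge: Edge | None = None


class ODESystem:
    """Right-hand side of the activation-cycle ODE model.

    The RHS of every species is, by construction, a signed sum of the
    per-term rates; this is what the flux decomposition relies on.
    Per-edge multiplicative attenuation factors (used by the inhibitory
    model) default to 1.
    """

    def __init__(self, net: NetworkSpec, params: Mapping[str, float]):
        missing = [p for p in net.parameter_schema() if p not in params]
        if missing:
            raise KeyError(f"parameter set is missing entries: {missing}")
        self.net = net
        self.params = dict(params)
        self.params_id = getattr(params, "id", "")
        self.species = tuple(
            f"{ent}_{form}" for ent in net.entities for form in ("i", "a")
        )
        self._idx = {name: i for i, name in enumerate(self.species)}
        self.attenuation: dict[str, float] = {}
        self.terms: tuple[Term, ...] = tuple(self._build_terms())
        # index bookkeeping for fast RHS evaluation
        self._tgt_a = np.array([self._idx[f"{t.target}_a"] for t in self.terms])
        self._tgt_i = np.array([self._idx[f"{t.target}_i"] for t in self.terms])
        self._effects = np.array([t.effect for t in self.terms], dtype=float)
        self._compile()

    def _compile(self) -> None:
        """Precompute index/constant arrays so rate evaluation is a handful
        of vectorised numpy operations (the per-term callables stay
        available for single-term inspection)."""
        P = self.params
        n_t = len(self.terms)
        kind = np.zeros(n_t, dtype=int)  # 0 linear, 1 MM, 2 Hill
        c1 = np.zeros(n_t)  # k or Vmax
        c2 = np.ones(n_t)  # Km
        c3 = np.ones(n_t)  # Hill n
        sub = np.zeros(n_t, dtype=int)
        mod = np.full(n_t, -1, dtype=int)  # -1: no modulator species
        self._input_slot = {}  # term index -> input name (dose multiplier)
        for i, t in enumerate(self.terms):
            if t.kind == "basal":
                ent = t.target
                sub[i] = self._idx[f"{ent}_{'i' if t.effect > 0 else 'a'}"]
                c1[i] = P[f"k_act_{ent}"] if t.effect > 0 else P[f"k_inact_{ent}"]
            elif t.kind == "input":
                name = t.label.split(":")[1].split(">")[0]
                inp = next(u for u in self.net.inputs if u.name == name)
                sub[i] = self._idx[f"{t.target}_{'i' if t.effect > 0 else 'a'}"]
                c1[i] = P[inp.param]
                self._input_slot[i] = name
            else:
                e = t.edge
                s_idx, m_idx = self._substrate_modulator(e)
                sub[i], mod[i] = s_idx, m_idx
                consts = dict(zip(e.constant_slots(), (P[p] for p in e.param_names)))
                if e.rate_law == "mass_action":
                    c1[i] = consts["k"]
                elif e.rate_law == "michaelis_menten":
                    kind[i], c1[i], c2[i] = 1, consts["vmax"], consts["km"]
                else:
                    kind[i] = 2
                    c1[i], c2[i], c3[i] = consts["vmax"], consts["km"], consts["n"]
        self._k_kind, self._k_c1, self._k_c2, self._k_c3 = kind, c1, c2, c3
        self._k_sub, self._k_mod = sub, mod
        self._mm_rows = np.nonzero(kind == 1)[0]
        self._hill_rows = np.nonzero(kind == 2)[0]
        self._atten_vec = np.ones(n_t)

    def _refresh_attenuation(self) -> None:
        self._atten_vec = np.array(
            [self.attenuation.get(t.label, 1.0) for t in self.terms]
        )

    # -- construction ------------------------------------------------------

    def _substrate_modulator(self, edge: Edge) -> tuple[int, int]:
        if edge.sign == ACTIVATION:
            sub = self._idx[f"{edge.target}_i"]
        else:
            sub = self._idx[f"{edge.target}_a"]
        mod = self._idx[f"{edge.source}_a"]
        return sub, mod

    def _build_terms(self):
        P = self.params
        for ent in self.net.entities:
            ia, aa = self._idx[f"{ent}_i"], self._idx[f"{ent}_a"]
            ka, kd = P[f"k_act_{ent}"], P[f"k_inact_{ent}"]
            yield Term(
                f"basal_act:{ent}", "basal", ent, +1,
                (lambda y, u, _k=ka, _j=ia: _k * y[_j]),
            )
            yield Term(
                f"basal_inact:{ent}", "basal", ent, -1,
                (lambda y, u, _k=kd, _j=aa: _k * y[_j]),
            )
        for edge in self.net.edges:
            law = RateLaw(
                edge.rate_law,
                dict(zip(edge.constant_slots(), (P[p] for p in edge.param_names))),
            )
            sub, mod = self._substrate_modulator(edge)
            effect = +1 if edge.sign == ACTIVATION else -1

            def _edge_rate(y, u, _law=law, _s=sub, _m=mod):
                return rate_law_eval(_law, y[_s], y[_m])

            yield Term(edge.label, "edge", edge.target, effect, _edge_rate, edge)
        for inp in self.net.inputs:
            k = P[inp.param]
            effect = +1 if inp.sign == ACTIVATION else -1
            sub = self._idx[f"{inp.target}_{'i' if effect > 0 else 'a'}"]
            yield Term(
                f"input:{inp.name}>{inp.target}", "input", inp.target, effect,
                (lambda y, u, _k=k, _s=sub, _n=inp.name: _k * u.get(_n, 0.0) * y[_s]),
            )

    # -- evaluation --------------------------------------------------------

    def with_attenuation(self, factors: Mapping[str, float]) -> "ODESystem":
        """Copy of this system with extra multiplicative edge attenuations
        (keyed by edge label); factors combine multiplicatively."""
        for lbl in factors:
            if lbl not in {t.label for t in self.terms if t.kind == "edge"}:
                raise KeyError(f"unknown edge {lbl!r}")
        new = ODESystem(self.net, self.params)
        combined = dict(self.attenuation)
        for lbl, f in factors.items():
            combined[lbl] = combined.get(lbl, 1.0) * float(f)
        new.attenuation = combined
        new._refresh_attenuation()
        return new

    def term_rates(self, y: np.ndarray, inputs: Mapping[str, float]) -> np.ndarray:
        """Unsigned rates of every term, with attenuation applied.

        ``y`` may be a state vector ``(n_species,)`` or a trajectory block
        ``(n_species, n_times)``.  Transient sub-tolerance negative
        excursions of the integrator are clipped to zero before the rate
        laws are applied.
        """
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        s = y[self._k_sub]
        m = np.where(
            (self._k_mod >= 0)[(...,) + (None,) * (y.ndim - 1)],
            y[np.maximum(self._k_mod, 0)],
            1.0,
        )
        c1 = self._k_c1 if y.ndim == 1 else self._k_c1[:, None]
        rates = c1 * m * s
        if self._mm_rows.size:
            r = self._mm_rows
            km = self._k_c2[r] if y.ndim == 1 else self._k_c2[r, None]
            rates[r] = rates[r] / (km + s[r])
        if self._hill_rows.size:
            r = self._hill_rows
            km = self._k_c2[r] if y.ndim == 1 else self._k_c2[r, None]
            n = self._k_c3[r] if y.ndim == 1 else self._k_c3[r, None]
            sn = s[r] ** (n - 1.0)  # one power of s already in `rates`
            rates[r] = rates[r] * sn / (km**n + s[r] * sn)
        for i, name in self._input_slot.items():
            rates[i] = rates[i] * inputs.get(name, 0.0)
        atten = self._atten_vec if y.ndim == 1 else self._atten_vec[:, None]
        return rates * atten

    def rhs(self, t: float, y: np.ndarray, inputs: Mapping[str, float]) -> np.ndarray:
        rates = self.term_rates(y, inputs)
        dydt = np.zeros_like(np.asarray(y, dtype=float))
        signed = self._effects * rates if rates.ndim == 1 else (
            self._effects[:, None] * rates
        )
        np.add.at(dydt, self._tgt_a, signed)
        np.add.at(dydt, self._tgt_i, -signed)
        return dydt

    def species_index(self, name: str) -> int:
        return self._idx[name]

    def active_index(self, entity: str) -> int:
        return self._idx[f"{entity}_a"]


def assemble_odes(net: NetworkSpec, params: Mapping[str, float]) -> ODESystem:
    """Bind a parameter set to a network, yielding an integrable ODE system.

    Raises ``KeyError`` naming any parameter the edges reference that is
    absent from ``params``.
    """
    return ODESystem(net, params)
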