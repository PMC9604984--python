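"""Chi-square calibration of the kinetic model to fold-change data.

The objective pools all conditions, markers and time points into one
residual vector r_i = (y_i^obs - y_i(P)) / sigma_i and minimises
chi^2 = sum r_i^2 by trust-region-reflective least squares in log10
parameter space, restarted from many seeded log-uniform starting points.
The best few percent of the restarts form the parameter ensemble whose
per-parameter spread (boxplot statistics) summarises identifiability.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .network import NetworkSpec, assemble_odes
from .params import ParameterSet
from .simulate import StimulationProtocol, default_protocols, run_protocol, steady_state
from .synth import ExperimentalDataset

__all__ = [
    "FitResult",
    "FitEntry",
    "EnsembleSummary",
    "make_simulator",
    "chi_square",
    "multistart_fit",
    "select_ensemble",
    "ensemble_summary",
]

logger = logging.getLogger(__name__)

PENALTY = 1e12  # chi-square assigned to a failed simulation


def make_simulator(net: NetworkSpec,
                   protocols: Mapping[str, StimulationProtocol] | None = None,
                   rtol: float = 1e-8, atol: float = 1e-10) -> Callable:
    """A simulator ``sim(P, condition, times) -> {marker: FC array}``
    suitable for :func:`chi_square`.

    The unstimulated steady state is recomputed per parameter set and
    shared across that set's conditions.
    """
    protocols = protocols or default_protocols()

    def sim(P: Mapping[str, float], condition: str, times: np.ndarray,
            _cache: dict = {}) -> dict[str, np.ndarray]:
        key = hash(tuple(sorted(P.items())))
        if _cache.get("key") != key:
            _cache["key"] = key
            _cache["sys"] = assemble_odes(net, P)
            # warm-start the steady-state solve from the previous set's rest
            # state (parameter sets within a fit sweep are usually close)
            _cache["y0"] = steady_state(_cache["sys"], guess=_cache.get("y0"))
        traj = run_protocol(
            _cache["sys"], protocols[condition], np.asarray(times, dtype=float),
            rtol=rtol, atol=atol, y0=_cache["y0"],
        )
        return traj.markers

    return sim


def _residuals(P: Mapping[str, float], data: ExperimentalDataset, sim: Callable,
               sigma_power: int = 1) -> np.ndarray:
    rows = []
    for cond in data.condition_labels():
        sub = data.summary[data.summary["condition"] == cond]
        times = np.unique(sub["time_h"].to_numpy())
        pred = sim(P, cond, times)
        tindex = {t: j for j, t in enumerate(times)}
        for _, row in sub.iterrows():
            y_hat = pred[row["marker"]][tindex[row["time_h"]]]
            rows.append((row["FC"] - y_hat) / row["sigma"] ** sigma_power)
    return np.asarray(rows, dtype=float)


def chi_square(P: Mapping[str, float], data: ExperimentalDataset, sim: Callable,
               sigma_power: int = 1, penalty: float = PENALTY) -> float:
    """Pooled chi-square of a parameter set against a dataset.

    ``sigma_power=1`` is the standard weighting (residual / sigma);
    ``sigma_power=2`` reproduces the sigma^2-inside-the-square variant.
    A simulation failure yields ``penalty`` (with a warning) instead of
    raising, so multi-start sweeps continue.
    """
    try:
        r = _residuals(P, data, sim, sigma_power)
    except Exception as exc:  # noqa: BLE001 - any solver failure is penalised
        logger.warning("simulation failed for parameter set %s: %s",
                       getattr(P, "id", "?"), exc)
        return penalty
    return float(r @ r)


@dataclass
class FitEntry:
    params: ParameterSet
    chisq: float
    status: str
    start_id: int
    seed: int


@dataclass
class FitResult:
    entries: list[FitEntry]
    free_names: tuple[str, ...]
    seed: int
    dataset_fingerprint: str
    n_residuals: int

    def sorted_entries(self) -> list[FitEntry]:
        return sorted(self.entries, key=lambda e: (e.chisq, e.start_id))

    @property
    def best(self) -> FitEntry:
        return self.sorted_entries()[0]


def _fingerprint(data: ExperimentalDataset) -> str:
    payload = data.summary.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def multistart_fit(data: ExperimentalDataset, sim: Callable, nominal: ParameterSet,
                   free_names: Sequence[str], n_starts: int = 20, seed: int = 0,
                   bounds_decades: float | Mapping[str, tuple[float, float]] = 2.0,
                   sigma_power: int = 1, start_mode: str = "random",
                   max_nfev: int | None = None) -> FitResult:
    """Multi-start trust-region least squares over log10(parameters).

    ``free_names`` selects the fitted subset of ``nominal``; the rest stay
    fixed.  Bounds are either +/- ``bounds_decades`` decades around the
    nominal values or an explicit log10 (lo, hi) per parameter.
    ``start_mode="random"`` draws log-uniform starts within the bounds;
    ``"nominal"`` starts every restart from the nominal values.  The end
    chi-square of each start never exceeds its start value (trust-region
    monotonicity); failed simulations inside the objective are penalised,
    not raised.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    free_names = tuple(free_names)
    if isinstance(bounds_decades, Mapping):
        lo = np.array([bounds_decades[n][0] for n in free_names])
        hi = np.array([bounds_decades[n][1] for n in free_names])
    else:
        centre = np.log10(nominal.to_array(free_names))
        lo, hi = centre - bounds_decades, centre + bounds_decades

    rng = np.random.default_rng(seed)
    sqrt_pen = math.sqrt(PENALTY)

    def residual_vec(x: np.ndarray) -> np.ndarray:
        P = nominal.from_array(free_names, 10.0**x)
        try:
            return _residuals(P, data, sim, sigma_power)
        except Exception as exc:  # noqa: BLE001
            logger.warning("simulation failed during fit: %s", exc)
            return np.full(n_res, sqrt_pen / math.sqrt(n_res))

    n_res = len(_residuals(nominal, data, sim, sigma_power))

    entries: list[FitEntry] = []
    failures: list[str] = []
    for start_id in range(n_starts):
        if start_mode == "nominal":
            x0 = np.log10(nominal.to_array(free_names))
        else:
            x0 = rng.uniform(lo, hi)
        try:
            res = least_squares(
                residual_vec, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
            fitted = nominal.from_array(free_names, 10.0**res.x, id=f"fit_{start_id}")
            entries.append(FitEntry(fitted, float(2 * res.cost), str(res.status),
                                    start_id, seed))
        except Exception as exc:  # noqa: BLE001
            failures.append(f"start {start_id}: {exc}")
    if not entries:
        raise RuntimeError("all optimisation starts failed:\n" + "\n".join(failures))
    return FitResult(entries, free_names, seed, _fingerprint(data), n_res)


def select_ensemble(fit: FitResult, fraction: float = 0.03) -> list[ParameterSet]:
    """The ceil(fraction * N) lowest-chi-square parameter sets, ties broken
    by start id."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not fit.entries:
        raise ValueError("empty fit result")
    k = math.ceil(fraction * len(fit.entries))
    return [e.params for e in fit.sorted_entries()[:k]]


@dataclass
class EnsembleSummary:
    """Per-parameter boxplot statistics of a retained ensemble (log10)."""

    parameters: tuple[str, ...]
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    table: "object" = field(default=None, repr=False)  # pandas view


def ensemble_summary(sets: Sequence[Mapping[str, float]],
                     names: Sequence[str] | None = None) -> EnsembleSummary:
    """Boxplot statistics (median, IQR, Tukey whiskers clipped to the data)
    of each parameter across the retained ensemble, on the log10 scale."""
    import pandas as pd

    if len(sets) < 2:
        raise ValueError("need at least 2 parameter sets to summarise spread")
    names = tuple(names or sets[0].keys())
    X = np.log10(np.array([[s[n] for n in names] for s in sets], dtype=float))
    q1, med, q3 = np.percentile(X, [25, 50, 75], axis=0)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    whisker_lo = np.array([X[:, j][X[:, j] >= lo_fence[j]].min() for j in range(X.shape[1])])
    whisker_hi = np.array([X[:, j][X[:, j] <= hi_fence[j]].max() for j in range(X.shape[1])])
    table = pd.DataFrame({
        "parameter": names, "median": med, "q1": q1, "q3": q3,
        "whisker_lo": whisker_lo, "whisker_hi": whisker_hi,
    })
    return EnsembleSummary(names, med, q1, q3, whisker_lo, whisker_hi, table)
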