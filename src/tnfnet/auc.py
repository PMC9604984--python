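"""Accumulated-signal (AUC) correlation analyses.

Marker accumulation over a window [0, T] is the trapezoidal area under its
fold-change trajectory.  The accumulated Caspase3 level is modelled as a
no-intercept linear combination of the accumulated pJNK and pAKT signals,

    AUC_casp3 = a * AUC_pJNK + b * AUC_pAKT,

fitted across replicate trajectories (e.g. the best-fit parameter
ensemble).  Normalising each term by the regression-reproduced average
accumulated Caspase3 gives the relative contributions

    A_pJNK = a <AUC_pJNK> / (a <AUC_pJNK> + b <AUC_pAKT>),   A_pAKT likewise,

which sum to 1 per window by construction.  A quartic polynomial maps the
ensemble-average <AUC_casp3> to the measured apoptosis percentage, turning
simulated Caspase3 accumulation into a phenotype prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AUCRecord",
    "RegressionResult",
    "CalibrationCurve",
    "auc",
    "auc_records",
    "fit_contributions",
    "fit_calibration",
    "predict_apoptosis",
    "sensitivity_ratio",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = (8.0, 12.0, 24.0)

AUC_COLUMNS = ["marker", "condition", "window_h", "id", "auc"]


def auc(time: Sequence[float], values: Sequence[float],
        window: tuple[float, float] = (0.0, 24.0)) -> float:
    """Trapezoidal area under a trajectory over ``window`` on the stored
    grid (no resampling); both window ends must lie on the grid."""
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    lo, hi = window
    if lo < t[0] or hi > t[-1]:
        raise ValueError(f"window [{lo}, {hi}] extends beyond the grid [{t[0]}, {t[-1]}]")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError("window must contain at least 2 grid points")
    return float(np.trapezoid(y[mask], t[mask]))


def auc_records(trajectories: Mapping[str, Mapping[str, np.ndarray]],
                time: Sequence[float], condition: str,
                windows: Sequence[float] = DEFAULT_WINDOWS) -> pd.DataFrame:
    """AUC table for a set of replicate marker trajectories.

    ``trajectories`` maps replicate/parameter-set id -> {marker: FC series}.
    """
    rows = []
    for rep_id, markers in trajectories.items():
        for marker, series in markers.items():
            for w in windows:
                rows.append((marker, condition, float(w), rep_id,
                             auc(time, series, (0.0, w))))
    return pd.DataFrame(rows, columns=AUC_COLUMNS)


@dataclass(frozen=True)
class AUCRecord:
    marker: str
    condition: str
    window_h: float
    id: str
    auc: float


@dataclass
class RegressionResult:
    """No-intercept contribution fit for one condition."""

    condition: str
    a: float  # pJNK coefficient
    b: float  # pAKT coefficient
    contributions: pd.DataFrame  # window_h, A_pJNK, A_pAKT
    r_squared: float
    residuals: np.ndarray
    n_obs: int
    pooling: str = "windows"
    averaging: str = "replicates"
    intercept: float = 0.0


def _design(records: pd.DataFrame) -> pd.DataFrame:
    wide = records.pivot_table(
        index=["window_h", "id"], columns="marker", values="auc"
    ).reset_index()
    for m in ("pJNK", "pAKT", "Casp3"):
        if m not in wide:
            raise ValueError(f"AUC records lack marker {m!r}")
    return wide


def fit_contributions(records: pd.DataFrame, per_window: bool = False,
                      intercept: bool = False,
                      denominator: str = "fitted") -> RegressionResult:
    """Fit AUC_casp3 = a*AUC_pJNK + b*AUC_pAKT for one condition and derive
    the per-window relative contributions.

    By default one (a, b) pair is fitted pooling all windows and replicate
    ids (``per_window=True`` restricts the fit to each window separately
    and concatenates the results).  ``denominator`` selects the averaged
    accumulated Caspase3 used in the normalisation: "fitted" (the
    regression-reproduced average, making A_pJNK + A_pAKT = 1 an identity)
    or "observed" (the literal data average).
    """
    conds = records["condition"].unique()
    if len(conds) != 1:
        raise ValueError(f"records must cover exactly one condition, got {list(conds)}")
    if denominator not in ("fitted", "observed"):
        raise ValueError(f"unknown denominator {denominator!r}")

    if per_window:
        parts = []
        for w in sorted(records["window_h"].unique()):
            sub = fit_contributions(records[records["window_h"] == w],
                                    per_window=False, intercept=intercept,
                                    denominator=denominator)
            parts.append((w, sub.a, sub.b, sub.contributions, sub.residuals))
        contrib = pd.concat([p[3] for p in parts], ignore_index=True)
        resid = np.concatenate([p[4] for p in parts])
        ss_res = float(resid @ resid)
        y = _design(records)["Casp3"].to_numpy()
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return RegressionResult(
            conds[0], float("nan"), float("nan"), contrib,
            1 - ss_res / ss_tot if ss_tot > 0 else 1.0, resid, len(y),
            pooling="per_window",
        )

    wide = _design(records)
    if len(wide) < 2:
        raise ValueError("need at least 2 (pJNK, pAKT, casp3) AUC triples")
    X = wide[["pJNK", "pAKT"]].to_numpy()
    if intercept:
        X = np.column_stack([X, np.ones(len(X))])
    y = wide["Casp3"].to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "AUC_pJNK and AUC_pAKT are collinear across observations; "
            "the contribution regression is rank deficient"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    c0 = float(coef[2]) if intercept else 0.0
    y_hat = X @ coef
    resid = y - y_hat
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0

    rows = []
    for w in sorted(wide["window_h"].unique()):
        sel = wide["window_h"] == w
        mean_jnk = float(wide.loc[sel, "pJNK"].mean())
        mean_akt = float(wide.loc[sel, "pAKT"].mean())
        if denominator == "fitted":
            denom = a * mean_jnk + b * mean_akt + c0
        else:
            denom = float(wide.loc[sel, "Casp3"].mean())
        rows.append((float(w), a * mean_jnk / denom, b * mean_akt / denom))
    contrib = pd.DataFrame(rows, columns=["window_h", "A_pJNK", "A_pAKT"])
    return RegressionResult(conds[0], a, b, contrib, r2, resid, len(y),
                            intercept=c0)


@dataclass
class CalibrationCurve:
    """Polynomial map from ensemble-average AUC_casp3 to apoptosis %."""

    condition: str
    coefficients: np.ndarray  # ascending powers
    valid_range: tuple[float, float]
    degree: int
    residual_norm: float = 0.0
    fitted_x: np.ndarray = field(default_factory=lambda: np.empty(0))


def fit_calibration(auc_means: Sequence[float], apoptosis_pct: Sequence[float],
                    degree: int = 4, condition: str = "") -> CalibrationCurve:
    """Least-squares polynomial (degree 4 by default) through
    (<AUC_casp3>, apoptosis %) pairs; the input range seen during fitting
    bounds later evaluations."""
    x = np.asarray(auc_means, dtype=float)
    y = np.asarray(apoptosis_pct, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if x.size < degree + 1:
        raise ValueError(f"need at least {degree + 1} pairs for degree {degree}, got {x.size}")
    poly = np.polynomial.Polynomial.fit(x, y, degree)
    coeffs = poly.convert().coef
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    return CalibrationCurve(
        condition, coeffs, (float(x.min()), float(x.max())), degree,
        float(np.linalg.norm(resid)), x.copy(),
    )


def predict_apoptosis(curve: CalibrationCurve, auc_mean: float) -> dict:
    """Apoptosis percentage predicted from an ensemble-average AUC_casp3.

    The polynomial value is clipped to [0, 100]; out-of-range inputs are
    flagged (``extrapolated``) rather than rejected.
    """
    raw = float(np.polynomial.polynomial.polyval(auc_mean, curve.coefficients))
    lo, hi = curve.valid_range
    clipped = min(max(raw, 0.0), 100.0)
    return {
        "apoptosis_pct": clipped,
        "raw": raw,
        "clipped": clipped != raw,
        "extrapolated": not (lo <= auc_mean <= hi),
    }


def sensitivity_ratio(perturbed: Sequence[float], reference: Sequence[float],
                      time: Sequence[float],
                      window: tuple[float, float] | None = None) -> float:
    """Ratio of windowed AUCs of a perturbed to a reference transient
    (both on the same grid)."""
    t = np.asarray(time, dtype=float)
    w = window if window is not None else (float(t[0]), float(t[-1]))
    ref = auc(t, reference, w)
    if ref == 0:
        raise ZeroDivisionError("reference transient has zero AUC")
    return auc(t, perturbed, w) / ref
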