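"""Readers, writers, run configuration and the staged pipeline.

All tabular artifacts are UTF-8 CSV/TSV with a mandatory header, '.'
decimal separator and times in hours; every output file carries the
configuration hash and the run seed (as a leading ``#`` comment for
tabular files, as fields for JSON).  A single global seed fans out to the
stages as ``seed + stage index`` in the canonical stage order
synth -> simulate -> fit -> flux -> branches -> auc.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import auc as auc_mod
from . import branches as br_mod
from . import calibrate as cal_mod
from . import flux as flux_mod
from .network import NetworkSpec, assemble_odes, build_network, read_edge_list
from .params import ParameterSet, default_truth
from .simulate import StimulationProtocol, default_protocols, run_protocol
from .synth import ExperimentalDataset, NoiseModel, error_sigma, generate_mfi

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_protocols",
    "write_protocols",
    "write_trajectories",
    "run_pipeline",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = ("synth", "simulate", "fit", "flux", "branches", "auc")

DATASET_REQUIRED = ["condition", "marker", "time_h", "replicate", "FC"]


class DatasetFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dataset round trip
# ---------------------------------------------------------------------------


def write_dataset(ds: ExperimentalDataset, path: str | Path,
                  meta: Mapping[str, object] | None = None) -> None:
    """One row per replicate measurement plus one ``replicate = -1`` row per
    spline-augmented summary point; per-point sigma and the augmented flag
    ride along on every row."""
    sig = ds.summary.set_index(["condition", "marker", "time_h"])
    rows = []
    for _, r in ds.replicates.iterrows():
        key = (r["condition"], r["marker"], r["time_h"])
        rows.append((r["condition"], r["marker"], r["time_h"], int(r["replicate"]),
                     r["FC"], sig.loc[key, "sigma"], bool(sig.loc[key, "augmented"])))
    aug = ds.summary[ds.summary["augmented"]]
    seen = set(map(tuple, ds.replicates[["condition", "marker", "time_h"]].to_numpy()))
    for _, r in aug.iterrows():
        if (r["condition"], r["marker"], r["time_h"]) in seen:
            continue  # augmented flag already carried by the replicate rows
        rows.append((r["condition"], r["marker"], r["time_h"], -1,
                     r["FC"], r["sigma"], True))
    frame = pd.DataFrame(
        rows,
        columns=["condition", "marker", "time_h", "replicate", "FC", "sigma", "augmented"],
    ).sort_values(["condition", "marker", "time_h", "replicate"])
    _write_csv(frame, path, meta)


def read_dataset(path: str | Path, c_abs: float = 0.05) -> ExperimentalDataset:
    """Read a dataset CSV (header mandatory: condition, marker, time_h,
    replicate, FC[, sigma, augmented]); sigma is recomputed from the
    replicates when absent."""
    raw = pd.read_csv(path, comment="#")
    missing = [c for c in DATASET_REQUIRED if c not in raw.columns]
    if missing:
        raise DatasetFormatError(f"dataset file {path} is missing column(s): {missing}")
    fc = pd.to_numeric(raw["FC"], errors="coerce")
    bad = np.nonzero(fc.isna().to_numpy() & raw["FC"].notna().to_numpy())[0]
    if raw["FC"].isna().any():
        bad = np.concatenate([bad, np.nonzero(raw["FC"].isna().to_numpy())[0]])
    if bad.size:
        row = int(bad.min()) + 2  # 1-based plus header line
        raise DatasetFormatError(f"non-numeric FC value at row {row} of {path}")
    raw["FC"] = fc
    has_sigma = "sigma" in raw.columns
    has_aug = "augmented" in raw.columns
    if not has_aug:
        raw["augmented"] = False
    raw["augmented"] = raw["augmented"].astype(bool)

    reps = raw[raw["replicate"] >= 0]
    replicates = reps[["condition", "marker", "time_h", "replicate", "FC"]].reset_index(
        drop=True
    )
    rows = []
    for (cond, marker, t), grp in raw.groupby(["condition", "marker", "time_h"],
                                              sort=False):
        meas = grp[grp["replicate"] >= 0]
        if len(meas):
            mean_fc = float(meas["FC"].mean())
            sigma = (float(meas["sigma"].iloc[0]) if has_sigma
                     else error_sigma(meas["FC"].to_numpy(), c_abs))
            augmented = bool(meas["augmented"].iloc[0])
        else:  # spline-augmented point carried without replicates
            mean_fc = float(grp["FC"].iloc[0])
            sigma = float(grp["sigma"].iloc[0]) if has_sigma else c_abs
            augmented = True
        rows.append((cond, marker, float(t), mean_fc, sigma, augmented))
    summary = pd.DataFrame(
        rows, columns=["condition", "marker", "time_h", "FC", "sigma", "augmented"]
    ).sort_values(["condition", "marker", "time_h"]).reset_index(drop=True)
    return ExperimentalDataset(replicates=replicates, summary=summary)


# ---------------------------------------------------------------------------
# protocols, trajectories, generic writers
# ---------------------------------------------------------------------------


def write_protocols(protocols: Mapping[str, StimulationProtocol], path: str | Path) -> None:
    doc = {
        label: {
            "label": p.label, "tnf_dose": p.tnf_dose, "tpl_dose": p.tpl_dose,
            "inhibitor": p.inhibitor, "inhibitor_dose": p.inhibitor_dose,
            "pretreat_offset": p.pretreat_offset, "horizon": p.horizon,
        }
        for label, p in protocols.items()
    }
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_protocols(path: str | Path) -> dict[str, StimulationProtocol]:
    with open(path) as fh:
        doc = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    return {label: StimulationProtocol(**kw) for label, kw in doc.items()}


def write_trajectories(trajs: Sequence, path: str | Path,
                       meta: Mapping[str, object] | None = None,
                       full_states: bool = True) -> None:
    """Long-format trajectory CSV: condition, parameter_set_id,
    species_or_marker, time_h, value."""
    rows = []
    for traj in trajs:
        label, pid = traj.protocol.label, traj.parameter_set_id
        for marker, series in traj.markers.items():
            for t, v in zip(traj.time, series):
                rows.append((label, pid, marker, float(t), float(v)))
        if full_states:
            for i, name in enumerate(traj.species):
                for t, v in zip(traj.time, traj.states[i]):
                    rows.append((label, pid, name, float(t), float(v)))
    frame = pd.DataFrame(
        rows, columns=["condition", "parameter_set_id", "species_or_marker",
                       "time_h", "value"],
    )
    _write_csv(frame, path, meta)


def _write_csv(frame: pd.DataFrame, path: str | Path,
               meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        frame.to_csv(fh, index=False)


def _write_json(obj, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    doc = {"meta": dict(meta or {}), "data": obj}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=_jsonify)


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a staged pipeline run."""

    out_dir: str
    seed: int = 0
    network: str = "default"  # "default" or a path to an edge-list file
    stages: tuple[str, ...] = STAGES
    tpl_dose: float = 60.0
    noise_c_rel: float = 0.10
    noise_c_abs: float = 0.05
    n_replicates: int = 3
    augment: bool = True
    n_starts: int = 8
    fraction: float = 0.25
    free_parameters: tuple[str, ...] = ("V_PI3K_AKT", "k_C1P_JNK", "s_Casp3")
    bounds_decades: float = 1.0
    branch_sources: tuple[str, ...] = ("NFkB", "TNFR1")
    branch_targets: tuple[str, ...] = ("AKT", "JNK")
    max_len: int = br_mod.MAX_LEN_DEFAULT
    windows: tuple[float, ...] = auc_mod.DEFAULT_WINDOWS
    n_ensemble_trajectories: int = 5
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown pipeline stage(s): {unknown}")
        if self.network != "default" and not Path(self.network).exists():
            raise FileNotFoundError(self.network)

    def config_hash(self) -> str:
        # out_dir is where results land, not part of the scientific
        # configuration: identical configs into different directories
        # must produce identical artifacts
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in sorted(self.__dict__.items()) if k != "out_dir"},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGES.index(stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("stages", "free_parameters", "branch_sources", "branch_targets",
                    "windows"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in canonical order, writing every
    artifact under ``config.out_dir``; halts (retaining partial outputs)
    on the first failing stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    net = build_network() if config.network == "default" else read_edge_list(config.network)
    truth = default_truth()
    sys = assemble_odes(net, truth)
    protocols = default_protocols(config.tpl_dose)
    timings: dict[str, float] = {}

    state: dict[str, object] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = _time.perf_counter()
        logger.info("running stage %s", stage)
        try:
            _run_stage(stage, config, net, sys, truth, protocols, out, meta, state)
        except Exception as exc:  # noqa: BLE001
            _write_json({"timings_s": timings, "failed_stage": stage},
                        out / "manifest.json", meta)
            raise PipelineError(stage, exc) from exc
        timings[stage] = round(_time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])

    _write_json({"timings_s": timings, "stages": list(config.stages)},
                out / "manifest.json", meta)
    return out


def _ensemble_params(truth: ParameterSet, n: int, seed: int) -> list[ParameterSet]:
    """Small log-normal jitter around truth: stand-ins for the best-fit
    ensemble when the fit stage is skipped or truncated."""
    rng = np.random.default_rng(seed)
    out = []
    kinetic = [k for k in truth if not k.startswith(("s_", "Ki_", "n_"))]
    for i in range(n):
        jitter = {k: truth[k] * 10 ** rng.normal(0.0, 0.02) for k in kinetic}
        out.append(truth.replace(jitter, id=f"ens_{i}"))
    return out


def _run_stage(stage, config: RunConfig, net: NetworkSpec, sys, truth, protocols,
               out: Path, meta, state) -> None:
    sseed = config.stage_seed(stage)
    if stage == "synth":
        noise = NoiseModel(config.noise_c_rel, config.noise_c_abs,
                           config.n_replicates, seed=sseed)
        mfi = generate_mfi(sys, protocols, noise)
        _write_csv(mfi, out / "mfi.csv", meta)
        from .synth import dataset_from_mfi, augment_spline
        ds = dataset_from_mfi(mfi, noise)
        if config.augment:
            ds = augment_spline(ds)
        write_dataset(ds, out / "dataset.csv", meta)
        state["dataset"] = ds
    elif stage == "simulate":
        trajs = [run_protocol(sys, p, rtol=config.rtol, atol=config.atol)
                 for p in protocols.values()]
        write_trajectories(trajs, out / "trajectories.csv", meta)
        state["trajectories"] = {t.protocol.label: t for t in trajs}
    elif stage == "fit":
        ds = state.get("dataset") or read_dataset(out / "dataset.csv")
        simf = cal_mod.make_simulator(net, protocols, config.rtol, config.atol)
        fit = cal_mod.multistart_fit(
            ds, simf, truth, config.free_parameters, n_starts=config.n_starts,
            seed=sseed, bounds_decades=config.bounds_decades,
        )
        ensemble = cal_mod.select_ensemble(fit, config.fraction)
        _write_json(
            {
                "free_parameters": list(fit.free_names),
                "dataset_fingerprint": fit.dataset_fingerprint,
                "n_residuals": fit.n_residuals,
                "entries": [
                    {"id": e.params.id, "chisq": e.chisq, "status": e.status,
                     "start_id": e.start_id, "seed": e.seed,
                     "parameters": {k: e.params[k] for k in fit.free_names}}
                    for e in fit.sorted_entries()
                ],
            },
            out / "fit.json", meta,
        )
        summ = cal_mod.ensemble_summary(ensemble) if len(ensemble) >= 2 else None
        if summ is not None:
            summ.table.to_csv(out / "ensemble.tsv", sep="\t", index=False)
        state["ensemble"] = ensemble
    elif stage == "flux":
        trajs = state.get("trajectories") or {
            p.label: run_protocol(sys, p, rtol=config.rtol, atol=config.atol)
            for p in protocols.values()
        }
        fluxes = {label: flux_mod.edge_fluxes(sys, t) for label, t in trajs.items()}
        frame = pd.concat([f.to_frame(label) for label, f in fluxes.items()],
                          ignore_index=True)
        _write_csv(frame, out / "fluxes.csv", meta)
        state["fluxes"] = fluxes
        state["trajectories"] = trajs
    elif stage == "branches":
        fluxes = state.get("fluxes")
        if fluxes is None:
            trajs = {p.label: run_protocol(sys, p, rtol=config.rtol, atol=config.atol)
                     for p in protocols.values()}
            fluxes = {label: flux_mod.edge_fluxes(sys, t) for label, t in trajs.items()}
        all_branches = []
        syn_rows = []
        for src in config.branch_sources:
            for tgt in config.branch_targets:
                for b in br_mod.enumerate_branches(net, src, tgt, config.max_len):
                    all_branches.append(b)
                    tr = br_mod.synergism_trace(b, fluxes,
                                                conditions=tuple(protocols.keys()))
                    for j, t in enumerate(tr.time):
                        syn_rows.append((b.id, float(t), tr.r_single_a[j],
                                         tr.r_single_b[j], tr.r_combined[j], tr.s[j]))
        br_mod.branch_table(all_branches).to_csv(out / "branches.tsv", sep="\t",
                                                 index=False)
        _write_csv(
            pd.DataFrame(syn_rows, columns=["branch", "time_h", "R_TNFa", "R_TPL",
                                            "R_comb", "S"]),
            out / "synergism.csv", meta,
        )
    elif stage == "auc":
        ensemble = state.get("ensemble") or _ensemble_params(
            truth, config.n_ensemble_trajectories, sseed)
        records = []
        reg_out = {}
        for label, proto in protocols.items():
            per_rep = {}
            time_grid = None
            for P in ensemble:
                traj = run_protocol(assemble_odes(net, P), proto,
                                    rtol=config.rtol, atol=config.atol)
                per_rep[P.id or "best"] = traj.markers
                time_grid = traj.time
            rec = auc_mod.auc_records(per_rep, time_grid, label, config.windows)
            records.append(rec)
            reg = auc_mod.fit_contributions(rec)
            reg_out[label] = {
                "a": reg.a, "b": reg.b, "r_squared": reg.r_squared,
                "n_obs": reg.n_obs,
                "averaging": reg.averaging,
                "contributions": reg.contributions.to_dict("records"),
            }
        _write_csv(pd.concat(records, ignore_index=True), out / "auc.csv", meta)
        _write_json(reg_out, out / "regression.json", meta)
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
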