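"""End-to-end orchestration of a WT-vs-mutant analysis from one YAML config.

A run loads the declared structures/trajectories, then executes the
requested stages in dependency order — displacement profiles, distance and
angle time series with windowed tetramer statistics and distributions,
H-bond pair statistics, ligand interaction energies — writing one CSV per
stage plus a machine-readable ``summary.json`` and a run log.  The config
is schema-validated (unknown keys rejected) before any computation starts;
results go to files only, never stdout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .energy import NonbondedParams, SwitchSpec, energy_window_stats
from .geometry import (
    AngleMetric,
    DistanceMetric,
    SiteSpec,
    metric_over_trajectory,
    residue_displacement,
)
from .hbonds import HBondCriteria, PairSpec, pair_hbond_timeseries, summarize_pairs
from .stats import histogram, tetramer_stats, window_average
from .structure import Selection, read_frame_times, read_pdb, read_trajectory

__all__ = ["RunConfig", "ConfigError", "load_config", "run"]


class ConfigError(ValueError):
    """A configuration problem detected before any computation."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StructureInput(_Base):
    label: str
    path: str


class TrajectoryInput(_Base):
    label: str
    path: str
    times_csv: Optional[str] = None


class SiteConfig(_Base):
    res_seq: int
    atom_names: list[str]
    chain_offset: int = 0


class DistanceMetricConfig(_Base):
    name: str
    site_a: SiteConfig
    site_b: SiteConfig


class AngleMetricConfig(_Base):
    name: str
    res_seq: int
    atom_from: str
    atom_to: str
    axis: list[float] = Field(default=[0.0, 0.0, 1.0])


class DisplacementConfig(_Base):
    reference: str  # structure label
    mobile: str


class HBondPairConfig(_Base):
    res_a: int
    res_b: int
    chain_offset: int = 0
    label: str = ""


class SwitchConfig(_Base):
    r_on: float = 10.0
    r_off: float = 12.0


class EnergyConfig(_Base):
    trajectory: str  # trajectory label
    params_csv: str
    ligand_chains: dict[str, str]  # subunit chain -> ligand chain
    protein_chains: list[str]
    switch: SwitchConfig = Field(default_factory=SwitchConfig)


class RunConfig(_Base):
    """Validated schema of a full analysis run."""

    out_dir: str
    seed: int = 0
    structures: list[StructureInput] = Field(default_factory=list)
    trajectories: list[TrajectoryInput] = Field(default_factory=list)
    tm_ranges: list[list[int]] = Field(default_factory=list)
    ring_order: Optional[list[str]] = None
    window: Optional[list[float]] = None
    histogram_bin_size: float = 15.0
    histogram_range: list[float] = Field(default=[0.0, 180.0])
    hbond_criteria: dict[str, float] = Field(default_factory=dict)
    displacement: list[DisplacementConfig] = Field(default_factory=list)
    distances: list[DistanceMetricConfig] = Field(default_factory=list)
    angles: list[AngleMetricConfig] = Field(default_factory=list)
    hbond_pairs: list[HBondPairConfig] = Field(default_factory=list)
    energy: Optional[EnergyConfig] = None
    trajectory_for_metrics: Optional[str] = None


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _check_paths(config: RunConfig) -> None:
    missing = []
    for s in config.structures:
        if not Path(s.path).exists():
            missing.append(s.path)
    for t in config.trajectories:
        if not Path(t.path).exists():
            missing.append(t.path)
        if t.times_csv and not Path(t.times_csv).exists():
            missing.append(t.times_csv)
    if config.energy and not Path(config.energy.params_csv).exists():
        missing.append(config.energy.params_csv)
    if missing:
        raise ConfigError(f"missing input files: {missing}")


def _site(cfg: SiteConfig) -> SiteSpec:
    return SiteSpec.make(
        res_seq=cfg.res_seq, atom_names=cfg.atom_names, chain_offset=cfg.chain_offset
    )


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary report dict."""
    _check_paths(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("gating_metrics.run")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)
    log.info("gating-metrics %s | config hash %s | seed %d",
             __version__, _config_hash(config), config.seed)

    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "failures": [],
    }

    structures = {}
    for s in config.structures:
        structures[s.label] = read_pdb(s.path)[0]
        log.info("loaded structure %s (%d atoms)", s.label, len(structures[s.label]))
    trajectories = {}
    for t in config.trajectories:
        times = read_frame_times(t.times_csv) if t.times_csv else None
        trajectories[t.label] = read_trajectory(t.path, times=times)
        log.info("loaded trajectory %s (%d frames)", t.label, trajectories[t.label].n_frames)

    fit_sel = Selection.make(
        res_seq_ranges=config.tm_ranges or None, backbone_only=True
    )

    def _window(traj):
        if config.window:
            return (config.window[0], config.window[1])
        return (float(traj.times[0]), float(traj.times[-1]))

    # -- displacement profiles -------------------------------------------
    for d in config.displacement:
        stage = f"displacement:{d.mobile}-vs-{d.reference}"
        try:
            prof = residue_displacement(
                structures[d.reference], structures[d.mobile], fit_sel
            )
            df = pd.DataFrame(
                prof.entries, columns=["chain", "res_seq", "res_name", "displacement_A"]
            )
            path = out_dir / f"{stage.replace(':', '_')}.csv"
            df.to_csv(path, index=False)
            max_disp = float(df["displacement_A"].max())
            report["stages"][stage] = {
                "csv": str(path),
                "n_residues": len(df),
                "max_displacement_A": max_disp,
                "note": "no conformational difference" if max_disp < 1e-6 else "",
            }
            log.info("%s: %d residues, max displacement %.3f A", stage, len(df), max_disp)
        except Exception as exc:  # stage failure: record and continue
            report["failures"].append({"stage": stage, "error": str(exc)})
            log.error("%s failed: %s", stage, exc)

    # -- trajectory metrics ----------------------------------------------
    metric_specs: list[DistanceMetric | AngleMetric] = [
        DistanceMetric(name=m.name, site_a=_site(m.site_a), site_b=_site(m.site_b))
        for m in config.distances
    ] + [
        AngleMetric(
            name=m.name, res_seq=m.res_seq, atom_from=m.atom_from,
            atom_to=m.atom_to, axis=tuple(m.axis),
        )
        for m in config.angles
    ]
    for traj_label, traj in trajectories.items():
        if config.trajectory_for_metrics and traj_label != config.trajectory_for_metrics:
            continue
        ring = config.ring_order or traj.topology.chains
        for metric in metric_specs:
            stage = f"metric:{traj_label}:{metric.name}"
            try:
                series = metric_over_trajectory(traj, metric, ring_order=ring)
                df = series.to_frame()
                path = out_dir / f"{traj_label}_{metric.name}.csv"
                df.to_csv(path, index=False)
                win = _window(traj)
                means = window_average(series, win)
                ws = tetramer_stats(means)
                pooled = np.concatenate(
                    [v for v in series.per_subunit.values()]
                )
                if isinstance(metric, AngleMetric):
                    dist = histogram(
                        pooled, config.histogram_bin_size,
                        tuple(config.histogram_range),
                    )
                else:
                    lo, hi = float(pooled.min()), float(pooled.max())
                    dist = histogram(pooled, max((hi - lo) / 12 or 1.0, 1e-9), (lo, hi + 1e-9))
                report["stages"][stage] = {
                    "csv": str(path),
                    "window": list(win),
                    "per_subunit_mean": means,
                    "tetramer_mean": ws.mean,
                    "tetramer_sd": ws.sd,
                    "histogram": {
                        "bin_edges": dist.bin_edges.tolist(),
                        "frequencies": dist.frequencies.tolist(),
                    },
                }
                log.info("%s: tetramer %.3f ± %.3f", stage, ws.mean, ws.sd)
            except Exception as exc:
                report["failures"].append({"stage": stage, "error": str(exc)})
                log.error("%s failed: %s", stage, exc)

    # -- H-bond pair statistics ------------------------------------------
    if config.hbond_pairs:
        criteria = HBondCriteria(**config.hbond_criteria) if config.hbond_criteria else HBondCriteria()
        pairs = [
            PairSpec(res_a=p.res_a, res_b=p.res_b, chain_offset=p.chain_offset, label=p.label)
            for p in config.hbond_pairs
        ]
        for traj_label, traj in trajectories.items():
            if config.trajectory_for_metrics and traj_label != config.trajectory_for_metrics:
                continue
            stage = f"hbonds:{traj_label}"
            try:
                ring = config.ring_order or traj.topology.chains
                series = pair_hbond_timeseries(traj, pairs, criteria, ring_order=ring)
                stats = summarize_pairs(series, _window(traj))
                rows = [
                    {
                        "pair": st.pair.name(),
                        "class": st.kind,
                        **{f"subunit_{i}": v for i, v in enumerate(st.per_subunit_mean)},
                        "mean": st.mean,
                        "sd": st.sd,
                    }
                    for st in stats
                ]
                path = out_dir / f"{traj_label}_hbond_pairs.csv"
                pd.DataFrame(rows).to_csv(path, index=False)
                report["stages"][stage] = {
                    "csv": str(path),
                    "pairs": {r["pair"]: {"mean": r["mean"], "sd": r["sd"]} for r in rows},
                }
                log.info("%s: %d pairs summarised", stage, len(rows))
            except Exception as exc:
                report["failures"].append({"stage": stage, "error": str(exc)})
                log.error("%s failed: %s", stage, exc)

    # -- ligand interaction energy ---------------------------------------
    if config.energy is not None:
        stage = f"energy:{config.energy.trajectory}"
        try:
            traj = trajectories[config.energy.trajectory]
            params = NonbondedParams.from_csv(config.energy.params_csv)
            spec = SwitchSpec(
                r_on=config.energy.switch.r_on, r_off=config.energy.switch.r_off
            )
            ligand_sels = {
                subunit: Selection.make(chain_ids=[lig_chain])
                for subunit, lig_chain in config.energy.ligand_chains.items()
            }
            protein_sel = Selection.make(chain_ids=config.energy.protein_chains)
            ws = energy_window_stats(
                traj, ligand_sels, protein_sel, params, spec, _window(traj)
            )
            rows = [
                {
                    "subunit": c,
                    "mean_total_kcal": m,
                    "mean_elec_kcal": ws.per_subunit_components[c][0],
                    "mean_vdw_kcal": ws.per_subunit_components[c][1],
                }
                for c, m in ws.per_subunit_mean.items()
            ]
            path = out_dir / f"{config.energy.trajectory}_energy.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            report["stages"][stage] = {
                "csv": str(path),
                "per_subunit_mean": ws.per_subunit_mean,
                "tetramer_mean": ws.mean,
                "tetramer_sd": ws.sd,
            }
            log.info("%s: tetramer %.3f ± %.3f kcal/mol", stage, ws.mean, ws.sd)
        except Exception as exc:
            report["failures"].append({"stage": stage, "error": str(exc)})
            log.error("%s failed: %s", stage, exc)

    report["ok"] = not report["failures"]
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("run %s; summary at %s", "completed" if report["ok"] else "FAILED",
             out_dir / "summary.json")
    for handler in list(log.handlers):
        handler.close()
        log.removeHandler(handler)
    return report
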