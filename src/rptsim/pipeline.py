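"""End-to-end orchestration: grow -> flow -> PBPK -> transport -> dose -> plan.

A :class:`RunConfig` pins every stage input (patient, injection, lattice,
solver settings, seed); :func:`run_pipeline` executes the stages in
dependency order and returns an artifact bundle whose JSON-serializable
summary embeds the config hash, seed and package version, so a rerun with
the same config is reproducible bit-for-bit (modulo timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .angiogenesis import (GrowthParams, LatticeGrid, grow_network,
                           make_taf_field, network_stats, save_network)
from .cdr import CDRParameters, field_time_integrals, run_transport
from .dosimetry import SValueTable, max_safe_activity, tumor_dose_report
from .microcirculation import FlowParameters, couple
from .organs import PatientParameters, default_patient, load_patient
from .pbpk import PBPKModel, default_time_grid, simulate, tumor_vascular_input


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    patient_file: str | None = None     # JSON/TOML; None -> reference patient
    A0_mbq: float = 7400.0
    aai: bool = False
    seed: int = 0
    t_end_min: float = 30000.0
    lattice: dict = field(default_factory=dict)       # LatticeGrid overrides
    growth: dict = field(default_factory=dict)        # GrowthParams overrides
    flow: dict = field(default_factory=dict)          # FlowParameters overrides
    cdr: dict = field(default_factory=dict)           # CDRParameters overrides
    cdr_dt_min: float = 1.0
    pbpk_rtol: float = 1e-8
    oar: str = "kidneys"
    oar_limit_gy: float = 8.0
    engine: str = "pbpk"                # "pbpk" or "pbpk+cdr"
    run_plan: bool = True
    run_cdr: bool = False
    out_dir: str | None = None

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # where results land does not change them
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"run configuration file not found: {path}")
        if path.suffix.lower() == ".toml":
            import tomllib
            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls(**d)


def _load_patient(cfg: RunConfig) -> PatientParameters:
    if cfg.patient_file is None:
        return default_patient()
    try:
        return load_patient(cfg.patient_file)
    except FileNotFoundError as exc:
        raise ConfigurationError(str(exc)) from exc


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact bundle.

    On a stage failure the bundle collected so far is attached to the raised
    exception as ``exc.partial_bundle`` together with a failure manifest.
    """
    from .organs import apply_amino_acid_infusion

    bundle: dict = {"meta": {
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "version": __version__, "config": dataclasses.asdict(cfg),
    }}
    stage = "configure"
    try:
        patient = apply_amino_acid_infusion(_load_patient(cfg), cfg.aai)

        stage = "grow"
        t0 = time.time()
        grid = LatticeGrid(**cfg.lattice)
        taf = make_taf_field(grid)
        net = grow_network(grid, taf, GrowthParams(**cfg.growth), seed=cfg.seed)
        bundle["network"] = net
        bundle["network_stats"] = {
            k: v for k, v in network_stats(net, grid).items() if k != "sv_field"}
        bundle["meta"]["grow_s"] = round(time.time() - t0, 3)

        stage = "flow"
        t0 = time.time()
        pressure = couple(net, grid, FlowParameters(**cfg.flow))
        bundle["pressure"] = pressure
        bundle["flow_summary"] = {
            "mean_tumor_ivp_mmhg": pressure.mean_tumor_ivp_mmhg(),
            "mean_tumor_ifp_mmhg": pressure.mean_tumor_ifp_mmhg(),
            "residual": pressure.residuals[-1],
        }
        bundle["meta"]["flow_s"] = round(time.time() - t0, 3)

        stage = "pbpk"
        t0 = time.time()
        traj = simulate(PBPKModel(patient), cfg.A0_mbq,
                        default_time_grid(cfg.t_end_min), rtol=cfg.pbpk_rtol)
        bundle["trajectories"] = traj
        bundle["meta"]["pbpk_s"] = round(time.time() - t0, 3)

        cdr_integrals = None
        if cfg.run_cdr or cfg.engine == "pbpk+cdr":
            stage = "cdr"
            t0 = time.time()
            fields = run_transport(pressure, tumor_vascular_input(traj),
                                   CDRParameters(**cfg.cdr),
                                   t_end=cfg.t_end_min, dt=cfg.cdr_dt_min)
            bundle["fields"] = fields
            cdr_integrals = field_time_integrals(
                fields, patient.organ_of_kind("tumor").V_int)
            bundle["meta"]["cdr_s"] = round(time.time() - t0, 3)

        stage = "dosimetry"
        s_table = SValueTable()
        report = tumor_dose_report(traj, s_table, cdr_integrals=cdr_integrals,
                                   T=cfg.t_end_min)
        bundle["dose_report"] = report

        if cfg.run_plan:
            stage = "plan"
            t0 = time.time()
            plan = max_safe_activity(patient, cfg.oar, cfg.oar_limit_gy,
                                     cfg.aai, engine="pbpk", s_table=s_table,
                                     T=cfg.t_end_min)
            bundle["plan"] = plan
            bundle["meta"]["plan_s"] = round(time.time() - t0, 3)

        if cfg.out_dir is not None:
            stage = "write"
            _write_bundle(cfg, bundle)
        return bundle
    except Exception as exc:
        exc.partial_bundle = bundle
        bundle["failure"] = {"stage": stage, "error": str(exc)}
        raise


def _write_bundle(cfg: RunConfig, bundle: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_network(bundle["network"], out / "network.csv")
    summary = {
        "meta": bundle["meta"],
        "network_stats": bundle["network_stats"],
        "flow_summary": bundle["flow_summary"],
        "dose_report": bundle["dose_report"].to_dict(),
    }
    if "plan" in bundle:
        p = bundle["plan"]
        summary["plan"] = {
            "oar": p.oar, "limit_gy": p.limit_gy, "aai": p.aai,
            "A_max_GBq": p.A_max_gbq, "oar_dose_gy": p.oar_dose_gy,
            "tumor_dose_gy": p.tumor_dose_gy, "engine": p.engine,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    bundle["trajectories"].to_frame().to_csv(out / "trajectories.csv", index=False)
    try:
        import h5py

        with h5py.File(out / "fields.h5", "w") as f:
            f.attrs["config_hash"] = cfg.config_hash()
            f.attrs["seed"] = cfg.seed
            f.attrs["version"] = __version__
            pr = bundle["pressure"]
            f.create_dataset("ifp_pa", data=pr.ifp)
            f.create_dataset("v_i_m_per_s", data=pr.v_i)
            f.create_dataset("psi_b_per_s", data=pr.psi_b)
            f.create_dataset("node_ij", data=pr.node_ij)
            f.create_dataset("node_pressure_pa", data=pr.node_pressure)
            if "fields" in bundle:
                g = f.create_group("tumor_fields")
                fl = bundle["fields"]
                g.create_dataset("snapshot_times_min", data=fl.snapshot_times)
                for name, stack in fl.snapshots.items():
                    g.create_dataset(name, data=stack)
    except OSError:
        pass
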