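"""End-to-end orchestration from a single JSON config.

Three runners cover the three workflows: structure → channel →
hydration/field profiles; spectroscopy traces → calibrations →
ΔpH/rates/fluxes; respiration batches → normalized tables.  Every
output directory receives a ``run_manifest.json`` embedding the resolved
config, the seed and a config hash, so identical configs reproduce
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import hydration, io, kinetics, respiration
from .channel import BulkDefinition, SearchSpec, build_grid, extend_to_bulk, find_channel
from .core import LiposomeSpec

logger = logging.getLogger("protonpath")

__all__ = ["RunConfig", "run_channel_pipeline", "run_kinetics_pipeline",
           "run_assay_pipeline"]


class RunConfig:
    """Validated run configuration loaded from a JSON file or dict."""

    def __init__(self, data: dict, base_dir: Path | None = None):
        self.data = data
        self.base_dir = Path(base_dir) if base_dir else Path.cwd()
        self.seed = int(data.get("seed", 0))
        self.output_dir = Path(data.get("output_dir", "protonpath_out"))
        if not self.output_dir.is_absolute():
            self.output_dir = self.base_dir / self.output_dir

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        return cls(json.loads(path.read_text()), base_dir=path.parent)

    def resolve(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    def require_file(self, rel) -> Path:
        p = self.resolve(rel)
        if not p.is_file():
            raise FileNotFoundError(f"config references missing file: {p}")
        return p

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_manifest(config: RunConfig, outdir: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.data,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))


def _search_spec(section: dict) -> SearchSpec:
    bulk = BulkDefinition(**section.get("bulk", {}))
    start = section["start"]
    if isinstance(start, (list, tuple)):
        start = np.asarray(start, float)
    return SearchSpec(
        start=start,
        probe_radius=float(section.get("probe_radius", 0.9)),
        excluded_residues=list(section.get("excluded_residues", [])),
        bulk=bulk,
    )


def run_channel_pipeline(config: RunConfig) -> dict:
    """Structure → channel → per-replica and aggregate profiles."""
    section = config.data["channel"]
    structure_path = config.require_file(section["structure"])
    charge_table = (
        config.require_file(section["charge_table"])
        if section.get("charge_table")
        else None
    )
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    structure = io.read_structure(structure_path, charge_table=charge_table)
    spec = _search_spec(section)
    grid = build_grid(
        structure,
        spec,
        spacing=float(section.get("spacing", 0.8)),
        margin=section.get("margin", 4.0),
    )
    try:
        path = find_channel(grid, spec, structure=structure)
        path = extend_to_bulk(path, grid, spec)
    except Exception:
        logger.exception("stage channel_search failed")
        raise
    path.to_frame().to_csv(outdir / "tunnel.csv", index=False,
                           float_format="%.17g")
    (outdir / "tunnel.json").write_text(json.dumps({
        "bottleneck_radius": path.bottleneck_radius,
        "length": path.length,
        "reached_bulk": path.reached_bulk,
        "segments": sorted(set(path.segments)),
        "seed": config.seed,
    }, indent=2))

    step = float(section.get("step", 1.0))
    capture = float(section.get("capture_radius", 2.0))
    exclusion = float(section.get("exclusion_radius", 2.0))
    occ_profiles, field_profiles = [], []
    for i, traj_rel in enumerate(section.get("trajectories", [])):
        traj_path = config.require_file(traj_rel)
        traj = io.read_trajectory(traj_path, replica_id=i)
        # the trajectory's own atom list (protein + solvent) defines the
        # system for hydration and field profiling
        traj_structure = io.read_structure(traj_path, charge_table=charge_table)
        if section.get("superpose_selection"):
            traj, _ = hydration.superpose(
                traj, traj_structure, section["superpose_selection"]
            )
        try:
            occ = hydration.water_occupancy(traj, traj_structure, path,
                                            capture_radius=capture, step=step)
            occ_profiles.append(occ)
        except ValueError as exc:
            logger.warning("stage hydration skipped for replica %d: %s", i, exc)
        fld = hydration.electric_field(traj, traj_structure, path,
                                       exclusion_radius=exclusion, step=step)
        field_profiles.append(fld)

    outputs = {"tunnel": outdir / "tunnel.csv"}
    for name, profiles in (("occupancy", occ_profiles), ("field", field_profiles)):
        if not profiles:
            continue
        io.write_profile_report(profiles, outdir / f"{name}_replicas")
        agg = hydration.aggregate_replicas(
            profiles, normalize=bool(section.get("normalize", False))
            if name == "occupancy" else False,
        )
        io.write_profile_report(agg, outdir / f"{name}_aggregate")
        outputs[name] = outdir / f"{name}_aggregate.csv"
    _write_manifest(config, outdir, "channel")
    return outputs


def run_kinetics_pipeline(config: RunConfig) -> dict:
    """Traces → calibrations → ΔpH / initial rates / proton fluxes."""
    section = config.data["kinetics"]
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    calib_cfg = section.get("ph_calibration", {})
    if "a" in calib_cfg:
        ph_calib = kinetics.PyranineCalibration(a=calib_cfg["a"], b=calib_cfg["b"])
    elif "points" in calib_cfg:
        pts = pd.read_csv(config.require_file(calib_cfg["points"]), comment="#")
        ph_calib = kinetics.fit_ph_calibration(
            list(zip(pts["ratio"], pts["pH"]))
        )
    else:
        ph_calib = None

    psi_cfg = section.get("psi_calibration", {})
    if "slope" in psi_cfg:
        psi_calib = kinetics.PsiCalibration(slope=psi_cfg["slope"],
                                            intercept=psi_cfg.get("intercept", 0.0))
    elif "points" in psi_cfg:
        pts = pd.read_csv(config.require_file(psi_cfg["points"]), comment="#")
        psi_calib = kinetics.fit_psi_calibration(
            list(zip(pts["delta_a"], pts["k_out"], pts["k_in"], pts["T"]))
        )
    else:
        psi_calib = None

    lip = LiposomeSpec(**section.get("liposome", {}))
    rows = []
    for rel in section.get("pyranine_traces", []):
        try:
            trace = io.read_trace(config.require_file(rel), ["I405", "I460"])
            event = float(trace.metadata.get("event_time",
                                             section.get("event_time", 60.0)))
            ph = kinetics.ph_trace(trace, ph_calib)
            res = kinetics.extract_delta_ph(
                ph, event_time=event,
                baseline_window=float(section.get("baseline_window", 60.0)),
            )
            rows.append({
                "trace": str(rel), "kind": "pyranine",
                "initial_pH": res.initial_pH, "final_pH": res.final_pH,
                "delta_pH": res.delta_pH, "k_per_s": res.exp_rate_constant,
                "flags": ";".join(res.flags),
            })
        except Exception as exc:  # corrupt trace: log, continue with the rest
            logger.warning("skipping pyranine trace %s: %s", rel, exc)
    for rel in section.get("oxonol_traces", []):
        try:
            trace = io.read_trace(config.require_file(rel), ["A588", "A625"])
            psi = kinetics.psi_trace(trace, psi_calib)
            rate = kinetics.initial_rate(
                psi, start=float(section.get("rate_start", 0.0)),
                window=float(section.get("rate_window", 1.0)),
            )
            rows.append({
                "trace": str(rel), "kind": "oxonol",
                "initial_rate_mV_s": rate,
                "proton_flux_per_s": kinetics.proton_flux(rate, lip),
            })
        except Exception as exc:
            logger.warning("skipping oxonol trace %s: %s", rel, exc)

    df = pd.DataFrame(rows)
    df.to_csv(outdir / "kinetics.csv", index=False, float_format="%.17g")
    summary: dict = {"seed": config.seed, "liposome": asdict(lip)}
    if not df.empty and "delta_pH" in df.columns:
        dph = df.loc[df["kind"] == "pyranine", "delta_pH"].dropna()
        if len(dph):
            summary["delta_pH_mean"] = float(dph.mean())
            summary["delta_pH_sd"] = float(dph.std(ddof=1)) if len(dph) > 1 else 0.0
    if not df.empty and "initial_rate_mV_s" in df.columns:
        rates = df.loc[df["kind"] == "oxonol", "initial_rate_mV_s"].dropna()
        if len(rates):
            summary["initial_rate_mean_mV_s"] = float(rates.mean())
    (outdir / "kinetics_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    _write_manifest(config, outdir, "kinetics")
    return {"table": outdir / "kinetics.csv",
            "summary": outdir / "kinetics_summary.json"}


def run_assay_pipeline(config: RunConfig) -> dict:
    """O₂ + FeCN traces per construct → normalized respiration table."""
    section = config.data["assays"]
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    reference_name = section["reference"]

    measured = {}
    for entry in section["constructs"]:
        name = entry["name"]
        try:
            o2 = io.read_trace(config.require_file(entry["o2_trace"]), ["O2"])
            fecn = io.read_trace(config.require_file(entry["fecn_trace"]),
                                 ["A410"])
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"construct {name!r}: {exc}") from exc
        raw = -respiration.linear_rate(o2, channel="O2")  # consumption > 0
        fecn_rate = abs(respiration.fecn_activity(fecn))
        measured[name] = (raw, float(entry["protein"]), fecn_rate)

    if reference_name not in measured:
        raise KeyError(f"reference construct {reference_name!r} not in batch")
    raw_r, prot_r, fecn_r = measured[reference_name]
    reference = respiration.NormalizedRate(
        raw_rate=raw_r, protein_conc=prot_r, fecn_rate=fecn_r, normalized=100.0
    )
    rows = []
    for name, (raw, prot, fecn) in measured.items():
        nr = respiration.normalize(raw, prot, fecn, reference)
        rows.append({
            "construct": name, "raw_rate": raw, "protein_mg_ml": prot,
            "fecn_rate": fecn, "normalized_percent": nr.normalized,
            "sd_percent": nr.sd,
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "respiration.csv", index=False, float_format="%.17g")
    _write_manifest(config, outdir, "assays")
    return {"table": outdir / "respiration.csv"}
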