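"""Readers and writers: PDB structures, multi-model trajectories,
delimited assay traces, and channel-profile reports.

Radii and charges are resolved from an optional side table (CSV with
columns ``residue_name, atom_name, vdw_radius, partial_charge``); atoms
not listed there fall back to the bundled Bondi element radii with zero
partial charge, and an atom resolvable by neither route is an error.
Only orthorhombic periodic boxes (CRYST1 with 90° angles) are supported.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.PDB.PDBExceptions import PDBConstructionException

from .core import (
    DEFAULT_SOLVENT_RESNAMES,
    AssayTrace,
    AtomRecord,
    ChannelProfile,
    StructureModel,
    Trajectory,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "read_trace",
    "write_trace",
    "read_charge_table",
    "write_profile_report",
    "read_profile_report",
    "load_element_radii",
    "load_residue_classes",
]


class StructureParseError(ValueError):
    pass


def load_element_radii() -> dict[str, float]:
    """Bundled Bondi element vdW radii (Å)."""
    with resources.files("protonpath.data").joinpath("vdw_radii.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["element"].str.upper(), df["vdw_radius"].astype(float)))


def load_residue_classes() -> dict[str, str]:
    """Bundled residue polarity classes (nonpolar/polar/titratable)."""
    path = resources.files("protonpath.data").joinpath("residue_classes.csv")
    with path.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["residue_name"].str.upper(), df["cls"]))


def read_charge_table(path) -> dict[tuple[str, str], tuple[float, float]]:
    """(residue_name, atom_name) -> (vdw_radius, partial_charge)."""
    df = pd.read_csv(path, comment="#")
    required = {"residue_name", "atom_name", "vdw_radius", "partial_charge"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"charge table missing columns: {sorted(missing)}")
    return {
        (str(r.residue_name).upper(), str(r.atom_name).upper()): (
            float(r.vdw_radius),
            float(r.partial_charge),
        )
        for r in df.itertuples()
    }


def _read_cryst1_box(path) -> np.ndarray | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]),
                               float(line[24:33]))
                    alpha, beta, gamma = (float(line[33:40]), float(line[40:47]),
                                          float(line[47:54]))
                except ValueError as exc:
                    raise StructureParseError(f"malformed CRYST1 record: {exc}")
                if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
                    raise StructureParseError(
                        "only orthorhombic periodic boxes are supported"
                    )
                if a * b * c == 0:
                    return None  # placeholder CRYST1, no real cell
                return np.array([a, b, c])
    return None


def _parse_pdb(path):
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        return parser.get_structure("model", str(path))
    except PDBConstructionException as exc:
        raise StructureParseError(f"malformed PDB record in {path}: {exc}") from exc


def _atom_records(model, charge_map, element_radii, solvent_resnames):
    records = []
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip().upper()
            for atom in residue:
                name = atom.get_name().strip().upper()
                element = (atom.element or "").strip().upper()
                if charge_map is not None and (resname, name) in charge_map:
                    radius, charge = charge_map[(resname, name)]
                elif element in element_radii:
                    radius, charge = element_radii[element], 0.0
                else:
                    raise StructureParseError(
                        f"cannot resolve radius/charge for atom {name} of "
                        f"{resname}{residue.get_id()[1]} (element {element!r}): "
                        "not in charge table and no default element radius"
                    )
                records.append(
                    AtomRecord(
                        serial=int(atom.get_serial_number()),
                        name=name,
                        residue_name=resname,
                        residue_id=int(residue.get_id()[1]),
                        chain=str(chain.get_id()),
                        position=np.array(atom.get_coord(), float),
                        vdw_radius=radius,
                        partial_charge=charge,
                        is_heavy=element != "H",
                        is_solvent=resname in solvent_resnames,
                    )
                )
    return records


def read_structure(
    path,
    charge_table=None,
    solvent_resnames=DEFAULT_SOLVENT_RESNAMES,
) -> StructureModel:
    """Read a PDB file into a StructureModel (first model only).

    ``charge_table`` is a path to a CSV side table assigning per-atom vdW
    radii and partial charges; see :func:`read_charge_table`.
    """
    charge_map = read_charge_table(charge_table) if charge_table else None
    structure = _parse_pdb(path)
    models = list(structure)
    if not models:
        raise StructureParseError(f"no models found in {path}")
    records = _atom_records(
        models[0], charge_map, load_element_radii(), frozenset(solvent_resnames)
    )
    return StructureModel(records, box=_read_cryst1_box(path))


def read_trajectory(
    path, frame_interval: float = 1.0, replica_id: int = 0
) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (one frame per MODEL).

    Binary trajectory formats enter through :class:`~protonpath.core.Trajectory`
    directly: any reader that yields an (n_frames, n_atoms, 3) array can
    construct one.
    """
    structure = _parse_pdb(path)
    frames = []
    n_atoms = None
    for model in structure:
        coords = np.array(
            [a.get_coord() for c in model for r in c for a in r], float
        )
        if n_atoms is None:
            n_atoms = len(coords)
        elif len(coords) != n_atoms:
            raise StructureParseError(
                f"frame {len(frames)} has {len(coords)} atoms, expected {n_atoms}"
            )
        frames.append(coords)
    if not frames:
        raise StructureParseError(f"no models found in {path}")
    return Trajectory(
        np.stack(frames), frame_interval=frame_interval, replica_id=replica_id
    )


def write_structure(structure: StructureModel, path) -> None:
    """Write a StructureModel to a PDB file (CRYST1 emitted if box set)."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("model")
    builder.init_model(0)
    current_chain = None
    current_res = None
    # group by (chain, residue) so the emitted file has contiguous
    # residues; readers group the same way, keeping round-trips aligned
    ordered = sorted(structure.atoms,
                     key=lambda a: (a.chain, a.residue_id, a.serial))
    for a in ordered:
        if a.chain != current_chain:
            builder.init_chain(a.chain)
            builder.init_seg("    ")
            current_chain = a.chain
            current_res = None
        key = (a.residue_id, a.residue_name)
        if key != current_res:
            builder.init_residue(a.residue_name, " ", a.residue_id, " ")
            current_res = key
        element = "H" if not a.is_heavy else ("O" if a.is_solvent else "C")
        # element guess is only used for PDB column alignment; radii and
        # charges always travel through the side table on re-read
        if a.name[:1] in ("O", "N", "S", "P", "H", "C"):
            element = a.name[0]
        builder.init_atom(
            a.name, a.position, 0.0, 1.0, " ", a.name.rjust(3), a.serial, element
        )
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    buf = _io.StringIO()
    pdbio.save(buf)
    text = buf.getvalue()
    if structure.box is not None:
        a, b, c = structure.box
        cryst = (
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} "
            f"P 1           1\n"
        )
        text = cryst + text
    Path(path).write_text(text)


def write_trajectory(structure: StructureModel, traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB (one MODEL per frame)."""
    traj.check_against(structure)
    chunks = []
    base_atoms = structure.atoms
    for f in range(traj.n_frames):
        frame_atoms = [
            AtomRecord(
                a.serial, a.name, a.residue_name, a.residue_id, a.chain,
                traj.frames[f][i], a.vdw_radius, a.partial_charge,
                a.is_heavy, a.is_solvent,
            )
            for i, a in enumerate(base_atoms)
        ]
        frame_model = StructureModel(frame_atoms, box=structure.box)
        buf = Path(path).with_suffix(".tmpframe")
        write_structure(frame_model, buf)
        body = "\n".join(
            line for line in buf.read_text().splitlines()
            if line.startswith(("ATOM", "HETATM", "TER"))
        )
        chunks.append(f"MODEL     {f + 1:4d}\n{body}\nENDMDL")
        buf.unlink()
    Path(path).write_text("\n".join(chunks) + "\nEND\n")


# ---------------------------------------------------------------------------
# Assay traces
# ---------------------------------------------------------------------------

def read_trace(path, schema: list[str]) -> AssayTrace:
    """Read a delimited trace with a ``time`` column plus ``schema`` channels.

    Lines starting with ``#`` are metadata: ``# key=value`` pairs are
    parsed into the metadata mapping, anything else is collected under
    ``comments``.
    """
    metadata: dict = {}
    comments: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body and " " not in body.split("=", 1)[0]:
                key, value = body.split("=", 1)
                try:
                    metadata[key.strip()] = json.loads(value.strip())
                except json.JSONDecodeError:
                    metadata[key.strip()] = value.strip()
            elif body:
                comments.append(body)
    if comments:
        metadata["comments"] = comments
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path}: no 'time' column")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channels {missing}")
    time = df["time"].to_numpy(float)
    if len(time) > 1 and not np.all(np.diff(time) > 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 1
        raise ValueError(f"{path}: time not strictly increasing at row {bad}")
    return AssayTrace(
        time, {c: df[c].to_numpy(float) for c in schema}, metadata=metadata
    )


def write_trace(trace: AssayTrace, path) -> None:
    lines = []
    for key, value in trace.metadata.items():
        if key == "comments":
            lines.extend(f"# {c}" for c in value)
        else:
            lines.append(f"# {key}={json.dumps(value)}")
    df = pd.DataFrame({"time": trace.time, **trace.channels})
    body = df.to_csv(index=False, float_format="%.17g")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + body)


# ---------------------------------------------------------------------------
# Profile reports
# ---------------------------------------------------------------------------

def write_profile_report(profiles, path) -> tuple[Path, Path]:
    """Write one or more ChannelProfiles as ``<path>.csv`` + ``<path>.json``.

    All profiles must share a coordinate grid.  The CSV holds one row per
    (replica, coordinate) with a column per populated quantity; the JSON
    summary records grid size, frame counts and contributing replicas.
    Values round-trip to machine precision through
    :func:`read_profile_report`.
    """
    if isinstance(profiles, ChannelProfile):
        profiles = [profiles]
    if not profiles:
        raise ValueError("empty profile list")
    for p in profiles:
        if len(p.coordinate) == 0:
            raise ValueError("empty profile")
        if not np.array_equal(p.coordinate, profiles[0].coordinate):
            raise ValueError("profiles do not share a coordinate grid")
    rows = []
    for idx, p in enumerate(profiles):
        rep = p.replicas[0] if len(p.replicas) == 1 else idx
        data = {"profile": idx, "replica": rep, "coordinate": p.coordinate}
        for q in p.quantities:
            data[q] = getattr(p, q)
        if p.field_vector is not None:
            data["field_x"] = p.field_vector[:, 0]
            data["field_y"] = p.field_vector[:, 1]
            data["field_z"] = p.field_vector[:, 2]
        rows.append(pd.DataFrame(data))
    df = pd.concat(rows, ignore_index=True)
    base = Path(path)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    df.to_csv(csv_path, index=False, float_format="%.17g")
    summary = {
        "n_points": int(len(profiles[0].coordinate)),
        "n_profiles": len(profiles),
        "quantities": sorted({q for p in profiles for q in p.quantities}),
        "n_frames": [int(p.n_frames) for p in profiles],
        "replicas": [list(map(int, p.replicas)) for p in profiles],
        "coordinate_range": [
            float(profiles[0].coordinate[0]),
            float(profiles[0].coordinate[-1]),
        ],
    }
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path


def read_profile_report(path) -> list[ChannelProfile]:
    """Read profiles written by :func:`write_profile_report`."""
    base = Path(path)
    df = pd.read_csv(base.with_suffix(".csv"), float_precision="round_trip")
    summary = json.loads(base.with_suffix(".json").read_text())
    profiles = []
    for i, (_, sub) in enumerate(df.groupby("profile", sort=True)):
        kwargs = {}
        for q in ("occupancy", "occupancy_sd", "field_magnitude", "radius"):
            if q in sub.columns:
                kwargs[q] = sub[q].to_numpy(float)
        if {"field_x", "field_y", "field_z"} <= set(sub.columns):
            kwargs["field_vector"] = sub[["field_x", "field_y", "field_z"]].to_numpy(
                float
            )
        profiles.append(
            ChannelProfile(
                coordinate=sub["coordinate"].to_numpy(float),
                n_frames=summary["n_frames"][i] if i < len(summary["n_frames"]) else 0,
                replicas=summary["replicas"][i] if i < len(summary["replicas"]) else [],
                **kwargs,
            )
        )
    return profiles
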