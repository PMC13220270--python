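"""Shared domain types for channel profiling and liposome assay analysis.

Conventions used throughout the package:

* lengths in Å, times in seconds (trajectory frame spacing in ns),
  charges in elementary charge e, potentials in mV, fields in V/Å;
* 0-based frame indexing;
* a residue is identified by its ``(chain, residue_id)`` pair;
* when a periodic box is present, distances use the minimum-image
  convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "AssayTrace",
    "LiposomeSpec",
    "ChannelProfile",
    "resolve_residues",
]

#: Water residue names recognised as solvent by default.
DEFAULT_SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "TP3"}
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position and the physics attached to it.

    ``vdw_radius`` (Å) makes the atom an obstacle for channel geometry;
    ``partial_charge`` (e) makes it a field source.  Solvent atoms are
    excluded from both roles downstream.
    """

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    vdw_radius: float
    partial_charge: float
    is_heavy: bool = True
    is_solvent: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.is_heavy and not self.is_solvent and self.vdw_radius <= 0:
            raise ValueError(
                f"heavy atom {self.name} {self.residue_name}{self.residue_id} "
                f"has non-positive vdW radius {self.vdw_radius}"
            )


class StructureModel:
    """An ordered collection of atoms with optional periodic box.

    Provides cached column views (positions, radii, charges, masks) so the
    geometry and electrostatics stages can work on arrays.
    """

    def __init__(self, atoms: Sequence[AtomRecord], box: np.ndarray | None = None):
        self.atoms: list[AtomRecord] = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serial numbers")
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            key = (a.chain, a.residue_id)
            if seen.setdefault(key, a.residue_name) != a.residue_name:
                raise ValueError(
                    f"residue {key} maps to both {seen[key]} and {a.residue_name}"
                )
        self.box = None if box is None else np.asarray(box, dtype=float).reshape(3)
        self._positions: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        if self._positions is None:
            self._positions = np.array([a.position for a in self.atoms], float)
        return self._positions

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], float)

    @property
    def solvent_mask(self) -> np.ndarray:
        return np.array([a.is_solvent for a in self.atoms], bool)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], bool)

    def residue_atoms(self) -> dict[tuple[str, int], list[int]]:
        """Atom indices grouped by (chain, residue_id)."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain, a.residue_id), []).append(i)
        return out


def resolve_residues(
    structure: StructureModel, selectors: Iterable[str]
) -> list[tuple[str, int]]:
    """Resolve residue selector strings to (chain, residue_id) keys.

    Two selector grammars are accepted: ``"chain:resid"`` (e.g. ``"A:329"``)
    and ``"RESNAME+resid"`` (e.g. ``"LYS+329"``, matched in any chain).
    """
    by_key = {}
    for a in structure.atoms:
        by_key.setdefault((a.chain, a.residue_id), a.residue_name)
    resolved: list[tuple[str, int]] = []
    for sel in selectors:
        sel = sel.strip()
        if ":" in sel:
            chain, resid = sel.split(":", 1)
            key = (chain, int(resid))
            if key not in by_key:
                raise KeyError(f"selector {sel!r}: residue {key} not in structure")
            resolved.append(key)
        elif "+" in sel:
            resname, resid_s = sel.split("+", 1)
            resid = int(resid_s)
            hits = [
                k
                for k, rn in by_key.items()
                if k[1] == resid and rn == resname.upper()
            ]
            if not hits:
                raise KeyError(f"selector {sel!r} matches no residue")
            resolved.extend(sorted(hits))
        else:
            raise ValueError(
                f"selector {sel!r}: expected 'chain:resid' or 'RESNAME+resid'"
            )
    return resolved


@dataclass
class Trajectory:
    """Per-frame coordinates for the atoms of one StructureModel.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å.  ``replica_id``
    carries the index of the independent simulation replica the frames
    belong to (simulation campaigns are typically run in triplicate).
    """

    frames: np.ndarray
    frame_interval: float = 1.0  # ns
    replica_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def check_against(self, structure: StructureModel) -> None:
        if self.n_atoms != len(structure):
            raise ValueError(
                f"trajectory has {self.n_atoms} atoms but structure has "
                f"{len(structure)}"
            )


class AssayTrace:
    """A timestamped multi-channel spectroscopy series.

    ``channels`` maps channel names (e.g. ``I405``/``I460`` for pyranine
    fluorescence, ``A588``/``A625`` for oxonol VI absorbance, ``O2`` for an
    oxygraph) to arrays aligned with ``time`` (seconds).  ``metadata``
    carries free-form labels such as the construct name and addition
    events with their timestamps.
    """

    def __init__(
        self,
        time: np.ndarray,
        channels: Mapping[str, np.ndarray],
        sample_interval: float | None = None,
        metadata: dict | None = None,
    ):
        self.time = np.asarray(time, dtype=float)
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in channels.items()}
        for name, arr in self.channels.items():
            if arr.shape != self.time.shape:
                raise ValueError(
                    f"channel {name!r} length {arr.shape} != time length "
                    f"{self.time.shape}"
                )
        if sample_interval is None and len(self.time) > 1:
            sample_interval = float(np.median(np.diff(self.time)))
        self.sample_interval = sample_interval
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.time)

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclass
class LiposomeSpec:
    """Geometry and electrical properties of the proteoliposomes.

    ``specific_capacitance`` is the bilayer capacitance per unit area in
    μF cm⁻²; ``diameter`` in nm.  ``orientation_fraction_n_inside`` is the
    fraction of transporters reconstituted with their proton-uptake (N)
    side facing the liposome interior.
    """

    diameter: float = 100.0  # nm
    specific_capacitance: float = 0.9  # μF cm⁻²
    orientation_fraction_n_inside: float = 0.75

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("liposome diameter must be positive")
        if self.specific_capacitance <= 0:
            raise ValueError("specific capacitance must be positive")
        if not 0.0 <= self.orientation_fraction_n_inside <= 1.0:
            raise ValueError("orientation fraction must lie in [0, 1]")


@dataclass
class ChannelProfile:
    """Per-coordinate quantities along a channel, with replica statistics.

    ``coordinate`` is the arc-length channel coordinate R (Å, N-side = 0).
    Occupancy is the fraction of frames with at least one water oxygen
    within the capture radius of the coordinate point; fields are in V/Å.
    """

    coordinate: np.ndarray
    occupancy: np.ndarray | None = None
    occupancy_sd: np.ndarray | None = None
    field_vector: np.ndarray | None = None  # (n_points, 3), V/Å
    field_magnitude: np.ndarray | None = None
    radius: np.ndarray | None = None
    n_frames: int = 0
    replicas: list = field(default_factory=list)

    def __post_init__(self):
        self.coordinate = np.asarray(self.coordinate, float)
        n = len(self.coordinate)
        for name in ("occupancy", "occupancy_sd", "field_magnitude", "radius"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if v.shape != (n,):
                    raise ValueError(f"{name} length mismatch with coordinate")
                setattr(self, name, v)
        if self.field_vector is not None:
            self.field_vector = np.asarray(self.field_vector, float).reshape(n, 3)
        if self.occupancy is not None:
            occ = self.occupancy
            if np.any((occ < -1e-12) | (occ > 1 + 1e-12)):
                raise ValueError("occupancy must lie in [0, 1]")
        if self.occupancy_sd is not None and np.any(self.occupancy_sd < -1e-12):
            raise ValueError("occupancy_sd must be non-negative")

    @property
    def quantities(self) -> list[str]:
        """Names of the per-point columns that are populated."""
        names = []
        for name in ("occupancy", "occupancy_sd", "field_magnitude", "radius"):
            if getattr(self, name) is not None:
                names.append(name)
        return names
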