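"""File formats, run configuration and the water-model parameter registry.

Interchange formats, all plain text:

* reference paths — multi-model PDB (one MODEL per node) or multi-frame
  XYZ, read and written through MDAnalysis;
* per-replica work tables — TSV with columns ``time_ps, s, z_nm2,
  s_center, work_kjmol``, one file per replica, direction encoded in the
  suffix (``.fwd.tsv`` / ``.bwd.tsv``), with metadata (config hash, seed,
  direction) in ``#`` comment lines;
* summaries — JSON.

Coordinates are stored internally in nm; Å inputs are converted at this
boundary. The registry also ships the force-field parameters of the
common fixed-charge water models, whose kinetic properties dominate the
dissipation of steered protein–ligand simulations.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .path_geometry import Frame, PathGeometryError, ReferencePath
from .steering_work import TrajectoryRecord
from .units import ANGSTROM_PER_NM


class FileFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Water-model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterModelParams:
    """Force-field parameters of a fixed-charge N-point water model.

    Lengths in Å, ϵ in kcal/mol, charges in elementary charge units,
    angle in degrees. 4-point models carry the oxygen–dummy distance
    ``om_bond``; flexible models carry bond/angle force constants
    (kcal/mol/Å² and kcal/mol/rad²).
    """

    name: str
    o_sigma: float
    o_epsilon: float
    o_charge: float
    h_charge: float
    oh_bond: float
    hoh_angle: float
    om_bond: float | None = None
    k_bond: float | None = None
    k_angle: float | None = None

    @property
    def n_points(self) -> int:
        return 4 if self.om_bond is not None else 3

    @property
    def is_flexible(self) -> bool:
        return self.k_bond is not None

    def molecular_charge(self) -> float:
        """Net charge per molecule; zero within the rounding of the
        printed charges (the negative charge sits on the dummy site for
        4-point models, on the oxygen for 3-point ones)."""
        return self.o_charge + 2.0 * self.h_charge


WATER_MODELS: dict[str, WaterModelParams] = {
    m.name: m
    for m in [
        WaterModelParams("TIP3P", 3.15061, 0.1521, -0.834, 0.417, 0.9572, 104.52),
        WaterModelParams(
            "TIP3P/Fw", 3.15061, 0.1521, -0.834, 0.417, 0.9572, 104.52,
            k_bond=529.581, k_angle=50.0,
        ),
        WaterModelParams(
            "OPC3", 3.17427, 0.163406, -0.89517, 0.447585, 0.97888, 109.47
        ),
        WaterModelParams(
            "TIP4P", 3.1565, 0.155, -1.04, 0.52, 0.9572, 104.52, om_bond=0.15
        ),
        WaterModelParams(
            "TIP4P/Fw", 3.1565, 0.155, -1.04, 0.52, 0.9572, 104.52, om_bond=0.15,
            k_bond=103.389, k_angle=2.287,
        ),
        WaterModelParams(
            "OPC", 3.16655, 0.212801, -1.3582, 0.6791, 0.8724, 103.6, om_bond=0.1594
        ),
    ]
}


def water_model_lookup(name: str) -> WaterModelParams:
    """Registry lookup; case-insensitive on the model name."""
    key = name.strip().upper().replace("-FW", "/FW")
    for k, v in WATER_MODELS.items():
        if k.upper() == key:
            return v
    raise KeyError(
        f"unknown water model {name!r}; available: {sorted(WATER_MODELS)}"
    )


def water_registry_checksum() -> str:
    """Stable digest over every registered constant (regression guard)."""
    payload = json.dumps(
        {k: asdict(v) for k, v in sorted(WATER_MODELS.items())}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serialisable configuration of a full steered-estimation run."""

    temperature: float = 300.0           # K
    k_spring: float = 500.0              # kJ/mol per S unit²
    z_wall_at: float = 0.05              # nm²
    k_wall: float = 0.0                  # kJ/mol/nm⁴
    s_start: float = 0.0
    s_end: float = 1.0
    duration: float = 5.0                # ps
    dt: float = 0.005                    # ps
    diffusion: float = 1.0               # unit²/ps
    n_nodes: int = 11
    n_fwd: int = 100
    n_bwd: int = 100
    n_boot: int = 500
    seed: int = 0
    path_file: str | None = None
    unit: str = "nm"
    v_bulk: float | None = None          # Å³
    output_dir: str = "."

    def __post_init__(self) -> None:
        positive = {
            "temperature": self.temperature, "k_spring": self.k_spring,
            "duration": self.duration, "dt": self.dt, "diffusion": self.diffusion,
        }
        for name, v in positive.items():
            if not v > 0:
                raise FileFormatError(f"{name} must be positive, got {v}")
        if self.z_wall_at < 0 or self.k_wall < 0:
            raise FileFormatError("wall parameters must be non-negative")
        if self.unit not in ("nm", "angstrom"):
            raise FileFormatError("unit must be 'nm' or 'angstrom'")
        if self.n_nodes < 2 or self.n_fwd < 1 or self.n_bwd < 1:
            raise FileFormatError("n_nodes >= 2 and replica counts >= 1 required")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Reference-path I/O (multi-model PDB / XYZ via MDAnalysis)
# ---------------------------------------------------------------------------

def _units_scale(unit: str, fmt: str) -> float:
    """File-unit → nm conversion factor. PDB is Å by convention."""
    if fmt == "pdb":
        return 1.0 / ANGSTROM_PER_NM
    if unit == "angstrom":
        return 1.0 / ANGSTROM_PER_NM
    if unit == "nm":
        return 1.0
    raise FileFormatError(f"unknown unit {unit!r}")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise FileFormatError(f"cannot infer format from {path}")


def write_path(
    ref: ReferencePath,
    filename: str | Path,
    fmt: str | None = None,
    unit: str = "nm",
) -> None:
    """Write a reference path as multi-model PDB or multi-frame XYZ."""
    import MDAnalysis as mda

    fmt = _infer_format(filename, fmt)
    scale = 1.0 / _units_scale(unit, fmt)  # nm → file units
    n_atoms = ref.frames[0].n_atoms
    u = mda.Universe.empty(
        n_atoms, n_residues=1, atom_resindex=np.zeros(n_atoms, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(ref.frames[0].atom_ids))
    u.add_TopologyAttr("resnames", ["LIG"])
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("elements", ["C"] * n_atoms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(filename), n_atoms=n_atoms, multiframe=True) as w:
            for frame in ref.frames:
                u.atoms.positions = frame.coords * scale
                w.write(u.atoms)


def read_path(
    filename: str | Path,
    fmt: str | None = None,
    unit: str = "nm",
    align_idx: tuple[int, ...] | None = None,
    cv_idx: tuple[int, ...] | None = None,
) -> ReferencePath:
    """Read a multi-model PDB or multi-frame XYZ file into a ReferencePath.

    ``unit`` declares the length unit of XYZ files (PDB is always Å);
    internal coordinates are nm.
    """
    import MDAnalysis as mda

    fmt = _infer_format(filename, fmt)
    scale = _units_scale(unit, fmt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(filename))
        except Exception as exc:  # MDAnalysis raises various parse errors
            raise FileFormatError(f"cannot parse {filename}: {exc}") from exc
        names = tuple(str(n) for n in u.atoms.names)
        if len(set(names)) != len(names):
            names = tuple(f"{n}_{i}" for i, n in enumerate(names))
        frames = []
        try:
            for ts in u.trajectory:
                if ts.positions.shape[0] != len(names):
                    raise FileFormatError(
                        f"model {ts.frame} has {ts.positions.shape[0]} atoms, "
                        f"expected {len(names)}"
                    )
                frames.append(Frame(ts.positions.astype(float) * scale, names))
        except FileFormatError:
            raise
        except ValueError as exc:  # e.g. atom count changes between models
            raise FileFormatError(f"{filename}: {exc}") from exc
    if len(frames) < 2:
        raise FileFormatError(f"{filename} holds {len(frames)} model(s); need >= 2")
    return ReferencePath(frames=frames, align_idx=align_idx, cv_idx=cv_idx)


# ---------------------------------------------------------------------------
# Work-table TSV dialect
# ---------------------------------------------------------------------------

WORK_TABLE_COLUMNS = ["time_ps", "s", "z_nm2", "s_center", "work_kjmol"]


def write_work_table(
    traj: TrajectoryRecord,
    filename: str | Path,
    config_hash: str = "",
    seed: int | None = None,
) -> None:
    """One replica's steered time series as TSV with metadata comments."""
    df = pd.DataFrame(
        {
            "time_ps": traj.times,
            "s": traj.s_values,
            "z_nm2": traj.z_values,
            "s_center": traj.schedule_values,
            "work_kjmol": traj.cumulative_work,
        }
    )
    header = [
        f"# direction: {traj.direction}",
        f"# config_hash: {config_hash}",
        f"# seed: {seed if seed is not None else ''}",
    ]
    with open(filename, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_work_table(filename: str | Path) -> TrajectoryRecord:
    """Read one replica's work table; direction from metadata or suffix."""
    direction = None
    with open(filename) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "direction:" in line:
                direction = line.split("direction:")[1].strip()
    if direction not in ("forward", "backward"):
        name = str(filename)
        if ".fwd." in name:
            direction = "forward"
        elif ".bwd." in name:
            direction = "backward"
        else:
            raise FileFormatError(
                f"{filename}: direction not found in metadata or filename"
            )
    df = pd.read_csv(filename, sep="\t", comment="#")
    missing = [c for c in WORK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{filename}: missing columns {missing}")
    return TrajectoryRecord(
        times=df["time_ps"].to_numpy(),
        s_values=df["s"].to_numpy(),
        z_values=df["z_nm2"].to_numpy(),
        schedule_values=df["s_center"].to_numpy(),
        cumulative_work=df["work_kjmol"].to_numpy(),
        direction=direction,
    )


def write_pmf_profile(pmf, filename: str | Path) -> None:
    """PMF as TSV: s, f_kjmol, stderr."""
    df = pd.DataFrame(
        {
            "s": pmf.node_s,
            "f_kjmol": pmf.f_values,
            "stderr": pmf.stderr if pmf.stderr is not None else np.nan,
        }
    )
    df.to_csv(filename, sep="\t", index=False)


def read_pmf_profile(filename: str | Path):
    from .estimators import PMFProfile

    df = pd.read_csv(filename, sep="\t", comment="#")
    stderr = df["stderr"].to_numpy() if "stderr" in df else None
    if stderr is not None and np.all(np.isnan(stderr)):
        stderr = None
    return PMFProfile(
        node_s=df["s"].to_numpy(), f_values=df["f_kjmol"].to_numpy(), stderr=stderr
    )


def write_json(data: dict, filename: str | Path) -> None:
    Path(filename).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
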