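"""Readers and writers for the structural and tabular formats of the pipeline.

Covers multi-pose PDBQT (AutoDock Vina / AutoDock 4 dialects), AutoDock DLG
energy records, multi-model PDB trajectories, grid parameter files (GPF), and
tab-separated pose/result tables.

These are deliberately small line-based parsers: the pipeline only needs atom
names, residue identity, coordinates, masses and per-model energies, and it
must report malformed input with exact line/model numbers.  Full chemistry
perception (bonds, CONECT, mmCIF, binary trajectories) is out of scope; an
adapter converting richer topologies into :class:`Atom` lists is the intended
extension point.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Pose",
    "TrajectoryFrame",
    "GridBox",
    "read_pose_pdbqt",
    "write_pose_pdbqt",
    "read_dlg_energies",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "write_gpf",
    "read_gpf",
    "read_pose_table",
    "write_results_table",
    "element_mass",
]

# Average atomic masses (amu) for elements common in protein/ligand systems.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845, "ZN": 65.38,
    "BR": 79.904, "I": 126.904, "SE": 78.971,
}

#: Fallback mass for unrecognised elements; COM weighting must never fail.
DEFAULT_MASS = 12.0

# AutoDock atom types that do not equal their element symbol.
_AD_TYPE_TO_ELEMENT = {
    "A": "C", "OA": "O", "NA": "N", "SA": "S", "HD": "H", "HS": "H",
    "NS": "N", "OS": "O", "CL": "CL", "BR": "BR", "ZN": "ZN", "MG": "MG",
    "MN": "MN", "CA": "CA", "FE": "FE",
}


def element_mass(element: str) -> float:
    """Mass (amu) for an element symbol; unknown symbols fall back to 12 amu
    with a warning so downstream mass weighting stays finite."""
    m = ELEMENT_MASSES.get(element.upper())
    if m is None:
        logger.warning("unknown element %r: assigning mass %.1f amu", element, DEFAULT_MASS)
        return DEFAULT_MASS
    return m


@dataclass(frozen=True)
class Atom:
    """One atom of a receptor, ligand pose, or trajectory frame.

    Coordinates are in Å in the docking frame; ``mass`` is in unified amu.
    """

    name: str
    element: str
    coords: tuple[float, float, float]
    residue_name: str = ""
    residue_number: int = 0
    chain_id: str = ""
    mass: float = DEFAULT_MASS

    def __post_init__(self) -> None:
        if len(self.coords) != 3 or not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.name!r}: coords must be 3 finite numbers, got {self.coords!r}")
        if not self.mass > 0:
            raise ValueError(f"atom {self.name!r}: mass must be positive, got {self.mass}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Pose:
    """One docked ligand conformation with its predicted binding affinity.

    ``affinity`` is in kcal/mol, more negative meaning stronger predicted
    binding; ``None`` flags a model whose energy remark was missing (scoring
    operations reject such poses).
    """

    drug_id: str
    target_id: str
    pose_index: int
    atoms: list[Atom]
    affinity: float | None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"pose {self.drug_id}/{self.target_id}#{self.pose_index}: atoms must be non-empty")
        if self.pose_index < 1:
            raise ValueError(f"pose_index must be >= 1, got {self.pose_index}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class TrajectoryFrame:
    """One frame of an MD trajectory: a time stamp (ns) and an ordered atom
    list whose ordering is identical across all frames of one trajectory."""

    time: float
    atoms: list[Atom]


@dataclass(frozen=True)
class GridBox:
    """Docking grid-box geometry: center, per-axis extent, and grid spacing.

    ``center`` and ``npts_or_size`` are kept in the units the source printed
    (grid-point counts or Å); ``spacing`` is in Å.
    """

    center: tuple[float, float, float]
    npts_or_size: tuple[float, float, float]
    spacing: float = 0.375

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if not all(s > 0 for s in self.npts_or_size):
            raise ValueError(f"grid size components must be positive, got {self.npts_or_size}")


# ---------------------------------------------------------------------------
# PDBQT / PDB
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int, pdbqt: bool) -> Atom:
    # PDB fixed columns: name 13-16, resName 18-20, chainID 22, resSeq 23-26,
    # x/y/z 31-54; PDBQT appends the AutoDock atom type at columns 78-79.
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resnum = int(line[22:26].strip() or 0)
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed coordinate line {lineno}: {line.rstrip()!r}") from exc
    elem = line[76:79].strip().upper() if len(line) > 76 else ""
    if pdbqt and elem:
        elem = _AD_TYPE_TO_ELEMENT.get(elem, elem)
    if not elem:
        # fall back to the leading letter(s) of the atom name
        m = re.match(r"[A-Za-z]+", name)
        cand = (m.group(0) if m else "C").upper()
        elem = cand[:2] if cand[:2] in ELEMENT_MASSES and len(cand) > 1 else cand[:1]
    return Atom(
        name=name, element=elem, coords=(x, y, z),
        residue_name=resname, residue_number=resnum, chain_id=chain,
        mass=element_mass(elem),
    )


# Vina writes "REMARK VINA RESULT: -8.0 ...", AutoDock 4 writes
# "USER    Estimated Free Energy of Binding    =   -8.07 kcal/mol".
_ENERGY_MARKERS = ("VINA RESULT", "Estimated Free Energy of Binding")
_FLOAT_RE = re.compile(r"[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?")


def _energy_from_remark(line: str) -> float | None:
    for marker in _ENERGY_MARKERS:
        idx = line.find(marker)
        if idx >= 0:
            m = _FLOAT_RE.search(line[idx + len(marker):])
            if m:
                return float(m.group(0))
    return None


def read_pose_pdbqt(path: str | Path, drug_id: str | None = None,
                    target_id: str = "") -> list[Pose]:
    """Read a multi-model PDBQT file into a list of :class:`Pose`.

    Models are delimited by MODEL/ENDMDL; ``pose_index`` follows model order
    starting at 1.  Both Vina-style and AutoDock 4-style energy remarks are
    accepted (the first numeric field after the marker is the affinity in
    kcal/mol).  A model with no energy remark yields a pose whose affinity is
    ``None``.  ``drug_id`` defaults to the file stem.
    """
    path = Path(path)
    if drug_id is None:
        drug_id = path.stem
    poses: list[Pose] = []
    atoms: list[Atom] = []
    affinity: float | None = None
    in_model = False
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                n_models += 1
                atoms, affinity = [], None
            elif rec == "ENDMDL":
                poses.append(Pose(drug_id, target_id, n_models, atoms, affinity))
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                if not in_model:  # single-model file without MODEL records
                    in_model = True
                    n_models = 1
                atoms.append(_parse_atom_line(line, lineno, pdbqt=True))
            elif rec in ("REMARK", "USER") and affinity is None:
                affinity = _energy_from_remark(line)
    if in_model and atoms:  # trailing model without ENDMDL
        poses.append(Pose(drug_id, target_id, n_models, atoms, affinity))
    if not poses:
        logger.warning("no poses found in %s", path)
    for p in poses:
        if p.affinity is None:
            logger.warning("pose %s#%d in %s has no energy remark", p.drug_id, p.pose_index, path)
    return poses


def write_pose_pdbqt(poses: Sequence[Pose], path: str | Path) -> None:
    """Write poses as a Vina-style multi-model PDBQT file (round-trips through
    :func:`read_pose_pdbqt`)."""
    lines: list[str] = []
    for i, pose in enumerate(poses, start=1):
        lines.append(f"MODEL {i}")
        if pose.affinity is not None:
            lines.append(f"REMARK VINA RESULT: {pose.affinity:8.3f}      0.000      0.000")
        for j, a in enumerate(pose.atoms, start=1):
            lines.append(
                f"ATOM  {j:5d} {a.name:<4s}{a.residue_name:>4s} {a.chain_id:1s}"
                f"{a.residue_number:4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"  1.00  0.00    +0.000 {a.element:<2s}"
            )
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


def read_multimodel_pdb(path: str | Path, frame_interval: float | None = None) -> list[TrajectoryFrame]:
    """Read a MODEL/ENDMDL-delimited PDB file as trajectory frames.

    Frame times (ns) come from an embedded ``REMARK TIME <ns>`` line when
    present, otherwise from ``frame_interval`` (frame k at k*interval), else
    they default to the frame index.  All models must have identical atom
    counts; a mismatch raises an error naming the offending model.
    """
    path = Path(path)
    frames: list[TrajectoryFrame] = []
    atoms: list[Atom] = []
    t_remark: float | None = None
    in_model = False
    model_no = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, model_no = True, model_no + 1
                atoms, t_remark = [], None
            elif rec == "ENDMDL":
                frames.append(TrajectoryFrame(time=t_remark if t_remark is not None else float("nan"), atoms=atoms))
                in_model = False
            elif rec in ("ATOM", "HETATM") and (in_model or model_no == 0):
                if model_no == 0:
                    in_model, model_no = True, 1
                atoms.append(_parse_atom_line(line, lineno, pdbqt=False))
            elif rec == "REMARK" and "TIME" in line.upper():
                m = _FLOAT_RE.search(line.upper().split("TIME", 1)[1])
                if m:
                    t_remark = float(m.group(0))
    if in_model and atoms:
        frames.append(TrajectoryFrame(time=t_remark if t_remark is not None else float("nan"), atoms=atoms))
    n0 = len(frames[0].atoms) if frames else 0
    for k, fr in enumerate(frames, start=1):
        if len(fr.atoms) != n0:
            raise ValueError(f"model {k}: atom count {len(fr.atoms)} differs from model 1 ({n0})")
        if math.isnan(fr.time):
            fr.time = (k - 1) * frame_interval if frame_interval is not None else float(k - 1)
    return frames


def write_multimodel_pdb(frames: Sequence[TrajectoryFrame], path: str | Path) -> None:
    """Write trajectory frames as a multi-model PDB with TIME remarks."""
    lines: list[str] = []
    for i, fr in enumerate(frames, start=1):
        lines.append(f"MODEL {i:8d}")
        lines.append(f"REMARK   TIME {fr.time:.6f} ns")
        for j, a in enumerate(fr.atoms, start=1):
            lines.append(
                f"ATOM  {j:5d} {a.name:<4s}{a.residue_name:>4s} {a.chain_id:1s}"
                f"{a.residue_number:4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"  1.00  0.00          {a.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# AutoDock DLG
# ---------------------------------------------------------------------------

_RUN_RE = re.compile(r"^(?:DOCKED:\s*)?(?:USER\s+)?Run\s*(?:=|:)?\s*(\d+)", re.IGNORECASE)


def read_dlg_energies(path: str | Path) -> list[tuple[int, float]]:
    """Extract ordered (run_index, free binding energy kcal/mol) records from
    an AutoDock 4 docking log.

    The minimum-energy record identifies the most favourable complex.  A run
    header with no energy line before end of file means the log was truncated;
    the error names the last complete record.
    """
    path = Path(path)
    records: list[tuple[int, float]] = []
    pending_run: int | None = None
    with open(path) as fh:
        for line in fh:
            m = _RUN_RE.match(line.strip())
            if m:
                pending_run = int(m.group(1))
                continue
            if "Estimated Free Energy of Binding" in line:
                fm = _FLOAT_RE.search(line.split("=", 1)[-1])
                if fm:
                    run = pending_run if pending_run is not None else len(records) + 1
                    records.append((run, float(fm.group(0))))
                    pending_run = None
    if pending_run is not None:
        last = f"run {records[-1][0]}" if records else "none"
        raise ValueError(
            f"truncated log {path}: run {pending_run} has no energy record (last complete record: {last})"
        )
    if not records:
        raise ValueError(f"no energy records found in {path}")
    return records


def lowest_energy_run(records: Iterable[tuple[int, float]]) -> tuple[int, float]:
    """The (run_index, energy) pair with the lowest binding energy."""
    return min(records, key=lambda r: r[1])


# ---------------------------------------------------------------------------
# GPF
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    """Format a grid number exactly as provided: integers without a decimal
    point, floats with their significant digits."""
    return f"{v:g}"


def write_gpf(box: GridBox, receptor_name: str) -> str:
    """Render a grid parameter file (GPF) for a receptor's docking box."""
    nx, ny, nz = box.npts_or_size
    cx, cy, cz = box.center
    return (
        f"npts {_fmt(nx)} {_fmt(ny)} {_fmt(nz)}"
        f"                        # num. grid points in xyz\n"
        f"spacing {_fmt(box.spacing)}                          # spacing (A)\n"
        f"receptor {receptor_name}                 # macromolecule\n"
        f"gridcenter {_fmt(cx)} {_fmt(cy)} {_fmt(cz)}"
        f"                  # xyz-coordinates or auto\n"
    )


def read_gpf(text: str) -> GridBox:
    """Parse GPF text back into a :class:`GridBox` (inverse of :func:`write_gpf`)."""
    npts = center = None
    spacing = None
    for line in text.splitlines():
        fields = line.split("#", 1)[0].split()
        if not fields:
            continue
        key = fields[0].lower()
        if key == "npts":
            npts = tuple(float(v) for v in fields[1:4])
        elif key == "spacing":
            spacing = float(fields[1])
        elif key == "gridcenter":
            center = tuple(float(v) for v in fields[1:4])
    if npts is None or center is None or spacing is None:
        raise ValueError("GPF text missing npts, spacing, or gridcenter")
    return GridBox(center=center, npts_or_size=npts, spacing=spacing)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

MANDATORY_POSE_COLUMNS = ("drug_id", "target_id", "pose_index", "affinity")


def read_pose_table(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 TSV pose/feature table.

    Mandatory columns: drug_id, target_id, pose_index, affinity; any further
    columns are carried as feature columns.  A ``-`` cell denotes absent data
    (read as NaN).  A non-numeric affinity raises an error naming the row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["-"], dtype={"drug_id": str, "target_id": str})
    for col in MANDATORY_POSE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"pose table {path}: missing mandatory column {col!r}")
    for row, val in enumerate(df["affinity"]):
        if not (pd.isna(val) or isinstance(val, (int, float))):
            try:
                float(val)
            except (TypeError, ValueError):
                raise ValueError(f"pose table {path}: non-numeric affinity {val!r} in row {row + 1}") from None
    df["affinity"] = pd.to_numeric(df["affinity"])
    df["pose_index"] = df["pose_index"].astype(int)
    return df


def write_results_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a results table as UTF-8 TSV with ``-`` for absent cells and an
    optional ``#`` header comment line (config hash / version stamp)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="-")
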