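"""File formats: multi-frame PDB / XYZ trajectories, matrix and assignment tables.

Human-facing conventions: atom indices and cluster labels are 1-based in
every file written here (PDB convention); the Python API is 0-based.
All tabular outputs embed provenance comment lines (tool version, command
line, seed, input checksum) prefixed with ``#``.
"""

from __future__ import annotations

import hashlib
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .cluster import ClusterAssignment
from .exceptions import FormatError, SemirigidError
from .matrix import STDDVMatrix, SYMMETRY_ATOL
from .trajectory import Trajectory

#: nm per Angstrom.
NM_PER_ANGSTROM = 0.1


def provenance_lines(seed: Optional[int] = None, checksum: Optional[str] = None,
                     extra: Optional[dict] = None) -> list[str]:
    """Comment lines recording how an output file was produced."""
    lines = [
        f"# semirigid {__version__}",
        f"# command: {' '.join(sys.argv)}",
    ]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if checksum is not None:
        lines.append(f"# input_sha256: {checksum}")
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    return lines


def sha256_of_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def matrix_checksum(s: STDDVMatrix) -> str:
    """Checksum of the matrix payload (rounded to the file precision)."""
    rounded = np.round(s.values, 9)
    return hashlib.sha256(rounded.tobytes()).hexdigest()[:16]


# -- trajectories -----------------------------------------------------------

def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "xyz"):
            raise FormatError(f"unknown format tag {fmt!r} (expected pdb or xyz)")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise FormatError(
        f"cannot infer trajectory format from {Path(path).name!r}; "
        "pass format='pdb' or 'xyz'"
    )


def read_trajectory(path, format: Optional[str] = None, selection="CA",
                    xyz_unit: str = "nm") -> Trajectory:
    """Read a multi-frame PDB (MODEL/ENDMDL) or XYZ trajectory.

    PDB coordinates are converted Angstrom -> nm; XYZ files default to nm
    (set ``xyz_unit="angstrom"`` otherwise).  The atom set must be
    identical in every frame.  ``selection`` filters by atom name after
    reading (default ``"CA"``; pass ``None`` to keep everything — XYZ
    files carry element symbols, not PDB atom names, so a ``"CA"``
    selection rarely applies to them).
    """
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        traj = _read_pdb(path)
    else:
        traj = _read_xyz(path, xyz_unit)
    return traj.select(selection)


def _read_pdb(path) -> Trajectory:
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on ragged / malformed models
        raise FormatError(f"failed to parse PDB {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise FormatError(f"PDB file {path} contains no frames or no atoms")
    meta = pd.DataFrame(
        {
            "atom_name": stack.atom_name,
            "res_id": stack.res_id,
            "res_name": stack.res_name,
            "chain_id": stack.chain_id,
        }
    )
    return Trajectory(stack.coord * NM_PER_ANGSTROM, meta)


def _read_xyz(path, unit: str) -> Trajectory:
    if unit not in ("nm", "angstrom"):
        raise FormatError(f"unknown xyz unit {unit!r}")
    scale = 1.0 if unit == "nm" else NM_PER_ANGSTROM
    lines = Path(path).read_text().splitlines()
    frames = []
    names = None
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from exc
        block = lines[pos + 2: pos + 2 + count]
        if len(block) < count:
            raise FormatError(
                f"{path}: frame {frame_no} truncated (expected {count} atoms)"
            )
        syms, coords = [], []
        for off, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: malformed atom line {pos + 3 + off}"
                )
            syms.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if names is None:
            names = syms
        elif syms != names or len(syms) != len(names):
            raise FormatError(
                f"{path}: frame {frame_no} atom set differs from frame 0"
            )
        frames.append(np.array(coords) * scale)
        pos += 2 + count
        frame_no += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    meta = pd.DataFrame(
        {
            "atom_name": names,
            "res_id": np.arange(1, len(names) + 1),
            "res_name": ["UNK"] * len(names),
            "chain_id": ["A"] * len(names),
        }
    )
    return Trajectory(np.stack(frames), meta)


def _to_stack(traj: Trajectory, b_factor: Optional[np.ndarray] = None):
    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords / NM_PER_ANGSTROM
    stack.atom_name = traj.atom_meta["atom_name"].to_numpy(dtype="U6")
    stack.res_id = traj.atom_meta["res_id"].to_numpy(dtype=int)
    stack.res_name = traj.atom_meta["res_name"].to_numpy(dtype="U5")
    stack.chain_id = traj.atom_meta["chain_id"].to_numpy(dtype="U4")
    stack.element = np.array(
        [name.strip()[:1] or "C" for name in stack.atom_name], dtype="U2"
    )
    if b_factor is not None:
        stack.set_annotation("b_factor", np.asarray(b_factor, dtype=float))
    return stack


def write_trajectory(traj: Trajectory, path, format: Optional[str] = None,
                     xyz_unit: str = "nm") -> None:
    """Write a trajectory as multi-frame PDB (Angstrom) or XYZ."""
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        pdb = PDBFile()
        pdb.set_structure(_to_stack(traj))
        pdb.write(str(path))
        return
    scale = 1.0 if xyz_unit == "nm" else 1.0 / NM_PER_ANGSTROM
    names = traj.atom_meta["atom_name"].tolist()
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {t}\n")
            for name, (x, y, z) in zip(names, traj.coords[t] * scale):
                fh.write(f"{name} {x:.9g} {y:.9g} {z:.9g}\n")


# -- matrices ---------------------------------------------------------------

def write_matrix(s: STDDVMatrix, path, labels=None, seed: Optional[int] = None,
                 checksum: Optional[str] = None) -> None:
    """Tab-delimited matrix with a header row/column of atom labels.

    Values are written with 9 significant digits, lossless for the
    precision the package works at.
    """
    n = s.n_atoms
    if labels is None:
        labels = [f"A{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise SemirigidError(f"need {n} labels, got {len(labels)}")
    extra = {}
    if s.n_frames_used is not None:
        extra["n_frames_used"] = s.n_frames_used
    if s.selection_label:
        extra["selection"] = s.selection_label
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, checksum=checksum, extra=extra):
            fh.write(line + "\n")
        fh.write("\t".join(["atom"] + list(labels)) + "\n")
        for i in range(n):
            row = "\t".join(f"{v:.9g}" for v in s.values[i])
            fh.write(f"{labels[i]}\t{row}\n")


def read_matrix(path) -> STDDVMatrix:
    """Read a matrix file written by :func:`write_matrix`.

    Validates squareness (with the offending line number on mismatch),
    symmetry to 1e-8 and a zero diagonal.
    """
    rows = []
    labels = []
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts) - 1} values, "
                    f"expected {len(header)}"
                )
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric value at line {lineno}"
                ) from exc
    if header is None or not rows:
        raise FormatError(f"{path}: no matrix data found")
    values = np.array(rows)
    if values.shape[0] != values.shape[1]:
        raise FormatError(
            f"{path}: matrix is {values.shape[0]} rows by "
            f"{values.shape[1]} columns, expected square"
        )
    if np.abs(values - values.T).max() > SYMMETRY_ATOL:
        raise FormatError(f"{path}: matrix is not symmetric (tolerance 1e-8)")
    if np.abs(np.diag(values)).max() > SYMMETRY_ATOL:
        raise FormatError(f"{path}: matrix diagonal is not zero")
    return STDDVMatrix(values)


# -- assignments ------------------------------------------------------------

def write_assignment(assignment: ClusterAssignment, path,
                     atom_meta: Optional[pd.DataFrame] = None,
                     seed: Optional[int] = None,
                     checksum: Optional[str] = None) -> None:
    """Tab-delimited atom-to-cluster table (1-based indices and labels)."""
    n = assignment.n_atoms
    if atom_meta is not None and len(atom_meta) != n:
        raise SemirigidError("atom_meta length does not match assignment")
    extra = {"n_clust": assignment.n_clust}
    if assignment.q is not None:
        extra["q"] = f"{assignment.q:.9g}"
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, checksum=checksum, extra=extra):
            fh.write(line + "\n")
        fh.write("atom_index\tatom_name\tresidue_id\tchain\tcluster_label\n")
        for i in range(n):
            if atom_meta is not None:
                row = atom_meta.iloc[i]
                name, res, chain = row["atom_name"], row["res_id"], row["chain_id"]
            else:
                name, res, chain = "CA", i + 1, "A"
            fh.write(
                f"{i + 1}\t{name}\t{res}\t{chain}\t{assignment.labels[i] + 1}\n"
            )


def read_assignment(path) -> ClusterAssignment:
    """Read an assignment table written by :func:`write_assignment`."""
    n_clust = None
    q = None
    labels = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                if line.startswith("# n_clust:"):
                    n_clust = int(line.split(":")[1])
                elif line.startswith("# q:"):
                    q = float(line.split(":")[1])
                continue
            if not line or line.startswith("atom_index"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}: malformed assignment row {line!r}")
            labels.append(int(parts[4]) - 1)
    if not labels:
        raise FormatError(f"{path}: no assignment rows found")
    if n_clust is None:
        n_clust = max(labels) + 1
    return ClusterAssignment(np.array(labels), n_clust, q=q)


def write_assignment_pdb(traj: Trajectory, assignment: ClusterAssignment,
                         path, frame: int = 0) -> None:
    """Single-model PDB with cluster labels in the temperature-factor column.

    Molecular viewers can then colour by B-factor to display the domains;
    labels are written 1-based.
    """
    if assignment.n_atoms != traj.n_atoms:
        raise SemirigidError(
            f"assignment covers {assignment.n_atoms} atoms, trajectory frame "
            f"has {traj.n_atoms}"
        )
    single = Trajectory(traj.coords[frame:frame + 1], traj.atom_meta)
    stack = _to_stack(single, b_factor=assignment.labels + 1.0)
    pdb = PDBFile()
    pdb.set_structure(stack)
    remarks = [f"REMARK 999 {line[2:]}" for line in provenance_lines()]
    pdb.lines = remarks + pdb.lines
    pdb.write(str(path))


def read_assignment_pdb(path) -> ClusterAssignment:
    """Recover cluster labels from the B-factor column of a PDB file."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
    labels = np.round(arr.b_factor).astype(int) - 1
    return ClusterAssignment(labels, int(labels.max()) + 1)
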