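"""Structure and trajectory file input/output.

PDB and GRO parsing/writing is delegated to biotite; thin validation layers
add the diagnostics this pipeline guarantees (offending line number for
malformed ATOM records, model index for inconsistent multi-model files,
explicit rejection of triclinic boxes).  Multi-model PDB is the native
trajectory format; other trajectory formats can be plugged in through
:func:`register_trajectory_adapter`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Callable

import numpy as np
import biotite.structure as struc
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from .core import Frame, ParseError, StructureError, Trajectory

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "register_trajectory_adapter",
]

_BOX_ORTHO_TOL = 1e-4


def _box_from_vectors(vectors: np.ndarray | None) -> np.ndarray | None:
    if vectors is None:
        return None
    vectors = np.asarray(vectors, dtype=float)
    off_diag = vectors - np.diag(np.diag(vectors))
    if np.abs(off_diag).max() > _BOX_ORTHO_TOL:
        raise StructureError(
            "triclinic boxes are not supported; only orthorhombic boxes"
        )
    return np.diag(vectors).copy()


def _atom_array_to_frame(arr: struc.AtomArray) -> Frame:
    box = _box_from_vectors(arr.box)
    return Frame(
        atom_names=arr.atom_name.astype(object),
        residue_numbers=arr.res_id,
        residue_names=arr.res_name.astype(object),
        positions=arr.coord,
        segment_ids=arr.chain_id.astype(object),
        box=box,
    )


def _frame_to_atom_array(frame: Frame) -> struc.AtomArray:
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame.positions, dtype=np.float32)
    arr.atom_name = frame.atom_names.astype("U6")
    arr.res_id = frame.residue_numbers
    arr.res_name = frame.residue_names.astype("U5")
    arr.chain_id = frame.segment_ids.astype("U4")
    arr.element = np.array(
        [_guess_element(name) for name in frame.atom_names], dtype="U2"
    )
    arr.hetero = np.isin(frame.residue_names, ["HEM", "HEC", "HOH"])
    if frame.box is not None:
        arr.box = np.diag(frame.box)
    return arr


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in {"FE", "CL", "BR", "NA", "MG", "ZN"} and len(stripped) > 1:
        # Bead names such as NA/NC (heme nitrogens) are nitrogens, not sodium;
        # only report a two-letter element for an unambiguous FE.
        if stripped[:2].upper() == "FE":
            return "FE"
    return stripped[0].upper()


def _validate_pdb_lines(lines: list[str], path: str) -> None:
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
            raise ParseError(
                f"{path}: truncated ATOM/HETATM record at line {lineno}"
            )


def read_structure(path, fmt: str | None = None) -> Frame:
    """Read a single-frame PDB or GRO file into a :class:`Frame`.

    ``fmt`` may be ``"pdb"`` or ``"gro"``; when omitted it is inferred from
    the file suffix.  Coordinates are returned in angstrom (GRO nanometres
    are converted), residue numbers and atom names verbatim from the file.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        text = path.read_text()
        lines = text.splitlines()
        _validate_pdb_lines(lines, str(path))
        try:
            pdb = PDBFile.read(_io.StringIO(text))
            arr = pdb.get_structure(model=1)
        except Exception as exc:  # pragma: no cover - biotite message passthrough
            raise ParseError(f"{path}: {exc}") from exc
    elif fmt == "gro":
        try:
            gro = GROFile.read(str(path))
            arr = gro.get_structure(model=1)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
    else:
        raise ParseError(f"unsupported structure format: {fmt!r}")
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no atoms")
    return _atom_array_to_frame(arr)


_TRAJECTORY_ADAPTERS: dict[str, Callable[..., Trajectory]] = {}


def register_trajectory_adapter(fmt: str, reader: Callable[..., Trajectory]) -> None:
    """Register a reader for an additional trajectory format (e.g. XTC/DCD).

    The reader receives the path and keyword arguments of
    :func:`read_trajectory` and must return a :class:`Trajectory`.  Core
    correctness of this package is certified on multi-model PDB; adapters are
    an optional integration point for binary formats.
    """
    _TRAJECTORY_ADAPTERS[fmt.lower()] = reader


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a trajectory; natively multi-model PDB, else a registered adapter.

    Frames are returned in file order; the frame count equals the model
    count.  All models must share the particle ordering: a mismatch raises
    :class:`StructureError` naming the 1-based model index.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in _TRAJECTORY_ADAPTERS:
        return _TRAJECTORY_ADAPTERS[fmt](path)
    if fmt != "pdb":
        raise ParseError(
            f"unsupported trajectory format {fmt!r}; register an adapter or "
            "provide multi-model PDB"
        )
    text = path.read_text()
    lines = text.splitlines()
    _validate_pdb_lines(lines, str(path))
    _check_model_consistency(lines, str(path))
    pdb = PDBFile.read(_io.StringIO(text))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise StructureError(f"{path}: no frames")
    box = _box_from_vectors(stack.box[0] if stack.box is not None else None)
    return Trajectory(
        atom_names=stack.atom_name.astype(object),
        residue_numbers=stack.res_id,
        residue_names=stack.res_name.astype(object),
        coordinates=np.asarray(stack.coord, dtype=float),
        segment_ids=stack.chain_id.astype(object),
        box=box,
    )


def _check_model_consistency(lines: list[str], path: str) -> None:
    counts: list[int] = []
    current: int | None = None
    saw_model = False
    for line in lines:
        if line.startswith("MODEL"):
            saw_model = True
            current = 0
        elif line.startswith("ENDMDL"):
            counts.append(current or 0)
            current = None
        elif line.startswith(("ATOM", "HETATM")):
            if current is None:
                if saw_model:
                    continue
                current = 0
                saw_model = False
            current += 1
    if current is not None and not saw_model:
        counts.append(current)
    if not counts or sum(counts) == 0:
        raise StructureError(f"{path}: no frames")
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise StructureError(
                f"{path}: atom count mismatch in model {i}: {c} != {counts[0]}"
            )


def write_structure(frame: Frame, path, fmt: str | None = None) -> None:
    """Write one frame as PDB or GRO (format inferred from suffix)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    arr = _frame_to_atom_array(frame)
    if fmt == "pdb":
        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    elif fmt == "gro":
        f = GROFile()
        f.set_structure(arr)
        f.lines[0] = "membpos frame"  # fixed title keeps output reproducible
        f.write(str(path))
    else:
        raise ParseError(f"unsupported structure format: {fmt!r}")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB."""
    arr = _frame_to_atom_array(traj.frame(0))
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coordinates, dtype=np.float32)
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(Path(path)))
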