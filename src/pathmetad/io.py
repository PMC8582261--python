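"""Reading and writing of structures and trajectories.

Supported formats: standard PDB (single- and multi-model; fixed columns,
first altloc kept, insertion codes ignored, HETATM excluded by default) and
XYZ.  A writer for reference paths emits the PLUMED-dialect path PDB (one
MODEL per frame, occupancy column = alignment weights, B-factor column =
displacement weights).

PDB parsing itself is delegated to biotite; a light pre-validation pass over
the raw lines produces the error diagnostics (line numbers, model names)
that the library's own exceptions do not carry.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .core import Structure, Trajectory
from .errors import FormatError, ParseError

__all__ = ["read_structure", "write_structure", "write_path_pdb", "read_xyz", "write_xyz"]


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        return format.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "ent"):
        return "pdb"
    if ext == "xyz":
        return "xyz"
    raise FormatError(f"cannot infer format from extension of '{path}'")


def _prevalidate_pdb(lines: Sequence[str]) -> None:
    """Check coordinate fields and per-model atom counts on raw PDB text."""
    model = 0
    counts: dict[int, int] = {}
    in_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            model += 1
            in_model = True
            counts.setdefault(model, 0)
        elif rec == "ENDMDL":
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"line {lineno}: truncated {rec} record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed coordinate field in {rec} record"
                ) from None
            key = model if (in_model or model > 0) else 0
            counts[key] = counts.get(key, 0) + 1
    if len(counts) > 1:
        ref_model, ref = next(iter(counts.items()))
        for m, c in counts.items():
            if c != ref:
                raise FormatError(
                    f"MODEL {m} has {c} atoms but MODEL {ref_model} has {ref}"
                )


def _structure_from_atom_array(arr: struc.AtomArray) -> Structure:
    return Structure(
        coords=np.asarray(arr.coord, dtype=float),
        atom_names=arr.atom_name.astype(object),
        residue_ids=np.asarray(arr.res_id, dtype=int),
        residue_names=arr.res_name.astype(object),
        elements=arr.element.astype(object),
        chain_ids=arr.chain_id.astype(object),
    )


def read_structure(path: str, format: str | None = None, include_hetatm: bool = False):
    """Read a PDB or XYZ file into a :class:`Structure` or :class:`Trajectory`.

    Multi-model PDB files (one MODEL/ENDMDL block per frame) and multi-frame
    XYZ files yield a :class:`Trajectory`; a single model yields a
    :class:`Structure`.  Coordinates are in angstrom.

    Raises
    ------
    ParseError
        On a malformed record, with the line number.
    FormatError
        When models disagree in atom count, naming the model.
    """
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return read_xyz(path)
    with open(path) as fh:
        lines = fh.readlines()
    _prevalidate_pdb(lines)
    pdb_file = pdbio.PDBFile.read(path)
    try:
        stack = pdb_file.get_structure(altloc="first")
    except Exception as exc:  # pragma: no cover - caught by prevalidation normally
        raise ParseError(f"PDB parsing failed for '{path}': {exc}") from exc
    if not include_hetatm:
        stack = stack[..., ~stack.hetero]
    if stack.array_length() == 0:
        raise FormatError(f"'{path}' contains no (non-HETATM) atoms")
    if stack.stack_depth() == 1:
        return _structure_from_atom_array(stack[0])
    return Trajectory([_structure_from_atom_array(stack[i]) for i in range(stack.stack_depth())])


def _to_atom_array(s: Structure) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = s.chain_ids.astype("U4")
    arr.res_id = s.residue_ids
    arr.res_name = s.residue_names.astype("U5")
    arr.atom_name = s.atom_names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def write_structure(path: str, obj, format: str | None = None) -> None:
    """Write a Structure or Trajectory as PDB or XYZ."""
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        write_xyz(path, obj)
        return
    pdb_file = pdbio.PDBFile()
    if isinstance(obj, Trajectory):
        arrays = [_to_atom_array(f) for f in obj]
        stack = struc.stack(arrays)
        pdb_file.set_structure(stack)
    else:
        pdb_file.set_structure(_to_atom_array(obj))
    pdb_file.write(path)


def read_xyz(path: str):
    """Read single- or multi-frame XYZ; elements become atom names."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count in XYZ file") from None
        if i + 1 + n >= len(lines) + 1:
            raise ParseError(f"line {i + 1}: XYZ frame declares {n} atoms but file ends early")
        coords = np.empty((n, 3))
        elements = np.empty(n, dtype=object)
        for k in range(n):
            lineno = i + 2 + k
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"line {lineno + 1}: malformed XYZ atom line")
            elements[k] = parts[0]
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {lineno + 1}: malformed XYZ coordinate") from None
        frames.append(Structure(coords, atom_names=elements.copy(), elements=elements))
        i += 2 + n
    if not frames:
        raise FormatError(f"'{path}' contains no XYZ frames")
    if len(frames) == 1:
        return frames[0]
    return Trajectory(frames)


def write_xyz(path: str, obj) -> None:
    frames = list(obj) if isinstance(obj, Trajectory) else [obj]
    with open(path, "w") as fh:
        for idx, f in enumerate(frames):
            fh.write(f"{f.n_atoms}\n")
            fh.write(f"frame {idx}\n")
            for el, (x, y, z) in zip(f.elements, f.coords):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def _pdb_atom_line(serial, name, res_name, chain, res_id, xyz, occ, bfac, element):
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{res_name:>3s} {chain:1s}"
        f"{res_id:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{bfac:6.2f}          {element:>2s}\n"
    )


def write_path_pdb(
    path: str,
    trajectory: Trajectory,
    align_weights: np.ndarray | None = None,
    displace_weights: np.ndarray | None = None,
) -> None:
    """Write a reference path as a PLUMED-dialect multi-model PDB.

    One MODEL per path frame; the occupancy column holds per-atom alignment
    weights and the B-factor column per-atom displacement weights (both
    default to 1.0), the convention expected by PLUMED's path CV readers.
    """
    n = trajectory.n_atoms
    aw = np.ones(n) if align_weights is None else np.asarray(align_weights, dtype=float)
    dw = np.ones(n) if displace_weights is None else np.asarray(displace_weights, dtype=float)
    if aw.shape != (n,) or dw.shape != (n,):
        raise FormatError("weight arrays must have one entry per atom")
    t = trajectory.template
    with open(path, "w") as fh:
        fh.write("REMARK  path reference frames (occupancy=align, bfactor=displace)\n")
        for m in range(len(trajectory)):
            fh.write(f"MODEL     {m + 1:>4d}\n")
            for k in range(n):
                fh.write(
                    _pdb_atom_line(
                        k + 1,
                        str(t.atom_names[k]),
                        str(t.residue_names[k]),
                        str(t.chain_ids[k])[:1] or "A",
                        int(t.residue_ids[k]),
                        trajectory.coords[m, k],
                        aw[k],
                        dw[k],
                        str(t.elements[k]),
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
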