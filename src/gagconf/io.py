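"""Ensemble readers and writers.

Multi-model PDB is handled through biotite's AtomArrayStack; XYZ uses a
bespoke writer/reader with optional extra columns (atom name, residue
index, residue class) after the coordinates, so round trips of this
package's own files are lossless while plain three-column XYZ still reads.
Coordinates are Å at every boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .structure import Ensemble, Structure, TopologyError, mass_of

# residue class <-> PDB residue code; extensible by callers. SGN and IDS are
# the wwPDB chemical components for N,6-di-O-sulfo-glucosamine and 2-O-sulfo
# iduronic acid (the heparin repeat).
RESIDUE_CODES: dict[str, str] = {
    "GlcNS(6S)": "SGN",
    "IdoA(2S)": "IDS",
    "pyranose": "PYR",
}


class ParseError(ValueError):
    """Raised when an input file cannot be read completely and consistently."""


def _codes_inverse(codes: dict[str, str]) -> dict[str, str]:
    return {v: k for k, v in codes.items()}


def detect_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise ParseError(f"cannot infer format from suffix {suffix!r}")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def write_pdb(ensemble: Ensemble, path: str | Path,
              residue_codes: Optional[dict[str, str]] = None) -> None:
    codes = {**RESIDUE_CODES, **(residue_codes or {})}
    top = ensemble.topology
    n = top.n_atoms
    array = bst.AtomArray(n)
    array.coord = np.zeros((n, 3), dtype=np.float32)
    array.set_annotation("atom_name", np.array(top.atom_names))
    array.set_annotation("element", np.array([e.upper() for e in top.elements]))
    array.set_annotation("res_id", top.residue_indices.astype(int))
    array.set_annotation(
        "res_name",
        np.array([codes.get(t, t[:3].upper()) for t in top.residue_types]),
    )
    array.set_annotation("chain_id", np.array(["A"] * n))
    array.set_annotation("hetero", np.ones(n, dtype=bool))
    stack = bst.stack([array] * ensemble.n_frames)
    stack.coord = ensemble.coordinates.astype(np.float32)
    f = bpdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb(path: str | Path, frame_spacing_ps: float = 100.0,
             residue_codes: Optional[dict[str, str]] = None) -> Ensemble:
    codes = _codes_inverse({**RESIDUE_CODES, **(residue_codes or {})})
    try:
        f = bpdb.PDBFile.read(str(path))
        n_models = f.get_model_count()
        stack = f.get_structure(model=None)
    except Exception as exc:
        raise ParseError(f"failed to parse PDB file {path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    if stack.stack_depth() != n_models:
        raise ParseError(
            f"{path}: inconsistent model count ({stack.stack_depth()} vs {n_models})"
        )
    names = list(stack.atom_name)
    elements = list(stack.element)
    res_idx = np.asarray(stack.res_id, dtype=int)
    res_names = [codes.get(r, r) for r in stack.res_name]
    try:
        masses = np.array(
            [mass_of(n_, e) for n_, e in zip(names, elements)]
        )
    except TopologyError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    topology = Structure(
        atom_names=names,
        elements=elements,
        masses=masses,
        residue_indices=res_idx,
        residue_types=res_names,
        positions=np.asarray(stack.coord[0], dtype=float),
    )
    return Ensemble(
        topology, np.asarray(stack.coord, dtype=float), frame_spacing_ps
    )


# ---------------------------------------------------------------------------
# XYZ (extended)
# ---------------------------------------------------------------------------


def write_xyz(ensemble: Ensemble, path: str | Path) -> None:
    top = ensemble.topology
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(
                f"frame {f} spacing_ps {ensemble.frame_spacing_ps}\n"
            )
            for i in range(top.n_atoms):
                x, y, z = ensemble.coordinates[f, i]
                fh.write(
                    f"{top.elements[i]:<2s} {x:15.6f} {y:15.6f} {z:15.6f} "
                    f"{top.atom_names[i]} {int(top.residue_indices[i])} "
                    f"{top.residue_types[i]}\n"
                )


def read_xyz(path: str | Path, frame_spacing_ps: float = 100.0) -> Ensemble:
    lines = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if lines[pos].strip() == "":
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from exc
        if pos + 1 + n >= len(lines) + 1 and pos + 2 + n > len(lines):
            raise ParseError(
                f"{path}: truncated frame {frame_no} "
                f"(expected {n} atoms, file ends early)"
            )
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise ParseError(
                f"{path}: truncated frame {frame_no} "
                f"(expected {n} atoms, got {len(body)})"
            )
        names, elements, ridx, rtypes, coords = [], [], [], [], []
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: malformed atom line {pos + 3 + k}"
                )
            elements.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            if len(parts) >= 7:
                names.append(parts[4])
                ridx.append(int(parts[5]))
                rtypes.append(parts[6])
            else:
                names.append(f"{parts[0]}{k + 1}")
                ridx.append(1)
                rtypes.append("UNK")
        masses = np.array(
            [mass_of(n_, e) for n_, e in zip(names, elements)]
        )
        frames.append(
            Structure(
                atom_names=names,
                elements=elements,
                masses=masses,
                residue_indices=np.array(ridx),
                residue_types=rtypes,
                positions=np.array(coords),
            )
        )
        pos += 2 + n
        frame_no += 1
    if not frames:
        raise ParseError(f"{path}: no frames found")
    try:
        return Ensemble.from_structures(frames, frame_spacing_ps)
    except TopologyError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def write_ensemble(
    ensemble: Ensemble, path: str | Path, format: Optional[str] = None
) -> None:
    fmt = format or detect_format(path)
    if fmt == "pdb":
        write_pdb(ensemble, path)
    elif fmt == "xyz":
        write_xyz(ensemble, path)
    else:
        raise ParseError(f"unsupported format {fmt!r}")


def read_ensemble(
    path: str | Path,
    format: Optional[str] = None,
    frame_spacing_ps: float = 100.0,
) -> Ensemble:
    fmt = format or detect_format(path)
    if fmt == "pdb":
        return read_pdb(path, frame_spacing_ps)
    if fmt == "xyz":
        return read_xyz(path, frame_spacing_ps)
    raise ParseError(f"unsupported format {fmt!r}")
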