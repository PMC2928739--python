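"""Reading and writing structures, trajectories and result tables.

Two trajectory sources are supported: multi-model PDB files (parsed with
biotite) and a plain-text frame table, one row per frame with ``chain:resnum:x``
/ ``:y`` / ``:z`` columns — the package's own exchange format, convenient for
synthetic trajectories and round-trip tests.  Result matrices and series go
out as CSV/TSV with ``chain:resnum`` labels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .core import Residue, Topology, Trajectory

__all__ = [
    "read_reference_structure",
    "read_trajectory",
    "topology_from_frame_table",
    "write_frame_table",
    "write_results",
    "read_results",
    "write_structures_pdb",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"  # lossless at 9 significant digits with margin


def _atoms_to_topology(atoms: struc.AtomArray) -> tuple[Topology, np.ndarray]:
    """Extract one Cα per residue, in file order.

    Residues without a Cα are skipped with a warning; duplicate
    (chain, residue number) pairs after altloc resolution are an error, as
    are insertion codes (they would make author numbering ambiguous).
    """
    if "ins_code" in atoms.get_annotation_categories():
        ins = atoms.ins_code
        if np.any(ins != ""):
            raise ValueError("insertion codes are not supported")
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    skipped = 0
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for lo, hi in zip(starts[:-1], starts[1:]):
        sub = atoms[lo:hi]
        key = (str(sub.chain_id[0]), int(sub.res_id[0]))
        ca = sub[sub.atom_name == "CA"]
        if len(ca) == 0:
            logger.warning("residue %s:%d has no CA atom; skipped", *key)
            skipped += 1
            continue
        if len(ca) > 1 or key in seen:
            raise ValueError(f"duplicate residue {key[0]}:{key[1]} in PDB file")
        seen.add(key)
        residues.append(Residue(key[0], key[1], str(ca.res_name[0])))
        coords.append(np.asarray(ca.coord[0], dtype=np.float64))
    if not residues:
        raise ValueError("no residues with CA atoms found")
    if skipped:
        logger.warning("%d residue(s) without CA were skipped", skipped)
    return Topology(residues), np.asarray(coords)


def read_reference_structure(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read a single-model PDB into a topology and one frame of Cα coordinates.

    Alternate locations are resolved to the highest-occupancy conformer
    (first listed on ties).
    """
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    return _atoms_to_topology(atoms)


def _frame_table_columns(topology: Topology) -> list[str]:
    cols = []
    for r in topology.residues:
        cols.extend(f"{r.label}:{ax}" for ax in "xyz")
    return cols


def write_frame_table(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as the delimited frame-table text format."""
    cols = _frame_table_columns(traj.topology)
    flat = traj.coordinates.reshape(traj.n_frames, -1)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "time_ns", traj.frame_times)
    with open(path, "w") as fh:
        fh.write(f"# equilibration_end_ns={traj.equilibration_end!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def topology_from_frame_table(path: str | Path) -> Topology:
    """Recover the residue topology from a frame-table header."""
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            line = fh.readline()
    residues = []
    seen = set()
    for col in line.strip().split(","):
        parts = col.split(":")
        if len(parts) != 3 or parts[2] not in "xyz":
            continue
        key = (parts[0], int(parts[1]))
        if key not in seen:
            seen.add(key)
            residues.append(Residue(key[0], key[1]))
    if not residues:
        raise ValueError(f"{path}: no residue columns found in header")
    return Topology(residues)


def _read_frame_table(
    path: Path, topology: Topology
) -> tuple[np.ndarray, np.ndarray | None, float]:
    equil = 0.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# equilibration_end_ns="):
        equil = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    times = df.pop("time_ns").to_numpy() if "time_ns" in df.columns else None
    n = len(topology)
    coords = np.empty((len(df), n, 3))
    for i, res in enumerate(topology.residues):
        for k, ax in enumerate("xyz"):
            col = f"{res.label}:{ax}"
            if col not in df.columns:
                raise ValueError(f"frame table is missing residue {res.label}")
            coords[:, i, k] = df[col].to_numpy()
    return coords, times, equil


def _read_multimodel_pdb(path: Path, topology: Topology) -> np.ndarray:
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no models found")
    frames = np.empty((n_models, len(topology), 3))
    for m in range(1, n_models + 1):
        atoms = pdb_file.get_structure(model=m, altloc="occupancy")
        ca = atoms[atoms.atom_name == "CA"]
        index = {
            (str(c), int(r)): j
            for j, (c, r) in enumerate(zip(ca.chain_id, ca.res_id))
        }
        for i, res in enumerate(topology.residues):
            j = index.get((res.chain_id, res.number))
            if j is None:
                raise ValueError(
                    f"frame {m}: residue {res.label} missing from trajectory"
                )
            frames[m - 1, i] = ca.coord[j]
    return frames


def read_trajectory(
    path: str | Path,
    topology: Topology,
    stride: int = 1,
    frame_interval_ns: float = 1.0,
    equilibration_end: float = 0.0,
) -> Trajectory:
    """Read a multi-model PDB or frame-table file against a known topology.

    Frames are decimated by ``stride``; times are assigned as the 1-based
    original frame index times ``frame_interval_ns``, so striding widens the
    spacing without re-timing the surviving frames.  A frame-table file's
    stored times and equilibration marker are honoured when present (unless
    an explicit ``equilibration_end`` is given).
    """
    path = Path(path)
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    if frame_interval_ns <= 0:
        raise ValueError("frame_interval_ns must be positive")
    stored_times = None
    if _looks_like_pdb(path):
        coords = _read_multimodel_pdb(path, topology)
        stored_equil = 0.0
    else:
        coords, stored_times, stored_equil = _read_frame_table(path, topology)
    if coords.shape[0] == 0:
        raise ValueError(f"{path}: empty trajectory")
    keep = np.arange(0, coords.shape[0], stride)
    coords = coords[keep]
    if stored_times is not None:
        times = stored_times[keep]
    else:
        times = (keep + 1) * frame_interval_ns
    equil = equilibration_end if equilibration_end > 0 else stored_equil
    return Trajectory(topology, coords, times, equil)


def _looks_like_pdb(path: Path) -> bool:
    if path.suffix.lower() in {".pdb", ".ent"}:
        return True
    with open(path) as fh:
        head = fh.readline()
    return head[:6].strip() in {"HEADER", "MODEL", "ATOM", "REMARK", "CRYST1", "TITLE"}


def write_results(
    data: pd.DataFrame | np.ndarray,
    path: str | Path,
    fmt: str = "csv",
    labels: list[str] | None = None,
) -> None:
    """Write a labelled matrix or series as CSV/TSV.

    Arrays get ``chain:resnum`` labels from ``labels``; values round-trip
    losslessly at 9 significant digits.
    """
    if fmt not in {"csv", "tsv"}:
        raise ValueError(f"unknown format {fmt!r}")
    if isinstance(data, np.ndarray):
        if data.size == 0:
            raise ValueError("refusing to write an empty result")
        if data.ndim == 1:
            df = pd.DataFrame({"value": data}, index=labels)
        elif data.ndim == 2:
            df = pd.DataFrame(data, index=labels, columns=labels)
        else:
            raise ValueError("only 1-D series and 2-D matrices are supported")
    else:
        df = data
        if df.size == 0:
            raise ValueError("refusing to write an empty result")
    sep = "," if fmt == "csv" else "\t"
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def read_results(path: str | Path, fmt: str = "csv") -> pd.DataFrame:
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def write_structures_pdb(
    topology: Topology,
    frames: np.ndarray,
    path: str | Path,
) -> None:
    """Write one or more Cα frames as a (multi-)model PDB file."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    n = len(topology)
    template = struc.AtomArray(n)
    template.chain_id = np.array([r.chain_id for r in topology.residues])
    template.res_id = np.array([r.number for r in topology.residues])
    template.res_name = np.array([r.name for r in topology.residues])
    template.atom_name = np.full(n, "CA")
    template.element = np.full(n, "C")
    stack = struc.stack(
        [_with_coord(template, f) for f in frames]
    )
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _with_coord(template: struc.AtomArray, coord: np.ndarray) -> struc.AtomArray:
    arr = template.copy()
    arr.coord = np.asarray(coord, dtype=np.float32)
    return arr
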