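"""Readers and writers for the delimited-text and structure formats.

Instrument-like data (kinetic traces, activity courses, thermograms) travel
as two-column delimited text with ``# key = value`` metadata header lines.
Structures and trajectories use PDB (single- or multi-MODEL, via biotite)
or a plain multi-frame XYZ format.  Readers resolve units explicitly
(temperatures given in deg C are converted to kelvin where the analysis
works in kelvin) and refuse ambiguous input rather than guessing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdb

from .dsc import Thermogram
from .flashkin import KineticTrace
from .inactivation import ActivitySeries, KELVIN_OFFSET
from .trajstat import Structure, Trajectory

COSOLVENT_RES_NAMES = ("SUC", "COS")
_FALLBACK_VDW = 1.7  # angstrom, used when the element has no tabulated radius


# ---------------------------------------------------------------------------
# delimited text


def _read_columns(path: str | Path) -> tuple[dict, np.ndarray, np.ndarray]:
    meta: dict = {}
    xs, ys = [], []
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected two numeric columns, got {line!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric value in {line!r}") from exc
    if not xs:
        raise ValueError(f"{path}: no data rows")
    x = np.asarray(xs)
    if not np.all(np.diff(x) > 0):
        bad = int(np.nonzero(np.diff(x) <= 0)[0][0]) + 2
        raise ValueError(f"{path}: abscissa not strictly increasing at data row {bad}")
    return meta, x, np.asarray(ys)


def _write_columns(
    path: str | Path, meta: dict, x: np.ndarray, y: np.ndarray, fmt: str = "%.10g"
) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        for a, b in zip(x, y):
            fh.write((fmt % a) + "\t" + (fmt % b) + "\n")


def read_trace(path: str | Path) -> KineticTrace:
    """Read a kinetic trace: columns time_s, intensity."""
    meta, t, y = _read_columns(path)
    temp = float(meta["temperature_C"]) if "temperature_C" in meta else None
    return KineticTrace(times=t, intensities=y, temperature=temp, solvent=meta.get("solvent"))


def write_trace(path: str | Path, trace: KineticTrace) -> None:
    meta = {"columns": "time_s intensity"}
    if trace.temperature is not None:
        meta["temperature_C"] = trace.temperature
    if trace.solvent is not None:
        meta["solvent"] = trace.solvent
    _write_columns(path, meta, trace.times, trace.intensities)


def read_series(path: str | Path) -> ActivitySeries:
    """Read a remaining-activity course: columns time_min, R_percent."""
    meta, t, r = _read_columns(path)
    temp = float(meta["temperature_C"]) if "temperature_C" in meta else None
    return ActivitySeries(times=t, R=r, temperature=temp, solvent=meta.get("solvent"))


def write_series(path: str | Path, series: ActivitySeries) -> None:
    meta = {"columns": "time_min R_percent"}
    if series.temperature is not None:
        meta["temperature_C"] = series.temperature
    if series.solvent is not None:
        meta["solvent"] = series.solvent
    _write_columns(path, meta, series.times, series.R)


def read_thermogram(path: str | Path) -> Thermogram:
    """Read a thermogram: columns temperature, heat capacity.

    The header must state ``temperature_unit`` (K or C) and ``units``
    (molar or specific); temperatures in deg C are converted to kelvin.
    """
    meta, T, cp = _read_columns(path)
    if "temperature_unit" not in meta:
        raise ValueError(f"{path}: header lacks temperature_unit (K or C)")
    unit = meta["temperature_unit"]
    if unit == "C":
        T = T + KELVIN_OFFSET
    elif unit != "K":
        raise ValueError(f"{path}: unknown temperature_unit {unit!r}")
    units = meta.get("units", "molar")
    extra = {
        k: float(meta[k])
        for k in ("scan_rate_K_min", "concentration_mg_ml", "mw_da", "psv_cm3_g")
        if k in meta
    }
    return Thermogram(T=T, Cp=cp, units=units, meta=extra)


def write_thermogram(path: str | Path, tg: Thermogram) -> None:
    meta = {
        "columns": "temperature_K Cp",
        "temperature_unit": "K",
        "units": tg.units,
    }
    for key, val in tg.meta.items():
        if isinstance(val, (int, float)):
            meta[key] = val
    _write_columns(path, meta, tg.T, tg.Cp)


# ---------------------------------------------------------------------------
# structures and trajectories


def _structure_from_atom_array(arr: struc.AtomArray) -> Structure:
    radii = np.array(
        [struc_info.vdw_radius_single(e) or _FALLBACK_VDW for e in arr.element]
    )
    masses = np.array([struc_info.mass(e) for e in arr.element])
    return Structure(
        name=arr.atom_name.copy(),
        element=arr.element.copy(),
        res_id=arr.res_id.copy(),
        res_name=arr.res_name.copy(),
        chain_id=arr.chain_id.copy(),
        coords=arr.coord.copy(),
        mass=masses,
        radius=radii,
    )


def _atom_array_from_structure(s: Structure, coords: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = s.name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.res_id = s.res_id.astype(int)
    arr.res_name = s.res_name.astype("U5")
    arr.chain_id = s.chain_id.astype("U4")
    return arr


def read_structure(path: str | Path) -> Structure:
    """Read a single-model PDB file (cosolvent residues included as atoms)."""
    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    return _structure_from_atom_array(arr)


def read_trajectory_pdb(
    path: str | Path,
    cosolvent_res_names: tuple[str, ...] = COSOLVENT_RES_NAMES,
    box: float | None = None,
) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory.

    Atoms whose residue name is in ``cosolvent_res_names`` are split off into
    the per-frame cosolvent coordinate set, grouped by residue id.
    """
    stack = pdb.PDBFile.read(str(path)).get_structure()
    first = stack[0]
    cos_mask = np.isin(first.res_name, cosolvent_res_names)
    solute = _structure_from_atom_array(first[~cos_mask])
    frames = stack.coord[:, ~cos_mask, :].astype(float)
    cosolvent = cosolvent_mol = None
    if cos_mask.any():
        cosolvent = stack.coord[:, cos_mask, :].astype(float)
        cosolvent_mol = first.res_id[cos_mask].copy()
    return Trajectory(
        reference=solute,
        frames=frames,
        frame_times=np.arange(frames.shape[0], dtype=float),
        cosolvent=cosolvent,
        cosolvent_mol=cosolvent_mol,
        box=box,
    )


def write_trajectory_pdb(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory (solute + optional cosolvent) as multi-MODEL PDB."""
    s = traj.reference
    arrays = []
    for i in range(traj.n_frames):
        arr = _atom_array_from_structure(s, traj.frames[i])
        if traj.cosolvent is not None:
            n_cos = traj.cosolvent.shape[1]
            cos = struc.AtomArray(n_cos)
            cos.coord = traj.cosolvent[i].astype(np.float32)
            cos.atom_name = np.full(n_cos, "C1")
            cos.element = np.full(n_cos, "C")
            cos.res_id = np.asarray(traj.cosolvent_mol, dtype=int) + int(s.res_id.max()) + 1
            cos.res_name = np.full(n_cos, COSOLVENT_RES_NAMES[0])
            cos.chain_id = np.full(n_cos, "X")
            cos.hetero = np.ones(n_cos, dtype=bool)
            arr = arr + cos
        arrays.append(arr)
    f = pdb.PDBFile()
    f.set_structure(struc.stack(arrays))
    f.write(str(path))


def read_xyz_frames(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a multi-frame XYZ file -> (atom labels, (n_frames, n_atoms, 3))."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    frames, labels = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected an atom count") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{i + 1}: truncated frame")
        frame_labels = [row.split()[0] for row in block]
        coords = np.array([[float(v) for v in row.split()[1:4]] for row in block])
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise ValueError(f"{path}: inconsistent atom labels between frames")
        frames.append(coords)
        i += 2 + n
    return labels, np.asarray(frames)


def write_xyz_frames(
    path: str | Path, labels: list[str], frames: np.ndarray, comment: str = ""
) -> None:
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{len(labels)}\n{comment}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
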