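"""Topology and trajectory I/O.

Reads single structures and multi-frame coordinate sets into a uniform
in-memory representation and writes the pipeline's tabular outputs.

Conventions
-----------
* Internal length unit is **nm** everywhere.  PDB files (native Å) are
  converted at the boundary and never after.
* Times are in **ps**; frame times are strictly increasing and uniformly
  spaced.
* Residue numbering is taken verbatim from the input file (1-based as
  deposited); no renumbering happens anywhere in the package.

Two trajectory formats are supported:

``pdb``
    Multi-model PDB; one MODEL per frame.  Models carry no time stamps so
    the frame spacing ``dt_ps`` must be supplied by the caller.
``frames``
    A plain-text format owned by this package: a header line
    ``"<natoms> <dt_ps>"`` followed, for each frame, by one ``"x y z"``
    line per atom, coordinates in nm.  Written with ``%.17g`` so that a
    write/read cycle is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.structure.info import mass as _element_mass

from .errors import (
    AnalysisError,
    ConfigurationError,
    FormatError,
    FrameConsistencyError,
)

_ANGSTROM_PER_NM = 10.0
_TIME_TOL = 1e-6  # ps; tolerance for comparing frame times


@dataclass
class Topology:
    """Atom-level metadata for one molecular system.

    Atom indices are implicit array positions: unique and contiguous from 0.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    _masses: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr_name in ("elements", "res_names", "res_ids", "chain_ids"):
            if len(getattr(self, arr_name)) != n:
                raise FormatError(
                    f"topology annotation '{arr_name}' has length "
                    f"{len(getattr(self, arr_name))}, expected {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def masses(self) -> np.ndarray:
        """Standard atomic masses (u) looked up from the element symbols."""
        if self._masses is None:
            self._masses = np.array(
                [float(_element_mass(str(e).capitalize())) for e in self.elements]
            )
        return self._masses

    def strands(self) -> dict[str, list[int]]:
        """Ordered unique residue numbers per chain label."""
        out: dict[str, list[int]] = {}
        for chain in sorted(set(self.chain_ids.tolist())):
            mask = self.chain_ids == chain
            seen: dict[int, None] = {}
            for rid in self.res_ids[mask].tolist():
                seen.setdefault(int(rid), None)
            out[str(chain)] = list(seen)
        return out

    def residue_atoms(self, chain: str, res_id: int) -> np.ndarray:
        """Indices of all atoms of one residue."""
        return np.flatnonzero((self.chain_ids == chain) & (self.res_ids == res_id))


@dataclass
class Trajectory:
    """Multi-frame coordinates (nm) bound to a :class:`Topology`."""

    topology: Topology
    times: np.ndarray          # (F,) ps
    coords: np.ndarray         # (F, N, 3) nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FrameConsistencyError(
                f"coordinate array has shape {self.coords.shape}, expected (F, N, 3)"
            )
        if self.coords.shape[0] != self.times.shape[0]:
            raise FrameConsistencyError(
                f"{self.coords.shape[0]} coordinate frames but "
                f"{self.times.shape[0]} time stamps"
            )
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FrameConsistencyError(
                f"frames carry {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.n_frames >= 2:
            diffs = np.diff(self.times)
            if np.any(diffs <= 0):
                raise FrameConsistencyError("frame times must be strictly increasing")
            if np.any(np.abs(diffs - diffs[0]) > _TIME_TOL):
                raise FrameConsistencyError("frame times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def dt(self) -> float:
        """Frame spacing in ps (undefined for <2 frames)."""
        if self.n_frames < 2:
            raise AnalysisError("frame spacing undefined for a <2-frame trajectory")
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _topology_from_atom_array(atoms: struc.AtomArray, path: str) -> Topology:
    chain_ids = np.asarray(atoms.chain_id, dtype="U4")
    if any(c.strip() == "" for c in chain_ids):
        raise FormatError(f"{path}: missing chain labels on one or more atoms")
    return Topology(
        atom_names=np.asarray(atoms.atom_name, dtype="U6"),
        elements=np.asarray(atoms.element, dtype="U2"),
        res_names=np.asarray(atoms.res_name, dtype="U5"),
        res_ids=np.asarray(atoms.res_id, dtype=int),
        chain_ids=chain_ids,
    )


def read_structure(path: str | Path, format: str = "pdb") -> tuple[Topology, np.ndarray]:
    """Read a single-structure file.

    Returns the :class:`Topology` and the first frame's coordinates in nm.
    """
    if format != "pdb":
        raise ConfigurationError(f"unsupported structure format: {format!r}")
    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises several types for malformed files
        raise FormatError(f"{path}: cannot parse as PDB: {exc}") from exc
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: file contains no atoms")
    topology = _topology_from_atom_array(atoms, str(path))
    coords_nm = np.asarray(atoms.coord, dtype=float) / _ANGSTROM_PER_NM
    return topology, coords_nm


def _scan_pdb_model_counts(path: Path) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (whole file if no MODELs)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM", "HETATM")):
                current += 1
    if not saw_model:
        counts = [current]
    elif in_model:  # unterminated final MODEL
        counts.append(current)
    return counts


def read_trajectory(
    topology: Topology,
    path: str | Path,
    format: str = "pdb",
    dt_ps: float | None = None,
) -> Trajectory:
    """Read a multi-frame coordinate file against an existing topology.

    Every frame must carry exactly ``topology.n_atoms`` atoms; a mismatch
    raises :class:`FrameConsistencyError` naming the offending frame.
    """
    path = Path(path)
    if format == "pdb":
        counts = _scan_pdb_model_counts(path)
        for i, c in enumerate(counts):
            if c != topology.n_atoms:
                raise FrameConsistencyError(
                    f"{path}: frame {i} has {c} atoms, topology has {topology.n_atoms}"
                )
        try:
            pdb_file = pdbio.PDBFile.read(str(path))
            stack = pdb_file.get_structure()
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse as PDB: {exc}") from exc
        coords = np.asarray(stack.coord, dtype=float) / _ANGSTROM_PER_NM
        if coords.ndim == 2:
            coords = coords[None, :, :]
        if dt_ps is None:
            raise ConfigurationError(
                "dt_ps must be supplied for multi-model PDB trajectories "
                "(PDB models carry no time stamps)"
            )
        times = np.arange(coords.shape[0], dtype=float) * float(dt_ps)
        return Trajectory(topology=topology, times=times, coords=coords)

    if format == "frames":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise FormatError(
                    f"{path}: line 1: expected header '<natoms> <dt_ps>'"
                )
            try:
                natoms = int(header[0])
                dt = float(header[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line 1: bad header values") from exc
            if natoms != topology.n_atoms:
                raise FrameConsistencyError(
                    f"{path}: header declares {natoms} atoms, topology has "
                    f"{topology.n_atoms}"
                )
            rows = []
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 'x y z'"
                    )
                rows.append([float(p) for p in parts])
        if len(rows) % natoms != 0:
            frame = len(rows) // natoms
            raise FrameConsistencyError(
                f"{path}: frame {frame} is incomplete "
                f"({len(rows) % natoms}/{natoms} atoms)"
            )
        coords = np.asarray(rows, dtype=float).reshape(-1, natoms, 3)
        if dt_ps is not None:
            dt = float(dt_ps)
        times = np.arange(coords.shape[0], dtype=float) * dt
        return Trajectory(topology=topology, times=times, coords=coords)

    raise ConfigurationError(f"unsupported trajectory format: {format!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _atom_array_from(topology: Topology, coords_nm: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    atoms = struc.AtomArray(n)
    atoms.atom_name = topology.atom_names
    atoms.element = topology.elements
    atoms.res_name = topology.res_names
    atoms.res_id = topology.res_ids
    atoms.chain_id = topology.chain_ids
    atoms.coord = np.asarray(coords_nm, dtype=np.float32) * _ANGSTROM_PER_NM
    return atoms


def write_structure(topology: Topology, coords_nm: np.ndarray, path: str | Path) -> None:
    """Write one frame as a PDB file (coordinates converted nm → Å)."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_atom_array_from(topology, coords_nm))
    pdb_file.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "frames") -> None:
    """Write a trajectory in multi-model PDB or the plain-frames format."""
    path = Path(path)
    if format == "pdb":
        stack = struc.stack(
            [_atom_array_from(traj.topology, traj.coords[i]) for i in range(traj.n_frames)]
        )
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
        return
    if format == "frames":
        dt = traj.dt if traj.n_frames >= 2 else 0.0
        with open(path, "w") as fh:
            fh.write(f"{traj.topology.n_atoms} {dt:.17g}\n")
            for frame in traj.coords:
                for x, y, z in frame:
                    fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        return
    raise ConfigurationError(f"unsupported trajectory format: {format!r}")


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------

def select_frames(traj: Trajectory, burn_in: float = 0.0, stride: float | None = None) -> Trajectory:
    """Discard a burn-in segment and subsample at a stride.

    Retains frames with time >= ``burn_in``, starting at the earliest such
    frame, every ``stride`` ps.  ``stride`` must be a positive multiple of
    the frame spacing (defaults to the spacing itself, i.e. no subsampling).
    Idempotent for the same ``(burn_in, stride)``.
    """
    if burn_in < 0:
        raise ConfigurationError("burn_in must be >= 0")
    if traj.n_frames == 0:
        return traj
    if stride is None:
        step = 1
    else:
        if traj.n_frames < 2:
            step = 1
            if stride <= 0:
                raise ConfigurationError("stride must be positive")
        else:
            ratio = float(stride) / traj.dt
            step = int(round(ratio))
            if stride <= 0 or step < 1 or abs(ratio - step) > 1e-9:
                raise ConfigurationError(
                    f"stride {stride} ps is not a positive multiple of the "
                    f"frame spacing {traj.dt} ps"
                )
    start = int(np.searchsorted(traj.times, burn_in - _TIME_TOL, side="left"))
    idx = np.arange(start, traj.n_frames, step)
    return Trajectory(
        topology=traj.topology,
        times=traj.times[idx],
        coords=traj.coords[idx],
    )


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_tsv(
    path: str | Path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a TSV with '#'-commented metadata lines and header row.

    Floats are formatted with ``repr`` precision so identical inputs yield
    byte-identical files.
    """
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# " + "\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.12g}" if isinstance(v, (float, np.floating)) else str(v)
                    for v in row
                )
                + "\n"
            )


def write_json(path: str | Path, payload: Mapping[str, object]) -> None:
    """Deterministic JSON output (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
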