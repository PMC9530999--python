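"""Per-frame transition-dipole geometry and the pairwise orientation factor.

A cyanine dye's S0→S1 transition dipole runs along the polymethine long
axis.  Each dye is reduced, per frame, to the two end points ``r`` and
``s`` of that axis (centroids of configurable atom selections; by default
the two indolenine-ring nitrogens, one per heterocycle), from which the
unit dipole direction, the dipole center, and the dye length follow.

For a dye pair (m, n) the geometry is summarized by the center-to-center
distance R_mn and the signed orientation factor

    kappa_mn = u_m . u_n - 3 (Rhat . u_m)(Rhat . u_n)

with u_i the unit dipole directions and Rhat the unit inter-center vector.
|kappa| <= 2, the extremes being the collinear arrangement (kappa = -2 for
parallel head-to-tail dipoles) and the parallel-stacked one (kappa = +1).
|kappa| <= 1 indicates predominantly stacked (H-like) dyes, |kappa| > 1
predominantly end-to-end (J-like) ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import (
    AnalysisError,
    ConfigurationError,
    DegenerateGeometryError,
    SelectionError,
)
from .trajectory_io import Topology, Trajectory, select_frames

if TYPE_CHECKING:
    from .exciton_coupling import CouplingConfig

_DEFAULT_END_R = ("N1",)
_DEFAULT_END_S = ("N2",)


@dataclass(frozen=True)
class DyeDefinition:
    """Names a dye residue, its end-atom selections, and its dipole magnitude.

    Parameters
    ----------
    label : str
        Free-form identifier, e.g. ``"Cy5_A"``.
    chain : str
        Chain label of the residue the dye is attached to.
    res_id : int
        Residue number of the dye residue (as in the input file).
    res_name : str, optional
        If given, checked against the topology.
    end_r, end_s : sequence of str
        Atom names whose centroids define the two dipole ends.  Default:
        the two indolenine nitrogens ``("N1",)`` / ``("N2",)``.
    mu_debye : float
        Transition dipole moment magnitude in Debye (>= 0).
    """

    label: str
    chain: str
    res_id: int
    res_name: str | None = None
    end_r: tuple[str, ...] = _DEFAULT_END_R
    end_s: tuple[str, ...] = _DEFAULT_END_S
    mu_debye: float = 0.0

    def __post_init__(self) -> None:
        if not self.end_r or not self.end_s:
            raise ConfigurationError(f"dye {self.label!r}: end selections must be non-empty")
        if set(self.end_r) & set(self.end_s):
            raise ConfigurationError(
                f"dye {self.label!r}: end_r and end_s selections must be disjoint"
            )
        if self.mu_debye < 0:
            raise ConfigurationError(f"dye {self.label!r}: mu_debye must be >= 0")

    def resolve(self, topology: Topology) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Atom indices of (whole residue, end_r selection, end_s selection)."""
        res_idx = topology.residue_atoms(self.chain, self.res_id)
        if res_idx.size == 0:
            raise SelectionError(
                f"dye {self.label!r}: no atoms for residue {self.res_id} "
                f"chain {self.chain}"
            )
        if self.res_name is not None:
            names = set(topology.res_names[res_idx].tolist())
            if self.res_name not in names:
                raise SelectionError(
                    f"dye {self.label!r}: residue {self.res_id} chain {self.chain} "
                    f"is {sorted(names)}, expected {self.res_name!r}"
                )
        atom_names = topology.atom_names[res_idx]

        def pick(selection: tuple[str, ...], which: str) -> np.ndarray:
            out = []
            for name in selection:
                hit = res_idx[atom_names == name]
                if hit.size == 0:
                    raise SelectionError(
                        f"dye {self.label!r}: atom {name!r} ({which}) not found in "
                        f"residue {self.res_id} chain {self.chain}"
                    )
                out.extend(hit.tolist())
            return np.asarray(out, dtype=int)

        return res_idx, pick(self.end_r, "end_r"), pick(self.end_s, "end_s")


@dataclass(frozen=True)
class DipoleGeometry:
    """One dye's dipole geometry in one frame (positions in nm)."""

    r: np.ndarray
    s: np.ndarray
    center: np.ndarray = field(init=False)
    u: np.ndarray = field(init=False)
    length: float = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        s = np.asarray(self.s, dtype=float)
        d = r - s
        length = float(np.linalg.norm(d))
        if length <= 0.0:
            raise DegenerateGeometryError("dipole ends coincide (zero-length dipole)")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "center", (r + s) / 2.0)
        object.__setattr__(self, "u", d / length)
        object.__setattr__(self, "length", length)


@dataclass(frozen=True)
class DimerObservation:
    """One frame's dimer record: time, distance, orientation, coupling."""

    time_ps: float
    R_nm: float
    kappa: float
    J_meV: float | None = None

    @property
    def abs_kappa(self) -> float:
        return abs(self.kappa)

    @property
    def abs_J(self) -> float | None:
        return None if self.J_meV is None else abs(self.J_meV)


# ---------------------------------------------------------------------------
# per-frame geometry
# ---------------------------------------------------------------------------

def dipole_from_frame(
    frame: np.ndarray, topology: Topology, dye: DyeDefinition
) -> DipoleGeometry:
    """Extract a dye's dipole geometry from one coordinate frame (nm)."""
    _, idx_r, idx_s = dye.resolve(topology)
    frame = np.asarray(frame, dtype=float)
    return DipoleGeometry(r=frame[idx_r].mean(axis=0), s=frame[idx_s].mean(axis=0))


def orientation_factor(m: DipoleGeometry, n: DipoleGeometry) -> float:
    """Signed orientation factor kappa for a dipole pair; |kappa| <= 2."""
    rvec = n.center - m.center
    dist = np.linalg.norm(rvec)
    if dist <= 0.0:
        raise DegenerateGeometryError("dipole centers coincide; kappa undefined")
    rhat = rvec / dist
    return float(m.u @ n.u - 3.0 * (rhat @ m.u) * (rhat @ n.u))


def center_distance(m: DipoleGeometry, n: DipoleGeometry) -> float:
    """Center-to-center distance R_mn in nm (symmetric in its arguments)."""
    return float(np.linalg.norm(m.center - n.center))


# ---------------------------------------------------------------------------
# trajectory-level series
# ---------------------------------------------------------------------------

def dipole_end_series(
    traj: Trajectory, dye: DyeDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """(F,3) end positions r and s for every frame (vectorized centroids)."""
    _, idx_r, idx_s = dye.resolve(traj.topology)
    return (
        traj.coords[:, idx_r, :].mean(axis=1),
        traj.coords[:, idx_s, :].mean(axis=1),
    )


def _kappa_series(
    u_m: np.ndarray, u_n: np.ndarray, rhat: np.ndarray
) -> np.ndarray:
    return np.einsum("fi,fi->f", u_m, u_n) - 3.0 * np.einsum(
        "fi,fi->f", rhat, u_m
    ) * np.einsum("fi,fi->f", rhat, u_n)


def observe_dimer(
    traj: Trajectory,
    dye_m: DyeDefinition,
    dye_n: DyeDefinition,
    stride: float | None = None,
    burn_in: float = 0.0,
    coupling: "CouplingConfig | None" = None,
) -> list[DimerObservation]:
    """Per-frame (time, R, kappa[, J]) records for a dye pair.

    Frames are selected via :func:`select_frames`; one observation per
    retained frame, in time order.  The excitonic coupling J (extended
    dipole approximation, meV) is included when a
    :class:`~hjdimer.exciton_coupling.CouplingConfig` is supplied and both
    dyes declare a positive dipole magnitude.
    """
    sub = select_frames(traj, burn_in=burn_in, stride=stride)
    if sub.n_frames == 0:
        raise AnalysisError("no frames retained after burn-in/stride selection")

    r_m, s_m = dipole_end_series(sub, dye_m)
    r_n, s_n = dipole_end_series(sub, dye_n)

    d_m = r_m - s_m
    d_n = r_n - s_n
    l_m = np.linalg.norm(d_m, axis=1)
    l_n = np.linalg.norm(d_n, axis=1)
    if np.any(l_m <= 0) or np.any(l_n <= 0):
        raise DegenerateGeometryError("zero-length dipole in at least one frame")
    u_m = d_m / l_m[:, None]
    u_n = d_n / l_n[:, None]

    c_m = (r_m + s_m) / 2.0
    c_n = (r_n + s_n) / 2.0
    rvec = c_n - c_m
    R = np.linalg.norm(rvec, axis=1)
    if np.any(R <= 0):
        raise DegenerateGeometryError("coincident dipole centers in at least one frame")
    kappa = _kappa_series(u_m, u_n, rvec / R[:, None])

    J: np.ndarray | None = None
    if coupling is not None and dye_m.mu_debye > 0 and dye_n.mu_debye > 0:
        from .exciton_coupling import extended_dipole_J_arrays

        J = extended_dipole_J_arrays(
            r_m, s_m, r_n, s_n, dye_m.mu_debye, dye_n.mu_debye, coupling
        )

    return [
        DimerObservation(
            time_ps=float(sub.times[i]),
            R_nm=float(R[i]),
            kappa=float(kappa[i]),
            J_meV=None if J is None else float(J[i]),
        )
        for i in range(sub.n_frames)
    ]


def observations_table(
    observations: Sequence[DimerObservation], trial: int | None = None
) -> list[list]:
    """Rows (time_ps, R_nm, kappa, abs_kappa, J_meV, abs_J_meV[, trial])
    for TSV output; missing J rendered as 'NA'."""
    rows = []
    for o in observations:
        row: list = [
            o.time_ps,
            o.R_nm,
            o.kappa,
            o.abs_kappa,
            "NA" if o.J_meV is None else o.J_meV,
            "NA" if o.J_meV is None else abs(o.J_meV),
        ]
        if trial is not None:
            row.append(trial)
        rows.append(row)
    return rows
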