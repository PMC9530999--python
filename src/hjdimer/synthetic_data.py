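"""Seed-controlled synthetic topologies and trajectories with known truth.

Real inputs for this pipeline are microsecond all-atom MD trajectories of
dye-labeled Holliday junctions, which cannot be regenerated at desk
scale.  This module stands in for them with two constructions whose
ground truth is known exactly:

* :func:`generate_dimer_trajectory` — two rigid rods (one per dye, two
  end pseudo-atoms each).  Per frame, the center separation R is drawn
  from a normal distribution and each rod is perturbed by independent
  small-angle rotations about two axes orthogonal to its director.  Modes
  emulate the geometries reported for dye dimers on junctions: stacked
  (``H_dimer``, R ~ 0.5 nm, perpendicular separation), end-to-end
  (``J_dimer``, R ~ 1.4 nm, longitudinal separation), separated-stacked
  (``separated_H``, ~2.5 nm), effectively-monomeric (``monomer``,
  ~4.2 nm), and per-frame ``mixture`` of those.

* :func:`generate_mock_junction` — a pseudo-atom four-strand junction
  (4 strands x 26 single-atom bases arranged as two straight duplexes
  crossing at a configurable inter-duplex angle) with three-atom dye
  residues (two ends + a center atom) whose placement encodes the
  isomer/attachment geometry: transverse dyes sit 0.5 nm apart in the
  Iso I-like arrangement and 4.0 nm apart in the Iso II-like one.

Everything is deterministic for a fixed (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dipole_geometry import DyeDefinition
from .errors import ConfigurationError
from .junction_geometry import ArmDefinition, Span
from .trajectory_io import Topology, Trajectory, write_structure, write_trajectory

MODES = ("H_dimer", "J_dimer", "separated_H", "monomer", "mixture")

#: Mode -> (mean R nm, sd R nm); chosen to emulate the reported peak
#: positions for the corresponding dimer arrangements.
MODE_R_DEFAULTS = {
    "H_dimer": (0.5, 0.04),
    "J_dimer": (1.4, 0.08),
    "separated_H": (2.5, 0.2),
    "monomer": (4.2, 0.3),
}

_R_FLOOR = 0.05  # nm; guards against non-physical draws from the R normal


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dimer ensemble.

    ``r_mean_nm`` / ``r_sd_nm`` default to the mode's canonical values
    (see :data:`MODE_R_DEFAULTS`).  ``angular_noise_deg`` is the SD of the
    per-axis small-angle rotations (10 degrees by default, a typical
    orientational jitter for tethered dyes).  Dye lengths default to the
    1.4 nm polymethine long axis of Cy5; dipole magnitudes to the Cy5
    TD-DFT value of 15.35 D.
    """

    mode: str
    n_frames: int
    dt_ps: float = 100.0
    seed: int = 0
    r_mean_nm: float | None = None
    r_sd_nm: float | None = None
    angular_noise_deg: float = 10.0
    l_m_nm: float = 1.4
    l_n_nm: float = 1.4
    mu_m_debye: float = 15.35
    mu_n_debye: float = 15.35
    mixture_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.r_sd_nm is not None and self.r_sd_nm < 0:
            raise ConfigurationError("r_sd_nm must be >= 0")
        if self.angular_noise_deg < 0:
            raise ConfigurationError("angular_noise_deg must be >= 0")
        if self.l_m_nm <= 0 or self.l_n_nm <= 0:
            raise ConfigurationError("dye lengths must be positive")
        if self.mode == "mixture":
            if not self.mixture_weights:
                raise ConfigurationError("mixture mode requires mixture_weights")
            if any(m not in MODE_R_DEFAULTS for m in self.mixture_weights):
                raise ConfigurationError("mixture weights must name concrete modes")
            total = sum(self.mixture_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"mixture weights sum to {total}, expected 1")

    def r_distribution(self, mode: str | None = None) -> tuple[float, float]:
        mode = mode or self.mode
        default_mean, default_sd = MODE_R_DEFAULTS.get(mode, (0.5, 0.04))
        mean = self.r_mean_nm if self.r_mean_nm is not None else default_mean
        sd = self.r_sd_nm if self.r_sd_nm is not None else default_sd
        return mean, sd


@dataclass
class GroundTruth:
    """Per-frame generator truth, written as a JSON-lines sidecar."""

    times_ps: np.ndarray
    R_nm: np.ndarray
    kappa: np.ndarray
    modes: list[str]

    def __post_init__(self) -> None:
        n = len(self.times_ps)
        if not (len(self.R_nm) == len(self.kappa) == len(self.modes) == n):
            raise ConfigurationError("ground-truth record lengths disagree")

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self.times_ps)):
                fh.write(
                    json.dumps(
                        {
                            "time_ps": float(self.times_ps[i]),
                            "R_nm": float(self.R_nm[i]),
                            "kappa": float(self.kappa[i]),
                            "mode": self.modes[i],
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "GroundTruth":
        times, R, kappa, modes = [], [], [], []
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                times.append(rec["time_ps"])
                R.append(rec["R_nm"])
                kappa.append(rec["kappa"])
                modes.append(rec["mode"])
        return cls(np.asarray(times), np.asarray(R), np.asarray(kappa), modes)


# ---------------------------------------------------------------------------
# rigid-rod dimer ensembles
# ---------------------------------------------------------------------------

def _dimer_topology() -> Topology:
    return Topology(
        atom_names=np.array(["N1", "N2", "N1", "N2"]),
        elements=np.array(["N", "N", "N", "N"]),
        res_names=np.array(["CY5", "CY5", "CY5", "CY5"]),
        res_ids=np.array([1, 1, 1, 1]),
        chain_ids=np.array(["A", "A", "B", "B"]),
    )


def dimer_dye_definitions(spec: SyntheticSpec) -> tuple[DyeDefinition, DyeDefinition]:
    """Dye definitions matching :func:`generate_dimer_trajectory` output."""
    return (
        DyeDefinition(label="dye_m", chain="A", res_id=1, mu_debye=spec.mu_m_debye),
        DyeDefinition(label="dye_n", chain="B", res_id=1, mu_debye=spec.mu_n_debye),
    )


def _noisy_directors(rng: np.random.Generator, n: int, sd_deg: float) -> np.ndarray:
    """Rod directors: x-hat perturbed by N(0, sd) rotations about y and z."""
    a = np.deg2rad(rng.normal(0.0, sd_deg, size=n)) if sd_deg > 0 else np.zeros(n)
    b = np.deg2rad(rng.normal(0.0, sd_deg, size=n)) if sd_deg > 0 else np.zeros(n)
    return np.stack(
        [np.cos(a) * np.cos(b), np.cos(a) * np.sin(b), -np.sin(a)], axis=1
    )


def generate_dimer_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a rigid-rod dimer ensemble with exact per-frame truth.

    Rod m is centered at the origin; rod n's center is displaced by the
    drawn R along the mode's canonical axis — perpendicular to the rods
    (z) for the stacked/separated/monomer modes, longitudinal (x) for the
    end-to-end mode.  With zero noise the stacked construction gives
    kappa = +1 exactly and the end-to-end one kappa = -2 exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    if spec.mode == "mixture":
        names = sorted(spec.mixture_weights)
        probs = np.array([spec.mixture_weights[m] for m in names])
        modes = [names[i] for i in rng.choice(len(names), size=n, p=probs)]
    else:
        modes = [spec.mode] * n

    R = np.empty(n)
    for i, m in enumerate(modes):
        mean, sd = spec.r_distribution(m)
        R[i] = rng.normal(mean, sd) if sd > 0 else mean
    # keep draws physical: strictly positive, and for end-to-end geometry
    # far enough that the inner rod ends cannot cross
    longitudinal = np.array([m == "J_dimer" for m in modes])
    floor = np.where(longitudinal, (spec.l_m_nm + spec.l_n_nm) / 2.0 + _R_FLOOR, _R_FLOOR)
    R = np.maximum(R, floor)

    u_m = _noisy_directors(rng, n, spec.angular_noise_deg)
    u_n = _noisy_directors(rng, n, spec.angular_noise_deg)

    axis = np.where(longitudinal[:, None], [[1.0, 0.0, 0.0]], [[0.0, 0.0, 1.0]])
    c_m = np.zeros((n, 3))
    c_n = axis * R[:, None]

    coords = np.empty((n, 4, 3))
    coords[:, 0] = c_m + 0.5 * spec.l_m_nm * u_m   # r_m (N1, chain A)
    coords[:, 1] = c_m - 0.5 * spec.l_m_nm * u_m   # s_m
    coords[:, 2] = c_n + 0.5 * spec.l_n_nm * u_n   # r_n (N1, chain B)
    coords[:, 3] = c_n - 0.5 * spec.l_n_nm * u_n   # s_n

    rhat = axis  # centers differ along the canonical axis only
    kappa = np.einsum("fi,fi->f", u_m, u_n) - 3.0 * np.einsum(
        "fi,fi->f", rhat, u_m
    ) * np.einsum("fi,fi->f", rhat, u_n)

    times = np.arange(n, dtype=float) * spec.dt_ps
    traj = Trajectory(topology=_dimer_topology(), times=times, coords=coords)
    truth = GroundTruth(times_ps=times, R_nm=R.copy(), kappa=kappa, modes=modes)
    return traj, truth


# ---------------------------------------------------------------------------
# mock four-strand junction
# ---------------------------------------------------------------------------

ISOMERS = ("IsoI", "IsoII")
ATTACHMENTS = ("adjacent", "transverse")

_BASE_RISE_NM = 0.34
_N_RESIDUES = 26
_DUPLEX_HALF_GAP_NM = 0.3    # duplexes in planes z = +/- this
_STRAND_HALF_SEP_NM = 0.125  # paired strands offset +/- this within a duplex
_DYE_RES_ID = 101
_DYE_LENGTH_NM = 1.4

#: (isomer, attachment) -> centers of the two dye rods (strand A first).
_DYE_CENTERS = {
    ("IsoI", "transverse"): (np.array([0.12, 0.12, 0.55]), np.array([0.12, 0.12, 0.05])),
    ("IsoII", "transverse"): (np.array([0.12, 0.12, 2.05]), np.array([0.12, 0.12, -1.95])),
    ("IsoI", "adjacent"): (np.array([0.12, 0.12, 0.55]), np.array([0.12, 1.52, 0.55])),
    ("IsoII", "adjacent"): (np.array([0.12, 0.12, 0.55]), np.array([0.12, 2.32, 0.55])),
}

#: Construction-value dye separations (nm), for oracle checks.
MOCK_DYE_SEPARATION = {
    key: float(np.linalg.norm(a - b)) for key, (a, b) in _DYE_CENTERS.items()
}


def _strand_positions(
    in_dir: np.ndarray, out_dir: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """(26,3) pseudo-base positions: residues 1-13 inbound, 14-26 outbound."""
    pos = np.empty((_N_RESIDUES, 3))
    for k in range(1, 14):
        pos[k - 1] = in_dir * (13.5 - k) * _BASE_RISE_NM + offset
    for k in range(14, 27):
        pos[k - 1] = out_dir * (k - 13.5) * _BASE_RISE_NM + offset
    return pos


def mock_junction_dyes(
    isomer: str, attachment: str
) -> tuple[DyeDefinition, DyeDefinition]:
    """Dye definitions matching :func:`generate_mock_junction` output."""
    partner = "C" if attachment == "transverse" else "B"
    return (
        DyeDefinition(label="Cy5_A", chain="A", res_id=_DYE_RES_ID,
                      res_name="CY5", mu_debye=15.35),
        DyeDefinition(label=f"Cy5_{partner}", chain=partner, res_id=_DYE_RES_ID,
                      res_name="CY5", mu_debye=15.35),
    )


def mock_junction_arms() -> tuple[list[ArmDefinition], list[ArmDefinition]]:
    """The two composite stacked duplexes of the mock junction."""
    duplex_1 = [ArmDefinition("duplex_AB", Span("A", 1, 26), Span("B", 26, 1))]
    duplex_2 = [ArmDefinition("duplex_CD", Span("C", 1, 26), Span("D", 26, 1))]
    return duplex_1, duplex_2


def generate_mock_junction(
    isomer: str,
    attachment: str,
    n_frames: int = 100,
    seed: int = 0,
    ida_deg: float = 60.0,
    dt_ps: float = 500.0,
    jitter_sd_nm: float = 0.0,
) -> tuple[Topology, Trajectory, GroundTruth]:
    """Pseudo-atom four-strand junction with dyes at isomer-dependent sites.

    Strands A/B form one straight duplex along x, strands C/D a second
    duplex rotated by ``ida_deg`` about z and offset below the first; each
    strand has 26 single-atom bases with residues 13/14 flanking the
    junction center.  Dye residues (atoms N1/N2 at the rod ends plus a
    center atom CM) are placed so that the transverse Iso I-like pair is
    0.5 nm apart and the transverse Iso II-like pair 4.0 nm apart, i.e.
    on opposite sides of the junction.  ``jitter_sd_nm`` adds optional
    isotropic Gaussian coordinate noise per frame (default none, so the
    construction values are exact).
    """
    if isomer not in ISOMERS:
        raise ConfigurationError(f"unknown isomer {isomer!r}; expected one of {ISOMERS}")
    if attachment not in ATTACHMENTS:
        raise ConfigurationError(
            f"unknown attachment {attachment!r}; expected one of {ATTACHMENTS}"
        )
    theta = np.deg2rad(ida_deg)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([np.cos(theta), np.sin(theta), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    n1 = np.cross(z, e1)
    n2 = np.cross(z, e2)

    up = _DUPLEX_HALF_GAP_NM * z
    routes = {
        "A": (e1, -e1, +_STRAND_HALF_SEP_NM * n1 + up),
        "B": (-e1, e1, -_STRAND_HALF_SEP_NM * n1 + up),
        "C": (e2, -e2, +_STRAND_HALF_SEP_NM * n2 - up),
        "D": (-e2, e2, -_STRAND_HALF_SEP_NM * n2 - up),
    }

    names, elements, res_names, res_ids, chains, coords = [], [], [], [], [], []
    for chain in "ABCD":
        in_dir, out_dir, offset = routes[chain]
        for k, pos in enumerate(_strand_positions(in_dir, out_dir, offset), start=1):
            names.append("C1")
            elements.append("C")
            res_names.append("DN")
            res_ids.append(k)
            chains.append(chain)
            coords.append(pos)

    dye_m, dye_n = mock_junction_dyes(isomer, attachment)
    center_a, center_b = _DYE_CENTERS[(isomer, attachment)]
    rod = 0.5 * _DYE_LENGTH_NM * np.array([1.0, 0.0, 0.0])
    for dye, center in ((dye_m, center_a), (dye_n, center_b)):
        for name, element, pos in (
            ("N1", "N", center + rod),
            ("N2", "N", center - rod),
            ("CM", "C", center),
        ):
            names.append(name)
            elements.append(element)
            res_names.append("CY5")
            res_ids.append(_DYE_RES_ID)
            chains.append(dye.chain)
            coords.append(pos)

    topology = Topology(
        atom_names=np.array(names),
        elements=np.array(elements),
        res_names=np.array(res_names),
        res_ids=np.array(res_ids),
        chain_ids=np.array(chains),
    )
    base = np.asarray(coords)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if jitter_sd_nm > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, jitter_sd_nm, size=frames.shape)
    times = np.arange(n_frames, dtype=float) * dt_ps
    traj = Trajectory(topology=topology, times=times, coords=frames)

    sep = MOCK_DYE_SEPARATION[(isomer, attachment)]
    truth = GroundTruth(
        times_ps=times,
        R_nm=np.full(n_frames, sep),
        kappa=np.ones(n_frames),  # parallel rods, perpendicular separation
        modes=[f"{isomer}_{attachment}"] * n_frames,
    )
    return topology, traj, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_synthetic_run(
    prefix: str | Path,
    topology: Topology,
    traj: Trajectory,
    truth: GroundTruth,
    format: str = "frames",
) -> dict[str, Path]:
    """Write topology (PDB), trajectory, and ground-truth sidecar.

    Returns the paths written, keyed by role.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "topology": prefix.with_name(prefix.name + "_topology.pdb"),
        "trajectory": prefix.with_name(
            prefix.name + ("_traj.pdb" if format == "pdb" else "_traj.frames")
        ),
        "truth": prefix.with_name(prefix.name + "_truth.jsonl"),
    }
    write_structure(topology, traj.coords[0], paths["topology"])
    write_trajectory(traj, paths["trajectory"], format=format)
    truth.to_jsonl(paths["truth"])
    return paths
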