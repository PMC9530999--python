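"""Dye–DNA contact maps.

The contact analysis reduces the system to 26 residue groups: the six
central bases (residue numbers 11–16 by default) of each of the four
strands, plus one group per dye.  Per frame, a base group is represented
by its center of mass; a dye group, to account for its anisotropic shape,
by three points — the whole-dye center of mass and the two dipole ends.
Two groups are in contact when the shortest distance between any pair of
their representative points is within the cutoff (1.2 nm by default, the
short-range interaction cutoff of the simulations being analyzed; the
comparison is closed, d <= cutoff).  The contact map entry (i, j) is the
fraction of analyzed frames in which groups i and j are in contact; the
diagonal is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dipole_geometry import DyeDefinition
from .errors import AnalysisError, TopologyError
from .trajectory_io import Topology, Trajectory, select_frames, write_tsv

DEFAULT_CUTOFF_NM = 1.2
DEFAULT_WINDOW = (11, 16)


@dataclass
class ResidueGroup:
    """One contact group: a central base or a dye.

    ``kind`` is ``"base"`` or ``"dye"``.  ``atom_indices`` are the member
    atoms (used for the center of mass); for dyes ``end_r_indices`` /
    ``end_s_indices`` add the two end-point centroids as further
    representative points.
    """

    label: str
    kind: str
    atom_indices: np.ndarray
    masses: np.ndarray
    end_r_indices: np.ndarray | None = None
    end_s_indices: np.ndarray | None = None
    heavy_only: bool = False

    def __post_init__(self) -> None:
        if self.atom_indices.size == 0:
            raise TopologyError(f"group {self.label!r} has no member atoms")
        if self.kind not in ("base", "dye"):
            raise TopologyError(f"group {self.label!r}: unknown kind {self.kind!r}")

    def representative_points(self, frame: np.ndarray) -> np.ndarray:
        """(P,3) representative points in one frame: COM, plus dye ends."""
        coords = frame[self.atom_indices]
        com = (coords * self.masses[:, None]).sum(axis=0) / self.masses.sum()
        points = [com]
        if self.kind == "dye":
            points.append(frame[self.end_r_indices].mean(axis=0))
            points.append(frame[self.end_s_indices].mean(axis=0))
        return np.asarray(points)


@dataclass
class ContactMap:
    """Symmetric residue-group contact-probability matrix."""

    labels: list[str]
    matrix: np.ndarray
    cutoff_nm: float
    n_frames_used: int
    stride_ps: float | None

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise AnalysisError("contact matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise AnalysisError("contact matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise AnalysisError("contact matrix diagonal must be 1")
        if m.min() < 0 or m.max() > 1:
            raise AnalysisError("contact probabilities must lie in [0, 1]")

    def entry(self, label_i: str, label_j: str) -> float:
        i = self.labels.index(label_i)
        j = self.labels.index(label_j)
        return float(self.matrix[i, j])

    def write_matrix_tsv(self, path, meta: Mapping[str, object] | None = None) -> None:
        rows = [
            [label] + [float(v) for v in self.matrix[i]]
            for i, label in enumerate(self.labels)
        ]
        write_tsv(path, ["group"] + self.labels, rows, meta=meta)

    def write_long_tsv(self, path, meta: Mapping[str, object] | None = None) -> None:
        rows = [
            [self.labels[i], self.labels[j], float(self.matrix[i, j])]
            for i in range(len(self.labels))
            for j in range(i, len(self.labels))
        ]
        write_tsv(path, ["group_i", "group_j", "probability"], rows, meta=meta)


# ---------------------------------------------------------------------------
# group construction
# ---------------------------------------------------------------------------

def build_groups(
    topology: Topology,
    dyes: Sequence[DyeDefinition],
    center_window: tuple[int, int] = DEFAULT_WINDOW,
    heavy_only: bool = False,
) -> list[ResidueGroup]:
    """Build the contact groups: window bases per strand plus one per dye.

    With the default window (11, 16) and a four-strand junction carrying
    two dyes this yields 4 x 6 + 2 = 26 groups.  A dye residue falling
    inside the window is not double-counted as a base: dyes are always
    their own group.  Base labels are ``"<number><strand>"`` (e.g.
    ``"13A"``); groups are ordered per strand, bases first, then that
    strand's dyes.
    """
    lo, hi = center_window
    if lo > hi:
        raise TopologyError(f"invalid center window {center_window}")
    masses = topology.masses
    heavy = topology.elements != "H"
    dye_keys = {(d.chain, d.res_id) for d in dyes}
    dyes_by_chain: dict[str, list[DyeDefinition]] = {}
    for d in dyes:
        dyes_by_chain.setdefault(d.chain, []).append(d)

    groups: list[ResidueGroup] = []
    for chain in sorted(topology.strands()):
        for res_id in range(lo, hi + 1):
            if (chain, res_id) in dye_keys:
                continue  # dyes are their own group
            idx = topology.residue_atoms(chain, res_id)
            if heavy_only:
                idx = idx[heavy[idx]]
            if idx.size == 0:
                raise TopologyError(
                    f"strand {chain} is missing residue {res_id} in the "
                    f"center window {lo}-{hi}"
                )
            groups.append(
                ResidueGroup(
                    label=f"{res_id}{chain}",
                    kind="base",
                    atom_indices=idx,
                    masses=masses[idx],
                    heavy_only=heavy_only,
                )
            )
        for dye in dyes_by_chain.get(chain, []):
            res_idx, idx_r, idx_s = dye.resolve(topology)
            groups.append(
                ResidueGroup(
                    label=dye.label,
                    kind="dye",
                    atom_indices=res_idx,
                    masses=masses[res_idx],
                    end_r_indices=idx_r,
                    end_s_indices=idx_s,
                )
            )
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise TopologyError("duplicate group labels")
    return groups


# ---------------------------------------------------------------------------
# contact evaluation
# ---------------------------------------------------------------------------

def in_contact(
    frame: np.ndarray,
    g1: ResidueGroup,
    g2: ResidueGroup,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> bool:
    """True iff the minimum representative-point distance is <= cutoff."""
    p1 = g1.representative_points(frame)
    p2 = g2.representative_points(frame)
    d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=2)
    return bool(d.min() <= cutoff)


def contact_map(
    trajs: Trajectory | Sequence[Trajectory],
    groups: Sequence[ResidueGroup],
    cutoff: float = DEFAULT_CUTOFF_NM,
    stride: float | None = 500.0,
    burn_in: float = 0.0,
) -> ContactMap:
    """Frame-averaged contact probabilities over one or more trajectories.

    Multiple trajectories (simulation trials) are pooled with frame-count
    weighting: the probability is total contact frames over total retained
    frames.  The diagonal is forced to 1.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    n_groups = len(groups)
    hits = np.zeros((n_groups, n_groups), dtype=np.int64)
    total_frames = 0
    for traj in trajs:
        sub = select_frames(traj, burn_in=burn_in, stride=stride)
        for f in range(sub.n_frames):
            frame = sub.coords[f]
            points = [g.representative_points(frame) for g in groups]
            for i in range(n_groups):
                for j in range(i + 1, n_groups):
                    d = np.linalg.norm(
                        points[i][:, None, :] - points[j][None, :, :], axis=2
                    )
                    if d.min() <= cutoff:
                        hits[i, j] += 1
        total_frames += sub.n_frames
    if total_frames == 0:
        raise AnalysisError("no frames retained for contact analysis")
    matrix = hits / float(total_frames)
    matrix = matrix + matrix.T
    np.fill_diagonal(matrix, 1.0)
    stride_out = None
    if stride is not None:
        stride_out = float(stride)
    return ContactMap(
        labels=[g.label for g in groups],
        matrix=matrix,
        cutoff_nm=float(cutoff),
        n_frames_used=int(total_frames),
        stride_ps=stride_out,
    )
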