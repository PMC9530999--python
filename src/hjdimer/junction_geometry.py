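"""Holliday-junction arm descriptors: inter-duplex angle and twist.

A stacked-X Holliday junction consists of two quasi-continuous duplexes.
This module fits an axis to each duplex and reports, per frame:

``IDA``
    the inter-duplex angle: the angle (degrees, in [0, 180]) between the
    two directed duplex axes;
``twist``
    the dihedral between the duplex planes about the inter-duplex offset
    vector, folded into [0, 90] so that coplanar duplexes give 0.

Convention (pinned here, since published junction-angle constructions
vary): an arm axis is the first principal direction of the ordered
base-pair centroids of the arm's two strand spans, with base pairs formed
index-wise between the spans as listed (the caller lists the spans in
pairing order).  The axis is directed from the first listed centroid to
the last, and re-oriented away from the junction center when one is
supplied.  A composite stacked duplex is described by concatenating its
two arms' centroids.  These angles are validated on constructed
geometries with known angles; they are a documented convention, not a
reproduction of any particular published construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError, DegenerateGeometryError, TopologyError
from .trajectory_io import Topology, Trajectory, select_frames

_DEG = 180.0 / np.pi


@dataclass(frozen=True)
class Span:
    """An ordered residue range on one chain; ``stop`` may be < ``start``
    to indicate descending order (antiparallel partner strand)."""

    chain: str
    start: int
    stop: int

    def residue_ids(self) -> list[int]:
        step = 1 if self.stop >= self.start else -1
        return list(range(self.start, self.stop + step, step))


@dataclass(frozen=True)
class ArmDefinition:
    """One duplex arm: two equal-length strand spans in pairing order."""

    label: str
    span_a: Span
    span_b: Span

    def __post_init__(self) -> None:
        na = len(self.span_a.residue_ids())
        nb = len(self.span_b.residue_ids())
        if na == 0 or nb == 0:
            raise TopologyError(f"arm {self.label!r}: empty residue span")
        if na != nb:
            raise TopologyError(
                f"arm {self.label!r}: spans have unequal lengths {na} and {nb}"
            )


@dataclass(frozen=True)
class JunctionAngles:
    """Per-frame junction descriptors (degrees)."""

    time_ps: float
    ida_deg: float
    twist_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ida_deg <= 180.0 and 0.0 <= self.twist_deg <= 180.0):
            raise AnalysisError("junction angles must lie in [0, 180] degrees")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def base_pair_centroids(
    frame: np.ndarray, topology: Topology, arm: ArmDefinition
) -> np.ndarray:
    """(P,3) centroids of the index-wise base pairs of an arm."""
    ids_a = arm.span_a.residue_ids()
    ids_b = arm.span_b.residue_ids()
    out = np.empty((len(ids_a), 3))
    for k, (ra, rb) in enumerate(zip(ids_a, ids_b)):
        idx_a = topology.residue_atoms(arm.span_a.chain, ra)
        idx_b = topology.residue_atoms(arm.span_b.chain, rb)
        if idx_a.size == 0 or idx_b.size == 0:
            raise TopologyError(
                f"arm {arm.label!r}: missing residue "
                f"{ra}{arm.span_a.chain} or {rb}{arm.span_b.chain}"
            )
        both = np.concatenate([frame[idx_a], frame[idx_b]])
        out[k] = both.mean(axis=0)
    return out


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] <= 1e-9:
        raise DegenerateGeometryError(
            "degenerate point set: no principal direction (all centroids coincide)"
        )
    return vt[0]


def arm_axis(
    frame: np.ndarray,
    topology: Topology,
    arm: ArmDefinition,
    center: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit axis and anchor point of one duplex arm.

    The axis is the first principal direction of the base-pair centroids,
    directed from the first listed centroid toward the last; when a
    junction ``center`` is given the axis is re-oriented to point away
    from it.  The anchor is the centroid mean.
    """
    centroids = base_pair_centroids(frame, topology, arm)
    if len(centroids) < 2:
        raise DegenerateGeometryError(f"arm {arm.label!r}: need >= 2 base pairs")
    axis = _principal_axis(centroids)
    direction = centroids[-1] - centroids[0]
    if axis @ direction < 0:
        axis = -axis
    anchor = centroids.mean(axis=0)
    if center is not None:
        outward = anchor - np.asarray(center, dtype=float)
        if np.linalg.norm(outward) > 1e-9 and axis @ outward < 0:
            axis = -axis
    return axis, anchor


def _composite_axis(
    frame: np.ndarray, topology: Topology, arms: Sequence[ArmDefinition]
) -> tuple[np.ndarray, np.ndarray]:
    centroids = np.concatenate(
        [base_pair_centroids(frame, topology, a) for a in arms]
    )
    if len(centroids) < 2:
        raise DegenerateGeometryError("composite duplex needs >= 2 base pairs")
    axis = _principal_axis(centroids)
    direction = centroids[-1] - centroids[0]
    if axis @ direction < 0:
        axis = -axis
    return axis, centroids.mean(axis=0)


def junction_angles(
    frame: np.ndarray,
    topology: Topology,
    duplex_1: Sequence[ArmDefinition],
    duplex_2: Sequence[ArmDefinition],
    time_ps: float = 0.0,
) -> JunctionAngles:
    """IDA and twist for one frame.

    Each duplex is a sequence of one or two arm definitions whose
    base-pair centroids are concatenated in the listed order (for a
    stacked duplex: the two coaxially stacked arms, tip-to-tip through
    the junction).  The twist requires a non-zero offset between the two
    duplex anchors and duplex axes not parallel to that offset.
    """
    axis1, anchor1 = _composite_axis(frame, topology, duplex_1)
    axis2, anchor2 = _composite_axis(frame, topology, duplex_2)
    cosang = float(np.clip(axis1 @ axis2, -1.0, 1.0))
    ida = float(np.arccos(cosang) * _DEG)

    offset = anchor2 - anchor1
    norm = np.linalg.norm(offset)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "duplex anchors coincide; twist about the inter-duplex vector is undefined"
        )
    d_hat = offset / norm
    n1 = np.cross(axis1, d_hat)
    n2 = np.cross(axis2, d_hat)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError(
            "a duplex axis is parallel to the inter-duplex vector; twist undefined"
        )
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    twist = float(np.arccos(np.clip(abs(n1 @ n2), 0.0, 1.0)) * _DEG)
    return JunctionAngles(time_ps=time_ps, ida_deg=ida, twist_deg=twist)


def junction_angle_series(
    traj: Trajectory,
    duplex_1: Sequence[ArmDefinition],
    duplex_2: Sequence[ArmDefinition],
    stride: float | None = None,
    burn_in: float = 0.0,
) -> list[JunctionAngles]:
    """IDA/twist time series over the retained frames of a trajectory."""
    sub = select_frames(traj, burn_in=burn_in, stride=stride)
    if sub.n_frames == 0:
        raise AnalysisError("no frames retained for junction-angle analysis")
    return [
        junction_angles(
            sub.coords[i], sub.topology, duplex_1, duplex_2, time_ps=float(sub.times[i])
        )
        for i in range(sub.n_frames)
    ]
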