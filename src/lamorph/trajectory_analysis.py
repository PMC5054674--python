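"""Shaping the motion: statistics on deformation-trajectory geometry.

Each subject's path through deformation-PC space across the 12 homologous
times is itself a landmark configuration — 12 "landmarks" in q dimensions
(q = 3 by default). A second-order GPA in shape space, with alignment
estimated from the three strictly homologous anchor times only (R peak,
atrial end-diastole, P peak; trajectory landmarks 1, 5, 9, 1-based),
yields trajectory *shape*; the raw configuration's centroid size yields
trajectory *size*; and the direction of the vector from landmark 1 to
landmark 5 yields trajectory *orientation* angles.

Anchor-only alignment keeps the interpolated in-between times passive, so
imperfect estimation of the non-event times cannot bias the
superimposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_geometry import ShapePCA, _kabsch, shape_pca
from .errors import (
    DegenerateConfigurationError,
    IncompleteTrajectoryError,
    UndefinedOrientationError,
    UnderDeterminedAlignmentError,
)
from .parallel_transport import DeformationPCA
from .temporal_homology import N_HOMOLOGOUS_TIMES

__all__ = [
    "Trajectory",
    "TrajectoryAttributes",
    "TrajectoryGPAResult",
    "build_trajectory",
    "build_cohort_trajectories",
    "trajectory_gpa",
    "trajectory_shape_pca",
    "trajectory_size",
    "trajectory_orientation",
    "trajectory_attributes",
    "DEFAULT_ANCHORS",
]

#: 1-based anchor landmarks: R peak, LA end-diastole, P peak
DEFAULT_ANCHORS = (1, 5, 9)


@dataclass
class Trajectory:
    """One subject's 12 x q configuration of deformation PC scores."""

    points: np.ndarray
    subject_id: str
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] != N_HOMOLOGOUS_TIMES:
            raise IncompleteTrajectoryError(
                f"a trajectory has {N_HOMOLOGOUS_TIMES} rows, got {self.points.shape}"
            )
        if self.points.shape[1] < 2:
            raise IncompleteTrajectoryError("a trajectory needs q >= 2 dimensions")

    @property
    def q(self) -> int:
        return self.points.shape[1]


@dataclass
class TrajectoryAttributes:
    """Scalar descriptors of one trajectory: shape scores, size, orientation."""

    shape_scores: np.ndarray
    size: float
    angle_12: float
    angle_13: float
    subject_id: str
    group: str = "unknown"


@dataclass
class TrajectoryGPAResult:
    """Anchor-aligned trajectories and their mean."""

    aligned: np.ndarray           # (n, 12, q)
    mean: np.ndarray              # (12, q)
    subject_ids: list[str]
    groups: list[str]
    anchors: tuple[int, ...]
    iterations: int


def build_trajectory(
    scores: np.ndarray | DeformationPCA,
    q: int = 3,
    subject_id: str = "",
    group: str = "unknown",
) -> Trajectory:
    """Assemble a 12 x q trajectory from a subject's deformation PC scores.

    ``scores`` is either a (12, n_components) matrix ordered by homologous
    time or a :class:`DeformationPCA` (then ``subject_id`` selects the
    subject). The first ``q`` score columns become the trajectory landmarks.
    """
    if isinstance(scores, DeformationPCA):
        mat = scores.trajectory_scores(subject_id)
        idx = scores.subject_ids.index(subject_id)
        group = scores.groups[idx]
    else:
        mat = np.asarray(scores, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != N_HOMOLOGOUS_TIMES:
        raise IncompleteTrajectoryError(
            f"expected scores at all {N_HOMOLOGOUS_TIMES} homologous times, "
            f"got shape {mat.shape}"
        )
    if q > mat.shape[1]:
        raise IncompleteTrajectoryError(
            f"q={q} requested but only {mat.shape[1]} score columns available"
        )
    return Trajectory(points=mat[:, :q].copy(), subject_id=subject_id, group=group)


def build_cohort_trajectories(pca: DeformationPCA, q: int = 3) -> list[Trajectory]:
    """One trajectory per subject of a deformation PCA."""
    return [build_trajectory(pca, q=q, subject_id=sid) for sid in pca.subject_ids]


def _anchor_rows(anchors: Sequence[int], q: int) -> np.ndarray:
    rows = np.asarray(sorted(set(anchors)), dtype=int)
    if np.any(rows < 1) or np.any(rows > N_HOMOLOGOUS_TIMES):
        raise UnderDeterminedAlignmentError(
            f"anchors must be 1-based indices in [1, {N_HOMOLOGOUS_TIMES}]"
        )
    if q >= 3 and rows.size < 3:
        raise UnderDeterminedAlignmentError(
            f"q={q} needs at least 3 anchor landmarks, got {rows.size}"
        )
    return rows - 1


def trajectory_gpa(
    trajectories: Sequence[Trajectory],
    anchors: Sequence[int] = DEFAULT_ANCHORS,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> TrajectoryGPAResult:
    """Second-order GPA in shape space with anchor-only alignment.

    Translation, scale and rotation are estimated from the anchor
    sub-configurations alone (a classic SS GPA on the anchors) and then
    applied to all 12 landmarks; non-anchor landmarks ride along passively
    and cannot influence the fit. Scale is the anchor sub-configuration's
    centroid size; rotations are proper (no reflections).
    """
    if len(trajectories) < 2:
        raise UnderDeterminedAlignmentError("trajectory GPA needs >= 2 trajectories")
    q = trajectories[0].q
    for t in trajectories[1:]:
        if t.q != q:
            raise UnderDeterminedAlignmentError("mixed trajectory dimensions")
    rows = _anchor_rows(anchors, q)

    x = np.stack([t.points for t in trajectories]).astype(float)  # (n, 12, q)
    n = x.shape[0]
    # translation + scale from anchors
    anchor_centroids = x[:, rows, :].mean(axis=1, keepdims=True)
    x = x - anchor_centroids
    anchor_cs = np.linalg.norm(x[:, rows, :], axis=(1, 2))
    if np.any(anchor_cs == 0):
        raise DegenerateConfigurationError("anchor landmarks coincide")
    x = x / anchor_cs[:, None, None]

    mean_anchor = x[0, rows, :].copy()
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            r = _kabsch(x[i, rows, :], mean_anchor)
            x[i] = x[i] @ r
        new_mean = x[:, rows, :].mean(axis=0)
        change = float(np.linalg.norm(new_mean - mean_anchor))
        mean_anchor = new_mean
        if change < tol:
            break
    if change >= tol:
        warnings.warn(
            f"trajectory GPA did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return TrajectoryGPAResult(
        aligned=x,
        mean=x.mean(axis=0),
        subject_ids=[t.subject_id for t in trajectories],
        groups=[t.group for t in trajectories],
        anchors=tuple(sorted(set(anchors))),
        iterations=iterations,
    )


def trajectory_shape_pca(aligned: TrajectoryGPAResult) -> ShapePCA:
    """PCA over vectorized anchor-aligned trajectories (trajectory-shape modes)."""
    return shape_pca(aligned.aligned, center_on="mean")


def trajectory_size(trajectory: Trajectory) -> float:
    """Centroid size of the raw (pre-alignment) trajectory configuration."""
    p = trajectory.points
    cs = float(np.linalg.norm(p - p.mean(axis=0)))
    if cs == 0.0:
        raise DegenerateConfigurationError("degenerate (static) trajectory")
    return cs


def trajectory_orientation(trajectory: Trajectory) -> tuple[float, float]:
    """Orientation angles (degrees) of the R-peak -> end-diastole vector.

    The vector from trajectory landmark 1 (R peak) to landmark 5 (atrial
    end-diastole) is projected on the (PC1, PC2) and (PC1, PC3) planes and
    its direction measured with the two-argument arctangent, in
    (-180, 180] degrees.
    """
    v = trajectory.points[4] - trajectory.points[0]
    if np.allclose(v, 0):
        raise UndefinedOrientationError("landmarks 1 and 5 coincide")
    angle_12 = float(np.degrees(np.arctan2(v[1], v[0])))
    if trajectory.q >= 3:
        angle_13 = float(np.degrees(np.arctan2(v[2], v[0])))
    else:
        angle_13 = float("nan")
    return angle_12, angle_13


def trajectory_attributes(
    trajectories: Sequence[Trajectory],
    anchors: Sequence[int] = DEFAULT_ANCHORS,
) -> tuple[list[TrajectoryAttributes], ShapePCA, TrajectoryGPAResult]:
    """Shape scores, size and orientation for every trajectory of a cohort."""
    aligned = trajectory_gpa(trajectories, anchors=anchors)
    pca = trajectory_shape_pca(aligned)
    attrs = []
    for i, t in enumerate(trajectories):
        a12, a13 = trajectory_orientation(t)
        attrs.append(
            TrajectoryAttributes(
                shape_scores=pca.scores[i],
                size=trajectory_size(t),
                angle_12=a12,
                angle_13=a13,
                subject_id=t.subject_id,
                group=t.group,
            )
        )
    return attrs, pca, aligned
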