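"""Linear-shift parallel transport of deformation trajectories.

When cyclic shape series from many subjects are pooled, an ordinary
GPA + PCA mixes two sources of variation: stable inter-individual shape
differences and the within-cycle deformation that is the actual object of
study. The linear shift (LS) is the tangent-plane form of parallel
transport: each subject's within-cycle deviations from its own reference
shape are re-attached to a common mannequin — here the Grand Mean (GM) of
the whole sample — so that the transported shapes express pure
deformation. Because the mannequin is the GM rather than the end-systolic
frame, both systolic and diastolic states appear as deformed states.

Working in the size-and-shape tangent space makes the shift a plain
vector operation; no re-rotation per subject is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_geometry import LandmarkConfiguration, ShapePCA, gpa, shape_pca
from .errors import InsufficientDataError, ShapeMismatchError
from .temporal_homology import N_HOMOLOGOUS_TIMES, HomologousSeries

__all__ = [
    "TransportedSeries",
    "DeformationPCA",
    "grand_mean_of_series",
    "linear_shift",
    "deformation_pca",
    "deformed_shape_at",
    "displacement_magnitude",
]


@dataclass
class TransportedSeries:
    """One subject's 12 Grand-Mean-centered deformed states.

    By construction the arithmetic mean of the 12 transported shapes is
    exactly the Grand Mean.
    """

    shapes: np.ndarray  # (12, k, 3)
    subject_id: str
    group: str = "unknown"


@dataclass
class DeformationPCA:
    """PCA of all subjects' transported shapes about the Grand Mean.

    Observations are the ``12 * n_subjects`` transported configurations;
    scores are retrievable by (subject, homologous-time index).
    """

    pca: ShapePCA
    grand_mean: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    row_index: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def scores_at(self, subject_id: str, time_index: int) -> np.ndarray:
        """Score vector for one subject at one homologous time (0-based)."""
        return self.pca.scores[self.row_index[(subject_id, time_index)]]

    def scores_by_time(self, time_index: int, n_components: int | None = None) -> np.ndarray:
        """(n_subjects, n_components) scores at one homologous time."""
        rows = [self.row_index[(sid, time_index)] for sid in self.subject_ids]
        s = self.pca.scores[rows]
        return s if n_components is None else s[:, :n_components]

    def trajectory_scores(self, subject_id: str, n_components: int | None = None) -> np.ndarray:
        """(12, n_components) score matrix across homologous times."""
        rows = [self.row_index[(subject_id, t)] for t in range(N_HOMOLOGOUS_TIMES)]
        s = self.pca.scores[rows]
        return s if n_components is None else s[:, :n_components]


def grand_mean_of_series(series: Sequence[HomologousSeries]) -> np.ndarray:
    """Grand Mean over all subjects' homologous-time shapes (the mannequin)."""
    return np.mean([s.as_array() for s in series], axis=(0, 1))


def linear_shift(
    series: HomologousSeries,
    grand_mean: np.ndarray,
    reference: Literal["subject_mean", "first_frame"] = "subject_mean",
) -> TransportedSeries:
    """Transport one subject's within-cycle deformation onto the Grand Mean.

    Each transported shape is ``GM + (shape_t - subject_reference)``. With
    the default reference (the subject's mean over its 12 homologous
    shapes) the transported trajectory is centered on the GM exactly.
    """
    x = series.as_array()  # (12, k, 3)
    gm = np.asarray(grand_mean, dtype=float)
    if gm.shape != x.shape[1:]:
        raise ShapeMismatchError(
            f"grand mean shape {gm.shape} != configuration shape {x.shape[1:]}"
        )
    if reference == "subject_mean":
        ref = x.mean(axis=0)
    elif reference == "first_frame":
        ref = x[0]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return TransportedSeries(
        shapes=gm + (x - ref), subject_id=series.subject_id, group=series.group
    )


def deformation_pca(transported: Sequence[TransportedSeries]) -> DeformationPCA:
    """PCA of pooled transported shapes, centered on the Grand Mean.

    The centering vector is the mean of the transported observations; with
    the subject-mean shift it coincides with the Grand Mean by
    construction.
    """
    if len(transported) < 2:
        raise InsufficientDataError("deformation PCA needs at least 2 subjects")
    data = np.concatenate([t.shapes for t in transported])  # (12n, k, 3)
    gm = np.mean([t.shapes.mean(axis=0) for t in transported], axis=0)
    pca = shape_pca(data, center_on=gm.reshape(-1))
    row_index = {}
    for i, t in enumerate(transported):
        for j in range(N_HOMOLOGOUS_TIMES):
            row_index[(t.subject_id, j)] = i * N_HOMOLOGOUS_TIMES + j
    return DeformationPCA(
        pca=pca,
        grand_mean=gm,
        subject_ids=[t.subject_id for t in transported],
        groups=[t.group for t in transported],
        row_index=row_index,
    )


def deformed_shape_at(
    pca: DeformationPCA, scores: np.ndarray
) -> LandmarkConfiguration:
    """Deformed state ``GM + sum_i score_i * loading_i`` as a configuration."""
    coords = pca.pca.reconstruct(np.asarray(scores, dtype=float)).reshape(
        pca.grand_mean.shape
    )
    return LandmarkConfiguration(coords)


def displacement_magnitude(
    shape: LandmarkConfiguration | np.ndarray, grand_mean: np.ndarray
) -> np.ndarray:
    """Per-landmark displacement |x - x_GM| (mm), for deformation colormaps."""
    x = shape.coords if isinstance(shape, LandmarkConfiguration) else np.asarray(shape)
    return np.linalg.norm(x - np.asarray(grand_mean), axis=1)
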