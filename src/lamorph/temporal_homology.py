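"""Homologous-time registration of cyclic landmark series.

Cine acquisitions of different subjects have different frame rates and
cycle lengths, so frame-by-frame comparison is meaningless. Three strictly
homologous electromechanical events anchor every cycle — the ECG R peak,
the time of maximal (end-diastolic) atrial volume, and the P peak — and
three equally spaced times are inserted between consecutive anchors,
giving a 12-point grid per cycle (the next R peak opens the next cycle and
is excluded).

Shapes at those times are not picked from the nearest frames: a pooled
size-and-shape GPA + PCA over all observed frames turns each subject's
cine into smooth per-component score traces, which are interpolated at the
grid times and mapped back through the loadings to full landmark
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .core_geometry import (
    LandmarkConfiguration,
    ProcrustesResult,
    ShapePCA,
    Topology,
    gpa,
    shape_pca,
)
from .errors import (
    InvalidEventsError,
    OutOfRangeError,
    ShapeMismatchError,
)

__all__ = [
    "EventAnnotations",
    "CineSequence",
    "HomologousSeries",
    "PooledDecomposition",
    "homologous_time_grid",
    "pooled_observed_decomposition",
    "interpolate_scores",
    "reconstruct_homologous_series",
]

N_HOMOLOGOUS_TIMES = 12
#: 0-based grid positions of the three strictly homologous events (R, ED, P)
EVENT_POSITIONS = (0, 4, 8)


@dataclass(frozen=True)
class EventAnnotations:
    """Electromechanical event times (ms) for one cardiac cycle."""

    t_R: float
    t_ED: float
    t_P: float
    t_R_next: float

    def __post_init__(self) -> None:
        if not (self.t_R < self.t_ED < self.t_P < self.t_R_next):
            raise InvalidEventsError(
                "events must satisfy t_R < t_ED < t_P < t_R_next, got "
                f"({self.t_R}, {self.t_ED}, {self.t_P}, {self.t_R_next})"
            )


@dataclass
class CineSequence:
    """One subject's observed cine: ordered frames, times, and events."""

    frames: list[LandmarkConfiguration]
    times: np.ndarray
    events: EventAnnotations
    subject_id: str
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != self.times.shape[0]:
            raise ShapeMismatchError("frame count does not match time count")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidEventsError("frame times must be strictly increasing")
        if self.times[0] > self.events.t_R or self.times[-1] < self.events.t_R_next:
            raise InvalidEventsError(
                "frames must span [t_R, t_R_next]: times "
                f"[{self.times[0]}, {self.times[-1]}] vs events "
                f"[{self.events.t_R}, {self.events.t_R_next}]"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_landmarks(self) -> int:
        return self.frames[0].n_landmarks


@dataclass
class HomologousSeries:
    """Twelve reconstructed configurations at homologous times."""

    shapes: list[LandmarkConfiguration]
    homologous_times: np.ndarray
    subject_id: str
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.homologous_times = np.asarray(self.homologous_times, dtype=float)
        if len(self.shapes) != N_HOMOLOGOUS_TIMES:
            raise InvalidEventsError(
                f"a homologous series has exactly {N_HOMOLOGOUS_TIMES} shapes"
            )

    def as_array(self) -> np.ndarray:
        return np.stack([s.coords for s in self.shapes])


def homologous_time_grid(events: EventAnnotations) -> np.ndarray:
    """Twelve homologous times from three annotated events.

    Each of the three inter-event intervals [t_R, t_ED], [t_ED, t_P],
    [t_P, t_R_next] contributes its left endpoint plus 3 equally spaced
    interior times; the closing t_R_next belongs to the next cycle and is
    excluded. Positions 0, 4, 8 (0-based) are therefore exactly t_R, t_ED
    and t_P.
    """
    anchors = (events.t_R, events.t_ED, events.t_P, events.t_R_next)
    grid = np.concatenate(
        [np.linspace(a, b, 5)[:4] for a, b in zip(anchors[:-1], anchors[1:])]
    )
    return grid


@dataclass
class PooledDecomposition:
    """Pooled SSS GPA + PCA over all observed frames of a cohort.

    Frame ordering inside ``pca.scores`` follows the cohort order; the
    per-subject row ranges are recorded so scores are retrievable by
    subject.
    """

    gpa_result: ProcrustesResult
    pca: ShapePCA
    subjects: list[CineSequence]
    frame_slices: dict[str, slice] = field(default_factory=dict)

    def scores_for(self, subject_id: str) -> np.ndarray:
        return self.pca.scores[self.frame_slices[subject_id]]

    def times_for(self, subject_id: str) -> np.ndarray:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s.times
        raise KeyError(subject_id)


def pooled_observed_decomposition(
    cohort: Sequence[CineSequence],
    tol: float = 1e-10,
    max_iter: int = 200,
    pooling_mode: Literal["pooled", "per_subject"] = "pooled",
) -> PooledDecomposition:
    """One size-and-shape GPA + PCA over all observed frames of all subjects.

    A single pooled alignment puts every frame of every subject in one
    common SSS frame, which the subsequent linear-shift step requires for
    inter-subject comparability. ``pooling_mode="per_subject"`` runs one
    GPA per subject and then aligns the per-subject means (sensitivity
    analysis only; scores are still pooled for the PCA).
    """
    if len(cohort) < 2:
        raise ShapeMismatchError("pooled decomposition needs at least 2 subjects")
    k = cohort[0].n_landmarks
    for s in cohort:
        if s.n_landmarks != k:
            raise ShapeMismatchError(
                f"subject {s.subject_id} has {s.n_landmarks} landmarks, expected {k}"
            )
    all_frames: list[np.ndarray] = []
    frame_slices: dict[str, slice] = {}
    start = 0
    for s in cohort:
        all_frames.extend(f.coords for f in s.frames)
        frame_slices[s.subject_id] = slice(start, start + s.n_frames)
        start += s.n_frames

    if pooling_mode == "pooled":
        result = gpa(all_frames, space="SSS", tol=tol, max_iter=max_iter)
    elif pooling_mode == "per_subject":
        aligned_blocks = []
        for s in cohort:
            sub = gpa([f.coords for f in s.frames], space="SSS", tol=tol,
                      max_iter=max_iter)
            aligned_blocks.append(sub)
        # rotate each subject block so its mean matches the mean of means
        means = [b.grand_mean for b in aligned_blocks]
        mean_gpa = gpa(means, space="SSS", tol=tol, max_iter=max_iter)
        aligned = np.concatenate(
            [b.aligned @ r for b, r in zip(aligned_blocks, mean_gpa.rotations)]
        )
        result = ProcrustesResult(
            aligned=aligned,
            grand_mean=aligned.mean(axis=0),
            rotations=np.tile(np.eye(3), (len(all_frames), 1, 1)),
            scales=np.ones(len(all_frames)),
            space="SSS",
            iterations=mean_gpa.iterations,
            final_change=mean_gpa.final_change,
        )
    else:
        raise ValueError(f"unknown pooling_mode {pooling_mode!r}")

    pca = shape_pca(result, center_on="mean")
    return PooledDecomposition(
        gpa_result=result, pca=pca, subjects=list(cohort),
        frame_slices=frame_slices,
    )


def interpolate_scores(
    times: np.ndarray,
    score_matrix: np.ndarray,
    query_times: np.ndarray,
    method: Literal["cubic", "linear"] = "cubic",
) -> np.ndarray:
    """Componentwise interpolation of PC score traces at query times.

    Natural cubic splines by default (``method="linear"`` for piecewise
    linear). Query times must lie within the observed span — no
    extrapolation.
    """
    times = np.asarray(times, dtype=float)
    scores = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    if scores.shape[0] != times.shape[0]:
        scores = scores.T
    if scores.shape[0] != times.shape[0]:
        raise ShapeMismatchError("score matrix rows must match time count")
    q = np.asarray(query_times, dtype=float)
    if q.min() < times.min() - 1e-9 or q.max() > times.max() + 1e-9:
        raise OutOfRangeError(
            f"query times [{q.min()}, {q.max()}] outside observed span "
            f"[{times.min()}, {times.max()}]"
        )
    if method == "cubic":
        return CubicSpline(times, scores, axis=0, bc_type="natural")(q)
    if method == "linear":
        return np.stack(
            [np.interp(q, times, scores[:, j]) for j in range(scores.shape[1])],
            axis=1,
        )
    raise ValueError(f"unknown interpolation method {method!r}")


def reconstruct_homologous_series(
    subject: CineSequence,
    decomposition: PooledDecomposition,
    n_components: int | None = None,
    method: Literal["cubic", "linear"] = "cubic",
) -> HomologousSeries:
    """Rebuild one subject's 12 homologous shapes from interpolated scores.

    All PCs are retained by default, making reconstruction lossless at
    observed times; ``n_components`` truncates the basis.
    """
    if subject.subject_id not in decomposition.frame_slices:
        raise KeyError(f"subject {subject.subject_id} not in the decomposition")
    grid = homologous_time_grid(subject.events)
    scores = decomposition.scores_for(subject.subject_id)
    if n_components is not None:
        scores = scores[:, :n_components]
    interp = interpolate_scores(subject.times, scores, grid, method=method)
    pca = decomposition.pca
    flat = pca.mean_vector + interp @ pca.loadings[:, : interp.shape[1]].T
    k = subject.n_landmarks
    topo = subject.frames[0].topology
    shapes = [
        LandmarkConfiguration(flat[i].reshape(k, 3), topology=topo)
        for i in range(N_HOMOLOGOUS_TIMES)
    ]
    return HomologousSeries(
        shapes=shapes,
        homologous_times=grid,
        subject_id=subject.subject_id,
        group=subject.group,
    )
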