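"""Procrustes machinery for landmark configurations.

Implements the geometric core of the pipeline: centering, centroid size,
optimal rotation (Kabsch, reflections excluded), Generalized Procrustes
Analysis (GPA) in either the Shape Space (SS, configurations rescaled to
unit centroid size) or the Size-and-Shape Space (SSS, sizes retained as a
biological attribute), and principal component analysis of the aligned
configurations.

The SSS is the natural arena for cardiac landmark data: after translation
and rotation the configurations live in a (locally) Euclidean tangent space
at the Grand Mean, so PCA can be applied directly without a further
spherical projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    InsufficientDataError,
    InvalidInputError,
    ShapeMismatchError,
)

__all__ = [
    "Topology",
    "LandmarkConfiguration",
    "ProcrustesResult",
    "ShapePCA",
    "center",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "shape_pca",
]


@dataclass(frozen=True)
class Topology:
    """Ring/apex surface topology of an atrial landmark cloud.

    The endocardial surface is sampled on ``rings`` horizontal circles of
    ``points_per_ring`` landmarks each, ordered base (mitral plane) to apex,
    plus a single apex point at ``apex_index``.
    """

    rings: int = 36
    points_per_ring: int = 36
    apex_index: int = 1296

    @property
    def n_landmarks(self) -> int:
        return self.rings * self.points_per_ring + 1

    def ring_indices(self, ring: int) -> np.ndarray:
        """Landmark indices of one ring (0-based, base ring is 0)."""
        start = ring * self.points_per_ring
        return np.arange(start, start + self.points_per_ring)


@dataclass
class LandmarkConfiguration:
    """One k x 3 landmark cloud in millimetres.

    Parameters
    ----------
    coords
        ``(k, 3)`` array of landmark coordinates (mm).
    topology
        Optional ring/apex topology; when present ``k`` must equal
        ``rings * points_per_ring + 1``.
    """

    coords: np.ndarray
    topology: Topology | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidInputError(
                f"coords must be (k, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("coords contain non-finite values")
        if self.topology is not None:
            expected = self.topology.n_landmarks
            if self.coords.shape[0] != expected:
                raise ShapeMismatchError(
                    f"topology implies {expected} landmarks, "
                    f"got {self.coords.shape[0]}"
                )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(coords, topology=self.topology)


def _as_matrix(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    x = np.asarray(config, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError(f"expected a 2-D landmark matrix, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("landmark matrix contains non-finite values")
    return x


def center(config):
    """Translate a configuration so its centroid is at the origin.

    Returns the same type as the input (``LandmarkConfiguration`` in,
    ``LandmarkConfiguration`` out; bare array in, bare array out).
    """
    x = _as_matrix(config)
    centered = x - x.mean(axis=0)
    if isinstance(config, LandmarkConfiguration):
        return config.with_coords(centered)
    return centered


def centroid_size(config) -> float:
    """Centroid size: root summed squared distance of landmarks from their centroid.

    The standard morphometric size measure; invariant to translation and
    rotation and homogeneous of degree one under scaling.
    """
    x = _as_matrix(config)
    if x.shape[0] < 2:
        raise DegenerateConfigurationError("centroid size needs at least 2 landmarks")
    cs = float(np.linalg.norm(x - x.mean(axis=0)))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return cs


def optimal_rotation(moving, target) -> np.ndarray:
    """Proper rotation (det = +1) minimising ||moving @ R - target||_F.

    Both configurations must be centered and share the landmark count.
    Reflections are excluded: anatomical landmark clouds must not mirror.
    """
    a = _as_matrix(moving)
    b = _as_matrix(target)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    return _kabsch(a, b)


def _kabsch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (m x m, det +1) minimising ||a R - b||."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    m = a.shape[1]
    corr = np.ones(m)
    corr[-1] = d if d != 0 else 1.0
    return (u * corr) @ vt


@dataclass
class ProcrustesResult:
    """Output of a Generalized Procrustes Analysis.

    ``aligned`` holds the superimposed configurations as an ``(n, k, m)``
    array; ``grand_mean`` is their arithmetic mean. In SSS mode every scale
    is 1 and centroid sizes are preserved; in SS mode each configuration was
    rescaled to unit centroid size (``scales`` stores the applied factors).
    """

    aligned: np.ndarray
    grand_mean: np.ndarray
    rotations: np.ndarray
    scales: np.ndarray
    space: Literal["SS", "SSS"]
    iterations: int
    final_change: float
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_configurations(self) -> int:
        return self.aligned.shape[0]


def gpa(
    configs: Sequence,
    space: Literal["SS", "SSS"] = "SSS",
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ProcrustesResult:
    """Generalized Procrustes Analysis.

    Iteratively superimposes ``configs`` on their evolving mean by
    translation and rotation — and, in SS mode only, a prior rescaling of
    every configuration to unit centroid size — until the Frobenius change
    of the mean drops below ``tol``.

    Parameters
    ----------
    configs
        Sequence of ``(k, m)`` arrays or ``LandmarkConfiguration`` objects
        with identical ``k``.
    space
        ``"SSS"`` (default) keeps sizes untouched; ``"SS"`` scales each
        configuration to unit centroid size before alignment.
    """
    if len(configs) < 2:
        raise InsufficientDataError("GPA needs at least 2 configurations")
    mats = [_as_matrix(c) for c in configs]
    k, m = mats[0].shape
    for x in mats[1:]:
        if x.shape != (k, m):
            raise ShapeMismatchError(
                f"mixed landmark counts: {(k, m)} vs {x.shape}"
            )
    x = np.stack(mats)                     # (n, k, m)
    n = x.shape[0]
    x = x - x.mean(axis=1, keepdims=True)  # center every configuration

    scales = np.ones(n)
    if space == "SS":
        cs = np.linalg.norm(x, axis=(1, 2))
        if np.any(cs == 0):
            raise DegenerateConfigurationError("degenerate configuration in GPA")
        scales = 1.0 / cs
        x = x * scales[:, None, None]
    elif space != "SSS":
        raise ValueError(f"space must be 'SS' or 'SSS', got {space!r}")

    rotations = np.tile(np.eye(m), (n, 1, 1))
    mean = x[0].copy()
    change = np.inf
    objective = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            r = _kabsch(x[i], mean)
            x[i] = x[i] @ r
            rotations[i] = rotations[i] @ r
        new_mean = x.mean(axis=0)
        objective.append(float(np.sum((x - new_mean) ** 2)))
        change = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last mean change {change:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return ProcrustesResult(
        aligned=x,
        grand_mean=mean,
        rotations=rotations,
        scales=scales,
        space=space,
        iterations=iterations,
        final_change=change,
        converged=converged,
        objective_history=objective,
    )


@dataclass
class ShapePCA:
    """PCA of vectorized aligned configurations.

    ``mean_vector`` is the centering vector (the sample mean, or an external
    reference such as the Grand Mean), ``loadings`` the orthonormal
    component directions as columns of a ``(p, n_components)`` matrix, and
    ``scores`` the per-observation coordinates along them.
    """

    mean_vector: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    landmark_shape: tuple[int, int] | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Rebuild vectorized configurations from score vectors.

        Accepts scores of length <= ``n_components``; missing trailing
        components are treated as zero.
        """
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        q = s.shape[1]
        if q > self.n_components:
            raise InvalidInputError(
                f"{q} scores given but only {self.n_components} components exist"
            )
        flat = self.mean_vector + s @ self.loadings[:, :q].T
        return flat[0] if np.ndim(scores) == 1 else flat

    def reconstruct_configuration(self, scores: np.ndarray) -> np.ndarray:
        """Rebuild one ``(k, m)`` configuration from a single score vector."""
        if self.landmark_shape is None:
            raise InvalidInputError("landmark_shape unknown for this PCA")
        return self.reconstruct(np.asarray(scores)).reshape(self.landmark_shape)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: largest-|entry| of each loading positive."""
    for j in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[idx, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def shape_pca(
    result: ProcrustesResult | np.ndarray,
    center_on: np.ndarray | Literal["mean"] = "mean",
) -> ShapePCA:
    """PCA of aligned configurations via SVD of the centered data matrix.

    Parameters
    ----------
    result
        A :class:`ProcrustesResult` or a raw ``(n, k, m)`` / ``(n, p)``
        observation array.
    center_on
        ``"mean"`` (default) centers on the sample mean; an explicit vector
        (or ``(k, m)`` matrix) centers on an external reference — used to
        run the deformation PCA about the Grand Mean mannequin.
    """
    if isinstance(result, ProcrustesResult):
        data = result.aligned
    else:
        data = np.asarray(result, dtype=float)
    if data.ndim == 3:
        n, k, m = data.shape
        landmark_shape = (k, m)
        flat = data.reshape(n, k * m)
    else:
        landmark_shape = None
        flat = data
    n, p = flat.shape
    if n < 2:
        raise InsufficientDataError("PCA needs at least 2 observations")

    if isinstance(center_on, str):
        if center_on != "mean":
            raise ValueError(f"center_on must be 'mean' or a vector, got {center_on!r}")
        mean_vector = flat.mean(axis=0)
    else:
        mean_vector = np.asarray(center_on, dtype=float).reshape(-1)
        if mean_vector.shape[0] != p:
            raise ShapeMismatchError(
                f"center vector length {mean_vector.shape[0]} != data dim {p}"
            )
    centered = flat - mean_vector
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # keep at most n components; eigenvalues of the covariance (ddof=1)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T.copy()
    scores = u * s
    _fix_signs(loadings, scores)
    total = eigenvalues.sum()
    if total > 0:
        variance_fraction = eigenvalues / total
    else:
        variance_fraction = np.zeros_like(eigenvalues)
    return ShapePCA(
        mean_vector=mean_vector,
        eigenvalues=eigenvalues,
        loadings=loadings,
        scores=scores,
        variance_fraction=variance_fraction,
        cumulative_fraction=np.cumsum(variance_fraction),
        landmark_shape=landmark_shape,
    )
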