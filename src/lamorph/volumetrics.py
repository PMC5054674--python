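"""Left-atrial cavity volume and phasic function indicators.

The atrial endocardium is sampled on rings of landmarks (base ring at the
mitral plane, apex point closing the far end). A closed triangulated
surface is built from that topology — adjacent rings stitched with quads
split into triangles, the open base capped by a centroid fan, the last
ring closed onto the apex — and the enclosed volume computed by the
divergence theorem (signed tetrahedra against the origin).

From the 12-point volume curve over homologous times the standard phasic
indicators of atrial function are derived:

    v_max   — maximal volume, at atrial end-diastole (grid position 5)
    v_min   — minimal volume, after the booster-pump contraction
    v_preA  — volume at the P peak (grid position 9), pre-atrial-contraction

    ef_global    = 100 (v_max - v_min) / v_max      (total emptying)
    ef_reservoir = 100 (v_max - v_min) / v_min      (expansion index)
    ef_conduit   = 100 (v_max - v_preA) / v_max     (passive emptying)
    ef_booster   = 100 (v_preA - v_min) / v_preA    (active emptying)
    booster_abs  = v_preA - v_min                   (ml)

Each formula is stated here explicitly so users can audit the convention;
denominator choices vary in the clinical literature and are switchable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_geometry import LandmarkConfiguration, Topology
from .errors import InvalidInputError
from .temporal_homology import EVENT_POSITIONS, HomologousSeries

__all__ = [
    "VolumeCurve",
    "VolumetricIndicators",
    "mesh_volume",
    "volume_curve",
    "la_function_indicators",
    "classic_global_parameters",
]


@dataclass
class VolumeCurve:
    """Volumes (ml) at the 12 homologous times (ms)."""

    volumes: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.volumes.shape != self.times.shape:
            raise InvalidInputError("volumes and times must have equal length")


@dataclass
class VolumetricIndicators:
    """Phasic left-atrial function indicators (volumes in ml, EFs in %)."""

    v_max: float
    v_min: float
    v_preA: float
    ef_global: float
    ef_reservoir: float
    ef_conduit: float
    ef_booster: float
    booster_abs: float
    flagged: bool = False


def _surface_triangles(topology: Topology) -> np.ndarray:
    """Triangle index array closing the ring/apex grid (centroid fan uses k)."""
    r, p = topology.rings, topology.points_per_ring
    tris = []
    # band between consecutive rings
    for ring in range(r - 1):
        a = ring * p
        b = (ring + 1) * p
        for j in range(p):
            jn = (j + 1) % p
            tris.append((a + j, a + jn, b + j))
            tris.append((a + jn, b + jn, b + j))
    # apex cap: last ring onto the apex point
    last = (r - 1) * p
    for j in range(p):
        jn = (j + 1) % p
        tris.append((last + j, last + jn, topology.apex_index))
    # base cap: centroid fan over ring 0; centroid appended as vertex k
    k = topology.n_landmarks
    for j in range(p):
        jn = (j + 1) % p
        tris.append((jn, j, k))
    return np.asarray(tris, dtype=int)


def mesh_volume(config: LandmarkConfiguration) -> float:
    """Enclosed volume (ml) of the closed ring/apex surface.

    Uses the divergence theorem: the sum of signed tetrahedron volumes
    spanned by each surface triangle and the origin. The result is
    orientation-corrected to be positive. Degenerate self-intersecting
    grids yield a best-effort signed volume with a warning.
    """
    if config.topology is None:
        raise InvalidInputError("mesh_volume requires ring/apex topology")
    topo = config.topology
    base_centroid = config.coords[topo.ring_indices(0)].mean(axis=0)
    verts = np.vstack([config.coords, base_centroid])
    tris = _surface_triangles(topo)
    v0, v1, v2 = (verts[tris[:, i]] for i in range(3))
    signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
    vol_mm3 = abs(signed)
    if vol_mm3 == 0.0:
        warnings.warn("degenerate surface: zero enclosed volume", RuntimeWarning,
                      stacklevel=2)
    return vol_mm3 / 1000.0  # mm^3 -> ml


def volume_curve(series: HomologousSeries) -> VolumeCurve:
    """Volume at each of the 12 homologous times of one subject."""
    vols = np.array([mesh_volume(s) for s in series.shapes])
    return VolumeCurve(volumes=vols, times=series.homologous_times)


def la_function_indicators(
    curve: VolumeCurve,
    ed_position: int = EVENT_POSITIONS[1],
    p_position: int = EVENT_POSITIONS[2],
    reservoir_denominator: str = "v_min",
) -> VolumetricIndicators:
    """Phasic function indicators from a 12-point volume curve.

    ``v_max`` is read at the end-diastolic grid position unless the global
    curve maximum exceeds it by 5% or more (then the maximum wins, with a
    warning). ``v_preA`` is the volume at the P-peak position. A noisy
    curve with ``v_preA`` outside [v_min, v_max] is flagged, not fatal.
    """
    v = curve.volumes
    if np.any(v <= 0):
        raise InvalidInputError("volumes must be positive")
    v_ed = float(v[ed_position])
    v_global_max = float(v.max())
    if v_global_max > v_ed * 1.05:
        warnings.warn(
            f"curve maximum {v_global_max:.1f} ml exceeds end-diastolic volume "
            f"{v_ed:.1f} ml by >5%; using the maximum",
            RuntimeWarning,
            stacklevel=2,
        )
        v_max = v_global_max
    else:
        v_max = v_ed
    v_min = float(v.min())
    v_preA = float(v[p_position])
    flagged = not (v_min - 1e-9 <= v_preA <= v_max + 1e-9)
    if flagged:
        warnings.warn("v_preA outside [v_min, v_max]; indicators flagged",
                      RuntimeWarning, stacklevel=2)
    if reservoir_denominator == "v_min":
        ef_reservoir = 100.0 * (v_max - v_min) / v_min
    elif reservoir_denominator == "v_max":
        ef_reservoir = 100.0 * (v_max - v_min) / v_max
    else:
        raise ValueError(f"unknown reservoir denominator {reservoir_denominator!r}")
    return VolumetricIndicators(
        v_max=v_max,
        v_min=v_min,
        v_preA=v_preA,
        ef_global=100.0 * (v_max - v_min) / v_max,
        ef_reservoir=ef_reservoir,
        ef_conduit=100.0 * (v_max - v_preA) / v_max,
        ef_booster=100.0 * (v_preA - v_min) / v_preA,
        booster_abs=v_preA - v_min,
        flagged=flagged,
    )


def classic_global_parameters(series: HomologousSeries) -> dict[str, np.ndarray]:
    """Surrogate classic global 3DSTE-style parameters per homologous time.

    Strains are referenced to the end-systolic (minimum-volume) frame, the
    convention of device-derived speckle-tracking outputs:

    - global longitudinal strain (%): per-meridian polyline length change
      (base ring to apex along one angular position), averaged over
      meridians;
    - global circumferential strain (%): per-ring closed-perimeter change,
      averaged over rings;
    - volume (ml) via :func:`mesh_volume`.
    """
    topo = series.shapes[0].topology
    if topo is None:
        raise InvalidInputError("classic parameters require ring/apex topology")
    r, p = topo.rings, topo.points_per_ring
    frames = series.as_array()  # (12, k, 3)
    vols = np.array([mesh_volume(s) for s in series.shapes])
    es = int(np.argmin(vols))

    rings = frames[:, : r * p, :].reshape(len(frames), r, p, 3)
    apex = frames[:, topo.apex_index, :]  # (12, 3)

    # meridian lengths: along rings at fixed angular index, then to the apex
    seg = np.linalg.norm(np.diff(rings, axis=1), axis=3).sum(axis=1)  # (12, p)
    tip = np.linalg.norm(rings[:, -1, :, :] - apex[:, None, :], axis=2)  # (12, p)
    meridian_len = seg + tip

    # ring perimeters (closed polygons)
    closed = np.concatenate([rings, rings[:, :, :1, :]], axis=2)
    perim = np.linalg.norm(np.diff(closed, axis=2), axis=3).sum(axis=2)  # (12, r)

    gls = 100.0 * (meridian_len / meridian_len[es] - 1.0).mean(axis=1)
    gcs = 100.0 * (perim / perim[es] - 1.0).mean(axis=1)
    return {"gls": gls, "gcs": gcs, "volume": vols, "es_index": es}
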