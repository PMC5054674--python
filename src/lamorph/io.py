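"""File formats: per-subject landmark cines, homologous series, deformation PCA.

On-disk dialect (all indices 0-based):

- one CSV per subject with columns ``frame_index, time_ms, landmark_index,
  x, y, z`` (mm), long format;
- a sidecar JSON per subject: ``{"rings": 36, "points_per_ring": 36,
  "apex_index": 1296, "subject_id": ..., "group": ...,
  "events": {"R": ..., "ED": ..., "P": ..., "R_next": ...}}``;
- a cohort JSON listing ``{"csv": ..., "json": ...}`` path pairs;
- HDF5 containers for the 12-shape homologous series and for the
  deformation PCA (grand mean, loadings, eigenvalues, per-observation
  scores with subject/time bookkeeping).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .core_geometry import LandmarkConfiguration, ShapePCA, Topology
from .errors import InvalidInputError
from .parallel_transport import DeformationPCA
from .temporal_homology import (
    N_HOMOLOGOUS_TIMES,
    CineSequence,
    EventAnnotations,
    HomologousSeries,
)

__all__ = [
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
    "write_series",
    "read_series",
    "write_deformation",
    "read_deformation",
    "scores_to_tidy",
]


def write_subject(subject: CineSequence, csv_path, json_path) -> None:
    """Write one subject's cine as CSV + sidecar JSON."""
    rows = []
    k = subject.n_landmarks
    lm = np.arange(k)
    for fi, (frame, t) in enumerate(zip(subject.frames, subject.times)):
        rows.append(
            pd.DataFrame(
                {
                    "frame_index": fi,
                    "time_ms": t,
                    "landmark_index": lm,
                    "x": frame.coords[:, 0],
                    "y": frame.coords[:, 1],
                    "z": frame.coords[:, 2],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False,
                                              float_format="%.6g")
    topo = subject.frames[0].topology
    meta = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "events": {
            "R": subject.events.t_R,
            "ED": subject.events.t_ED,
            "P": subject.events.t_P,
            "R_next": subject.events.t_R_next,
        },
    }
    if topo is not None:
        meta.update(
            rings=topo.rings,
            points_per_ring=topo.points_per_ring,
            apex_index=topo.apex_index,
        )
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_subject(csv_path, json_path) -> CineSequence:
    """Read one subject's cine from the CSV + JSON dialect."""
    meta = json.loads(Path(json_path).read_text())
    topo = None
    if "rings" in meta:
        topo = Topology(
            rings=int(meta["rings"]),
            points_per_ring=int(meta["points_per_ring"]),
            apex_index=int(meta["apex_index"]),
        )
    df = pd.read_csv(csv_path)
    required = {"frame_index", "time_ms", "landmark_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"cine CSV must have columns {sorted(required)}")
    frames = []
    times = []
    for fi, sub in df.groupby("frame_index", sort=True):
        sub = sub.sort_values("landmark_index")
        frames.append(
            LandmarkConfiguration(sub[["x", "y", "z"]].to_numpy(), topology=topo)
        )
        times.append(float(sub["time_ms"].iloc[0]))
    ev = meta["events"]
    return CineSequence(
        frames=frames,
        times=np.asarray(times),
        events=EventAnnotations(ev["R"], ev["ED"], ev["P"], ev["R_next"]),
        subject_id=str(meta.get("subject_id", Path(csv_path).stem)),
        group=str(meta.get("group", "unknown")),
    )


def write_cohort(cohort: Sequence[CineSequence], out_dir) -> Path:
    """Write a cohort directory with per-subject files and a cohort JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in cohort:
        csv_p = out / f"{s.subject_id}.csv"
        json_p = out / f"{s.subject_id}.json"
        write_subject(s, csv_p, json_p)
        entries.append({"csv": csv_p.name, "json": json_p.name})
    index = out / "cohort.json"
    index.write_text(json.dumps({"subjects": entries}, indent=1))
    return index


def read_cohort(cohort_json) -> list[CineSequence]:
    """Read all subjects listed in a cohort JSON."""
    path = Path(cohort_json)
    index = json.loads(path.read_text())
    return [
        read_subject(path.parent / e["csv"], path.parent / e["json"])
        for e in index["subjects"]
    ]


def write_series(series: Sequence[HomologousSeries], h5_path) -> None:
    """Store homologous series (12 x k x 3 per subject) in HDF5."""
    with h5py.File(h5_path, "w") as f:
        for s in series:
            g = f.create_group(s.subject_id)
            g.create_dataset("shapes", data=s.as_array())
            g.create_dataset("times", data=s.homologous_times)
            g.attrs["group"] = s.group
            topo = s.shapes[0].topology
            if topo is not None:
                g.attrs["rings"] = topo.rings
                g.attrs["points_per_ring"] = topo.points_per_ring
                g.attrs["apex_index"] = topo.apex_index


def read_series(h5_path) -> list[HomologousSeries]:
    out = []
    with h5py.File(h5_path, "r") as f:
        for sid in f:
            g = f[sid]
            topo = None
            if "rings" in g.attrs:
                topo = Topology(
                    rings=int(g.attrs["rings"]),
                    points_per_ring=int(g.attrs["points_per_ring"]),
                    apex_index=int(g.attrs["apex_index"]),
                )
            shapes = [
                LandmarkConfiguration(c, topology=topo) for c in g["shapes"][()]
            ]
            out.append(
                HomologousSeries(
                    shapes=shapes,
                    homologous_times=g["times"][()],
                    subject_id=sid,
                    group=str(g.attrs["group"]),
                )
            )
    return out


def write_deformation(defo: DeformationPCA, h5_path) -> None:
    """Store a deformation PCA (mannequin, basis, scores) in HDF5."""
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("grand_mean", data=defo.grand_mean)
        f.create_dataset("loadings", data=defo.pca.loadings)
        f.create_dataset("eigenvalues", data=defo.pca.eigenvalues)
        f.create_dataset("scores", data=defo.pca.scores)
        f.create_dataset("mean_vector", data=defo.pca.mean_vector)
        str_dt = h5py.string_dtype()
        f.create_dataset("subject_ids", data=defo.subject_ids, dtype=str_dt)
        f.create_dataset("groups", data=defo.groups, dtype=str_dt)


def read_deformation(h5_path) -> DeformationPCA:
    with h5py.File(h5_path, "r") as f:
        gm = f["grand_mean"][()]
        eigenvalues = f["eigenvalues"][()]
        total = eigenvalues.sum()
        vf = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
        pca = ShapePCA(
            mean_vector=f["mean_vector"][()],
            eigenvalues=eigenvalues,
            loadings=f["loadings"][()],
            scores=f["scores"][()],
            variance_fraction=vf,
            cumulative_fraction=np.cumsum(vf),
            landmark_shape=tuple(gm.shape),
        )
        subject_ids = [s.decode() for s in f["subject_ids"][()]]
        groups = [s.decode() for s in f["groups"][()]]
    row_index = {
        (sid, t): i * N_HOMOLOGOUS_TIMES + t
        for i, sid in enumerate(subject_ids)
        for t in range(N_HOMOLOGOUS_TIMES)
    }
    return DeformationPCA(
        pca=pca, grand_mean=gm, subject_ids=subject_ids, groups=groups,
        row_index=row_index,
    )


def scores_to_tidy(defo: DeformationPCA, n_components: int | None = None) -> pd.DataFrame:
    """Tidy per-(subject, time, PC) score table."""
    n_comp = n_components or defo.pca.n_components
    rows = []
    for i, sid in enumerate(defo.subject_ids):
        for t in range(N_HOMOLOGOUS_TIMES):
            s = defo.pca.scores[defo.row_index[(sid, t)]][:n_comp]
            for j, val in enumerate(s):
                rows.append((sid, defo.groups[i], t, j + 1, val))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "time_index", "pc_index", "score"]
    )
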