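"""File formats: NIfTI label volumes, TrackVis .trk, plain-text polylines,
CSV connectomes, and cohort manifests.

Conventions
-----------
* Streamline coordinates are world-space millimetres (RAS) everywhere;
  .trk files are written with the parcellation's voxel-to-world affine
  in the header and read back to mm via nibabel's rasmm conversion.
* The text polyline format is whitespace-delimited: ``#`` lines are
  comments, each streamline is a ``track <n_points>`` line followed by
  that many ``x y z`` rows.
* A cohort on disk is a manifest CSV (columns subject_id, group, path)
  pointing at one adjacency-matrix CSV per subject, plus an optional
  ground-truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram
from nibabel.streamlines.trk import TrkFile

from .core import Cohort, Connectome, Parcellation, StreamlineSet
from .synthetic import GroundTruth

__all__ = [
    "save_parcellation", "load_parcellation",
    "save_trk", "load_trk",
    "save_polylines_text", "load_polylines_text",
    "save_connectome_csv", "load_connectome_csv",
    "save_edge_list", "save_cohort", "load_cohort",
    "save_ground_truth", "load_ground_truth",
]


# -- parcellations -------------------------------------------------------

def save_parcellation(parc: Parcellation, nifti_path, regions_path) -> None:
    img = nib.Nifti1Image(parc.label_volume.astype(np.int32), parc.affine)
    nib.save(img, str(nifti_path))
    parc.regions.to_csv(regions_path, index=False)


def load_parcellation(nifti_path, regions_path) -> Parcellation:
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    regions = pd.read_csv(regions_path)
    return Parcellation(label_volume=labels, affine=img.affine, regions=regions)


# -- streamlines ---------------------------------------------------------

def save_trk(streamlines: StreamlineSet, path, parcellation: Parcellation) -> None:
    """Write TrackVis .trk; header geometry comes from the parcellation."""
    hdr = TrkFile.create_empty_header()
    hdr["voxel_to_rasmm"] = parcellation.affine.astype(np.float32)
    hdr["voxel_sizes"] = parcellation.voxel_sizes.astype(np.float32)
    hdr["dimensions"] = np.array(parcellation.label_volume.shape, dtype=np.int16)
    hdr["voxel_order"] = b"RAS"
    tg = Tractogram(list(streamlines), affine_to_rasmm=np.eye(4))
    TrkFile(tg, header=hdr).save(str(path))


def load_trk(path) -> StreamlineSet:
    trk = nib.streamlines.load(str(path))  # points come back in rasmm
    return StreamlineSet([np.asarray(s, dtype=float) for s in trk.streamlines],
                         coordinate_space="structural")


def save_polylines_text(streamlines: StreamlineSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# conntrace polylines v1 (mm coordinates)\n")
        fh.write(f"# coordinate_space {streamlines.coordinate_space}\n")
        for pts in streamlines:
            fh.write(f"track {len(pts)}\n")
            for x, y, z in pts:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def load_polylines_text(path) -> StreamlineSet:
    space = "structural"
    streamlines = []
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "coordinate_space":
                    space = parts[1]
                continue
            if not line.startswith("track "):
                raise ValueError(f"malformed polyline file near: {line!r}")
            k = int(line.split()[1])
            pts = [np.fromstring(next(lines), sep=" ") for _ in range(k)]
            streamlines.append(np.vstack(pts))
    return StreamlineSet(streamlines, coordinate_space=space)


# -- connectomes ---------------------------------------------------------

def save_connectome_csv(con: Connectome, matrix_path, nodes_path=None) -> None:
    labels = con.node_labels()
    pd.DataFrame(con.matrix, index=labels, columns=labels).to_csv(matrix_path)
    if nodes_path is not None:
        con.nodes.to_csv(nodes_path, index=False)


def load_connectome_csv(matrix_path, nodes_path=None, subject_id="") -> Connectome:
    df = pd.read_csv(matrix_path, index_col=0)
    M = df.to_numpy()
    if nodes_path is not None:
        nodes = pd.read_csv(nodes_path)
    else:
        labels = [int(c) for c in df.columns]
        nodes = pd.DataFrame({"label": labels,
                              "name": [f"region_{l}" for l in labels],
                              "cx": 0.0, "cy": 0.0, "cz": 0.0})
    return Connectome(matrix=M, nodes=nodes, subject_id=subject_id,
                      total_tracks_retained=int(M.sum() // 2))


def save_edge_list(con: Connectome, path) -> None:
    labels = con.node_labels()
    iu = np.triu_indices(con.n_nodes, k=1)
    w = con.matrix[iu]
    nz = w > 0
    pd.DataFrame({"i": labels[iu[0][nz]], "j": labels[iu[1][nz]],
                  "weight": w[nz]}).to_csv(path, index=False)


# -- cohorts -------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir, truth: GroundTruth | None = None) -> Path:
    """Write per-subject matrix CSVs + manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    labels = cohort.nodes["label"].to_numpy(dtype=int)
    for i in range(cohort.n_subjects):
        rel = f"{cohort.subject_ids[i]}.csv"
        pd.DataFrame(cohort.matrices[i], index=labels, columns=labels) \
            .to_csv(out / rel)
        rows.append({"subject_id": cohort.subject_ids[i],
                     "group": cohort.groups[i], "path": rel})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    cohort.nodes.to_csv(out / "nodes.csv", index=False)
    if truth is not None:
        save_ground_truth(truth, out / "ground_truth.json")
    return manifest


def load_cohort(manifest_path) -> Cohort:
    manifest = Path(manifest_path)
    df = pd.read_csv(manifest)
    mats = []
    for rel in df["path"]:
        m = pd.read_csv(manifest.parent / rel, index_col=0).to_numpy()
        mats.append(m)
    nodes_path = manifest.parent / "nodes.csv"
    nodes = pd.read_csv(nodes_path) if nodes_path.exists() else None
    return Cohort(matrices=np.stack(mats),
                  groups=df["group"].to_numpy(),
                  subject_ids=df["subject_id"].astype(str).tolist(),
                  nodes=nodes)


def save_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_edges": sorted([list(e) for e in truth.planted_edges]),
        "novel_edges": sorted([list(e) for e in truth.novel_edges]),
        "mean_a": np.asarray(truth.mean_a).tolist(),
        "mean_b": np.asarray(truth.mean_b).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        planted_edges=frozenset(tuple(e) for e in d["planted_edges"]),
        novel_edges=frozenset(tuple(e) for e in d["novel_edges"]),
        mean_a=np.asarray(d["mean_a"]),
        mean_b=np.asarray(d["mean_b"]),
    )
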