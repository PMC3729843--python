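"""Core in-memory containers for the connectome pipeline.

A *parcellation* labels brain voxels with integer region ids (0 is
background) and carries the voxel-to-world affine so that streamline
coordinates, given in millimetres, can be mapped onto regions.  A
*streamline set* is a bag of 3-D polylines produced by (or standing in
for) tractography.  A *connectome* is the symmetric, zero-diagonal,
nonnegative-integer region-by-region track-count matrix built from
them, and a *cohort* stacks one connectome per subject together with
binary group labels for statistics and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "StreamlineSet",
    "Connectome",
    "Cohort",
    "NATIVE_DIFFUSION",
    "STRUCTURAL",
]

# coordinate_space tags for StreamlineSet
NATIVE_DIFFUSION = "native-diffusion"
STRUCTURAL = "structural"


def _as_affine(affine) -> np.ndarray:
    A = np.asarray(affine, dtype=float)
    if A.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {A.shape}")
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    return A


@dataclass
class Parcellation:
    """Integer label volume + voxel-to-world affine + region table.

    ``regions`` must have columns ``label``, ``name``, ``cx``, ``cy``,
    ``cz`` (world-space centroid, mm).  Label 0 is background and never
    appears in the region table.
    """

    label_volume: np.ndarray
    affine: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label_volume must be 3-D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label_volume must be integer-typed")
        self.affine = _as_affine(self.affine)
        required = {"label", "name", "cx", "cy", "cz"}
        missing = required - set(self.regions.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        labels_in_volume = set(np.unique(self.label_volume)) - {0}
        table_labels = set(int(x) for x in self.regions["label"])
        if 0 in table_labels:
            raise ValueError("label 0 is reserved for background")
        stray = labels_in_volume - table_labels
        if stray:
            raise ValueError(f"volume contains labels absent from region table: {sorted(stray)}")
        cent = self.regions[["cx", "cy", "cz"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(cent)):
            raise ValueError("region centroids must be finite")

    @property
    def labels(self) -> np.ndarray:
        return self.regions["label"].to_numpy(dtype=int)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def centroids(self) -> np.ndarray:
        return self.regions[["cx", "cy", "cz"]].to_numpy(dtype=float)


@dataclass
class StreamlineSet:
    """Ordered collection of 3-D polylines, coordinates in mm."""

    streamlines: list
    coordinate_space: str = STRUCTURAL

    def __post_init__(self):
        cleaned = []
        for i, s in enumerate(self.streamlines):
            pts = np.asarray(s, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (k, 3) point array")
            if pts.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            cleaned.append(pts)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]


@dataclass
class Connectome:
    """Symmetric nonnegative-integer track-count matrix over regions."""

    matrix: np.ndarray
    nodes: pd.DataFrame
    subject_id: str = ""
    total_tracks_retained: int = 0

    def __post_init__(self):
        M = np.asarray(self.matrix)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.issubdtype(M.dtype, np.integer):
            if not np.allclose(M, np.round(M)):
                raise ValueError("connectome weights must be integers")
            M = np.round(M).astype(np.int64)
        if np.any(M < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(np.diag(M) != 0):
            raise ValueError("connectome diagonal must be zero")
        if not np.array_equal(M, M.T):
            raise ValueError("connectome matrix must be symmetric")
        if len(self.nodes) != M.shape[0]:
            raise ValueError("node table length must match matrix dimension")
        self.matrix = M.astype(np.int64)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def node_labels(self) -> np.ndarray:
        return self.nodes["label"].to_numpy(dtype=int)


@dataclass
class Cohort:
    """Stack of per-subject adjacency matrices with binary group labels.

    ``matrices`` has shape (n_subjects, n, n); each slice must satisfy
    the Connectome invariants.  ``groups`` holds one of exactly two
    group labels per subject (e.g. "A"/"B" or "valval"/"met").
    """

    matrices: np.ndarray
    groups: np.ndarray
    subject_ids: list = field(default_factory=list)
    nodes: pd.DataFrame | None = None

    def __post_init__(self):
        M = np.asarray(self.matrices)
        if M.ndim != 3 or M.shape[1] != M.shape[2]:
            raise ValueError("matrices must have shape (n_subjects, n, n)")
        self.matrices = M
        self.groups = np.asarray(self.groups)
        if self.groups.shape != (M.shape[0],):
            raise ValueError("one group label per subject required")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(M.shape[0])]
        if len(self.subject_ids) != M.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if self.nodes is None:
            n = M.shape[1]
            self.nodes = pd.DataFrame(
                {
                    "label": np.arange(1, n + 1),
                    "name": [f"region_{i}" for i in range(1, n + 1)],
                    "cx": np.zeros(n),
                    "cy": np.zeros(n),
                    "cz": np.zeros(n),
                }
            )

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    def group_names(self) -> tuple:
        """The two group labels in sorted order."""
        uniq = sorted(set(self.groups.tolist()))
        if len(uniq) != 2:
            raise ValueError(f"cohort must have exactly 2 groups, found {len(uniq)}")
        return tuple(uniq)

    def split(self):
        """(matrices_a, matrices_b) for the sorted group pair."""
        ga, gb = self.group_names()
        return self.matrices[self.groups == ga], self.matrices[self.groups == gb]

    def connectome(self, i: int) -> Connectome:
        return Connectome(
            matrix=self.matrices[i],
            nodes=self.nodes,
            subject_id=str(self.subject_ids[i]),
            total_tracks_retained=int(self.matrices[i].sum() // 2),
        )
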