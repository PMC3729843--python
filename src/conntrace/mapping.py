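"""Streamline-to-parcellation connectome mapping.

The mapping rule is the *contact point* rule: a track contributes to a
region pair whenever it traverses between the two regions, not merely
when it starts in one and ends in the other.  Three modes are exposed:

``all_pairs``
    For each streamline, take the set R of distinct regions it touches
    and increment every unordered pair of R exactly once per
    streamline.  Re-entries do not double-count.
``transitions``
    Increment only pairs that are adjacent in the collapsed sequence of
    touched regions, once per occurrence (re-crossings count again).
``endpoints``
    Increment the (first, last) region pair only, and only when both
    exist and differ — the classical start/end convention.

Region lookup is nearest-voxel (labels are categorical, never
interpolated), with the voxel-center, 0-based index convention: voxel
(i, j, k) has its center at ``affine @ (i, j, k, 1)``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .core import Connectome, Parcellation, StreamlineSet

logger = logging.getLogger("conntrace.mapping")

MODES = ("all_pairs", "transitions", "endpoints")

__all__ = [
    "MODES",
    "transform_streamlines",
    "resample_polyline",
    "regions_touched",
    "map_connectome",
    "filter_tracks_by_edges",
]


def transform_streamlines(streamlines: StreamlineSet, affine,
                          coordinate_space: str | None = None) -> StreamlineSet:
    """Apply a 4x4 affine to every point of every streamline.

    Point order and streamline count are preserved.  ``coordinate_space``
    optionally retags the output (e.g. "structural" after moving tracks
    from native diffusion space).
    """
    A = np.asarray(affine, dtype=float)
    if A.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {A.shape}")
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    R, t = A[:3, :3], A[:3, 3]
    out = [pts @ R.T + t for pts in streamlines]
    space = coordinate_space if coordinate_space is not None else streamlines.coordinate_space
    return StreamlineSet(out, coordinate_space=space)


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Densify a polyline so consecutive samples are at most ``step`` apart.

    Original vertices are always retained; each segment of length L is
    subdivided into ceil(L/step) equal pieces.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pts = np.asarray(points, dtype=float)
    pieces = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        L = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(L / step)))
        frac = np.arange(1, n + 1, dtype=float)[:, None] / n
        pieces.append(a + frac * (b - a))
    return np.vstack(pieces)


def _default_step(parcellation: Parcellation) -> float:
    return 0.5 * float(parcellation.voxel_sizes.min())


def _labels_at(points: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Region label under each world-space point; -1 if outside the volume."""
    inv = np.linalg.inv(parcellation.affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    idx = np.round(vox).astype(np.int64)
    shape = parcellation.label_volume.shape
    inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    labels = np.full(len(points), -1, dtype=np.int64)
    if inside.any():
        ii = idx[inside]
        labels[inside] = parcellation.label_volume[ii[:, 0], ii[:, 1], ii[:, 2]]
    return labels


def regions_touched(streamline, parcellation: Parcellation,
                    step: float | None = None) -> np.ndarray:
    """Collapsed ordered sequence of region labels a streamline contacts.

    The polyline is resampled at spacing <= ``step`` (default: half the
    smallest voxel edge), each sample is mapped to its nearest voxel, and
    background / out-of-volume samples are discarded before consecutive
    duplicates are collapsed.  May be empty.
    """
    if step is None:
        step = _default_step(parcellation)
    pts = resample_polyline(np.asarray(streamline, dtype=float), step)
    labels = _labels_at(pts, parcellation)
    labels = labels[labels > 0]
    if labels.size == 0:
        return labels
    keep = np.ones(labels.size, dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    return labels[keep]


def _increments(seq: np.ndarray, mode: str) -> list:
    """Unordered label pairs a streamline increments, with multiplicity."""
    if mode == "all_pairs":
        R = sorted(set(seq.tolist()))
        return [(a, b) for i, a in enumerate(R) for b in R[i + 1:]]
    if mode == "transitions":
        return [tuple(sorted((int(a), int(b)))) for a, b in zip(seq[:-1], seq[1:])]
    if mode == "endpoints":
        if len(seq) >= 2 and seq[0] != seq[-1]:
            return [tuple(sorted((int(seq[0]), int(seq[-1]))))]
        return []
    raise ValueError(f"unknown mapping mode {mode!r}; expected one of {MODES}")


def map_connectome(streamlines: StreamlineSet, parcellation: Parcellation,
                   mode: str = "all_pairs", step: float | None = None) -> Connectome:
    """Build a track-count connectome from streamlines under a mapping mode.

    ``total_tracks_retained`` records how many streamlines contributed at
    least one increment, mirroring the per-subject retained-fiber count.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mapping mode {mode!r}; expected one of {MODES}")
    labels = parcellation.labels
    index = {int(l): i for i, l in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n), dtype=np.int64)
    retained = 0
    n_short = 0
    for sl in streamlines:
        seq = regions_touched(sl, parcellation, step=step)
        if len(seq) < 2:
            n_short += 1
        pairs = _increments(seq, mode)
        if pairs:
            retained += 1
        for a, b in pairs:
            ia, ib = index[int(a)], index[int(b)]
            M[ia, ib] += 1
            M[ib, ia] += 1
    if n_short:
        logger.info("%d of %d streamlines touched <2 regions and contributed nothing",
                    n_short, len(streamlines))
    return Connectome(matrix=M, nodes=parcellation.regions.copy(),
                      total_tracks_retained=retained)


def _normalize_edge_set(edge_set: Iterable, parcellation: Parcellation) -> set:
    known = set(int(l) for l in parcellation.labels)
    out = set()
    for a, b in edge_set:
        a, b = int(a), int(b)
        if a not in known or b not in known:
            raise ValueError(f"edge ({a}, {b}) references unknown region label")
        out.add((min(a, b), max(a, b)))
    return out


def filter_tracks_by_edges(streamlines: StreamlineSet, parcellation: Parcellation,
                           edge_set: Iterable, mode: str = "all_pairs",
                           step: float | None = None) -> StreamlineSet:
    """Reverse connectome-mapping: keep streamlines that hit a given edge set.

    Returns exactly the streamlines that would increment at least one
    edge of ``edge_set`` under the given mode, preserving input order.
    Used to project a significant network component back onto the
    tractogram.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mapping mode {mode!r}; expected one of {MODES}")
    edges = _normalize_edge_set(edge_set, parcellation)
    kept = []
    for sl in streamlines:
        seq = regions_touched(sl, parcellation, step=step)
        pairs = {(int(a), int(b)) for a, b in _increments(seq, mode)}
        if pairs & edges:
            kept.append(sl)
    return StreamlineSet(kept, coordinate_space=streamlines.coordinate_space)
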