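"""Multi-reader consensus, VOI extraction, and perspective slice selection.

A lesion marked by several readers yields several nearby center coordinates.
Marks of the same kind closer than a distance threshold are merged (single
linkage) into one consensus object whose center is the mean of the merged
centers and whose approval count is the cluster size.  Objects of opposite
kind whose consensus centers fall within the threshold are ambiguous and both
are dropped.  Around each surviving consensus center a fixed physical cube
(default 30 mm) is cropped, resampled to an isotropic 56^3 voxel grid by
trilinear interpolation, and min-max normalised to [0, 1].  Each VOI is then
sliced along the three orthogonal perspectives, and a fixed number of planes
(default 6) is selected at equal intervals across the object's span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist, pdist

from .phantoms import NODULE, NON_NODULE, SyntheticScan

logger = logging.getLogger(__name__)

VOI_RESOLUTION = 56
CUBE_MM = 30.0

# perspective name -> volume axis whose planes form the slice stack
PERSPECTIVES = {"V1": 2, "V2": 1, "V3": 0}  # transverse XY, coronal XZ, sagittal YZ


@dataclass
class ConsensusObject:
    kind: str
    center_mm: np.ndarray
    approval_count: int
    extent_mm: np.ndarray
    source_scan: str = ""

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, float)
        self.extent_mm = np.asarray(self.extent_mm, float)


@dataclass
class VolumeOfInterest:
    data: np.ndarray
    label: str
    consensus: ConsensusObject
    native_cube_voxels: np.ndarray

    def __post_init__(self):
        if self.data.shape != (VOI_RESOLUTION,) * 3:
            raise ValueError(f"VOI must be {VOI_RESOLUTION}^3, got {self.data.shape}")


@dataclass
class PerspectiveStack:
    perspective: str
    slices: list[np.ndarray]
    slice_indices: list[int] = field(default_factory=list)


def merge_reader_annotations(annotations: pd.DataFrame,
                             distance_threshold_mm: float = 5.0):
    """Cluster same-kind reader marks of one scan into consensus objects.

    Single-linkage clustering of the center coordinates cut at the distance
    threshold; each cluster becomes one :class:`ConsensusObject` with the mean
    center, element-wise max extent, and the cluster size as approval count.
    The result is independent of the row order of the input table.
    """
    if distance_threshold_mm <= 0:
        raise ValueError("distance_threshold_mm must be > 0")
    if len(annotations) == 0:
        return []
    kinds = annotations["kind"].unique()
    scans = annotations["scan_id"].unique()
    if len(kinds) != 1 or len(scans) != 1:
        raise ValueError("merge_reader_annotations expects one scan and one kind")
    centers = annotations[["cx_mm", "cy_mm", "cz_mm"]].to_numpy(float)
    extents = annotations[["ex_mm", "ey_mm", "ez_mm"]].to_numpy(float)
    if len(centers) == 1:
        cluster_ids = np.array([1])
    else:
        cluster_ids = fcluster(linkage(pdist(centers), method="single"),
                               t=distance_threshold_mm, criterion="distance")
    out = []
    for cid in np.unique(cluster_ids):
        sel = cluster_ids == cid
        out.append(ConsensusObject(
            kind=str(kinds[0]),
            center_mm=centers[sel].mean(axis=0),
            approval_count=int(sel.sum()),
            extent_mm=extents[sel].max(axis=0),
            source_scan=str(scans[0])))
    # deterministic ordering regardless of input permutation
    out.sort(key=lambda o: tuple(o.center_mm))
    return out


def eliminate_conflicts(nodules, non_nodules, distance_threshold_mm: float = 5.0):
    """Drop every nodule/non-nodule pair whose centers are closer than the
    threshold — the readers disagreed about what the object is."""
    if not nodules or not non_nodules:
        return list(nodules), list(non_nodules)
    nc = np.array([o.center_mm for o in nodules])
    mc = np.array([o.center_mm for o in non_nodules])
    close = cdist(nc, mc) < distance_threshold_mm
    keep_n = [o for o, drop in zip(nodules, close.any(axis=1)) if not drop]
    keep_m = [o for o, drop in zip(non_nodules, close.any(axis=0)) if not drop]
    n_dropped = (len(nodules) - len(keep_n)) + (len(non_nodules) - len(keep_m))
    if n_dropped:
        logger.info("eliminated %d conflicting objects", n_dropped)
    return keep_n, keep_m


def build_consensus(annotations: pd.DataFrame, distance_threshold_mm: float = 5.0,
                    min_approval: int = 1):
    """Run merge + conflict elimination over a full multi-scan table."""
    objects = []
    for scan_id, scan_rows in annotations.groupby("scan_id"):
        per_kind = {}
        for kind in (NODULE, NON_NODULE):
            rows = scan_rows[scan_rows["kind"] == kind]
            per_kind[kind] = merge_reader_annotations(rows, distance_threshold_mm) if len(rows) else []
        nods, nons = eliminate_conflicts(per_kind[NODULE], per_kind[NON_NODULE],
                                         distance_threshold_mm)
        objects.extend(o for o in nods + nons if o.approval_count >= min_approval)
    return objects


def extract_voi(scan: SyntheticScan, consensus: ConsensusObject,
                cube_mm: float = CUBE_MM, out_res: int = VOI_RESOLUTION) -> VolumeOfInterest:
    """Crop a physical cube around the consensus center and resample to
    ``out_res^3`` by trilinear interpolation, min-max normalised to [0, 1].

    Centers too close to the scan border are handled by clamping the crop
    window inside the volume (the effective center shifts); a constant input
    region maps to an all-zero VOI (divide-by-zero guard on normalisation).
    """
    spacing = np.asarray(scan.spacing_mm, float)
    shape = np.asarray(scan.volume.shape)
    c_vox = consensus.center_mm / spacing
    if np.any(c_vox < 0) or np.any(c_vox > shape - 1):
        raise ValueError("consensus center lies outside the scan volume")
    native = np.maximum(np.round(cube_mm / spacing).astype(int), 1)
    if np.any(native > shape):
        raise ValueError("crop cube does not fit inside the scan")
    start = c_vox - (native - 1) / 2.0
    clamped = np.clip(start, 0, shape - native)
    if not np.allclose(clamped, start):
        logger.info("crop window clamped at scan border for %s", consensus.source_scan)
    coords = np.meshgrid(*[np.linspace(clamped[a], clamped[a] + native[a] - 1, out_res)
                           for a in range(3)], indexing="ij")
    data = map_coordinates(scan.volume.astype(np.float64), np.stack(coords),
                           order=1, mode="nearest")
    lo, hi = data.min(), data.max()
    # tolerance guard: interpolation of a constant region jitters at ~1e-16
    if hi - lo > 1e-9 * max(abs(hi), abs(lo), 1.0):
        data = (data - lo) / (hi - lo)
    else:
        data = np.zeros_like(data)
    return VolumeOfInterest(data=data, label=consensus.kind, consensus=consensus,
                            native_cube_voxels=native)


def select_slices(voi: VolumeOfInterest, perspective: str,
                  n_slices: int = 6, cube_mm: float = CUBE_MM) -> PerspectiveStack:
    """Pick ``n_slices`` planes at equal intervals across the object's span.

    For nodules the span along the perspective axis comes from the consensus
    extent (boundary annotations exist only for nodules); non-nodules use the
    full VOI span.  Indices are the rounded linear grid including both span
    endpoints; a degenerate span (< n_slices planes) repeats boundary planes.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"perspective must be one of {sorted(PERSPECTIVES)}")
    axis = PERSPECTIVES[perspective]
    res = voi.data.shape[axis]
    if voi.label == NODULE:
        span_planes = voi.consensus.extent_mm[axis] / cube_mm * res
        mid = (res - 1) / 2.0
        lo = int(np.clip(np.floor(mid - span_planes / 2), 0, res - 1))
        hi = int(np.clip(np.ceil(mid + span_planes / 2), 0, res - 1))
    else:
        lo, hi = 0, res - 1
    if n_slices == 1:
        idx = np.array([int(np.round((lo + hi) / 2.0))])
    else:
        idx = np.round(np.linspace(lo, hi, n_slices)).astype(int)
    if len(np.unique(idx)) < n_slices:
        logger.warning("degenerate span [%d, %d]: repeated boundary planes", lo, hi)
    slices = [np.take(voi.data, int(i), axis=axis) for i in idx]
    return PerspectiveStack(perspective=perspective, slices=slices,
                            slice_indices=[int(i) for i in idx])


def perspective_stacks(voi: VolumeOfInterest, n_slices: int = 6):
    """The three perspective stacks (V1, V2, V3) of one VOI."""
    return {p: select_slices(voi, p, n_slices) for p in PERSPECTIVES}


def split_dataset(objects, train_frac: float = 0.7, seed=0):
    """Stratified train/test split: train size = floor(train_frac * total),
    per-class quotas by largest remainder, deterministic per seed."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    objects = list(objects)
    labels = np.array([getattr(o, "label", None) or o.kind for o in objects])
    rng = np.random.default_rng(seed)
    n_train_total = int(np.floor(train_frac * len(objects)))
    classes = sorted(set(labels))
    quota = {c: int(np.floor(train_frac * (labels == c).sum())) for c in classes}
    remainders = sorted(classes, key=lambda c: -(train_frac * (labels == c).sum() % 1))
    i = 0
    while sum(quota.values()) < n_train_total:
        c = remainders[i % len(remainders)]
        if quota[c] < (labels == c).sum():
            quota[c] += 1
        i += 1
    train_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        rng.shuffle(members)
        train_idx.extend(members[:quota[c]])
    train_set = set(train_idx)
    train = [objects[i] for i in sorted(train_set)]
    test = [objects[i] for i in range(len(objects)) if i not in train_set]
    return train, test
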