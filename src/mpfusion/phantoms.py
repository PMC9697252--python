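"""Synthetic CT-like phantom scans for exercising the nodule-classification pipeline.

Real chest-CT archives annotate bright, compact pulmonary nodules alongside
confusable non-nodule structures (vessels, scars, noise), each marked by
several radiologists whose centers disagree slightly.  This module generates
volumes with the same statistical skeleton: quasi-spherical Gaussian-profile
nodules, elongated tubes / dim blobs / speckle patches as distractors, additive
background noise, and multiple simulated readers with center jitter and a
per-reader miss probability.  It makes no attempt at CT physics (no beam
hardening, no reconstruction kernel); the point is shape/intensity structure
the downstream classifiers must separate.

All generators are deterministic for a fixed seed and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

NODULE = "nodule"
NON_NODULE = "non_nodule"

ANNOTATION_COLUMNS = [
    "scan_id", "reader_id", "kind",
    "cx_mm", "cy_mm", "cz_mm", "ex_mm", "ey_mm", "ez_mm",
]


@dataclass(frozen=True)
class ReaderAnnotation:
    reader_id: int
    center_mm: np.ndarray
    kind: str


@dataclass
class GroundTruthObject:
    """One lesion-like object with its simulated multi-reader annotations."""

    kind: str
    center_mm: np.ndarray
    extent_mm: np.ndarray
    peak_intensity: float
    reader_annotations: list[ReaderAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.extent_mm = np.asarray(self.extent_mm, dtype=float)
        if self.kind not in (NODULE, NON_NODULE):
            raise ValueError(f"unknown object kind {self.kind!r}")
        if np.any(self.extent_mm <= 0) or np.any(self.extent_mm > 30):
            raise ValueError("extent_mm components must lie in (0, 30]")


@dataclass
class SyntheticScan:
    """A 3D scalar volume with physical voxel spacing and ground-truth objects."""

    scan_id: str
    volume: np.ndarray
    spacing_mm: np.ndarray
    objects: list[GroundTruthObject] = field(default_factory=list)

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=np.float32)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be positive")

    @property
    def physical_size_mm(self) -> np.ndarray:
        return np.asarray(self.volume.shape) * self.spacing_mm


@dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    Defaults: 96^3 voxels at 0.6 mm isotropic spacing (a 30 mm cube spans 50
    native voxels, exercising the 50 -> 56 resampling), 4 simulated readers
    with 1.0 mm center jitter and a 25% per-reader miss probability.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    background_mean: float = 0.10
    noise_sd: float = 0.05
    n_readers: int = 4
    jitter_sd_mm: float = 1.0
    miss_prob: float = 0.25
    border_margin_mm: float = 15.0
    min_separation_mm: float = 12.0
    # nodule geometry (axis-aligned size in mm, mildly anisotropic)
    nodule_extent_range_mm: tuple[float, float] = (5.0, 12.0)
    anisotropy_range: tuple[float, float] = (0.85, 1.15)
    tube_axis_ratio: float = 4.0
    tube_radius_mm: float = 1.5
    speckle_radius_mm: float = 6.0


# intensity regimes for the separability dial: "easy" guarantees nodule peak
# >= 3x distractor peak over the background noise; "hard" overlaps the ranges
# so a central-intensity threshold is no longer sufficient.
_INTENSITY = {
    "easy": {"nodule_peak": (0.90, 1.10), "distractor_peak": (0.20, 0.30),
             "speckle_amplitude": 0.15},
    "hard": {"nodule_peak": (0.45, 0.70), "distractor_peak": (0.40, 0.65),
             "speckle_amplitude": 0.30},
}


def _mm_to_voxel(center_mm, spacing_mm):
    return np.asarray(center_mm, float) / np.asarray(spacing_mm, float)


def _check_center_inside(volume, spacing_mm, center_mm):
    idx = _mm_to_voxel(center_mm, spacing_mm)
    if np.any(idx < 0) or np.any(idx > np.asarray(volume.shape) - 1):
        raise ValueError(
            f"center {np.asarray(center_mm)} mm lies outside the volume "
            f"(shape {volume.shape}, spacing {spacing_mm} mm)")


def _gaussian_blob(volume, spacing_mm, center_mm, sigma_mm, peak):
    """Additively blend an anisotropic Gaussian profile; local-box evaluation."""
    out = volume.astype(np.float32, copy=True)
    if peak == 0:
        return out
    spacing = np.asarray(spacing_mm, float)
    c_vox = _mm_to_voxel(center_mm, spacing)
    # 5 sigma support captures the profile to float32 precision
    half = np.ceil(5.0 * np.asarray(sigma_mm) / spacing).astype(int)
    lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
    hi = np.minimum(np.ceil(c_vox).astype(int) + half + 1, volume.shape)
    grids = [np.arange(lo[a], hi[a]) * spacing[a] - center_mm[a] for a in range(3)]
    dx, dy, dz = np.meshgrid(*grids, indexing="ij")
    sx, sy, sz = sigma_mm
    rho2 = (dx / sx) ** 2 + (dy / sy) ** 2 + (dz / sz) ** 2
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (peak * np.exp(-0.5 * rho2)).astype(np.float32)
    return out


def inject_nodule(volume, spacing_mm, center_mm, extent_mm, peak):
    """Blend a bright quasi-spherical lesion into ``volume`` (copy returned).

    The profile is an anisotropic Gaussian whose value at ``center_mm`` is
    ``peak`` and whose per-axis sigma is ``extent_mm / 4`` — the object's
    axis-aligned size corresponds to roughly +-2 sigma of visible signal, and
    intensity beyond twice the extent is below float32 noise.
    """
    center_mm = np.asarray(center_mm, float)
    extent_mm = np.asarray(extent_mm, float)
    if np.any(extent_mm <= 0):
        raise ValueError("extent_mm must be positive")
    _check_center_inside(volume, spacing_mm, center_mm)
    return _gaussian_blob(volume, spacing_mm, center_mm, extent_mm / 4.0, peak)


def inject_distractor(volume, spacing_mm, kind, params, seed):
    """Blend one non-nodule structure: an elongated ``tube``, a dim ``blob``,
    or a local ``speckle`` noise patch.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    params = dict(params)
    center = np.asarray(params["center_mm"], float)
    _check_center_inside(volume, spacing_mm, center)
    if kind == "tube":
        ratio = float(params.get("axis_ratio", 4.0))
        radius = float(params.get("radius_mm", 1.5))
        peak = float(params.get("peak", 0.25))
        axis = int(params.get("axis", rng.integers(0, 3)))
        sigma = np.full(3, radius)
        sigma[axis] = radius * ratio
        return _gaussian_blob(volume, spacing_mm, center, sigma, peak)
    if kind == "blob":
        extent = np.asarray(params.get("extent_mm", (8.0, 8.0, 8.0)), float)
        peak = float(params.get("peak", 0.25))
        return _gaussian_blob(volume, spacing_mm, center, extent / 4.0, peak)
    if kind == "speckle":
        amplitude = float(params.get("amplitude", 0.15))
        radius = float(params.get("radius_mm", 6.0))
        out = volume.astype(np.float32, copy=True)
        if amplitude == 0:
            return out
        spacing = np.asarray(spacing_mm, float)
        c_vox = _mm_to_voxel(center, spacing)
        half = np.ceil(radius / spacing).astype(int)
        lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
        hi = np.minimum(np.ceil(c_vox).astype(int) + half + 1, volume.shape)
        grids = [np.arange(lo[a], hi[a]) * spacing[a] - center[a] for a in range(3)]
        dx, dy, dz = np.meshgrid(*grids, indexing="ij")
        mask = dx**2 + dy**2 + dz**2 <= radius**2
        patch = rng.normal(0.0, amplitude, size=mask.shape) * mask
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += patch.astype(np.float32)
        return out
    raise ValueError(f"unknown distractor kind {kind!r}")


def simulate_readers(obj: GroundTruthObject, n_readers: int, jitter_sd_mm: float,
                     miss_prob: float, seed) -> GroundTruthObject:
    """Fill ``reader_annotations`` with jittered multi-reader marks.

    Each reader independently misses the object with probability ``miss_prob``;
    a retained reader reports the true center plus isotropic Gaussian jitter
    with standard deviation ``jitter_sd_mm``.  If every reader misses, the
    miss draws are repeated so at least one annotation is always present.
    """
    if n_readers < 1:
        raise ValueError("n_readers must be >= 1")
    if not (0 <= miss_prob < 1):
        raise ValueError("miss_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    while True:
        kept = rng.random(n_readers) >= miss_prob
        if kept.any():
            break
    annotations = []
    for reader_id in np.flatnonzero(kept):
        jitter = rng.normal(0.0, jitter_sd_mm, size=3)
        annotations.append(ReaderAnnotation(
            reader_id=int(reader_id),
            center_mm=obj.center_mm + jitter,
            kind=obj.kind))
    return replace(obj, reader_annotations=annotations)


def _place_centers(n, low_mm, high_mm, min_sep_mm, rng, max_tries=20000):
    """Rejection-sample n points in an axis-aligned box with minimum pairwise
    separation; restarts from scratch if the configuration dead-ends."""
    for _ in range(50):
        centers: list[np.ndarray] = []
        tries = 0
        while len(centers) < n and tries < max_tries:
            cand = rng.uniform(low_mm, high_mm)
            tries += 1
            if all(np.linalg.norm(cand - c) >= min_sep_mm for c in centers):
                centers.append(cand)
        if len(centers) == n:
            return centers
    raise RuntimeError("could not place objects with the requested separation")


def generate_dataset(n_scans: int, objects_per_scan: int, separability: str = "easy",
                     config: PhantomConfig | None = None, seed=0):
    """Generate annotated phantom scans and the flat multi-reader table.

    Returns ``(scans, annotations)`` where ``annotations`` is a DataFrame with
    one row per reader annotation (columns ``scan_id, reader_id, kind,
    cx_mm, cy_mm, cz_mm, ex_mm, ey_mm, ez_mm``).  Nodule / non-nodule counts
    are balanced to within one object over the whole dataset.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if separability not in _INTENSITY:
        raise ValueError(f"separability must be one of {sorted(_INTENSITY)}")
    cfg = config or PhantomConfig()
    intens = _INTENSITY[separability]
    rng = np.random.default_rng(seed)

    total = n_scans * objects_per_scan
    # alternate labels through a global sequence: balanced within +-1
    labels = [NODULE if i % 2 == 0 else NON_NODULE for i in range(total)]
    rng.shuffle(labels)
    # reshuffle cannot unbalance; distribute sequentially over scans
    spacing = np.asarray(cfg.spacing_mm, float)
    size_mm = np.asarray(cfg.grid_shape) * spacing
    low = np.full(3, cfg.border_margin_mm)
    high = size_mm - cfg.border_margin_mm

    scans: list[SyntheticScan] = []
    rows = []
    distractor_cycle = ["tube", "blob", "speckle"]
    d_counter = 0
    for s in range(n_scans):
        scan_id = f"scan{s:04d}"
        volume = rng.normal(cfg.background_mean, cfg.noise_sd,
                            size=cfg.grid_shape).astype(np.float32)
        scan_labels = labels[s * objects_per_scan:(s + 1) * objects_per_scan]
        centers = _place_centers(objects_per_scan, low, high,
                                 cfg.min_separation_mm, rng)
        objects = []
        for kind, center in zip(scan_labels, centers):
            if kind == NODULE:
                base = rng.uniform(*cfg.nodule_extent_range_mm)
                extent = base * rng.uniform(*cfg.anisotropy_range, size=3)
                peak = rng.uniform(*intens["nodule_peak"])
                volume = inject_nodule(volume, spacing, center, extent, peak)
                obj = GroundTruthObject(NODULE, center, extent, peak)
            else:
                dkind = distractor_cycle[d_counter % 3]
                d_counter += 1
                dseed = int(rng.integers(0, 2**31 - 1))
                if dkind == "tube":
                    peak = rng.uniform(*intens["distractor_peak"])
                    axis = int(rng.integers(0, 3))
                    params = {"center_mm": center, "axis_ratio": cfg.tube_axis_ratio,
                              "radius_mm": cfg.tube_radius_mm, "peak": peak,
                              "axis": axis}
                    extent = np.full(3, 4 * cfg.tube_radius_mm)
                    extent[axis] = 4 * cfg.tube_radius_mm * cfg.tube_axis_ratio
                    volume = inject_distractor(volume, spacing, "tube", params, dseed)
                elif dkind == "blob":
                    peak = rng.uniform(*intens["distractor_peak"])
                    base = rng.uniform(*cfg.nodule_extent_range_mm)
                    extent = base * rng.uniform(*cfg.anisotropy_range, size=3)
                    params = {"center_mm": center, "extent_mm": extent, "peak": peak}
                    volume = inject_distractor(volume, spacing, "blob", params, dseed)
                else:
                    amplitude = intens["speckle_amplitude"]
                    extent = np.full(3, 2 * cfg.speckle_radius_mm)
                    params = {"center_mm": center, "amplitude": amplitude,
                              "radius_mm": cfg.speckle_radius_mm}
                    volume = inject_distractor(volume, spacing, "speckle", params, dseed)
                    peak = amplitude
                extent = np.clip(extent, 1e-3, 30.0)
                obj = GroundTruthObject(NON_NODULE, center, extent, peak)
            obj = simulate_readers(obj, cfg.n_readers, cfg.jitter_sd_mm,
                                   cfg.miss_prob, int(rng.integers(0, 2**31 - 1)))
            objects.append(obj)
            for ann in obj.reader_annotations:
                rows.append({
                    "scan_id": scan_id, "reader_id": ann.reader_id, "kind": ann.kind,
                    "cx_mm": ann.center_mm[0], "cy_mm": ann.center_mm[1],
                    "cz_mm": ann.center_mm[2],
                    "ex_mm": obj.extent_mm[0], "ey_mm": obj.extent_mm[1],
                    "ez_mm": obj.extent_mm[2],
                })
        scans.append(SyntheticScan(scan_id, volume, spacing, objects))
    annotations = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return scans, annotations


# ---------------------------------------------------------------------------
# on-disk formats


def save_scan_nifti(scan: SyntheticScan, path):
    affine = np.diag(list(scan.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(scan.volume, affine), str(path))


def load_scan_nifti(path, scan_id=None) -> SyntheticScan:
    img = nib.load(str(path))
    spacing = np.asarray(img.header.get_zooms()[:3], float)
    data = np.asarray(img.dataobj, dtype=np.float32)
    return SyntheticScan(scan_id or Path(path).stem, data, spacing)


def save_scan_raw(scan: SyntheticScan, path):
    """Little-endian float32 raw volume plus a JSON sidecar with dims/spacing."""
    path = Path(path)
    scan.volume.astype("<f4").tofile(path)
    sidecar = {"dims": list(scan.volume.shape),
               "spacing_mm": [float(s) for s in scan.spacing_mm]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_scan_raw(path, scan_id=None) -> SyntheticScan:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype="<f4").reshape(sidecar["dims"])
    return SyntheticScan(scan_id or path.stem, data, np.asarray(sidecar["spacing_mm"]))
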