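"""Volume and cohort I/O plus region-of-interest geometry.

Volumes are single-file NIfTI-1 images holding a 3D grid of nonnegative
activity counts.  The assumed axis convention is axis 0 = left-right (x),
axis 1 = posterior-anterior (y), axis 2 = inferior-superior (z) in a
RAS-oriented grid; no reorientation is attempted.  Voxel indices are
0-based and ROI boxes are half-open intervals.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

GROUPS = ("AD", "control")

#: default ROI box size in voxels (x, y, z)
DEFAULT_ROI_EXTENTS = (22, 29, 3)

#: default fractional (x, y, z) position of the *left* parietal ROI center;
#: the right ROI is the mirror image about the mid-sagittal plane.
DEFAULT_LEFT_ROI_FRACTION = (0.30, 0.62, 0.55)


@dataclasses.dataclass(frozen=True)
class BrainVolume:
    """A 3D scalar intensity grid (arbitrary counts units).

    Invariants: values finite and nonnegative, every axis at least 3
    voxels long.
    """

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError("volume must be 3D")
        if min(arr.shape) < 3:
            raise ValueError("volume must be at least 3 voxels along every axis")
        if not np.isfinite(arr).all():
            raise ValueError("volume contains non-finite voxels")
        if (arr < 0).any():
            raise ValueError("volume contains negative voxels")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def as_array(vol) -> np.ndarray:
    """Return the underlying float array of a BrainVolume or array-like."""
    if isinstance(vol, BrainVolume):
        return vol.data
    return np.asarray(vol, dtype=np.float64)


def wrap_like(template, data: np.ndarray):
    """Wrap ``data`` as BrainVolume if ``template`` was one, else pass through."""
    if isinstance(template, BrainVolume):
        return BrainVolume(data)
    return data


@dataclasses.dataclass(frozen=True)
class ROIBox:
    """An axis-aligned voxel box, half-open along every axis.

    The box covers ``[center - extents // 2, center - extents // 2 + extents)``
    so the stored center is the integer center voxel of the box.
    """

    side: str
    center: tuple[int, int, int]
    extents: tuple[int, int, int]

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"ROI side must be 'left' or 'right', got {self.side!r}")
        center = tuple(int(c) for c in self.center)
        extents = tuple(int(e) for e in self.extents)
        if len(center) != 3 or len(extents) != 3:
            raise ValueError("ROI center and extents must be integer triples")
        if any(e < 1 for e in extents):
            raise ValueError("ROI extents must all be >= 1")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "extents", extents)

    @property
    def start(self) -> tuple[int, int, int]:
        return tuple(c - e // 2 for c, e in zip(self.center, self.extents))

    @property
    def stop(self) -> tuple[int, int, int]:
        return tuple(s + e for s, e in zip(self.start, self.extents))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    @property
    def n_voxels(self) -> int:
        ex, ey, ez = self.extents
        return ex * ey * ez

    def validate_within(self, shape: Sequence[int]) -> None:
        """Raise if any part of the box falls outside ``shape`` (never clip)."""
        for lo, hi, n in zip(self.start, self.stop, shape):
            if lo < 0 or hi > n:
                raise ValueError("ROI exceeds volume bounds")

    def contains_point(self, point: Sequence[float]) -> bool:
        return all(lo <= p < hi for lo, hi, p in zip(self.start, self.stop, point))


def boxes_overlap(a: ROIBox, b: ROIBox) -> bool:
    return all(a.start[i] < b.stop[i] and b.start[i] < a.stop[i] for i in range(3))


def default_parietal_rois(
    shape: Sequence[int],
    *,
    centers: Sequence[Sequence[int]] | None = None,
    extents: Sequence[int] = DEFAULT_ROI_EXTENTS,
) -> tuple[ROIBox, ROIBox]:
    """Left and right parietal ROI boxes for a volume of the given shape.

    Without explicit ``centers`` the left box center sits at fractional
    position :data:`DEFAULT_LEFT_ROI_FRACTION` of the volume shape and the
    right box is its exact mirror about the mid-sagittal plane, so the two
    default boxes are reflection-symmetric.  Boxes that would fall outside
    the volume, or overlap, are an error — never silently clipped.
    """
    shape = tuple(int(n) for n in shape)
    extents = tuple(int(e) for e in extents)
    if centers is not None:
        (lc, rc) = centers
        left = ROIBox("left", tuple(lc), extents)
        right = ROIBox("right", tuple(rc), extents)
    else:
        lc = tuple(
            int(round(f * n)) for f, n in zip(DEFAULT_LEFT_ROI_FRACTION, shape)
        )
        left = ROIBox("left", lc, extents)
        # mirror the left box: [s, s+e) -> [nx - s - e, nx - s)
        rx_start = shape[0] - left.start[0] - extents[0]
        rc = (rx_start + extents[0] // 2, lc[1], lc[2])
        right = ROIBox("right", rc, extents)
    left.validate_within(shape)
    right.validate_within(shape)
    if boxes_overlap(left, right):
        raise ValueError("left and right ROI boxes overlap")
    return left, right


def read_volume(path) -> BrainVolume:
    """Read a single-file NIfTI-1 volume; reject non-3D or invalid data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError("volume must be 3D")
    return BrainVolume(np.asarray(data, dtype=np.float64))


def write_volume(vol, path) -> None:
    """Write a volume as float64 NIfTI-1 with an identity affine."""
    arr = as_array(vol)
    img = nib.Nifti1Image(arr.astype(np.float64), np.eye(4))
    nib.save(img, str(path))


def write_label_volume(labels: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int32), np.eye(4))
    nib.save(img, str(path))


MANIFEST_COLUMNS = ["subject_id", "group", "volume_path"]


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV with columns subject_id, group, volume_path.

    Relative volume paths are resolved against the manifest's directory;
    every path must resolve to an existing file at load time.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df = df[MANIFEST_COLUMNS].copy()
    if df["subject_id"].duplicated().any():
        raise ValueError("manifest subject_id values must be unique")
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"manifest group values must be in {GROUPS}, got {bad}")
    base = path.parent
    resolved = []
    for p in df["volume_path"]:
        full = Path(p)
        if not full.is_absolute():
            full = base / full
        if not full.exists():
            raise ValueError(f"manifest volume path does not exist: {p}")
        resolved.append(str(full))
    df["volume_path"] = resolved
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict ({} when empty)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg


def rois_from_config(shape, cfg: dict | None) -> tuple[ROIBox, ROIBox]:
    """Build ROI boxes from a config mapping (``roi`` section) or defaults."""
    if not cfg:
        return default_parietal_rois(shape)
    roi = cfg.get("roi", {}) if "roi" in cfg else cfg
    extents = tuple(roi.get("extents", DEFAULT_ROI_EXTENTS))
    centers = None
    if "left" in roi or "right" in roi:
        try:
            centers = (tuple(roi["left"]["center"]), tuple(roi["right"]["center"]))
        except KeyError as exc:
            raise ValueError("roi config must give left/right center triples") from exc
    return default_parietal_rois(shape, centers=centers, extents=extents)
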