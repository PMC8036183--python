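"""Slice-stack preparation: decomposition, class balancing, augmentation.

A 3D SUVR volume is re-expressed as an ordered stack of 2D slices along one
anatomical axis (axial / coronal / sagittal). All slices of one scan form
the channel dimension of a single training example, so the network emits
one probability per scan. Class imbalance is handled by random minority
oversampling; geometric augmentation applies one in-plane affine transform
identically to every slice of a stack (a rigidly rotated head moves all
slices together).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .suvr import SUVRImage, load_suvr

AXES = ("sagittal", "coronal", "axial")
#: Volume axis index sliced over for each decomposition, for (x, y, z) grids.
_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}

#: SUVR values are clipped to this range and scaled to [0, 1] before the CNN.
SUVR_CLIP_MAX = 3.0


@dataclass
class SliceStack:
    """One scan decomposed along one axis.

    ``planes`` has shape (n_slices, h, w): the slice index runs along the
    chosen anatomical axis, in increasing voxel-index order.
    """

    planes: np.ndarray
    axis: str
    scan_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("planes must be (n_slices, h, w) with >= 1 slice")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")

    @property
    def n_slices(self) -> int:
        return self.planes.shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


@dataclass
class Dataset:
    """Labelled collection of slice stacks."""

    items: list[tuple[SliceStack, int]]

    def __post_init__(self) -> None:
        for _, label in self.items:
            if label not in (0, 1):
                raise ValueError("labels must be 0 or 1")

    @property
    def class_counts(self) -> tuple[int, int]:
        labels = [label for _, label in self.items]
        return labels.count(0), labels.count(1)

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class AugmentParams:
    """Ranges for random in-plane affine augmentation.

    Conventional mild defaults: rotation within +/-10 degrees, shift within
    +/-10% of the field, shear +/-0.1, zoom +/-10%, left-right flip with
    probability 0.5.
    """

    max_rotation_deg: float = 10.0
    max_shift_frac: float = 0.10
    max_shear: float = 0.10
    max_zoom_frac: float = 0.10
    flip_lr: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_rotation_deg", "max_shift_frac", "max_shear",
                     "max_zoom_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def decompose(img: SUVRImage | np.ndarray, axis: str,
              scan_id: str = "", label: int | None = None) -> SliceStack:
    """Decompose a 3D volume into a stack of 2D slices along one axis."""
    vol = img.voxels if isinstance(img, SUVRImage) else np.asarray(img)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if axis not in _AXIS_INDEX:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
    planes = np.moveaxis(vol, _AXIS_INDEX[axis], 0)
    if isinstance(img, SUVRImage) and not scan_id:
        scan_id = img.scan_id
    return SliceStack(planes=planes.copy(), axis=axis, scan_id=scan_id,
                      label=label)


def restack(stack: SliceStack) -> np.ndarray:
    """Inverse of :func:`decompose`: rebuild the 3D volume."""
    return np.moveaxis(stack.planes, 0, _AXIS_INDEX[stack.axis]).copy()


def normalize_intensity(planes: np.ndarray, clip_max: float = SUVR_CLIP_MAX
                        ) -> np.ndarray:
    """Clip SUVR values to [0, clip_max] and rescale to [0, 1].

    SUVR is already a ratio scale, so a fixed clip keeps the mapping
    identical across scans and folds (no per-scan statistics leak).
    """
    return np.clip(planes, 0.0, clip_max) / clip_max


def oversample_minority(ds: Dataset, rng_seed: int) -> Dataset:
    """Balance classes by duplicating random minority items.

    Minority items are sampled with replacement and appended until class
    counts are equal; majority items are untouched and every added item is
    an exact copy (same object) of an existing minority item.
    """
    n0, n1 = ds.class_counts
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to oversample")
    if n0 == n1:
        return Dataset(items=list(ds.items))
    minority = 0 if n0 < n1 else 1
    pool = [item for item in ds.items if item[1] == minority]
    deficit = abs(n0 - n1)
    rng = np.random.default_rng(rng_seed)
    extra = [pool[i] for i in rng.integers(0, len(pool), size=deficit)]
    return Dataset(items=list(ds.items) + extra)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def apply_affine(stack: SliceStack, rotation_deg: float = 0.0,
                 shift: tuple[float, float] = (0.0, 0.0), shear: float = 0.0,
                 zoom: float = 1.0, flip: bool = False) -> SliceStack:
    """Apply one in-plane affine transform identically to all planes.

    The transform is centred on the plane centre; out-of-field pixels are
    filled with 0 (bilinear interpolation). ``shift`` is in pixels (row,
    col); ``zoom`` > 1 magnifies. A left-right flip is applied as an exact
    array reversal of the column axis before the affine resampling, so a
    flip-only transform is an exact involution.
    """
    planes = stack.planes
    if flip:
        planes = planes[:, :, ::-1]

    identity = (rotation_deg == 0.0 and shear == 0.0 and zoom == 1.0
                and shift == (0.0, 0.0))
    if identity:
        return replace(stack, planes=planes.copy())

    h, w = stack.plane_shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    shear_m = np.array([[1.0, shear], [0.0, 1.0]])
    fwd = rot @ shear_m * zoom
    # ndimage maps output coords through `matrix` to input coords
    inv = np.linalg.inv(fwd)
    offset = center - inv @ (center + np.asarray(shift, dtype=float))
    out = np.empty_like(planes, dtype=np.float64)
    for i in range(planes.shape[0]):
        out[i] = ndimage.affine_transform(
            planes[i].astype(np.float64), inv, offset=offset, order=1,
            mode="constant", cval=0.0,
        )
    return replace(stack, planes=out)


def augment(stack: SliceStack, params: AugmentParams) -> SliceStack:
    """Sample one random affine transform from the parameter ranges and
    apply it to the whole stack. Deterministic per ``params.rng_seed``."""
    rng = np.random.default_rng(params.rng_seed)
    h, w = stack.plane_shape
    rotation = float(rng.uniform(-params.max_rotation_deg,
                                 params.max_rotation_deg)) \
        if params.max_rotation_deg > 0 else 0.0
    shift = (
        float(rng.uniform(-params.max_shift_frac, params.max_shift_frac) * h)
        if params.max_shift_frac > 0 else 0.0,
        float(rng.uniform(-params.max_shift_frac, params.max_shift_frac) * w)
        if params.max_shift_frac > 0 else 0.0,
    )
    shear = float(rng.uniform(-params.max_shear, params.max_shear)) \
        if params.max_shear > 0 else 0.0
    zoom = float(1.0 + rng.uniform(-params.max_zoom_frac,
                                   params.max_zoom_frac)) \
        if params.max_zoom_frac > 0 else 1.0
    flip = bool(rng.random() < 0.5) if params.flip_lr else False
    return apply_affine(stack, rotation_deg=rotation, shift=shift,
                        shear=shear, zoom=zoom, flip=flip)


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def load_manifest_dataset(
    manifest_csv: str | Path, axis: str,
    mask_paths: Callable[[str], np.ndarray] | None = None,
    normalize: bool = True,
) -> Dataset:
    """Build a Dataset from a CSV manifest (scan_id, path, label).

    ``path`` must point to a 3D SUVR NIfTI. Intensity normalization (clip
    to [0, 3], scale to [0, 1]) is applied unless disabled.
    """
    df = pd.read_csv(manifest_csv)
    required = {"scan_id", "path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must contain columns {sorted(required)}")
    items = []
    for row in df.itertuples():
        img = load_suvr(row.path, scan_id=str(row.scan_id))
        stack = decompose(img, axis, label=int(row.label))
        planes = normalize_intensity(stack.planes) if normalize else stack.planes
        items.append((replace(stack, planes=planes), int(row.label)))
    return Dataset(items=items)
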