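"""SUVR quantification from dynamic amyloid PET.

A dynamic PET scan is a 4D activity volume with a frame schedule. The
standardized uptake value ratio (SUVR) image is the voxelwise tracer uptake
averaged over a late time window (default 50-70 min post-injection), divided
by the identically windowed mean of a reference-region time-activity curve
(grey-matter cerebellum). All volumes are assumed spatially aligned on a
common grid; this module never resamples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Default SUVR time window in minutes post-injection.
DEFAULT_WINDOW_MIN = (50.0, 70.0)

#: Minimum fraction of the window that must be covered by fully contained
#: frames; partially overlapping frames are excluded, not fractionally
#: weighted.
MIN_WINDOW_COVERAGE = 0.95


def _validate_schedule(schedule: Sequence[tuple[float, float]]) -> np.ndarray:
    """Return the schedule as an (n, 2) float array of (start_s, duration_s).

    Frames must be contiguous, non-overlapping and strictly increasing.
    """
    sched = np.asarray(schedule, dtype=float)
    if sched.ndim != 2 or sched.shape[1] != 2:
        raise ValueError("frame schedule must be a sequence of (start_s, duration_s)")
    if np.any(sched[:, 1] <= 0):
        raise ValueError("frame durations must be strictly positive")
    starts = sched[:, 0]
    ends = starts + sched[:, 1]
    if not np.all(np.diff(starts) > 0):
        raise ValueError("frame starts must be strictly increasing")
    if not np.allclose(ends[:-1], starts[1:]):
        raise ValueError("frames must be contiguous (no gaps or overlaps)")
    return sched


@dataclass
class DynamicPETImage:
    """4D dynamic PET volume with its frame schedule.

    Parameters
    ----------
    voxels:
        Non-negative activity concentration, shape (x, y, z, frame).
    frame_schedule:
        Ordered list of (start_s, duration_s) per frame; contiguous,
        non-overlapping, strictly increasing.
    voxel_size_mm:
        Isotropic or per-axis voxel size in mm.
    affine:
        Optional NIfTI affine, stored for I/O only; computation is done in
        voxel space (0-based indices).
    """

    voxels: np.ndarray
    frame_schedule: Sequence[tuple[float, float]]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("dynamic PET must be 4D (x, y, z, frame)")
        sched = _validate_schedule(self.frame_schedule)
        if len(sched) != self.voxels.shape[3]:
            raise ValueError(
                f"schedule has {len(sched)} frames but volume has "
                f"{self.voxels.shape[3]}"
            )
        self.frame_schedule = [tuple(row) for row in sched]
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def frame_mid_times_s(self) -> np.ndarray:
        sched = np.asarray(self.frame_schedule)
        return sched[:, 0] + sched[:, 1] / 2.0


@dataclass
class TimeActivityCurve:
    """Mean regional activity per frame of a dynamic scan."""

    times: np.ndarray  # frame mid-times, seconds
    values: np.ndarray  # mean activity per frame inside the region
    region_name: str = ""
    frame_schedule: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")


@dataclass
class SUVRImage:
    """3D SUVR volume on a fixed grid."""

    voxels: np.ndarray
    window_min: tuple[float, float] = DEFAULT_WINDOW_MIN
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("SUVR image must be 3D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("SUVR voxels must be finite")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _check_mask(mask: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != tuple(grid_shape):
        raise ValueError(f"mask grid {mask.shape} != image grid {tuple(grid_shape)}")
    return mask.astype(bool)


def extract_reference_tac(
    dyn: DynamicPETImage, ref_mask: np.ndarray, region_name: str = "cerebellar_gm"
) -> TimeActivityCurve:
    """Extract the reference-region time-activity curve.

    The TAC value for each frame is the unweighted mean of the voxel values
    inside the binary mask.
    """
    mask = _check_mask(ref_mask, dyn.grid_shape)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("reference mask is empty")
    values = dyn.voxels[mask].mean(axis=0, dtype=np.float64)
    return TimeActivityCurve(
        times=dyn.frame_mid_times_s,
        values=values,
        region_name=region_name,
        frame_schedule=dyn.frame_schedule,
    )


def select_window_frames(
    frame_schedule: Sequence[tuple[float, float]],
    window_min: tuple[float, float] = DEFAULT_WINDOW_MIN,
) -> np.ndarray:
    """Indices of frames whose intervals lie entirely inside the window.

    Frames partially overlapping the window are excluded with a warning.
    Raises if the selected frames cover less than 95% of the window.
    """
    w0, w1 = float(window_min[0]) * 60.0, float(window_min[1]) * 60.0
    if not w1 > w0:
        raise ValueError("window end must be after window start")
    sched = _validate_schedule(frame_schedule)
    starts, durs = sched[:, 0], sched[:, 1]
    ends = starts + durs
    inside = (starts >= w0) & (ends <= w1)
    partial = (ends > w0) & (starts < w1) & ~inside
    if np.any(partial):
        logger.warning(
            "%d frame(s) partially overlap the %g-%g min window and are excluded",
            int(partial.sum()), window_min[0], window_min[1],
        )
    covered = durs[inside].sum()
    if covered < MIN_WINDOW_COVERAGE * (w1 - w0):
        raise ValueError(
            f"frames cover only {covered:.0f} s of the "
            f"{w1 - w0:.0f} s window [{window_min[0]}, {window_min[1]}] min"
        )
    return np.flatnonzero(inside)


def compute_suvr(
    dyn: DynamicPETImage,
    ref: TimeActivityCurve,
    window_min: tuple[float, float] = DEFAULT_WINDOW_MIN,
    scan_id: str = "",
) -> SUVRImage:
    """Compute the SUVR image over a late time window.

    Voxelwise duration-weighted mean over fully in-window frames, divided by
    the identically windowed duration-weighted mean of the reference TAC.
    """
    idx = select_window_frames(dyn.frame_schedule, window_min)
    durs = np.asarray(dyn.frame_schedule, dtype=float)[idx, 1]
    w = durs / durs.sum()
    ref_mean = float(np.dot(np.asarray(ref.values)[idx], w))
    if ref_mean <= 0:
        raise ValueError("windowed reference mean must be strictly positive")
    num = np.tensordot(dyn.voxels[..., idx].astype(np.float64), w, axes=([3], [0]))
    return SUVRImage(
        voxels=num / ref_mean,
        window_min=tuple(window_min),
        voxel_size_mm=dyn.voxel_size_mm,
        affine=dyn.affine,
        scan_id=scan_id,
    )


def make_average_template(suvrs: Sequence[SUVRImage]) -> SUVRImage:
    """Voxelwise arithmetic mean of spatially aligned SUVR images.

    Used to build an average PET template (e.g. from 5 negative and 5
    positive scans) onto which external scans can be aligned upstream.
    """
    if len(suvrs) == 0:
        raise ValueError("need at least one SUVR image")
    grid = suvrs[0].grid_shape
    for img in suvrs:
        if img.grid_shape != grid:
            raise ValueError("all SUVR images must share one grid")
    mean = np.mean([img.voxels for img in suvrs], axis=0)
    return SUVRImage(
        voxels=mean,
        window_min=suvrs[0].window_min,
        voxel_size_mm=suvrs[0].voxel_size_mm,
        affine=suvrs[0].affine,
        scan_id="template",
    )


def apply_brain_mask(
    img: SUVRImage, gm_mask: np.ndarray, wm_mask: np.ndarray
) -> SUVRImage:
    """Zero all voxels outside the union of grey- and white-matter masks."""
    gm = _check_mask(gm_mask, img.grid_shape)
    wm = _check_mask(wm_mask, img.grid_shape)
    out = np.where(gm | wm, img.voxels, 0.0)
    return SUVRImage(
        voxels=out,
        window_min=img.window_min,
        voxel_size_mm=img.voxel_size_mm,
        affine=img.affine,
        scan_id=img.scan_id,
    )


# ---------------------------------------------------------------------------
# NIfTI / sidecar I/O
# ---------------------------------------------------------------------------

def save_dynamic(dyn: DynamicPETImage, nii_path: str | Path) -> None:
    """Write a 4D NIfTI plus a JSON frame-schedule sidecar (same stem)."""
    nii_path = Path(nii_path)
    nib.save(nib.Nifti1Image(dyn.voxels.astype(np.float32), dyn.affine), nii_path)
    sidecar = nii_path.with_suffix("").with_suffix(".json") \
        if nii_path.name.endswith(".nii.gz") else nii_path.with_suffix(".json")
    frames = [
        {"start_s": float(s), "duration_s": float(d)} for s, d in dyn.frame_schedule
    ]
    sidecar.write_text(json.dumps({"frames": frames}, indent=1))


def load_dynamic(
    nii_path: str | Path, schedule_path: str | Path | None = None
) -> DynamicPETImage:
    """Read a 4D NIfTI and its JSON frame-schedule sidecar."""
    nii_path = Path(nii_path)
    if schedule_path is None:
        schedule_path = nii_path.with_suffix("").with_suffix(".json") \
            if nii_path.name.endswith(".nii.gz") else nii_path.with_suffix(".json")
    img = nib.load(nii_path)
    meta = json.loads(Path(schedule_path).read_text())
    schedule = [(f["start_s"], f["duration_s"]) for f in meta["frames"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zooms = img.header.get_zooms()[:3]
    return DynamicPETImage(
        voxels=np.asarray(img.dataobj),
        frame_schedule=schedule,
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=img.affine,
    )


def save_suvr(img: SUVRImage, nii_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(img.voxels.astype(np.float32), img.affine), nii_path)


def load_suvr(nii_path: str | Path, scan_id: str = "") -> SUVRImage:
    img = nib.load(nii_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zooms = img.header.get_zooms()[:3]
    return SUVRImage(
        voxels=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=img.affine,
        scan_id=scan_id or Path(nii_path).name.split(".")[0],
    )


def save_mask(mask: np.ndarray, affine: np.ndarray, nii_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), nii_path)


def load_mask(nii_path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(nii_path).dataobj) > 0
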