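"""Synthetic dynamic-PET brain phantom.

Generates spatially aligned dynamic scans with the contrast structure an
amyloid classifier relies on: amyloid-negative scans show clear grey/white
matter contrast (low cortical uptake relative to white matter), amyloid-
positive scans show elevated cortical uptake that erodes that contrast.
Geometry is deliberately simple — a cortical grey-matter ellipsoidal shell
around a white-matter core, plus a separate cerebellar grey-matter blob that
serves as the SUVR reference region.

Kinetics follow a saturating plateau, a_r(t) = A_ref * SUVR_r * (1 - e^{-t/tau})
with tau = 10 min, so the plateau is effectively reached (>99%) well before
the 50-70 min SUVR window and the windowed ratio to the cerebellar reference
equals the per-scan SUVR target exactly in the noise-free case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .suvr import DynamicPETImage, _validate_schedule, save_dynamic, save_mask

#: The 29-frame acquisition schedule (seconds) of a 110-min dynamic protocol:
#: 1x15, 3x5, 3x10, 4x60, 2x150, 2x300, 4x600, 10x300.
DEFAULT_FRAME_DURATIONS_S: tuple[float, ...] = (
    (15.0,) + (5.0,) * 3 + (10.0,) * 3 + (60.0,) * 4 + (150.0,) * 2
    + (300.0,) * 2 + (600.0,) * 4 + (300.0,) * 10
)


def default_frame_schedule() -> list[tuple[float, float]]:
    starts = np.concatenate([[0.0], np.cumsum(DEFAULT_FRAME_DURATIONS_S)[:-1]])
    return [(float(s), float(d)) for s, d in zip(starts, DEFAULT_FRAME_DURATIONS_S)]


#: Plateau time constant (s); 1 - e^{-3000/600} > 0.993 at 50 min.
KINETIC_TAU_S = 600.0

REGIONS = ("cortical_gm", "white_matter", "cerebellar_gm")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort.

    Defaults give a clearly separable cohort: negative cortical SUVR 1.0
    versus positive 1.6, on a white-matter background of 1.7 (non-specific
    tracer retention in white matter is high for amyloid tracers, which is
    why negatives show strong grey/white contrast). ``between_subject_sd``
    jitters the per-scan cortical and white-matter targets to create
    biological spread; ``noise_cv`` is the coefficient of variation of
    multiplicative Gaussian voxel noise applied independently per frame.
    """

    grid_shape: tuple[int, int, int] = (79, 95, 68)
    voxel_size_mm: float = 2.0
    cortical_suvr_neg: float = 1.0
    cortical_suvr_pos: float = 1.6
    wm_suvr: float = 1.7
    ref_activity_kbq: float = 20.0
    noise_cv: float = 0.05
    frame_schedule: Sequence[tuple[float, float]] = field(
        default_factory=default_frame_schedule
    )
    between_subject_sd: float = 0.05

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        for name in ("voxel_size_mm", "cortical_suvr_neg", "cortical_suvr_pos",
                     "wm_suvr", "ref_activity_kbq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cortical_suvr_pos <= self.cortical_suvr_neg:
            raise ValueError("cortical_suvr_pos must exceed cortical_suvr_neg")
        if self.noise_cv < 0 or self.between_subject_sd < 0:
            raise ValueError("noise_cv and between_subject_sd must be >= 0")
        _validate_schedule(self.frame_schedule)


@dataclass
class PhantomScan:
    """One synthetic scan: dynamic volume, label, masks and ground truth."""

    dynamic: DynamicPETImage
    label: int
    masks: dict[str, np.ndarray]
    truth: dict[str, float]
    scan_id: str = ""


def _ellipsoid(grid: tuple[int, int, int], center_frac, semi_frac) -> np.ndarray:
    """Binary ellipsoid; center and semi-axes in fractions of the grid."""
    nx, ny, nz = grid
    cx, cy, cz = (f * (n - 1) for f, n in zip(center_frac, grid))
    ax, ay, az = (max(f * n, 0.5) for f, n in zip(semi_frac, grid))
    x, y, z = np.ogrid[:nx, :ny, :nz]
    return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
            + ((z - cz) / az) ** 2) <= 1.0


def make_masks(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Layered brain layout: GM shell, WM core, cerebellar GM blob below.

    Masks are mutually disjoint; ``whole_brain`` is their union. Layout is
    defined in grid fractions so any sufficiently large grid works.
    """
    brain = _ellipsoid(grid_shape, (0.5, 0.55, 0.62), (0.36, 0.36, 0.30))
    core = _ellipsoid(grid_shape, (0.5, 0.55, 0.62), (0.22, 0.22, 0.18))
    cereb = _ellipsoid(grid_shape, (0.5, 0.18, 0.15), (0.15, 0.11, 0.10))
    cereb &= ~brain  # keep regions disjoint even on coarse grids
    gm = brain & ~core
    wm = brain & core
    masks = {
        "cortical_gm": gm,
        "white_matter": wm,
        "cerebellar_gm": cereb,
        "whole_brain": gm | wm | cereb,
    }
    for name in REGIONS:
        if not masks[name].any():
            raise ValueError(
                f"grid {grid_shape} too small: region '{name}' is empty"
            )
    return masks


def _frame_shape_factors(schedule: Sequence[tuple[float, float]]) -> np.ndarray:
    """Frame-averaged value of (1 - e^{-t/tau}) over each frame interval."""
    sched = np.asarray(schedule, dtype=float)
    t0 = sched[:, 0]
    t1 = t0 + sched[:, 1]
    tau = KINETIC_TAU_S
    return 1.0 - tau / (t1 - t0) * (np.exp(-t0 / tau) - np.exp(-t1 / tau))


def generate_phantom(
    spec: PhantomSpec, label: int, rng_seed: int, scan_id: str = ""
) -> PhantomScan:
    """Generate one synthetic dynamic scan.

    Per-scan cortical and white-matter SUVR targets are the class targets
    plus Gaussian between-subject jitter; the cerebellar reference is pinned
    at SUVR 1 by construction. Deterministic for a fixed seed.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    rng = np.random.default_rng(rng_seed)
    masks = make_masks(spec.grid_shape)

    ctx_base = spec.cortical_suvr_pos if label else spec.cortical_suvr_neg
    jitter = rng.normal(0.0, spec.between_subject_sd, size=2) \
        if spec.between_subject_sd > 0 else np.zeros(2)
    truth = {
        "cortical_gm": max(float(ctx_base + jitter[0]), 0.05),
        "white_matter": max(float(spec.wm_suvr + jitter[1]), 0.05),
        "cerebellar_gm": 1.0,
    }

    shape = _frame_shape_factors(spec.frame_schedule)
    n_frames = len(shape)
    suvr_map = np.zeros(spec.grid_shape, dtype=np.float32)
    for region in REGIONS:
        suvr_map[masks[region]] = truth[region]

    vox = suvr_map[..., None] * (spec.ref_activity_kbq * shape).astype(np.float32)
    if spec.noise_cv > 0:
        noise = rng.standard_normal(
            vox.shape, dtype=np.float32) * np.float32(spec.noise_cv)
        vox = vox * (1.0 + noise)
        np.clip(vox, 0.0, None, out=vox)

    dyn = DynamicPETImage(
        voxels=vox,
        frame_schedule=list(spec.frame_schedule),
        voxel_size_mm=(spec.voxel_size_mm,) * 3,
    )
    return PhantomScan(
        dynamic=dyn, label=int(label), masks=masks, truth=truth,
        scan_id=scan_id or f"scan_seed{rng_seed}",
    )


def generate_cohort(
    spec: PhantomSpec, n_neg: int, n_pos: int, seed: int
) -> list[PhantomScan]:
    """Generate a cohort of exactly n_neg negative and n_pos positive scans.

    Per-scan seeds are derived deterministically from the cohort seed, so
    the cohort is reproducible and individual scans can be regenerated.
    """
    if n_neg < 0 or n_pos < 0:
        raise ValueError("counts must be non-negative")
    if n_neg + n_pos < 1:
        raise ValueError("cohort must contain at least one scan")
    master = np.random.default_rng(seed)
    scans = []
    labels = [0] * n_neg + [1] * n_pos
    for i, label in enumerate(labels):
        scan_seed = int(master.integers(0, 2**31 - 1))
        scans.append(
            generate_phantom(spec, label, scan_seed, scan_id=f"phantom_{i:04d}")
        )
    return scans


def write_cohort(scans: Sequence[PhantomScan], out_dir: str | Path) -> Path:
    """Write a cohort to disk: 4D NIfTI + schedule sidecars, 3D mask NIfTIs
    and a CSV manifest (scan_id, label, cortical_suvr, path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        stem = out_dir / scan.scan_id
        save_dynamic(scan.dynamic, stem.with_suffix(".nii.gz"))
        for name, mask in scan.masks.items():
            save_mask(mask, scan.dynamic.affine,
                      out_dir / f"{scan.scan_id}_mask_{name}.nii.gz")
        rows.append({
            "scan_id": scan.scan_id,
            "label": scan.label,
            "cortical_suvr": scan.truth["cortical_gm"],
            "path": str(stem.with_suffix(".nii.gz")),
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
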