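"""Class activation maps from the GAP-headed network.

Because the classification head is a global average pool followed by a
single sigmoid unit, the pre-sigmoid logit decomposes exactly as

    logit = mean_{x,y}( sum_n W_n * f_n(x, y) ) + b

where f_n are the final pre-GAP feature maps and (W_n, b) the dense head.
The weighted sum CAM(x, y) = sum_n W_n * f_n(x, y) therefore localizes the
evidence behind the prediction; its spatial mean plus the bias reproduces
the logit to floating-point tolerance, which doubles as a correctness check
of the whole forward pass. Negative CAM values are kept — they mark
evidence for the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cnn import TrainedModel, _sigmoid
from .dataprep import SliceStack


@dataclass
class ActivationMap:
    """CAM for one scan: raw (feature-map resolution) and upsampled."""

    raw: np.ndarray
    upsampled: np.ndarray
    probability: float
    scan_id: str = ""
    axis: str = ""


def compute_cam(model: TrainedModel, stack: SliceStack | np.ndarray
                ) -> ActivationMap:
    """Weighted sum of the final pre-GAP feature maps.

    The probability is recorded from the same forward pass; the upsampled
    map is a bilinear interpolation of the raw map to the input plane size.
    """
    planes = stack.planes if isinstance(stack, SliceStack) else np.asarray(stack)
    x = np.moveaxis(planes, 0, -1)
    fmaps = model.feature_maps(x)[0].astype(np.float64)  # (h', w', C)
    w, b = model.gap_dense_weights
    if fmaps.shape[-1] != w.shape[0]:
        raise ValueError("dense head does not match final feature-map count")
    raw = fmaps @ w.astype(np.float64)
    logit = raw.mean() + b
    probability = float(_sigmoid(np.array([logit]))[0])

    h_in, w_in = planes.shape[1], planes.shape[2]
    zoom = (h_in / raw.shape[0], w_in / raw.shape[1])
    upsampled = ndimage.zoom(raw, zoom, order=1, grid_mode=True,
                             mode="nearest")
    return ActivationMap(
        raw=raw,
        upsampled=upsampled,
        probability=probability,
        scan_id=stack.scan_id if isinstance(stack, SliceStack) else "",
        axis=model.axis,
    )


def render_overlay(
    amap: ActivationMap,
    background: np.ndarray,
    out_path: str | Path,
    cmap: str = "jet",
    alpha: float = 0.45,
) -> Path:
    """Blend the min-max normalized CAM over a background slice and write a
    raster image (format from the file suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    background = np.asarray(background)
    if background.shape != amap.upsampled.shape:
        raise ValueError(
            f"background shape {background.shape} != CAM "
            f"{amap.upsampled.shape}")
    span = amap.upsampled.max() - amap.upsampled.min()
    heat = (amap.upsampled - amap.upsampled.min()) / (span if span > 0 else 1.0)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(background.T, cmap="gray", origin="lower")
    ax.imshow(heat.T, cmap=cmap, alpha=alpha, origin="lower",
              vmin=0.0, vmax=1.0)
    ax.set_axis_off()
    ax.set_title(f"{amap.scan_id} p={amap.probability:.2f}", fontsize=9)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
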