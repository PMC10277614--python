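"""Automatic tissue localisation on slide thumbnails.

This is the automatic half of "semi-automatic" overview generation: find the
tissue on a low-resolution thumbnail and return its level-0 bounding box so
the overview crop frames tissue rather than empty glass.  The manual half is
the config override — a user-supplied bounding box always wins (see
figure_layout).

The tissue score of a pixel is ``max(saturation, 1 - brightness)``: stained
tissue is either chromatic (eosin pink, DAB brown, EBER blue — high
saturation) or dark (dense hematoxylin), while the glass background is
bright and unsaturated.  The score is thresholded with Otsu's method, the
mask is closed with a small disk, and components below a fraction of the
thumbnail area are dropped as debris.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import morphology
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .wsi_core import ParameterError, RasterImage, RegionL0, SlidePyramid, thumbnail

logger = logging.getLogger("pathoverview")

__all__ = ["TissueMask", "tissue_mask", "tissue_bbox", "detect_tissue_bbox"]

#: max dimension of the detection thumbnail; fixed so the morphology radii
#: below operate at a stable physical scale.
DETECTION_THUMB_PX = 1024
DEFAULT_MIN_COMPONENT_FRAC = 0.005
CLOSING_RADIUS_PX = 2


@dataclass
class TissueMask:
    """Binary tissue mask at thumbnail scale plus the parameters that made it."""

    mask: np.ndarray  # H x W bool
    thumb_downsample: float
    params: dict = field(default_factory=dict)


def tissue_mask(
    thumb: RasterImage,
    thumb_downsample: float = 1.0,
    min_component_frac: float = DEFAULT_MIN_COMPONENT_FRAC,
) -> TissueMask:
    """Segment tissue on an RGB thumbnail.

    A blank thumbnail (near-zero score variance) yields an empty mask with a
    warning rather than an exception, so downstream figure rendering can fall
    back to the whole slide.
    """
    px = thumb.pixels
    if max(px.shape[0], px.shape[1]) < 64:
        raise ParameterError("thumbnail max dimension must be >= 64")
    hsv = rgb2hsv(px)
    score = np.maximum(hsv[..., 1], 1.0 - hsv[..., 2])
    params = {
        "threshold_method": "otsu",
        "min_component_frac": min_component_frac,
        "closing_radius_px": CLOSING_RADIUS_PX,
    }
    if float(np.var(score)) < 1e-6:
        warnings.warn("blank thumbnail: tissue score has ~zero variance", stacklevel=2)
        return TissueMask(
            np.zeros(score.shape, dtype=bool), thumb_downsample, params
        )
    thr = threshold_otsu(score)
    fg = score > thr
    fg = morphology.closing(fg, morphology.disk(CLOSING_RADIUS_PX)).astype(bool)
    min_size = max(1, int(min_component_frac * score.size))
    try:
        fg = morphology.remove_small_objects(fg, max_size=min_size - 1)
    except TypeError:  # scikit-image < 0.26
        fg = morphology.remove_small_objects(fg, min_size=min_size)
    params["otsu_threshold"] = float(thr)
    return TissueMask(fg, thumb_downsample, params)


def tissue_bbox(
    mask: TissueMask,
    margin_frac: float = 0.0,
    level0_dims: tuple[int, int] | None = None,
) -> RegionL0:
    """Level-0 bounding box of the retained foreground, with optional margin.

    Each side of the tight box is pushed outward by
    ``margin_frac * max(box_w, box_h)`` level-0 pixels, then clamped to the
    slide.  An empty mask falls back to the whole slide (with a warning) so
    figures still render.
    """
    if not (0.0 <= margin_frac <= 0.5):
        raise ParameterError(f"margin_frac must be in [0, 0.5], got {margin_frac}")
    d = mask.thumb_downsample
    if level0_dims is None:
        level0_dims = (
            int(round(mask.mask.shape[1] * d)),
            int(round(mask.mask.shape[0] * d)),
        )
    w0, h0 = level0_dims
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        warnings.warn(
            "empty tissue mask: falling back to whole-slide bounding box",
            stacklevel=2,
        )
        return RegionL0(0, 0, w0, h0)
    x0 = math.floor(cols[0] * d)
    y0 = math.floor(rows[0] * d)
    x1 = math.ceil((cols[-1] + 1) * d)
    y1 = math.ceil((rows[-1] + 1) * d)
    margin = round(margin_frac * max(x1 - x0, y1 - y0))
    x0, y0 = x0 - margin, y0 - margin
    x1, y1 = x1 + margin, y1 + margin
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(w0, x1), min(h0, y1)
    return RegionL0(x0, y0, x1 - x0, y1 - y0)


def detect_tissue_bbox(
    slide: SlidePyramid,
    margin_frac: float = 0.0,
    max_px: int = DETECTION_THUMB_PX,
) -> RegionL0:
    """Thumbnail → mask → level-0 bbox in one call (the common pipeline)."""
    thumb, eff = thumbnail(slide, max_px)
    mask = tissue_mask(thumb, thumb_downsample=eff)
    return tissue_bbox(mask, margin_frac=margin_frac, level0_dims=slide.dimensions)
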