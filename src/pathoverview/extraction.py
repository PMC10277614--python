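"""Overview extraction: downsampled crop, scale bar, ROI inset, annotation.

One panel of a histology figure is built from four pieces produced here:

* an overview — the tissue crop read from the coarsest pyramid level that
  still meets the requested output size, then box-filter downsampled so the
  longest edge lands exactly on the target (never upsampled);
* a scale bar whose physical length is drawn from the "nice" set
  {1, 2, 5} x 10^k microns, chosen to minimise log-distance to a target
  fraction of the image width, and rendered in a white margin band below the
  tissue so it never occludes pixels a pathologist needs;
* a high-magnification inset of a selected region of interest, specified
  either in level-0 pixels or by a physical width in microns (e.g. a 250 um
  inset at 0.25 um/px covers 1000 level-0 px);
* a rectangle marking the inset's footprint on the overview.

Orientation harmonisation across serial sections is restricted to quarter
turns plus an optional horizontal mirror, which keeps every coordinate
mapping exact.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .wsi_core import (
    CalibrationMissingError,
    EmptyRegionError,
    ParameterError,
    RasterImage,
    RegionL0,
    SlidePyramid,
    read_region,
    resize_area,
)

logger = logging.getLogger("pathoverview")

__all__ = [
    "Transform",
    "ScaleBar",
    "OverviewImage",
    "choose_level",
    "compute_scale_bar",
    "extract_overview",
    "resolve_roi",
    "extract_inset",
    "annotate_roi",
]

#: scale bar target length as a fraction of image width
DEFAULT_BAR_FRAC = 0.25
#: allowed scale bar width fraction window
BAR_FRAC_MIN, BAR_FRAC_MAX = 0.10, 0.40
#: margin band height as a fraction of the image height
BAND_FRAC = 0.06


# ---------------------------------------------------------------------------
# Transforms (quarter turns + mirror)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transform:
    """Counter-clockwise quarter turns followed by an optional horizontal flip."""

    rotate90: int = 0
    flip_h: bool = False

    def __post_init__(self) -> None:
        if self.rotate90 not in (0, 1, 2, 3):
            raise ParameterError(f"rotate90 must be 0..3, got {self.rotate90}")

    @property
    def is_identity(self) -> bool:
        return self.rotate90 == 0 and not self.flip_h

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        out = np.rot90(pixels, k=self.rotate90)
        if self.flip_h:
            out = np.fliplr(out)
        return np.ascontiguousarray(out)

    def out_dims(self, w: int, h: int) -> tuple[int, int]:
        return (h, w) if self.rotate90 % 2 else (w, h)

    def map_point(self, x: float, y: float, w: int, h: int) -> tuple[float, float]:
        """Map a continuous point through the transform of a ``w x h`` image."""
        for _ in range(self.rotate90):
            x, y = y, w - x  # one CCW quarter turn in image coordinates
            w, h = h, w
        if self.flip_h:
            x = w - x
        return (x, y)

    def map_rect(
        self, x: float, y: float, rw: float, rh: float, w: int, h: int
    ) -> tuple[float, float, float, float]:
        """Map an axis-aligned rectangle; exact because turns are multiples of 90°."""
        corners = [
            self.map_point(cx, cy, w, h)
            for cx, cy in ((x, y), (x + rw, y), (x, y + rh), (x + rw, y + rh))
        ]
        xs = [c[0] for c in corners]
        ys = [c[1] for c in corners]
        return (min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))


# ---------------------------------------------------------------------------
# Level selection
# ---------------------------------------------------------------------------

def choose_level(slide: SlidePyramid, extent: RegionL0, target_px: int) -> int:
    """Finest pyramid level whose rendering of ``extent`` fits in ``target_px``.

    Returns the smallest downsample ``d`` with ``max(extent dims)/d <=
    target_px``; if even the coarsest level is too large, returns the
    coarsest (subsequent resampling then only ever shrinks).
    """
    if target_px < 64:
        raise ParameterError(f"target_px must be >= 64, got {target_px}")
    longest = max(extent.w, extent.h)
    for level, d in enumerate(slide.level_downsamples):
        if longest / d <= target_px:
            return level
    return slide.level_count - 1


def _coarsest_level_at_least(
    slide: SlidePyramid, extent: RegionL0, out_px: int
) -> int:
    """Coarsest level at which ``extent`` still spans >= out_px (for insets)."""
    longest = max(extent.w, extent.h)
    chosen = 0
    for level, d in enumerate(slide.level_downsamples):
        if longest / d >= out_px:
            chosen = level
    return chosen


# ---------------------------------------------------------------------------
# Scale bars
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleBar:
    """A physically-true scale bar: nice length in microns, px span, label."""

    length_um: float
    length_px: int
    label: str


def _nice_candidates() -> list[float]:
    return [m * 10.0**k for k in range(-2, 6) for m in (1.0, 2.0, 5.0)]


def _bar_label(length_um: float) -> str:
    if length_um >= 1000:
        return f"{length_um / 1000:.1f} mm"
    return f"{length_um:g} µm"


def compute_scale_bar(
    um_per_px: float, image_width_px: int, target_frac: float = DEFAULT_BAR_FRAC
) -> ScaleBar:
    """Pick the nice bar length closest (in log space) to a width fraction.

    Candidates are {1,2,5}x10^k um; the chosen bar must span 10-40% of the
    image width.  If no nice value fits that window (pathological aspect
    ratios), the globally nearest candidate is used with a warning.
    """
    if um_per_px <= 0:
        raise ParameterError(f"um_per_px must be > 0, got {um_per_px}")
    if image_width_px < 64:
        raise ParameterError(f"image_width_px must be >= 64, got {image_width_px}")
    target_um = target_frac * image_width_px * um_per_px
    width_um = image_width_px * um_per_px
    in_window = [
        c
        for c in _nice_candidates()
        if BAR_FRAC_MIN <= c / width_um <= BAR_FRAC_MAX
    ]
    pool = in_window
    if not pool:
        warnings.warn(
            "no nice scale-bar length fits the 10-40% width window; relaxing",
            stacklevel=2,
        )
        pool = _nice_candidates()
    best = min(pool, key=lambda c: abs(math.log(c / target_um)))
    return ScaleBar(
        length_um=best,
        length_px=round(best / um_per_px),
        label=_bar_label(best),
    )


def _draw_scale_band(pixels: np.ndarray, bar: ScaleBar) -> tuple[np.ndarray, int]:
    """Append a white band below the image and draw the bar + label in it."""
    h, w = pixels.shape[:2]
    band_h = max(22, round(BAND_FRAC * h))
    canvas = np.full((h + band_h, w, 3), 255, dtype=np.uint8)
    canvas[:h] = pixels
    img = Image.fromarray(canvas)
    draw = ImageDraw.Draw(img)
    x0 = max(4, round(0.02 * w))
    bar_y = h + band_h // 2
    draw.rectangle(
        [x0, bar_y - 2, x0 + bar.length_px - 1, bar_y + 1], fill=(0, 0, 0)
    )
    font = ImageFont.load_default()  # Pillow's bundled fixed bitmap font
    draw.text((x0 + bar.length_px + 8, h + (band_h - 11) // 2), bar.label,
              fill=(0, 0, 0), font=font)
    return np.asarray(img), band_h


# ---------------------------------------------------------------------------
# Overview extraction
# ---------------------------------------------------------------------------

@dataclass
class OverviewImage:
    """A rendered overview plus the provenance needed to reason about it.

    ``effective_downsample`` is level-0 px per overview px along the crop's
    own axes (before any transform); ``margin_band_px`` rows at the bottom of
    ``image`` are the scale-bar band (0 when no bar was drawn).
    """

    image: RasterImage
    source_level: int
    effective_downsample: float
    crop: RegionL0
    transform: Transform = field(default_factory=Transform)
    scale_bar: ScaleBar | None = None
    margin_band_px: int = 0

    @property
    def body(self) -> np.ndarray:
        """The tissue pixels, excluding the scale-bar band."""
        h = self.image.height - self.margin_band_px
        return self.image.pixels[:h]


def extract_overview(
    slide: SlidePyramid,
    crop: RegionL0,
    target_px: int = 1000,
    transform: Transform = Transform(),
    with_scale_bar: bool = True,
) -> OverviewImage:
    """Render the overview for one slide crop.

    The crop is read at the level picked by :func:`choose_level` and box
    downsampled so its longest edge equals ``target_px`` (kept as-is when
    the data is already smaller — no upsampling).  A scale bar is computed
    from the slide's micron calibration; when calibration is absent the bar
    is suppressed with a warning, never fabricated.
    """
    w0, h0 = slide.dimensions
    clamped = crop.clamp(w0, h0)
    if clamped is None:
        raise EmptyRegionError(f"crop {crop} empty after clamping to {w0}x{h0}")
    # read from the coarsest level that still spans target_px, so the final
    # box resample only ever shrinks and the output lands exactly on target
    level = _coarsest_level_at_least(slide, clamped, target_px)
    raw = read_region(slide, clamped, level)
    rw, rh = raw.width, raw.height
    if max(rw, rh) > target_px:
        scale = target_px / max(rw, rh)
        out_w = target_px if rw >= rh else max(1, round(rw * scale))
        out_h = target_px if rh > rw else max(1, round(rh * scale))
        pixels = resize_area(raw.pixels, out_w, out_h)
    else:
        pixels = raw.pixels
        out_w, out_h = rw, rh
    eff_ds = clamped.w / out_w
    pixels = transform.apply(pixels)

    bar: ScaleBar | None = None
    band_h = 0
    if with_scale_bar:
        if slide.mpp is None:
            warnings.warn(
                f"{slide.source_path}: no micron calibration; rendering "
                "overview without a scale bar",
                stacklevel=2,
            )
        else:
            # the displayed horizontal axis follows the crop's y axis after
            # an odd number of quarter turns
            mpp_axis = slide.mpp[1] if transform.rotate90 % 2 else slide.mpp[0]
            bar = compute_scale_bar(mpp_axis * eff_ds, pixels.shape[1])
            pixels, band_h = _draw_scale_band(pixels, bar)

    return OverviewImage(
        image=RasterImage(
            pixels,
            provenance=f"overview({slide.source_path.name}, level={level})",
        ),
        source_level=level,
        effective_downsample=eff_ds,
        crop=clamped,
        transform=transform,
        scale_bar=bar,
        margin_band_px=band_h,
    )


# ---------------------------------------------------------------------------
# Insets
# ---------------------------------------------------------------------------

def resolve_roi(
    slide: SlidePyramid,
    roi: RegionL0 | None = None,
    roi_center: tuple[float, float] | None = None,
    physical_width_um: float | None = None,
) -> RegionL0:
    """Turn either ROI form into a level-0 rectangle.

    A centre + physical width needs calibration: the level-0 span is
    ``round(width_um / mpp)`` per axis (a 250 um inset at 0.25 um/px covers
    1000 level-0 px).  Without calibration the caller must pass a pixel-unit
    rectangle instead.
    """
    if roi is not None:
        return roi
    if roi_center is None or physical_width_um is None:
        raise ParameterError(
            "provide either roi, or roi_center with physical_width_um"
        )
    if slide.mpp is None:
        raise CalibrationMissingError(
            f"{slide.source_path}: no micron calibration — specify the "
            "inset as a pixel-unit roi (RegionL0) instead of a physical width"
        )
    w_l0 = round(physical_width_um / slide.mpp[0])
    h_l0 = round(physical_width_um / slide.mpp[1])
    return RegionL0(
        round(roi_center[0] - w_l0 / 2),
        round(roi_center[1] - h_l0 / 2),
        max(1, w_l0),
        max(1, h_l0),
    )


def extract_inset(
    slide: SlidePyramid,
    roi: RegionL0 | None = None,
    roi_center: tuple[float, float] | None = None,
    physical_width_um: float | None = None,
    out_px: int = 256,
    transform: Transform = Transform(),
) -> RasterImage:
    """High-magnification crop of a region of interest.

    The ROI is either an explicit level-0 rectangle or a centre point plus a
    physical width in microns (see :func:`resolve_roi`).  Data is read at
    the coarsest level that still spans ``out_px`` so the final resample only
    ever shrinks, then box-resampled to ``out_px`` wide.
    """
    if out_px < 64:
        raise ParameterError(f"out_px must be >= 64, got {out_px}")
    roi = resolve_roi(slide, roi, roi_center, physical_width_um)
    w0, h0 = slide.dimensions
    clamped = roi.clamp(w0, h0)
    if clamped is None:
        raise EmptyRegionError(f"inset roi {roi} empty after clamping")
    level = _coarsest_level_at_least(slide, clamped, out_px)
    raw = read_region(slide, clamped, level)
    if raw.width > out_px:
        out_h = max(1, round(raw.height * out_px / raw.width))
        pixels = resize_area(raw.pixels, out_px, out_h)
    else:
        pixels = raw.pixels
    pixels = transform.apply(pixels)
    return RasterImage(
        pixels, provenance=f"inset({slide.source_path.name}, roi={clamped})"
    )


# ---------------------------------------------------------------------------
# ROI annotation
# ---------------------------------------------------------------------------

def _draw_rect_outline(
    pixels: np.ndarray, x0: int, y0: int, x1: int, y1: int, thickness: int = 2
) -> None:
    h, w = pixels.shape[:2]
    x0c, y0c = max(0, x0), max(0, y0)
    x1c, y1c = min(w, x1), min(h, y1)
    if x1c <= x0c or y1c <= y0c:
        return
    t = thickness
    pixels[y0c : min(y0c + t, y1c), x0c:x1c] = 0
    pixels[max(y1c - t, y0c) : y1c, x0c:x1c] = 0
    pixels[y0c:y1c, x0c : min(x0c + t, x1c)] = 0
    pixels[y0c:y1c, max(x1c - t, x0c) : x1c] = 0


def annotate_roi(ov: OverviewImage, roi: RegionL0) -> OverviewImage:
    """Mark a level-0 ROI on an overview with a 2-px black rectangle.

    The ROI is mapped through the crop offset, the effective downsample and
    the overview's transform.  The input overview is left unmodified; a ROI
    that misses the crop entirely returns an unannotated copy with a warning.
    """
    inter = roi.intersect(ov.crop)
    pixels = ov.image.pixels.copy()
    if inter is None:
        warnings.warn(
            f"roi {roi} does not intersect overview crop {ov.crop}; "
            "skipping annotation",
            stacklevel=2,
        )
        return replace(
            ov, image=RasterImage(pixels, provenance=ov.image.provenance)
        )
    d = ov.effective_downsample
    rx = (inter.x - ov.crop.x) / d
    ry = (inter.y - ov.crop.y) / d
    rw, rh = inter.w / d, inter.h / d
    # untransformed body dims
    body_h = ov.image.height - ov.margin_band_px
    body_w = ov.image.width
    uw, uh = (
        (body_h, body_w) if ov.transform.rotate90 % 2 else (body_w, body_h)
    )
    tx, ty, tw, th = ov.transform.map_rect(rx, ry, rw, rh, uw, uh)
    x0, y0 = round(tx), round(ty)
    x1, y1 = round(tx + tw), round(ty + th)
    body = pixels[:body_h]
    _draw_rect_outline(body, x0, y0, x1, y1, thickness=2)
    return replace(
        ov,
        image=RasterImage(pixels, provenance=ov.image.provenance + "+roi"),
    )
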