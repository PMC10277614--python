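"""Pyramidal whole-slide image data model and reader.

Whole-slide scans are stored as image pyramids: level 0 is the full-resolution
scan and each subsequent level is a pre-computed reduction.  Every public API
in this package works in a single spatial reference frame — level-0 pixels,
origin at the top-left, half-open rectangles — so that callers never juggle
per-level coordinates.  Micron calibration (microns per level-0 pixel, MPP)
is carried alongside the pyramid and is the basis for physically correct
scale bars and micron-specified regions of interest.

Backends: generic pyramidal TIFF via :mod:`tifffile` (windowed reads through
its zarr interface), and Hamamatsu NDPI via :mod:`openslide` when that
optional dependency is importable.  Calibration comes from a JSON sidecar
``<slide>.meta.json`` (keys ``mpp_x``, ``mpp_y``), which is authoritative
over TIFF resolution tags because resolution-unit dialects are ambiguous;
for NDPI it comes from the vendor metadata.  Missing calibration is reported
as absent, never guessed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import zarr
from PIL import Image

logger = logging.getLogger("pathoverview")

__all__ = [
    "PathOverviewError",
    "SlideFormatError",
    "InvalidPyramidError",
    "EmptyRegionError",
    "CalibrationMissingError",
    "ParameterError",
    "RegionL0",
    "RasterImage",
    "SlidePyramid",
    "open_slide",
    "read_region",
    "thumbnail",
    "map_l0_to_level",
    "effective_mpp",
    "resize_area",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PathOverviewError(Exception):
    """Base class for all errors raised by this package."""


class SlideFormatError(PathOverviewError):
    """The file is not a slide format the backend can read."""


class InvalidPyramidError(SlideFormatError):
    """The file opened but its pyramid structure is inconsistent."""


class EmptyRegionError(PathOverviewError):
    """A requested region is empty after clamping to slide bounds."""


class CalibrationMissingError(PathOverviewError):
    """An operation needs micron calibration but the slide carries none."""


class ParameterError(PathOverviewError, ValueError):
    """A parameter is outside its documented domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionL0:
    """Half-open rectangle ``[x, x+w) x [y, y+h)`` in level-0 pixels.

    The origin is the slide's top-left corner.  ``w`` and ``h`` must be
    at least 1.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ParameterError(f"region must have w,h >= 1, got {self.w}x{self.h}")

    def clamp(self, level0_w: int, level0_h: int) -> "RegionL0 | None":
        """Intersect with the slide bounds; ``None`` if nothing remains."""
        x0 = max(self.x, 0)
        y0 = max(self.y, 0)
        x1 = min(self.x + self.w, level0_w)
        y1 = min(self.y + self.h, level0_h)
        if x1 <= x0 or y1 <= y0:
            return None
        return RegionL0(x0, y0, x1 - x0, y1 - y0)

    def intersect(self, other: "RegionL0") -> "RegionL0 | None":
        x0 = max(self.x, other.x)
        y0 = max(self.y, other.y)
        x1 = min(self.x + self.w, other.x + other.w)
        y1 = min(self.y + self.h, other.y + other.h)
        if x1 <= x0 or y1 <= y0:
            return None
        return RegionL0(x0, y0, x1 - x0, y1 - y0)


@dataclass
class RasterImage:
    """8-bit RGB raster plus a free-text note on where it came from."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError(f"RasterImage expects HxWx3, got shape {px.shape}")
        if px.dtype != np.uint8:
            px = np.clip(px, 0, 255).astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SlidePyramid:
    """Metadata handle for an opened pyramidal slide.

    ``level_dims`` are ``(width_px, height_px)`` pairs, level 0 first;
    ``level_downsamples`` start at 1.0 and strictly increase.  ``mpp`` is
    microns per level-0 pixel ``(x, y)`` or ``None`` when the file carries
    no trustworthy calibration.
    """

    source_path: Path
    level_count: int
    level_dims: list[tuple[int, int]]
    level_downsamples: list[float]
    mpp: tuple[float, float] | None = None
    vendor: str = "generic-tiff"

    def __post_init__(self) -> None:
        if self.level_count < 1 or len(self.level_dims) != self.level_count:
            raise InvalidPyramidError(
                f"{self.source_path}: pyramid must have >= 1 level"
            )
        ds = self.level_downsamples
        if abs(ds[0] - 1.0) > 1e-9 or any(b <= a for a, b in zip(ds, ds[1:])):
            raise InvalidPyramidError(
                f"{self.source_path}: downsamples must start at 1.0 and strictly "
                f"increase, got {ds}"
            )
        w0, h0 = self.level_dims[0]
        for k, (w, h) in enumerate(self.level_dims):
            d = ds[k]
            if abs(w - w0 / d) > 1.0 + 1e-6 or abs(h - h0 / d) > 1.0 + 1e-6:
                raise InvalidPyramidError(
                    f"{self.source_path}: level {k} dims {(w, h)} inconsistent with "
                    f"downsample {d} of level-0 dims {(w0, h0)}"
                )
        if self.mpp is not None:
            mx, my = self.mpp
            if not (0 < mx < 100 and 0 < my < 100):
                raise InvalidPyramidError(
                    f"{self.source_path}: implausible mpp {self.mpp}"
                )

    @property
    def dimensions(self) -> tuple[int, int]:
        """Level-0 ``(width, height)``."""
        return self.level_dims[0]


# ---------------------------------------------------------------------------
# Opening slides
# ---------------------------------------------------------------------------

def _sidecar_mpp(path: Path) -> tuple[float, float] | None:
    """Read the `<slide>.meta.json` calibration sidecar if present."""
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    try:
        mx, my = float(meta["mpp_x"]), float(meta["mpp_y"])
    except (KeyError, TypeError, ValueError):
        logger.warning("calibration sidecar %s is malformed; ignoring", sidecar)
        return None
    return (mx, my)


def _tag_mpp(page: "tifffile.TiffPage") -> tuple[float, float] | None:
    """Best-effort MPP from TIFF resolution tags; None unless plausible."""
    tags = page.tags
    try:
        unit = tags["ResolutionUnit"].value
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
    except KeyError:
        return None
    per_um = {2: 1 / 25400.0, 3: 1 / 10000.0}.get(int(unit))  # inch, cm
    if per_um is None:
        return None

    def _ratio(v: object) -> float:
        if isinstance(v, tuple):
            num, den = v
            return num / den if den else 0.0
        return float(v)

    rx, ry = _ratio(xres), _ratio(yres)
    if rx <= 0 or ry <= 0:
        return None
    mpp = (1.0 / (rx * per_um), 1.0 / (ry * per_um))
    if not all(0 < m < 100 for m in mpp):
        return None
    return mpp


def _open_tiff(path: Path) -> SlidePyramid:
    try:
        tf = tifffile.TiffFile(path)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise SlideFormatError(f"cannot read {path} as a TIFF slide: {exc}") from exc
    with tf:
        series = tf.series[0]
        levels = series.levels
        dims: list[tuple[int, int]] = []
        for lv in levels:
            shape = lv.shape
            if len(shape) < 2:
                raise InvalidPyramidError(f"{path}: level has shape {shape}")
            h, w = shape[0], shape[1]
            dims.append((int(w), int(h)))
        mpp = _sidecar_mpp(path)
        if mpp is None:
            mpp = _tag_mpp(series.pages[0])
    w0, h0 = dims[0]
    downs = [max(w0 / w, h0 / h) if (w, h) != (w0, h0) else 1.0 for w, h in dims]
    # Snap near-integer ratios so 8000/2000 reads as exactly 4.0.
    downs = [round(d) if abs(d - round(d)) < 0.02 and d >= 1 else d for d in downs]
    return SlidePyramid(
        source_path=path,
        level_count=len(dims),
        level_dims=dims,
        level_downsamples=[float(d) for d in downs],
        mpp=mpp,
        vendor="generic-tiff",
    )


def _open_ndpi(path: Path) -> SlidePyramid:
    try:
        import openslide
    except ImportError as exc:
        raise SlideFormatError(
            f"{path}: NDPI requires the optional openslide backend, which is "
            "not installed"
        ) from exc
    osl = openslide.OpenSlide(str(path))
    dims = [(int(w), int(h)) for w, h in osl.level_dimensions]
    downs = [float(d) for d in osl.level_downsamples]
    props = osl.properties
    mpp = None
    if "openslide.mpp-x" in props and "openslide.mpp-y" in props:
        mpp = (float(props["openslide.mpp-x"]), float(props["openslide.mpp-y"]))
    return SlidePyramid(
        source_path=path,
        level_count=len(dims),
        level_dims=dims,
        level_downsamples=downs,
        mpp=mpp,
        vendor="ndpi",
    )


def open_slide(path: str | Path) -> SlidePyramid:
    """Open a pyramidal slide (generic/pyramidal TIFF, or NDPI via openslide).

    Raises :class:`SlideFormatError` for unreadable or non-slide files and
    :class:`InvalidPyramidError` when the pyramid violates its invariants.
    Missing micron calibration yields ``mpp=None``; it is never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise SlideFormatError(f"slide file not found: {path}")
    if path.suffix.lower() == ".ndpi":
        return _open_ndpi(path)
    return _open_tiff(path)


# ---------------------------------------------------------------------------
# Coordinate mapping and region reads
# ---------------------------------------------------------------------------

def map_l0_to_level(region: RegionL0, downsample: float) -> tuple[int, int, int, int]:
    """Map a level-0 rectangle into level space at the given downsample.

    Offsets are floored; sizes are rounded but never below 1 px, so a
    sub-pixel region still addresses one level pixel.  The round trip back
    to level 0 errs by less than ``downsample`` px per coordinate.
    """
    if downsample < 1:
        raise ParameterError(f"downsample must be >= 1, got {downsample}")
    x = int(region.x // downsample)
    y = int(region.y // downsample)
    w = max(1, round(region.w / downsample))
    h = max(1, round(region.h / downsample))
    return (x, y, w, h)


def _read_level_window(
    slide: SlidePyramid, level: int, x: int, y: int, w: int, h: int
) -> np.ndarray:
    """Read a window from one pyramid level as uint8 RGB."""
    if slide.vendor == "ndpi":
        import openslide

        osl = openslide.OpenSlide(str(slide.source_path))
        d = slide.level_downsamples[level]
        img = osl.read_region((int(x * d), int(y * d)), level, (w, h))
        return np.asarray(img.convert("RGB"))
    with tifffile.TiffFile(slide.source_path) as tf:
        store = tf.series[0].aszarr()
        root = zarr.open(store, mode="r")
        # a pyramidal series opens as a multiscales group keyed by level
        arr = root[str(level)] if isinstance(root, zarr.Group) else root
        lw, lh = slide.level_dims[level]
        x1, y1 = min(x + w, lw), min(y + h, lh)
        window = np.asarray(arr[y:y1, x:x1])
    if window.ndim == 2:
        window = np.stack([window] * 3, axis=-1)
    return np.ascontiguousarray(window[..., :3]).astype(np.uint8, copy=False)


def read_region(slide: SlidePyramid, region: RegionL0, level: int) -> RasterImage:
    """Read the level-``level`` pixels covering a level-0 region.

    The region is clamped to the slide bounds; a region that clamps to
    nothing raises :class:`EmptyRegionError`.  The returned image has
    dimensions ``(round(w/d), round(h/d))`` within 1 px, where ``d`` is the
    level's downsample.
    """
    if not (0 <= level < slide.level_count):
        raise IndexError(
            f"level {level} out of range [0, {slide.level_count}) for "
            f"{slide.source_path}"
        )
    w0, h0 = slide.dimensions
    clamped = region.clamp(w0, h0)
    if clamped is None:
        raise EmptyRegionError(
            f"region {region} is empty after clamping to {w0}x{h0}"
        )
    d = slide.level_downsamples[level]
    x, y, w, h = map_l0_to_level(clamped, d)
    pixels = _read_level_window(slide, level, x, y, w, h)
    return RasterImage(
        pixels,
        provenance=(
            f"{slide.source_path.name} level={level} d={d} region="
            f"({clamped.x},{clamped.y},{clamped.w},{clamped.h})"
        ),
    )


def resize_area(pixels: np.ndarray, out_w: int, out_h: int) -> np.ndarray:
    """Deterministic area-average (box filter) resample to ``out_w x out_h``."""
    if pixels.shape[1] == out_w and pixels.shape[0] == out_h:
        return pixels.copy()
    img = Image.fromarray(pixels)
    return np.asarray(img.resize((out_w, out_h), Image.Resampling.BOX))


def thumbnail(slide: SlidePyramid, max_px: int) -> tuple[RasterImage, float]:
    """Whole-slide thumbnail with max dimension ``<= max_px``.

    Reads the coarsest pyramid level that still has max dimension
    ``>= max_px`` and box-downsamples it; a slide already smaller than
    ``max_px`` is returned at its finest available size (never upsampled).
    Returns the image and the effective downsample relative to level 0.
    """
    if max_px < 64:
        raise ParameterError(f"max_px must be >= 64, got {max_px}")
    w0, h0 = slide.dimensions
    # coarsest level whose max dim still reaches max_px
    level = 0
    for k in range(slide.level_count):
        if max(slide.level_dims[k]) >= max_px:
            level = k
        else:
            break
    lw, lh = slide.level_dims[level]
    pixels = _read_level_window(slide, level, 0, 0, lw, lh)
    if max(lw, lh) > max_px:
        scale = max_px / max(lw, lh)
        out_w = max_px if lw >= lh else max(1, round(lw * scale))
        out_h = max_px if lh > lw else max(1, round(lh * scale))
        pixels = resize_area(pixels, out_w, out_h)
    eff = max(w0, h0) / max(pixels.shape[1], pixels.shape[0])
    return (
        RasterImage(pixels, provenance=f"thumbnail({slide.source_path.name})"),
        float(eff),
    )


def effective_mpp(slide: SlidePyramid, level: int) -> tuple[float, float]:
    """Microns per pixel at a pyramid level (mpp scaled by its downsample).

    Raises :class:`CalibrationMissingError` when the slide carries no
    calibration — consumers must then suppress scale bars, never invent one.
    """
    if slide.mpp is None:
        raise CalibrationMissingError(
            f"{slide.source_path}: no micron calibration; scale bars must be "
            "suppressed"
        )
    if not (0 <= level < slide.level_count):
        raise IndexError(f"level {level} out of range")
    d = slide.level_downsamples[level]
    return (slide.mpp[0] * d, slide.mpp[1] * d)
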