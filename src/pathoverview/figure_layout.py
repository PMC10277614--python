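"""Patient-level grid figures: rows of samples x columns of stains.

A figure config declares, per panel, which slide to show (or a placeholder
text when histology is unavailable), the stain label, an optional region of
interest for the inset, and an orientation transform.  Panels are rendered
independently — overview crop (automatic tissue box unless overridden),
annotated ROI rectangle, inset composited top-right with a black border,
label band — and placed row-major on a white canvas with gutters.  A JSON
manifest records, per panel, the crop actually used, pyramid level,
downsample, scale-bar length and any warnings, so every figure is auditable.
Composition is pure: reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw, ImageFont

from .extraction import (
    BAND_FRAC,
    Transform,
    annotate_roi,
    extract_inset,
    extract_overview,
    resolve_roi,
)
from .tissue_detection import detect_tissue_bbox
from .wsi_core import (
    ParameterError,
    PathOverviewError,
    RasterImage,
    RegionL0,
    open_slide,
)

logger = logging.getLogger("pathoverview")

__all__ = [
    "FigureError",
    "RoiSpec",
    "PanelSpec",
    "FigureConfig",
    "load_figure_config",
    "layout_dims",
    "render_panel",
    "compose_figure",
    "save_figure",
    "atomic_write_bytes",
    "atomic_write_text",
]


class FigureError(PathOverviewError):
    """Figure-level failure (e.g. every panel failed to render)."""


# ---------------------------------------------------------------------------
# Config model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """Inset ROI: either a level-0 rectangle or centre + physical width."""

    region: RegionL0 | None = None
    center: tuple[float, float] | None = None
    physical_width_um: float | None = None

    def __post_init__(self) -> None:
        has_rect = self.region is not None
        has_um = self.center is not None and self.physical_width_um is not None
        if has_rect == has_um:
            raise ParameterError(
                "roi needs exactly one of: region, or center+physical_width_um"
            )


@dataclass
class PanelSpec:
    row_label: str
    stain: str
    slide_path: Path | None = None
    placeholder_text: str | None = None
    roi: RoiSpec | None = None
    transform: Transform = field(default_factory=Transform)
    tissue_bbox: RegionL0 | None = None  # manual override of auto detection

    def __post_init__(self) -> None:
        if (self.slide_path is None) == (self.placeholder_text is None):
            raise ParameterError(
                f"panel '{self.row_label}/{self.stain}': exactly one of "
                "slide_path / placeholder_text must be given"
            )


@dataclass
class FigureConfig:
    patient_id: str
    panels: list[PanelSpec]
    cols: int = 4
    panel_px: tuple[int, int] = (800, 640)
    inset_frac: float = 0.3
    gutter_px: int = 24
    label_band_px: int = 48
    scale_bar: bool = True
    bbox_margin_frac: float = 0.02
    output_path: Path | None = None
    output_format: str = "png"

    def __post_init__(self) -> None:
        if not self.panels:
            raise ParameterError("figure needs at least one panel")
        if self.cols < 1:
            raise ParameterError("cols must be >= 1")
        if min(self.panel_px) < 128:
            raise ParameterError("panel dims must be >= 128 px")
        if not (0.05 <= self.inset_frac <= 0.9):
            raise ParameterError("inset_frac must be in [0.05, 0.9]")


def _parse_region(raw) -> RegionL0:
    if isinstance(raw, dict):
        return RegionL0(int(raw["x"]), int(raw["y"]), int(raw["w"]), int(raw["h"]))
    return RegionL0(*(int(v) for v in raw))


def _parse_roi(raw) -> RoiSpec:
    if "region" in raw:
        return RoiSpec(region=_parse_region(raw["region"]))
    return RoiSpec(
        center=(float(raw["center"][0]), float(raw["center"][1])),
        physical_width_um=float(raw["physical_width_um"]),
    )


def load_figure_config(path: str | Path) -> FigureConfig:
    """Load a figure config from YAML or JSON (see docs for the schema)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"figure config not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "panels" not in raw:
        raise ParameterError(f"{path}: figure config must be a mapping with 'panels'")
    base = path.parent
    panels = []
    for p in raw["panels"]:
        slide_path = p.get("slide_path")
        if slide_path is not None:
            slide_path = Path(slide_path)
            if not slide_path.is_absolute():
                slide_path = base / slide_path
        tr = p.get("transform", {})
        panels.append(
            PanelSpec(
                row_label=str(p.get("row_label", "")),
                stain=str(p.get("stain", "")),
                slide_path=slide_path,
                placeholder_text=p.get("placeholder_text"),
                roi=_parse_roi(p["roi"]) if p.get("roi") else None,
                transform=Transform(
                    rotate90=int(tr.get("rotate90", 0)),
                    flip_h=bool(tr.get("flip_h", False)),
                ),
                tissue_bbox=(
                    _parse_region(p["tissue_bbox"]) if p.get("tissue_bbox") else None
                ),
            )
        )
    out = raw.get("output", {}) or {}
    out_path = out.get("path")
    return FigureConfig(
        patient_id=str(raw.get("patient_id", "")),
        panels=panels,
        cols=int(raw.get("cols", 4)),
        panel_px=tuple(raw.get("panel_px", (800, 640))),
        inset_frac=float(raw.get("inset_frac", 0.3)),
        gutter_px=int(raw.get("gutter_px", 24)),
        label_band_px=int(raw.get("label_band_px", 48)),
        scale_bar=bool(raw.get("scale_bar", True)),
        bbox_margin_frac=float(raw.get("bbox_margin_frac", 0.02)),
        output_path=Path(out_path) if out_path else None,
        output_format=str(out.get("format", "png")),
    )


# ---------------------------------------------------------------------------
# Layout arithmetic
# ---------------------------------------------------------------------------

def layout_dims(cfg: FigureConfig) -> tuple[int, int]:
    """Canvas size: cols x rows of (panel + label band) with gutters between."""
    rows = math.ceil(len(cfg.panels) / cfg.cols)
    pw, ph = cfg.panel_px
    w = cfg.cols * pw + (cfg.cols - 1) * cfg.gutter_px
    h = rows * (ph + cfg.label_band_px) + (rows - 1) * cfg.gutter_px
    return (w, h)


# ---------------------------------------------------------------------------
# Panel rendering
# ---------------------------------------------------------------------------

def _label_band(width: int, height: int, text: str) -> np.ndarray:
    band = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(band)
    draw.text((6, max(2, (height - 11) // 2)), text, fill=(0, 0, 0),
              font=ImageFont.load_default())
    return np.asarray(band)


def _placeholder_panel(cfg: FigureConfig, text: str) -> np.ndarray:
    pw, ph = cfg.panel_px
    panel = Image.new("RGB", (pw, ph), (230, 230, 230))
    draw = ImageDraw.Draw(panel)
    font = ImageFont.load_default()
    tw = draw.textlength(text, font=font)
    draw.text(((pw - tw) / 2, ph / 2 - 6), text, fill=(60, 60, 60), font=font)
    return np.asarray(panel)


def _fit_target_px(cfg: FigureConfig, crop: RegionL0, transform: Transform) -> int:
    """Max-dim target so the overview (plus scale-bar band) fits the panel."""
    pw, ph = cfg.panel_px
    dw, dh = transform.out_dims(crop.w, crop.h)
    longest = max(dw, dh)
    t_w = pw * longest / dw
    band_allow = (ph - 24) / (1 + BAND_FRAC)
    t_h = band_allow * longest / dh
    return max(64, int(min(t_w, t_h, pw)))


def render_panel(spec: PanelSpec, cfg: FigureConfig) -> tuple[np.ndarray, dict]:
    """Render one panel (overview + optional inset + label band).

    Returns the panel raster of size ``(panel_w, panel_h + label_band)`` and
    a manifest entry.  A slide that fails to open degrades to a placeholder
    panel carrying the error text; the figure still completes.
    """
    pw, ph = cfg.panel_px
    entry: dict = {
        "row_label": spec.row_label,
        "stain": spec.stain,
        "slide": str(spec.slide_path) if spec.slide_path else None,
        "warnings": [],
    }
    if spec.placeholder_text is not None:
        panel = _placeholder_panel(cfg, spec.placeholder_text)
        entry["placeholder"] = spec.placeholder_text
    else:
        try:
            panel, entry = _render_slide_panel(spec, cfg, entry)
        except PathOverviewError as exc:
            msg = f"{type(exc).__name__}: {exc}"
            logger.warning("panel %s/%s failed: %s", spec.row_label, spec.stain, msg)
            entry["warnings"].append(msg)
            entry["placeholder"] = "render failed"
            panel = _placeholder_panel(cfg, "render failed")
    band = _label_band(pw, cfg.label_band_px, f"{spec.row_label}  {spec.stain}")
    return np.vstack([panel, band]), entry


def _render_slide_panel(
    spec: PanelSpec, cfg: FigureConfig, entry: dict
) -> tuple[np.ndarray, dict]:
    pw, ph = cfg.panel_px
    slide = open_slide(spec.slide_path)
    crop = spec.tissue_bbox
    if crop is None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            crop = detect_tissue_bbox(slide, margin_frac=cfg.bbox_margin_frac)
        entry["warnings"] += [str(w.message) for w in caught]
        entry["tissue_bbox_source"] = "auto"
    else:
        entry["tissue_bbox_source"] = "manual"
    target = _fit_target_px(cfg, crop, spec.transform)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ov = extract_overview(
            slide, crop, target_px=target, transform=spec.transform,
            with_scale_bar=cfg.scale_bar,
        )
        roi_l0 = None
        if spec.roi is not None:
            roi_l0 = resolve_roi(
                slide, spec.roi.region, spec.roi.center, spec.roi.physical_width_um
            )
            ov = annotate_roi(ov, roi_l0)
    entry["warnings"] += [str(w.message) for w in caught]

    panel = np.full((ph, pw, 3), 255, dtype=np.uint8)
    img = ov.image.pixels
    ih, iw = img.shape[:2]
    if ih > ph or iw > pw:  # safety net; _fit_target_px should prevent this
        from .wsi_core import resize_area

        s = min(pw / iw, ph / ih)
        img = resize_area(img, max(1, int(iw * s)), max(1, int(ih * s)))
        ih, iw = img.shape[:2]
    ox, oy = (pw - iw) // 2, (ph - ih) // 2
    panel[oy : oy + ih, ox : ox + iw] = img

    if spec.roi is not None and roi_l0 is not None:
        inset_w = max(64, round(cfg.inset_frac * pw))
        inset = extract_inset(
            slide, roi=roi_l0, out_px=inset_w, transform=spec.transform
        ).pixels
        bh, bw = inset.shape[:2]
        bordered = np.zeros((bh + 4, bw + 4, 3), dtype=np.uint8)  # 2-px black border
        bordered[2:-2, 2:-2] = inset
        panel[0 : bordered.shape[0], pw - bordered.shape[1] : pw] = bordered
        entry["inset_px"] = [int(bw), int(bh)]
        entry["roi_l0"] = [roi_l0.x, roi_l0.y, roi_l0.w, roi_l0.h]

    entry.update(
        {
            "crop": [crop.x, crop.y, crop.w, crop.h],
            "level": ov.source_level,
            "downsample": ov.effective_downsample,
            "scale_bar_um": ov.scale_bar.length_um if ov.scale_bar else None,
        }
    )
    return panel, entry


# ---------------------------------------------------------------------------
# Figure composition
# ---------------------------------------------------------------------------

def compose_figure(cfg: FigureConfig) -> tuple[RasterImage, dict]:
    """Render every panel and place them row-major on a white canvas.

    Raises :class:`FigureError` only if *all* panels fail; individual
    failures degrade to placeholder panels recorded in the manifest.
    """
    cw, ch = layout_dims(cfg)
    canvas = np.full((ch, cw, 3), 255, dtype=np.uint8)
    pw, ph = cfg.panel_px
    cell_h = ph + cfg.label_band_px
    entries = []
    failures = 0
    for i, spec in enumerate(cfg.panels):
        panel, entry = render_panel(spec, cfg)
        if entry.get("placeholder") == "render failed":
            failures += 1
        r, c = divmod(i, cfg.cols)
        x = c * (pw + cfg.gutter_px)
        y = r * (cell_h + cfg.gutter_px)
        canvas[y : y + cell_h, x : x + pw] = panel
        entries.append(entry)
    if failures == len(cfg.panels) and not any(
        p.placeholder_text for p in cfg.panels
    ):
        raise FigureError(f"figure {cfg.patient_id}: all panels failed to render")
    manifest = {
        "patient_id": cfg.patient_id,
        "canvas_px": [cw, ch],
        "panels": entries,
        "warning_count": sum(len(e["warnings"]) for e in entries),
    }
    return RasterImage(canvas, provenance=f"figure({cfg.patient_id})"), manifest


def atomic_write_bytes(path: Path, data: bytes) -> None:
    """Write via a temp file in the same directory then rename (atomic)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


def _encode_png(pixels: np.ndarray, fmt: str = "png") -> bytes:
    import io

    buf = io.BytesIO()
    Image.fromarray(pixels).save(buf, format=fmt.upper())
    return buf.getvalue()


def save_figure(cfg: FigureConfig, out_path: str | Path | None = None) -> dict:
    """Compose the figure and write image + ``<figure>.manifest.json``.

    Both files are written atomically (temp + rename).  Returns the manifest.
    """
    out = Path(out_path) if out_path else cfg.output_path
    if out is None:
        raise ParameterError("no output path: set output.path or pass out_path")
    image, manifest = compose_figure(cfg)
    atomic_write_bytes(out, _encode_png(image.pixels, cfg.output_format))
    atomic_write_text(
        out.with_suffix(out.suffix + ".manifest.json"),
        json.dumps(manifest, indent=1, sort_keys=True),
    )
    return manifest
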