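"""Deterministic pyramidal-slide fixtures with machine-readable ground truth.

Real whole-slide scans are multi-gigabyte vendor files; these fixtures stand
in for them so the reader, tissue detector, and figure composer can all be
exercised against known geometry.  A fixture is a white slide carrying one
or more elliptical "tissue" blobs (emulating an H&E or IHC section) and,
optionally, a checkerboard region of interest whose exact pixels are
predictable, plus two JSON sidecars: the micron calibration and the ground
truth (tight tissue bounding box, ROI rectangle, spec echo).

Every pyramid level is rendered analytically at its own scale — sampling
the same continuous scene at pixel centres — rather than by downsampling
level 0.  Level-consistency tests therefore exercise the reader, not the
generator.  Geometry is fully deterministic; the seed only drives optional
speckle noise (off by default), so identical spec+seed runs produce
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .wsi_core import ParameterError, RegionL0

__all__ = [
    "SlideSpecError",
    "TissueEllipse",
    "CheckerboardROI",
    "SlideSpec",
    "GroundTruth",
    "render_level",
    "generate_slide",
    "load_slide_spec",
    "random_slide_spec",
    "paper_panel_suite",
    "PANEL_STAINS",
    "STAIN_FILLS",
]


class SlideSpecError(ParameterError):
    """A slide spec violates its own constraints."""


@dataclass(frozen=True)
class TissueEllipse:
    """Axis-aligned ellipse in level-0 coordinates emulating a tissue section."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    fill_rgb: tuple[int, int, int] = (160, 90, 150)


@dataclass(frozen=True)
class CheckerboardROI:
    """Checkerboard patch with period ``period_px`` (level-0 px) inside ``region``."""

    region: RegionL0
    period_px: int = 64
    rgb_a: tuple[int, int, int] = (60, 30, 90)
    rgb_b: tuple[int, int, int] = (220, 190, 230)


@dataclass
class SlideSpec:
    level0_dims: tuple[int, int] = (8000, 6000)
    downsamples: tuple[float, ...] = (1, 4, 16, 64)
    mpp: tuple[float, float] = (0.25, 0.25)
    background_rgb: tuple[int, int, int] = (255, 255, 255)
    tissue_shapes: list[TissueEllipse] = field(default_factory=list)
    roi_pattern: CheckerboardROI | None = None
    seed: int = 0
    speckle: float = 0.0  # stddev of optional additive noise, 0 disables

    def __post_init__(self) -> None:
        ds = self.downsamples
        if not ds or ds[0] != 1 or any(b <= a for a, b in zip(ds, ds[1:])):
            raise SlideSpecError(f"downsamples must start at 1 and increase: {ds}")
        w0, h0 = self.level0_dims
        for sh in self.tissue_shapes:
            (cx, cy), (a, b) = sh.center, sh.semi_axes
            if a <= 0 or b <= 0:
                raise SlideSpecError(f"ellipse semi-axes must be > 0: {sh}")
            if cx - a < 0 or cy - b < 0 or cx + a > w0 or cy + b > h0:
                raise SlideSpecError(f"ellipse exceeds level-0 bounds {w0}x{h0}: {sh}")
        if self.roi_pattern is not None:
            r = self.roi_pattern.region
            if self.roi_pattern.period_px < 2:
                raise SlideSpecError("checkerboard period_px must be >= 2")
            if r.clamp(w0, h0) != r:
                raise SlideSpecError(f"roi region exceeds level-0 bounds: {r}")


@dataclass
class GroundTruth:
    """What the generator knows exactly about a written fixture."""

    tissue_bbox_l0: RegionL0
    roi_region: RegionL0 | None
    spec: SlideSpec

    def to_json(self) -> str:
        def _region(r: RegionL0 | None):
            return None if r is None else {"x": r.x, "y": r.y, "w": r.w, "h": r.h}

        payload = {
            "tissue_bbox_l0": _region(self.tissue_bbox_l0),
            "roi_region": _region(self.roi_region),
            "spec": json.loads(json.dumps(asdict(self.spec), default=_plain)),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _plain(obj):
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(obj)


def _truth_bbox(spec: SlideSpec) -> RegionL0:
    """Tight integer union bbox of all shape extents (exact arithmetic)."""
    if not spec.tissue_shapes:
        w0, h0 = spec.level0_dims
        return RegionL0(0, 0, w0, h0)
    x0 = min(math.floor(s.center[0] - s.semi_axes[0]) for s in spec.tissue_shapes)
    y0 = min(math.floor(s.center[1] - s.semi_axes[1]) for s in spec.tissue_shapes)
    x1 = max(math.ceil(s.center[0] + s.semi_axes[0]) for s in spec.tissue_shapes)
    y1 = max(math.ceil(s.center[1] + s.semi_axes[1]) for s in spec.tissue_shapes)
    w0, h0 = spec.level0_dims
    x0, y0 = max(0, x0), max(0, y0)
    return RegionL0(x0, y0, min(w0, x1) - x0, min(h0, y1) - y0)


def render_level(spec: SlideSpec, downsample: float) -> np.ndarray:
    """Analytic rendering of the scene at one pyramid scale.

    Pixel ``(i, j)`` at downsample ``d`` samples the continuous scene at the
    level-0 point ``((j+0.5)d, (i+0.5)d)``, so level 0 agrees exactly with an
    integer-grid rasterisation and coarser levels are true point samples of
    the same scene.
    """
    w0, h0 = spec.level0_dims
    w = max(1, round(w0 / downsample))
    h = max(1, round(h0 / downsample))
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.background_rgb
    ys = (np.arange(h, dtype=np.float64) + 0.5) * downsample  # level-0 y of centres
    xs = (np.arange(w, dtype=np.float64) + 0.5) * downsample
    for shape in spec.tissue_shapes:
        (cx, cy), (a, b) = shape.center, shape.semi_axes
        inside = (((xs - cx) / a) ** 2)[None, :] + (((ys - cy) / b) ** 2)[:, None] <= 1.0
        img[inside] = shape.fill_rgb
    roi = spec.roi_pattern
    if roi is not None:
        r = roi.region
        in_x = np.flatnonzero((xs >= r.x) & (xs < r.x + r.w))
        in_y = np.flatnonzero((ys >= r.y) & (ys < r.y + r.h))
        if in_x.size and in_y.size:
            kx = np.floor((xs[in_x] - r.x) / roi.period_px).astype(np.int64)
            ky = np.floor((ys[in_y] - r.y) / roi.period_px).astype(np.int64)
            parity = (ky[:, None] + kx[None, :]) % 2
            tile = np.where(
                (parity == 0)[..., None],
                np.uint8(roi.rgb_a),
                np.uint8(roi.rgb_b),
            ).astype(np.uint8)
            img[np.ix_(in_y, in_x)] = tile
    if spec.speckle > 0:
        rng = np.random.default_rng((spec.seed, int(round(downsample))))
        noise = rng.normal(0.0, spec.speckle, size=img.shape)
        img = np.clip(img.astype(np.float64) + noise, 0, 255).astype(np.uint8)
    return img


def generate_slide(spec: SlideSpec, out_path: str | Path) -> GroundTruth:
    """Write a pyramidal TIFF fixture plus calibration and truth sidecars.

    The TIFF is uncompressed and tiled 256x256 for bit-exact reproducibility;
    identical spec+seed yields byte-identical files.  Sidecars are
    ``<slide>.meta.json`` (mpp) and ``<slide>.truth.json`` (ground truth).
    """
    out_path = Path(out_path)
    levels = [render_level(spec, d) for d in spec.downsamples]
    with tifffile.TiffWriter(out_path) as tw:
        tw.write(
            levels[0],
            subifds=len(levels) - 1,
            tile=(256, 256),
            compression=None,
            photometric="rgb",
            software="pathoverview-synthetic",
        )
        for lv in levels[1:]:
            tw.write(
                lv,
                subfiletype=1,
                tile=(256, 256),
                compression=None,
                photometric="rgb",
            )
    meta = {"mpp_x": spec.mpp[0], "mpp_y": spec.mpp[1]}
    out_path.with_suffix(out_path.suffix + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True)
    )
    truth = GroundTruth(
        tissue_bbox_l0=_truth_bbox(spec),
        roi_region=spec.roi_pattern.region if spec.roi_pattern else None,
        spec=spec,
    )
    out_path.with_suffix(out_path.suffix + ".truth.json").write_text(truth.to_json())
    return truth


def load_slide_spec(path: str | Path) -> SlideSpec:
    """Load a SlideSpec from a YAML or JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SlideSpecError(f"{path}: slide spec must be a mapping")
    shapes = [
        TissueEllipse(
            center=tuple(s["center"]),
            semi_axes=tuple(s["semi_axes"]),
            fill_rgb=tuple(s.get("fill_rgb", (160, 90, 150))),
        )
        for s in raw.get("tissue_shapes", [])
    ]
    roi = None
    if raw.get("roi_pattern"):
        rp = raw["roi_pattern"]
        roi = CheckerboardROI(
            region=RegionL0(*rp["region"]),
            period_px=int(rp.get("period_px", 64)),
            rgb_a=tuple(rp.get("rgb_a", (60, 30, 90))),
            rgb_b=tuple(rp.get("rgb_b", (220, 190, 230))),
        )
    return SlideSpec(
        level0_dims=tuple(raw.get("level0_dims", (8000, 6000))),
        downsamples=tuple(raw.get("downsamples", (1, 4, 16, 64))),
        mpp=tuple(raw.get("mpp", (0.25, 0.25))),
        background_rgb=tuple(raw.get("background_rgb", (255, 255, 255))),
        tissue_shapes=shapes,
        roi_pattern=roi,
        seed=int(raw.get("seed", 0)),
        speckle=float(raw.get("speckle", 0.0)),
    )


# The 11 Table-1 markers plus H&E, the lineage/QC stains (CD45, pan-keratin
# AE1/AE3) and the light chains — one fixture per column of a full
# immunophenotyping panel figure.
PANEL_STAINS: tuple[str, ...] = (
    "H&E",
    "CD45",
    "AE1/AE3",
    "CD20",
    "CD79A",
    "CD3",
    "BCL2",
    "CD56",
    "CD10",
    "BCL6",
    "MUM1",
    "CD138",
    "CD30",
    "EBER",
    "IgK",
    "IgL",
)

# Stain-specific tissue fills: pink/purple for H&E, DAB-brown shades for IHC
# markers, deep blue-black for the EBER chromogen.
STAIN_FILLS: dict[str, tuple[int, int, int]] = {
    "H&E": (205, 120, 175),
    "CD45": (140, 85, 40),
    "AE1/AE3": (235, 225, 210),
    "CD20": (130, 75, 35),
    "CD79A": (145, 90, 45),
    "CD3": (200, 170, 140),
    "BCL2": (120, 70, 30),
    "CD56": (225, 215, 200),
    "CD10": (230, 220, 205),
    "BCL6": (190, 160, 130),
    "MUM1": (125, 72, 32),
    "CD138": (210, 185, 155),
    "CD30": (135, 80, 38),
    "EBER": (40, 45, 90),
    "IgK": (150, 95, 50),
    "IgL": (170, 120, 75),
}


def random_slide_spec(seed: int) -> SlideSpec:
    """Randomised small single-ellipse slide for detection-robustness sweeps.

    Geometry and fill are drawn from ``seed``: an ellipse covering 12-35% of
    each slide dimension, placed fully inside a 1280x960 slide at 0.5 um/px.
    """
    rng = np.random.default_rng(seed)
    w0, h0 = 1280, 960
    a = float(rng.uniform(0.12, 0.35) * w0)
    b = float(rng.uniform(0.12, 0.35) * h0)
    cx = float(rng.uniform(a, w0 - a))
    cy = float(rng.uniform(b, h0 - b))
    fill = tuple(int(v) for v in rng.integers(30, 200, 3))
    return SlideSpec(
        level0_dims=(w0, h0),
        downsamples=(1, 4),
        mpp=(0.5, 0.5),
        tissue_shapes=[TissueEllipse(center=(cx, cy), semi_axes=(a, b),
                                     fill_rgb=fill)],
        seed=seed,
    )


def _slug(label: str) -> str:
    return label.replace("&", "").replace("/", "-").replace(" ", "_")


def paper_panel_suite(
    out_dir: str | Path,
    seed: int = 0,
    level0_dims: tuple[int, int] = (2000, 1500),
) -> list[tuple[Path, GroundTruth, str]]:
    """One fixture per stain of a full IHC panel, sharing identical geometry.

    Emulates the serial sections of a multi-stain characterisation figure:
    the same tissue profile (one ellipse plus a checkerboard ROI) rendered
    with a stain-specific fill per label.  Returns (path, truth, stain)
    triples in panel order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    w0, h0 = level0_dims
    ellipse_kwargs = dict(
        center=(w0 / 2, h0 / 2),
        semi_axes=(w0 * 0.3, h0 * 0.27),
    )
    roi = CheckerboardROI(
        region=RegionL0(round(w0 * 0.44), round(h0 * 0.42), round(w0 * 0.12), round(w0 * 0.12)),
        period_px=16,
    )
    results: list[tuple[Path, GroundTruth, str]] = []
    for stain in PANEL_STAINS:
        spec = SlideSpec(
            level0_dims=level0_dims,
            downsamples=(1, 4, 16),
            tissue_shapes=[TissueEllipse(fill_rgb=STAIN_FILLS[stain], **ellipse_kwargs)],
            roi_pattern=roi,
            seed=seed,
        )
        path = out_dir / f"{_slug(stain)}.tiff"
        truth = generate_slide(spec, path)
        results.append((path, truth, stain))
    return results
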