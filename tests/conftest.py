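"""Shared fixtures and the independent scene rasteriser used as an oracle.

The oracle renders the same continuous scene as the slide generator —
pixel (i, j) at downsample d samples the level-0 point ((j+0.5)d, (i+0.5)d)
— but with scalar per-pixel loops and its own arithmetic, so pixel-exact
agreement genuinely cross-checks generator and reader.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathoverview import (
    CheckerboardROI,
    RegionL0,
    SlideSpec,
    TissueEllipse,
    generate_slide,
    open_slide,
)
from pathoverview.synthetic_slides import random_slide_spec  # noqa: F401
# re-exported for tests; randomised geometry lives with the generator


def oracle_window(
    spec: SlideSpec, lx: int, ly: int, w: int, h: int, downsample: float = 1.0
) -> np.ndarray:
    """Independent rasterisation of a level-space window of the scene."""
    out = np.empty((h, w, 3), dtype=np.uint8)
    roi = spec.roi_pattern
    for i in range(h):
        y = (ly + i + 0.5) * downsample
        for j in range(w):
            x = (lx + j + 0.5) * downsample
            colour = spec.background_rgb
            for shape in spec.tissue_shapes:
                (cx, cy), (a, b) = shape.center, shape.semi_axes
                dx, dy = (x - cx) / a, (y - cy) / b
                if dx * dx + dy * dy <= 1.0:
                    colour = shape.fill_rgb
            if roi is not None:
                r = roi.region
                if r.x <= x < r.x + r.w and r.y <= y < r.y + r.h:
                    kx = int((x - r.x) // roi.period_px)
                    ky = int((y - r.y) // roi.period_px)
                    colour = roi.rgb_a if (kx + ky) % 2 == 0 else roi.rgb_b
            out[i, j] = colour
    return out


def make_ellipse_spec() -> SlideSpec:
    """The canonical 8000x6000 fixture: one ellipse + a checkerboard ROI."""
    return SlideSpec(
        level0_dims=(8000, 6000),
        downsamples=(1, 4, 16),
        mpp=(0.25, 0.25),
        tissue_shapes=[
            TissueEllipse(center=(4000, 3000), semi_axes=(2500, 1500),
                          fill_rgb=(140, 110, 160))
        ],
        roi_pattern=CheckerboardROI(
            region=RegionL0(3500, 2500, 1000, 1000), period_px=64
        ),
    )


@pytest.fixture(scope="session")
def ellipse_spec():
    return make_ellipse_spec()


@pytest.fixture(scope="session")
def ellipse_slide(tmp_path_factory, ellipse_spec):
    """(path, ground truth, opened SlidePyramid) for the canonical fixture."""
    path = tmp_path_factory.mktemp("slides") / "ellipse.tiff"
    truth = generate_slide(ellipse_spec, path)
    return path, truth, open_slide(path)


@pytest.fixture(scope="session")
def uncalibrated_slide(tmp_path_factory, ellipse_spec):
    """Same scene but with the calibration sidecar removed after writing."""
    path = tmp_path_factory.mktemp("slides_nocal") / "nocal.tiff"
    generate_slide(ellipse_spec, path)
    path.with_suffix(path.suffix + ".meta.json").unlink()
    return open_slide(path)
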