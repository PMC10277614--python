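# Methods

## Problem and scope

Digital pathology review of xenograft cohorts needs two things this package
provides: (1) reproducible patient-level overview figures from pyramidal
whole-slide images (WSI) — a low-magnification tissue overview per stain,
a marked region of interest (ROI) shown as a high-magnification inset, and
a physically correct scale bar — and (2) a machine-readable summary of the
cohort's immunophenotype table (marker calls, immunoglobulin light-chain
restriction, EBER status) together with the count statistics a report
quotes. The driving use case is quality control of a non-small-cell lung
cancer patient-derived xenograft (PDX) program in which a subset of
transplanted tumour regions grew as EBV-driven human B-cell
lymphoproliferations rather than carcinoma.

## Coordinate and calibration model

A WSI is an image pyramid: level 0 at full scan resolution, coarser levels
at strictly increasing downsamples (1, 4, 16, 64 is typical). All public
APIs take **level-0 pixel coordinates**, origin top-left, half-open
rectangles (`RegionL0`); level-space coordinates exist only inside the
reader. Regions are clamped to slide bounds rather than rejected — ROIs
near tissue edges are routine — and raise only when clamping empties them.

Micron calibration (`mpp`, microns per level-0 pixel) comes from, in order
of authority: a JSON sidecar `<slide>.meta.json` (keys `mpp_x`, `mpp_y`);
TIFF resolution tags when the unit is inch or centimetre and the implied
value is plausible (0 < mpp < 100 µm); vendor metadata for NDPI via the
optional openslide backend. Calibration is never guessed: operations that
need physical units (scale bars, micron-specified ROIs) suppress their
output or raise `CalibrationMissingError` when it is absent. The sidecar
outranks TIFF tags because resolution-unit dialects are ambiguous across
writers while the sidecar is bit-exact.

**No upsampling anywhere.** Requests for more pixels than the data holds
return the finest available data; fabricated resolution misleads the
reader of a histology figure.

## Synthetic slides as study material

Vendor WSI files are multi-gigabyte and not redistributable, so all tests
and the acceptance run operate on generated pyramidal TIFFs with exact
ground truth. A fixture is a white slide with elliptical "tissue" blobs
and an optional checkerboard ROI; each pyramid level is rendered
**analytically at its own scale** (pixel *(i, j)* at downsample *d*
samples the continuous scene at the level-0 point *((j+0.5)d, (i+0.5)d)*)
rather than resampled from level 0, so level-consistency tests exercise
the reader, not the generator. Files are uncompressed, tiled 256×256;
identical spec + seed gives byte-identical output. The seed drives only
optional speckle noise (off by default) — geometry is deterministic so
assertions can be exact.

Defaults mirror the scanned slides the tool targets: 0.25 µm/px scanner
calibration, tissue sections a few millimetres across, and a 16-stain
panel (H&E; CD45 and pan-keratin AE1/AE3 for lineage QC; the B/T/plasma
markers CD20, CD79A, CD3, BCL2, CD56, CD10, BCL6, MUM1, CD138, CD30; EBER;
IgK and IgL) with stain-specific fill colours emulating chromogen hues.
What the fixtures deliberately do **not** emulate: histological texture,
staining gradients, pen marks, coverslip artefacts, multi-specimen slides.
Passing tests therefore validate geometry, calibration arithmetic and
composition logic, not segmentation robustness on real tissue.

The randomised detection sweep uses 1280×960 slides (two levels, 0.5 µm/px)
with one ellipse covering 12–35% of each dimension in a random low-to-mid
brightness colour — small enough that a 20-slide sweep runs in seconds
while still varying position, size, aspect and hue.

## Tissue detection

The "automatic" half of semi-automatic overview generation. On a thumbnail
(max dimension fixed at 1024 px so morphology radii act at a stable scale)
each pixel's tissue score is `max(saturation, 1 − brightness)`: chromogenic
stains (eosin pink, DAB brown, EBER blue) are saturated, dense hematoxylin
is dark, and glass is bright and unsaturated — one score covers all 16
stains. The score is thresholded by Otsu's method, closed with a 2-px disk,
and connected components below 0.5% of the thumbnail area are dropped as
debris. Degenerate inputs degrade, never crash: a blank thumbnail yields an
empty mask with a warning, and an empty mask falls back to the whole-slide
bounding box so figures still render. The "manual" half is a user-supplied
bounding box in the figure config, which bypasses detection entirely.

The tight box is scaled to level 0 through the thumbnail downsample
(floor/ceil so the box never shrinks through rounding), then each side is
pushed outward by `margin_frac × max(box_w, box_h)` and clamped. Expected
accuracy is ±2 thumbnail pixels per edge, the blur radius introduced by
box-filter thumbnailing plus closing.

## Overview, scale bar, inset

`extract_overview` reads the crop from the **coarsest pyramid level that
still spans the target size**, then box-filter (area-average) downsamples
so the longest edge lands exactly on the target; when even level 0 is
smaller, the data is returned as-is. Box filtering is deterministic and
anti-aliased; nearest-neighbour is never used for output pixels. The
companion `choose_level` utility answers the converse question — the
finest level whose rendering of an extent fits *within* a pixel budget —
and is what callers should use to bound read sizes.

Scale-bar lengths come from the "nice" set {1, 2, 5}×10^k µm. The chosen
length minimises `|log(candidate/target)|` where target = 25% of the image
width in microns, subject to the bar spanning 10–40% of the image width;
if no nice value fits that window (pathological aspect ratios) the nearest
candidate is used with a warning. On a ~5 mm-wide tissue overview this
lands on 1.0 mm, the convention used in the figures this tool reproduces.
Labels are `"1.0 mm"`-style above 1000 µm, integer microns below. The bar
is drawn in a white margin band appended below the tissue (height 6% of
the image, minimum 22 px) so it never occludes tissue; the label uses
Pillow's built-in fixed bitmap font, which renders identically across
platforms and keeps the output byte-reproducible.

Insets are specified either as a level-0 rectangle or as a centre plus a
physical width: a 250 µm inset at 0.25 µm/px spans `round(250/0.25) = 1000`
level-0 pixels. Orientation harmonisation across serial sections is
restricted to quarter turns plus a horizontal mirror, keeping every
coordinate mapping exact; the ROI rectangle drawn on the overview is
mapped corner-by-corner through crop offset, downsample and transform.

## Figure composition

A figure config (YAML/JSON, see `docs/figure_config.md`) declares panels
in row-major order — rows are tissue samples, columns stains. Each panel:
overview centred on a white panel canvas, ROI rectangle, inset composited
top-right with a 2-px black border at a configurable fraction of panel
width (default 0.3), and a label band. Unavailable histology is a light
grey placeholder panel with centred text; a slide that fails to open
degrades to a placeholder and a manifest warning rather than failing the
figure (a figure-level error is raised only when *every* slide panel
fails). The JSON manifest beside the PNG records, per panel, the crop
actually used, level, downsample, scale-bar length and warnings.
Composition is pure — inputs untouched, reruns byte-identical — and all
outputs are written atomically (temp file + rename).

## Cohort summary

The phenotype table is a CSV with one row per xenograft, eleven marker
columns in printed order and an `ig` column. The call vocabulary is closed
(`+`, `-`, `#` focal/partial, `unavailable`); unknown tokens are rejected
with the row and column named, and `#` is kept as its own category rather
than folded into positive or negative — lossless is the only safe choice
for a call whose precise definition is not machine-readable. Light-chain
codes `K`/`L` mean restriction; a parenthesised second chain (`K (L)`,
`L (K)`) means a dual-expressing population and is classified `dual`
regardless of which chain dominates. The bundled table has 16 rows, one of
which (a sample with no histology material) is fully `unavailable` and is
excluded from the evaluable denominator.

Two-group comparisons of lymphoproliferation rates use the plain Pearson
chi-square on the 2×2 table, df = 1, **no continuity correction**,
two-sided, α = 0.05, with p from the upper tail; the settings are echoed
in the summary output so the choice is auditable. Formatted percentages
round half away from zero to one decimal (`Decimal`-based, so 11.05 →
"11.1%" regardless of binary float representation). Rank tests
(Mann-Whitney, Kruskal-Wallis) are exposed as generic operations over
user-supplied per-sample vectors only: the published record for the
latency and harvest-time comparisons contains medians, not per-sample
values, so no fixture accompanies them and no result is claimed.

## Numerical and design choices

- **Pyramid metadata**: level downsamples are inferred from level dimension
  ratios and snapped to integers when within 2% — TIFF pyramids store
  dimensions, not downsample factors. Level dims must agree with
  `level0/downsample` within ±1 px or the file is rejected as an invalid
  pyramid.
- **`map_l0_to_level`**: offsets floor, sizes round but never below 1 px,
  so a sub-pixel region still addresses one level pixel; the round trip
  back to level 0 errs by < downsample px per coordinate.
- **Thumbnailing** reads the coarsest level whose longest edge still
  reaches the requested size, then box-downsamples — never more than one
  level's worth of excess data is read.
- **Problem sizes**: the canonical test fixture is 8000×6000 px with
  levels at 1/4/16 (a scaled-down stand-in for gigapixel scans — the same
  code path, three orders of magnitude less data); the detection sweep
  uses 20 randomised 1280×960 slides; composed figures use 8–16 panels of
  400×320 px. These sizes make the full suite and the acceptance run
  complete in a couple of minutes on one core while exercising every
  contract at full fidelity.
- **Exit codes** (CLI): 0 success, 1 usage error, 2 data error; stdout is
  silent on success; a JSON-lines run log is written beside each output.

## Known limitations

- NDPI reading requires the optional `openslide` dependency; without it
  only pyramidal TIFF is supported and NDPI files fail with a clear format
  error.
- Tissue detection returns the union bounding box: multiple specimens on
  one slide are framed together, and pen marks or coverslip artefacts are
  not removed.
- Rotation is limited to quarter turns; free-angle alignment of serial
  sections is out of scope.
- No colour management or stain normalisation: panels show scanner-native
  colour.
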