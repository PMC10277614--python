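# Figure configuration schema

A figure config is a YAML or JSON mapping consumed by
`pathoverview figure CONFIG.yaml` or `pathoverview.load_figure_config`.
Relative `slide_path` entries resolve against the config file's directory.

## Top-level keys

| key               | type                | default    | meaning                                        |
|-------------------|---------------------|------------|------------------------------------------------|
| `patient_id`      | str                 | `""`       | identifier echoed into the manifest            |
| `panels`          | list of panel maps  | *required* | row-major panel order (rows = samples)         |
| `cols`            | int ≥ 1             | 4          | panels per row                                 |
| `panel_px`        | [w, h], each ≥ 128  | [800, 640] | panel canvas size in px                        |
| `inset_frac`      | float 0.05–0.9      | 0.3        | inset width as fraction of panel width         |
| `gutter_px`       | int                 | 24         | spacing between panels                         |
| `label_band_px`   | int                 | 48         | height of the label band under each panel      |
| `scale_bar`       | bool                | true       | draw scale bars (needs micron calibration)     |
| `bbox_margin_frac`| float 0–0.5         | 0.02       | margin around the auto-detected tissue box     |
| `output`          | {`path`, `format`}  | —          | output image path and format (png default)     |

## Panel keys

Exactly one of `slide_path` / `placeholder_text` per panel.

| key                | type                     | meaning                                          |
|--------------------|--------------------------|--------------------------------------------------|
| `row_label`        | str                      | sample label (e.g. `"CRUK0764 IR xenograft"`)    |
| `stain`            | str                      | stain label (e.g. `"CD20"`)                      |
| `slide_path`       | path                     | pyramidal slide to render                        |
| `placeholder_text` | str                      | grey placeholder panel text                      |
| `roi`              | map, optional            | inset ROI (below)                                |
| `transform`        | {`rotate90` 0–3, `flip_h`} | orientation fix (quarter turns CCW, then mirror) |
| `tissue_bbox`      | [x, y, w, h] or map      | manual level-0 crop, bypasses tissue detection   |

A `roi` is either a level-0 rectangle or a centre plus physical width
(physical width requires slide calibration):

```yaml
roi: {region: [3500, 2500, 1000, 1000]}       # level-0 pixels
roi: {center: [4000, 3000], physical_width_um: 250}
```

## Full example

```yaml
patient_id: CRUK0733
cols: 2
panel_px: [800, 640]
inset_frac: 0.3
scale_bar: true
panels:
  - row_label: "CRUK0733 R5"
    stain: "CD20"
    slide_path: slides/cruk0733_r5_cd20.tiff
    roi: {center: [41000, 30500], physical_width_um: 250}
    transform: {rotate90: 1}
  - row_label: "CRUK0733 R5"
    stain: "EBER"
    slide_path: slides/cruk0733_r5_eber.tiff
    roi: {center: [41000, 30500], physical_width_um: 250}
  - row_label: "CRUK0733 R1"
    stain: "CD20"
    placeholder_text: "Histology sample unavailable"
  - row_label: "CRUK0733 R1"
    stain: "EBER"
    placeholder_text: "Histology sample unavailable"
output:
  path: figures/cruk0733_panel.png
  format: png
```

The run writes `figures/cruk0733_panel.png`, a manifest
`figures/cruk0733_panel.png.manifest.json` (per-panel crop, level,
downsample, scale-bar length, warnings) and a JSON-lines run log.
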