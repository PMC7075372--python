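# shiftcheck

Two QA tools for radiotherapy treatment planning that close the
"wrong shift instructions" error pathway:

1. **Treat Sheet** (`treat-sheet`) — reads a DICOM RT Plan, computes the couch
   shift from the plan user origin to the beam isocenter (or between two plans
   on the same CT scan), transforms it with the patient-orientation-aware
   DICOM→IEC 61217 rotation, and renders a printable pre-treatment document.
   Shift values are *hardcoded to centimeters* and labeled with anatomical
   direction words (Left/Right, Anterior/Posterior, Superior/Inferior), with
   the IEC fixed-frame components as a secondary line. Computed values can be
   manually overridden for in-room setups; the original values are always
   retained and the sheet carries a prominent `MANUAL OVERRIDE` banner.
2. **Origin check** (`origin-check`) — reads a DICOM RT Structure Set, finds
   the three CT simulation marker contours by a configurable naming
   convention (two lateral markers plus one anterior-or-posterior surface
   marker), derives the point where the user origin should have been set
   (lateral-marker average for y and z, surface-marker x), and flags plans
   whose actual user origin deviates beyond a tolerance (default 2.0 mm,
   Euclidean).

A synthetic-fixture generator (`gen-fixture`) produces complete CT / RT
Structure Set / RT Plan bundles with known ground truth, so everything is
testable without clinical data.

## Layout

| Module | Purpose |
| --- | --- |
| `shiftcheck.geometry` | Frames (DICOM patient LPS, IEC 61217 fixed), the 8 patient-position rotation matrices, anatomical direction labeling |
| `shiftcheck.dicom_io` | Minimal geometry extraction from RT Plan / RT Structure Set / CT files |
| `shiftcheck.origin_check` | Marker matching, intersection rule, tolerance verdict |
| `shiftcheck.shift_sheet` | Shift computation, centimeter instructions, overrides, text/PDF/JSON rendering |
| `shiftcheck.synthetic_fixtures` | Deterministic synthetic DICOM bundles with ground truth |
| `shiftcheck.cli` | `shiftcheck` umbrella command plus the three standalone entry points |
| `shiftcheck._dicom`, `shiftcheck._pdf` | Internal helpers: explicit-VR-little-endian DICOM codec, one-page PDF writer |

## CLI

```bash
# generate a synthetic bundle with a 10 mm user-origin error
gen-fixture --position HFS --offset 0,0,10 --seed 3 --out /tmp/fx

# run the origin check: exit 0 = PASS, 2 = FLAG, 3 = NOT-EVALUABLE, 1 = error
origin-check /tmp/fx/rs.dcm --tolerance 2.0 --json

# render the Treat Sheet (text, PDF or lossless JSON)
treat-sheet /tmp/fx/rp.dcm --format pdf --out sheet.pdf
treat-sheet /tmp/fx/rp.dcm --plan-b other_rp.dcm   # plan-to-plan shift
```

All subcommands are also available as `shiftcheck <subcommand>`. A YAML
config (`--config`) can set marker naming patterns (case-insensitive globs),
`tolerance_mm`, the checklist text, a user-origin override and the default
output format.

Plain DICOM has no "user origin" attribute; the tools assume the common TPS
export convention that coordinates are shifted so the user origin is the
DICOM origin `(0,0,0)`, and accept `--origin x,y,z` for exports that differ.

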