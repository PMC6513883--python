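# File formats

Canonical schemas for every file behavekin reads or writes. Field aliases
accepted by the readers are noted; writers always emit the canonical names.

## Detection dialects (input)

### 1. Single-box JSON (`read_box_json`)

One bounding box per image, absolute pixel corners. A JSON array (or an
object keyed by image identifier) of records:

```json
[{"image": "img_000123.png", "x1": 10.0, "y1": 20.0,
  "x2": 50.0, "y2": 60.0, "conf": 0.93}]
```

* `image` (aliases `image_id`, `file`, `frame`): the frame index is the
  trailing integer of the identifier; records without one use file order.
* `conf` (aliases `confidence`, `score`): optional; absent means a manual
  label, confidence 1.0.
* Swapped corners are repaired (and counted in the parse report);
  malformed records are skipped and counted; a file with zero parseable
  records is a format error.

### 2. Normalized multi-class box JSON (`read_normalized_box_json`)

Class id plus center/size relative to the image (up to 80 classes):

```json
[{"image": "frame_000045.png", "class": 3, "cx": 0.41, "cy": 0.52,
  "w": 0.07, "h": 0.07, "conf": 0.88}]
```

* pixel box = `((cx−w/2)·W, (cy−h/2)·H, (cx+w/2)·W, (cy+h/2)·H)`.
* `class` (alias `class_id`) indexes the caller-supplied class-name list;
  an out-of-range id is a format error.
* Normalized values outside [0, 1] by more than 0.05 skip the record.

### 3. Per-frame keypoint JSON (`read_keypoint_json`)

A directory with one file per frame (`*_000000000123_keypoints.json`),
each holding a `people` list of flat `(x, y, c)` triplets:

```json
{"version": 1.3,
 "people": [{"pose_keypoints_2d": [612.3, 410.8, 0.91, ...],
             "hand_left_keypoints_2d": [...],
             "hand_right_keypoints_2d": [...]}]}
```

* The caller maps output labels to `(source, index)` pairs, e.g.
  `{"r_wrist": ("pose", 4), "r_index_mcp": ("hand_right", 5)}`
  (see `behavekin.synthetic.KEYPOINT_LAYOUT` for the full default).
* A `(0, 0, 0)` triplet means the keypoint was not detected → gap.
* With several people, the person with the highest mean confidence over
  the named keypoints is kept (policy configurable).

## Calibration corners (input/output)

CSV, one row per corner:

```
view,row,col,u,v
0,0,0,231.4189,187.0145
```

`view` groups a full interior-corner grid; `(row, col)` is the board
position in row-major order; `(u, v)` pixels. Every view must contain the
complete grid.

## Stereo rig JSON (output of `calibrate`, input to `reach`)

```json
{"format": "behavekin-rig v1", "world_units": "mm",
 "camera_a": {"intrinsics": {"fx":, "fy":, "cx":, "cy":, "skew":, "k1":, "k2":},
              "rotation": [[...3x3...]], "translation": [x, y, z],
              "image_width": 448, "image_height": 460},
 "camera_b": {...}, "meta": {...}}
```

Rotation/translation are world → camera; the world frame is anchored to
the first shared checkerboard view.

## Trajectory CSV (output/input)

```
# behavekin-trajectory v1
# label: paw
# units: mm
# fps: 124
frame,x,y,z,confidence
0,1.25,0.03,-0.8,0.91
1,,,,0
```

Empty x/y/z cells are gap frames. `label`, `units` and `fps` header lines
are mandatory.

## Other outputs

* **Per-reach summary CSV** — one row per reach: onset/offset frames and
  seconds, peak/max/mean speed, distance traveled, duration, path-length
  ratio, velocity-peak and onset counts.
* **Ethogram CSV** — per frame in each contact epoch: `frame`, `epoch`,
  `label`, and the five pairwise part distances (cm).
* **Three-chamber report JSON** — per-cup time (s), percentage of
  interaction time and of session, chamber occupancy, transition count,
  interaction bouts with timestamps.
* **Distance matrix CSV** (ids as header/index), **merge-table CSV**
  (scipy linkage convention), **Newick dendrogram**, **assignments CSV**.
* **Parse report JSON** — record counts, skipped/repaired/deduplicated
  counts and messages for each detection file read.
* **manifest.json** — tool version, command, seed, resolved configuration
  and SHA-256 of every input, for bit-exact replay.
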