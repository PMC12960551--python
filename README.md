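# footmetry

Landmark-based 3D foot morphometry for digital orthotic workflows:

* **mesh_io** — STL (binary + ASCII) and ASCII PLY meshes, landmark files,
  measurement / deviation reports. All coordinates are millimetres.
* **registration** — builds the anatomical frame from the three plantar
  landmarks (heel origin, Y towards the metatarsal midpoint, Z towards the
  dorsum) and rigidly registers the scan to the world frame.
* **morphometry** — the 15 foot measurements (lengths, widths, girths, arch
  height / index, ankle angle) from a registered mesh + landmarks.
* **reliability_stats** — two-way ANOVA mean squares, absolute-agreement
  single-rater ICC with 95% CI, reliability classification, and the
  closed-form ICC sample-size calculation.
* **deviation_compare** — signed surface deviations between meshes and
  ±tolerance conformity summaries (default ±1 mm).
* **synthetic_foot** — parametric phantom feet with ground-truth landmarks,
  weight-bearing deformation, rater landmark-noise models, and fully
  simulated reliability studies (no external data needed).

## Landmark file schema

Six fixed ids: `HEEL, MT1, MT5, ARCH, MED_MAL, LAT_MAL`. CSV:

```csv
id,x,y,z
HEEL,0.0,25.0,0.0
MT1,-47.5,180.0,0.0
MT5,47.5,180.0,0.0
ARCH,-21.0,105.0,18.0
MED_MAL,-23.0,45.0,66.0
LAT_MAL,23.0,45.0,62.0
```

or JSON: `{"side": "right", "source": "guided", "landmarks": {"HEEL": [x,y,z], ...}}`.
`HEEL`, `MT1`, `MT5` and `ARCH` are required; the malleoli are optional but
without them the scan is not trimmed for foot length and hindfoot girth /
ankle angle are left unset (flagged in the report).

## CLI

```sh
footmetry measure foot.stl landmarks.csv --out results/
footmetry reliability panel.csv --mode both --out results/
footmetry compare design_a.stl design_b.stl --tol 1.0 --out results/
footmetry simulate study.cfg --out results/
```

`simulate` takes a `key = value` config file:

```ini
n_subjects = 12
feet_per_subject = 2
conditions = NWB,HWB
rater_mode = guided     # or scan_derived
sigma = 0.8
n_raters = 3
repetitions = 1
seed = 7
resolution = 32
```

Every successful run writes a machine-readable `run_log.json` (seed, config,
library versions) next to its outputs. Rating panels are long-format CSV with
columns `subject, rater, repetition, condition, measurement, value`.

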