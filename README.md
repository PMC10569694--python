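# stereocount

Design-based automated neuron counting for 3D light-sheet-style volumes.

The package implements the full counting workflow: random cubic counting
subvolumes placed strictly inside an atlas-labeled region (a digital optical
fractionator), sparse-label random-forest voxel classification with
ilastik/Labkit-style multi-scale features, erosion-seeded 3D watershed with
dams to split touching nuclei, a volume filter that discards debris and
partitions fused clusters by the mean single-neuron volume, and density /
total-number / coefficient-of-variation statistics. A built-in synthetic
phantom generator (bright ellipsoidal nuclei on textured background,
anisotropic voxels, controllable touching fraction, full ground truth) makes
every stage testable without real data, including emulation of
uncorrected-morphology deformation via dense displacement fields.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks (headline
F1, density-estimator recovery, component/watershed/sampling/volume-filter
properties, deformation percent-difference). All fixtures are generated
programmatically — no binary data ships with the repo.

## CLI

All stages are exposed as subcommands of one entry point:

```bash
# synthetic phantom with ground truth (TIFF + NIfTI + CSV centroids)
stereocount simulate --out-dir sim --extent 30,113,113 --seed 1

# random counting cubes inside region 1 of a label map
stereocount sample --labelmap sim/labels.nii --region 1 --n 15 \
    --edge-um 100 --spacing 4,1.8,1.8 --seed 1 --out plan.json

# train / predict / split / evaluate
stereocount train --volume sim/phantom.tif --ann ann.csv --seed 1 --out model.bin
stereocount predict --volume sim/phantom.tif --model model.bin --out prob.tif
stereocount instances --mask prob.tif --spacing 4,1.8,1.8 --out inst.tif
stereocount evaluate --pred inst.tif --truth sim/truth.tif \
    --spacing 4,1.8,1.8 --out eval.json

# full region count (sampling -> classification -> watershed -> filter -> stats)
stereocount count --volume sim/phantom.tif --labelmap sim/labels.nii \
    --region 1 --model model.bin --n 15 --seed 1 --out report.csv

# or everything from a config file
stereocount run --config run.yaml
```

Volumes are (z, y, x) multi-page TIFFs with voxel spacing in micrometres
embedded as JSON (ImageJ-style spacing metadata is also understood; spacing
is mandatory — there is no implicit default). Label maps are integer NIfTI-1
or TIFF grids with an optional `id,name` sidecar CSV. Reports are CSV, one
row per region/specimen.

## Library layout

| module | contents |
| --- | --- |
| `stereocount.types` | `VolumeImage`, `RegionLabelMap`, `SparseAnnotations`, `ClassifierModel` |
| `stereocount.io` | TIFF/NIfTI/CSV/model readers and writers |
| `stereocount.phantom` | phantom + region-phantom generators, deformation, annotation sampling |
| `stereocount.sampling` | region masks, region volume, random subvolume plans |
| `stereocount.classify` | multi-scale features, forest training and prediction |
| `stereocount.instances` | erosion-seeded watershed, connected components |
| `stereocount.counting` | volume filter, densities, summaries, CV, percent difference |
| `stereocount.evaluate` | instance matching and precision/recall/F1 |
| `stereocount.pipeline` | end-to-end orchestration and run configs |
| `stereocount.benchmarks` | self-contained phantom experiments used by the acceptance checks |
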