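# poretomo

Micrometer-scale pore-structure analysis of 3D X-ray microtomography
volumes: segmentation of grayscale reconstructions into pore/solid masks,
connected pore-network metrics, per-axis pore frequency curves, and 1D
multifractal analysis (singularity and Rényi spectra) for testing the
homogeneity and isotropy of porous media such as pelletized-wood biochar.

Because beamline scan data is rarely redistributable, the package ships a
synthetic-phantom module that generates every kind of input the pipeline
consumes: noisy grayscale volumes with solid/pore contrast, isotropic
fragment-packed and anisotropic tube-array binary structures, and 1D
binomial-cascade measures with closed-form multifractal spectra used as
estimator oracles.

## Layout

| module | contents |
| --- | --- |
| `poretomo.phantoms` | fragment-pack / tube-array phantom generation, grayscale rendering, binomial cascades and their exact spectra |
| `poretomo.volio` | TIFF stack I/O (multi-page or one-file-per-slice) |
| `poretomo.segmentation` | quantization (×100 000 → int16), thresholding (solid > 8), largest-solid-component retention, centered ROI crop |
| `poretomo.metrics` | pore labelling, total porosity (≥ 4-voxel rule), largest-pore connectivity fraction, 3D-perimeter surface area, SA/V, unit conversions |
| `poretomo.curves` | per-slice pore-voxel frequency curves along each axis |
| `poretomo.multifractal` | dyadic partitioning, moment sums, Chhabra–Jensen α/f estimation, Rényi dimensions D_q, R²-gated acceptance, spectrum shape descriptors |
| `poretomo.pipeline` | end-to-end orchestration, isotropy/homogeneity report, cohort aggregation, YAML/JSON config |
| `poretomo.cli` | `poretomo` command with subcommands `phantom`, `segment`, `metrics`, `curves`, `mfa`, `run`, `aggregate` |

## CLI quick start

```sh
# synthesize a noisy grayscale phantom, then run the full chain
poretomo phantom --shape 64 64 64 --porosity 0.577 --grayscale --out gray.tif
poretomo segment --input gray.tif --out mask.tif
poretomo metrics --mask mask.tif
poretomo curves --mask mask.tif --out-dir curves/
poretomo mfa --curve curves/curve_axis0.csv --out spectrum.csv \
    --descriptors-out descriptors.json
```

Multi-sample runs are driven by a config file:

```yaml
samples:
  - name: sample1
    group: SWP550
    phantom: {shape: [128, 128, 128], target_porosity: 0.577,
              structure: fragment_pack, seed: 1}
voxel_edge_um: 0.87
```

```sh
poretomo run --config config.yaml --out-dir out/
poretomo aggregate out/sample1/metrics.json
```

`run` writes per-sample metrics (JSON), per-axis curves and spectra (CSV),
an isotropy report, and a `manifest.json` recording every parameter and
seed; reruns with the same config are bit-identical.

## Conventions

- Volumes are indexed `(z, y, x)`; binary masks use `True` = pore.
- Default parameters mirror the reference study: scale factor 100 000,
  threshold 8 (strictly greater ⇒ solid), voxel edge 0.87 µm, ROI 1024³,
  minimum pore size 4 voxels, q ∈ [−9, 9], dyadic levels k = 1..10,
  R² ≥ 0.9.
- Binary masks on disk: 8-bit TIFF, 0 = solid, 255 = pore.
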