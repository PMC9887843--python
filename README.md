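# ndvicam

A tested Python library + CLI for producing calibrated NDVI imagery from a
low-cost dual-camera rig: one off-the-shelf RGB camera measuring visible red
(620 nm, red Bayer channel) and one IR-unfiltered camera behind a blue
lighting filter measuring near-infrared (750 nm), e.g. the Raspberry Pi
PiCamera / NoIR pair. It is aimed at plant scientists and phenotyping
engineers who need reflectance-accurate NDVI from consumer cameras without
commercial multispectral hardware.

The Normalised Difference Vegetation Index is

```
NDVI = (NIR − RED) / (NIR + RED)
```

with NIR and RED as relative reflectance (0–100 %). Healthy, chlorophyll-rich
leaves absorb red and reflect NIR strongly, pushing NDVI toward 1. Getting
*reflectance* (rather than raw pixel brightness) out of a consumer camera is
the hard part, and is what this package implements:

* **Six-reference empirical-line calibration.** The mean digital number (DN)
  of six in-scene reference materials of known reflectance is fitted to
  `R/100 = a·(DN/255)^γ + b`, with the gamma exponent fitted freely so the
  camera's built-in gamma correction is absorbed by the model. A
  two-reference mode (brightest + darkest material, fixed de-gamma exponent
  2.12766) is provided for field work.
* **Exposure selection**: the longest shutter speed keeping the brightest
  reference below DN 240, so the full sensor range is usable without
  saturation.
* **Red-leak correction.** The NIR camera's filter transmits 5–15 % of red
  light; the leaked fraction `f` is predicted from the filter transmission
  curve and subtracted per pixel (`NIR_corr = NIR_meas − f·RED`).
* **Registration** of the NIR frame onto the red frame (translation-only,
  normalized cross-correlation with sub-pixel parabolic refinement).
* **16-bit encoding**: reflectance 0–100 % ↔ codes 0–65 536 and NDVI −1…+1 ↔
  codes 0–65 536 (stored codes clamp at 65 535), decoded by
  `NDVI = code·(2/65536) − 1`.
* **Verification**: a wavelength sweep comparing camera NDVI against
  spectrometer NDVI across candidate red (600–700 nm) and NIR (700–800 nm)
  bands — a faithful calibration minimizes the difference at the camera's
  own band centres.
* **A synthetic scene simulator** (chlorophyll-dependent leaf spectra,
  calibration board, gamma/saturation/noise/leak/misalignment camera model,
  idealized spectrometer) so the whole pipeline runs and is tested with no
  hardware.

## Worked example

Simulate a scene with three leaves (chlorophyll 10/30/50 µg cm⁻²) plus the
calibration board, then run the full pipeline:

```python
import ndvicam as nc

spec, panel, leaf_rois = nc.standard_scene(
    [10.0, 30.0, 50.0], noise_sd=1.5, leak_fraction=0.10,
    shift=(2.0, -1.5), seed=42,
)
red, nir, truth = nc.render_scene(spec, panel=panel)
nc.write_image(red, "red.png"); nc.write_image(nir, "nir.png")

cfg = nc.RunConfig.from_dict({
    "red_image": "red.png", "nir_image": "nir.png", "output_dir": "out",
    "panel_rois": [[r.row0, r.col0, r.height, r.width] for r in panel.rois],
    "analysis_rois": {f"leaf{i}": [r.row0 + 4, r.col0 + 4, r.height - 8, r.width - 8]
                      for i, r in enumerate(leaf_rois)},
    "leak_fraction": 0.10, "search_radius": 8,
})
summary = nc.run_pipeline(cfg)
```

The run logs each stage and prints, among other numbers:

```
calibration red: gamma=2.1312 rmse=0.016%; nir: gamma=2.1299 rmse=0.024%
estimated shift dx=2.04 dy=-1.59 score=0.940
leaf0: n=256 mean=0.0344  leaf1: mean=0.1625  leaf2: mean=0.2817
```

The fitted gamma (~2.13) is the camera's gamma correction recovered from the
six reference patches; the shift estimate matches the simulated (2.0, −1.5) px
misalignment to within 0.1 px; and the per-leaf mean NDVI values agree with
the scene's ground truth (0.0338 / 0.1606 / 0.2804) to better than 0.01.
Outputs land in `out/`: `ndvi.png` (16-bit, with JSON sidecar), per-camera
calibration models, `stats.csv` and `summary.json`.

The same steps are available from the shell:

```sh
ndvicam simulate --leaves 10,30,50 --seed 42 --out scene/
ndvicam ndvi --config run.yaml
ndvicam verify --camera-csv camera.csv --spectra-csv scene/spectra.csv --out v
ndvicam stats --image out/ndvi.png --roi 70,8,16,16
```

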