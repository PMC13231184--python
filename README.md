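# pavasc

Ultrasound-guided photoacoustic (US/PA) analysis of the skin vasculature
overlying subcutaneous implants, as a tested, reusable Python pipeline:

- **core** — `Volume3D` domain types, NIfTI/TIFF volume I/O, trilinear
  isotropic resampling (default 0.1 mm), and a YAML/JSON study manifest.
- **synthetic** — US/PA phantoms (anechoic water over a hyperechoic curved
  skin interface, Gaussian-profile tubular vessels with wavelength-dependent
  Hb/HbO2 contrast, vertical implant-ridge artifacts) and longitudinal
  exposed-vs-healthy cohorts with known ground truth.
- **segmentation** — columnwise water–skin interface detection (Otsu or
  fixed threshold), 0.5 mm skin-shell extraction, square/circle/full lateral
  ROIs, and water normalization of PA amplitudes.
- **unmixing** — voxelwise non-negative least-squares spectral unmixing of
  Hb and HbO2 from the six 700–950 nm volumes (closed-form two-chromophore
  NNLS, vectorized), total hemoglobin and optional sO2.
- **vessels** — MIP, 0–1 normalization, single-scale 2-D Jerman vesselness
  (scale 4, tau 0.5), Hessian-eigenvector vessel orientation, and
  suppression of near-vertical structures (angle in (−0.5, 0.5) rad).
- **biomarkers** — per-session PA vasculature (mean 532 nm amplitude in the
  skin shell), vascular density (mean suppressed vesselness map) and total
  hemoglobin level; baseline-normalized longitudinal series.
- **stats** — linear mixed-effects group × time interaction test (random
  intercept per subject, OLS fallback for singular fits), per-subject
  cross-correlation lag estimation against skin scores (negative lag =
  biomarker leads), and one-sided one-sample t-tests.
- **spatial** — 2-D total-hemoglobin maps, mean normalization, Gaussian
  smoothing, consecutive-week hemoglobin-reduction masks, and localization
  scoring against synthetic ground truth.

The bundled Hb/HbO2 molar extinction table
(`src/pavasc/data/hb_extinction.csv`) is adapted from the compilation by
S. Prahl, Oregon Medical Laser Center
(<https://omlc.org/spectra/hemoglobin/>), subsampled and linearly
interpolated.

## CLI

```bash
pavasc simulate out/cohort --seed 7 --n-healthy 3 --n-exposed 2   # phantom cohort + manifest
pavasc segment out/cohort/manifest.yaml --subject e01 --week 0 --out-dir out/seg
pavasc unmix   out/cohort/manifest.yaml --subject e01 --week 0 --out-dir out/unmix
pavasc vessels out/cohort/manifest.yaml --subject e01 --week 0 --out-dir out/vessels
pavasc biomarkers out/cohort/manifest.yaml --out-csv out/biomarkers.csv
pavasc stats out/biomarkers.csv --out-prefix out/stats
pavasc spatial out/cohort/manifest.yaml --subject e01 --out-dir out/spatial
```

### Manifest schema

```yaml
spacing_mm: [0.1, 0.1, 0.1]
subjects:
  - id: e01
    group: exposed            # healthy | exposed (or implant-design labels)
    roi: {shape: square, size_mm: 14, center_mm: [11.5, 11.5]}
    sessions:
      - week: 0
        score: 5              # skin-health score, 5 (intact) .. 1 (severe)
        us: e01_w00_us.tif
        pa: {532: e01_w00_pa532.tif, 700: e01_w00_pa700.tif, ...}
```

Volumes are NIfTI (`.nii`/`.nii.gz`, spacing from the header) or multi-page
TIFF (spacing from the manifest), indexed (X lateral, Y elevational,
Z depth, Z increasing downward from the water).

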