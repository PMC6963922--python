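# hsifruit

A tested, reusable re-implementation of a near-infrared hyperspectral-imaging
workflow for classifying the geographical origin of dried fruits from
single-fruit spectra:

```
image correction -> fruit segmentation -> spectral preprocessing
    -> effective-wavelength selection -> PLS-DA / SVM / 1-D CNN -> report
```

Because no public hypercube accession exists, the package ships a first-class
synthetic-scene generator that emulates the instrument (320-pixel line scan,
256 bands over 874–1734 nm, dark/white reference frames) and the sample
structure (three origin classes with overlapping reflectance signatures,
non-touching fruit blobs on a dark plate). Every downstream stage is tested
against that generator's ground truth.

## Layout

| Module | Role |
| --- | --- |
| `hsifruit.synthetic` | origin signatures, scene rendering, dataset generation |
| `hsifruit.cube` | hypercube containers, reflectance correction, HDF5 + ENVI I/O |
| `hsifruit.segmentation` | single-band Otsu binarization, connected-component ROIs |
| `hsifruit.wavelet` | Daubechies filter construction, periodized DWT, shrinkage |
| `hsifruit.preprocess` | band crop (31–230), wavelet denoising, area normalization, per-fruit averaging |
| `hsifruit.selection` | Savitzky–Golay second derivative, spread-ranked wavelength selection |
| `hsifruit.models` | PCA, SIMPLS PLS-DA, RBF-SVM decade grid search, numpy 1-D CNN |
| `hsifruit.evaluate` | stratified splits, confusion matrices, accuracy, report tables |
| `hsifruit.pipeline` | end-to-end orchestration with derived per-stage seeds |

The CNN (Conv64-Conv32, kernel 3, no padding, max-pool 2, batch norm, dense
512/128/3, softmax cross-entropy, SGD) is implemented directly in numpy —
forward, backward and training loop — so no deep-learning framework is
required. The wavelet filters are likewise built at run time by spectral
factorization rather than vendored tables.

## CLI

```bash
# full experiment from one config (JSON or YAML of RunConfig fields)
hsifruit run-all --config cfg.json --out runs/demo --seed 1

# or stage by stage
hsifruit simulate --config scene.json --out scenes/ --seed 1
hsifruit correct  --in scenes/scene000.h5 --out corrected.h5
hsifruit segment  --in corrected.h5 --out labels.csv
hsifruit extract  --scenes scenes/ --out table.csv
hsifruit select   --table table.csv --out ew.json
hsifruit train    --table table.csv --model plsda --out model.pkl
hsifruit predict  --model model.pkl --table table.csv --out pred.csv
hsifruit evaluate --predictions pred.csv
```

`run-all` produces six fitted models (PLS-DA, SVM, CNN × full spectra,
effective wavelengths), confusion matrices for the calibration, validation
and prediction splits, a tidy `accuracy.csv`, and a manifest from which the
run can be reproduced bit-for-bit.

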