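# patternspec

Second-order image statistics for animal colour patterns and natural scenes:
measure the **spectral slope** — the slope of the rotationally averaged 2-D
Fourier amplitude spectrum against spatial frequency on log–log axes — of
receptor-view images, and compare slope distributions between groups
(male/female specimens vs. background scenes) with a hierarchical Bayesian
model.

## What's inside

| module | role |
| --- | --- |
| `patternspec.synthetic` | ground-truth generators: power-law images of chosen exponent, abdomen-shaped masks, multispectral stacks with known filter curves/dark offset/saturation, hierarchical cohorts |
| `patternspec.filters` | computational receptor filters: least-squares weighted sums of camera-filter sensitivity curves, applied per pixel to image stacks |
| `patternspec.prep` | dark-noise subtraction, exposure-stability QC (0.5% rule), saturated-pixel repair, normalization, excitation transform E = P/(P+1) |
| `patternspec.cropping` | largest inscribed square in a mask (dynamic programming) and centre square crops |
| `patternspec.spectrum` | cosine taper, FFT amplitude spectrum, rotational averaging, frequency-range selection and per-species harmonization (cycles/mm), log binning, slope fit |
| `patternspec.acuity` | physical-unit bounds: analysed-frequency ceiling from sensor geometry, resolution limit from viewing distance and inter-receptor angle |
| `patternspec.stats` | hierarchical Gaussian model `slope ~ sex + (sex \| species)` plus a region submodel for scenes; custom Metropolis-within-Gibbs sampler, split-Rhat/ESS diagnostics, posterior contrasts |
| `patternspec.pipeline` / `patternspec.cli` | manifest-driven batch orchestration, synthetic study simulation, JSON reports |

## CLI

```bash
# synthetic end-to-end demo
patternspec simulate /tmp/study --n-species 6 --n-per-sex 3 --image-size 320
patternspec run-all /tmp/study/manifest.csv /tmp/run

# individual stages
patternspec acuity                          # 24.4 and 26.5 cycles/mm at defaults
patternspec center-crop 1036 1392           # -> 1036 px square at col 178
patternspec crop mask.png                   # largest inscribed square
patternspec filters-fit target.csv filter_*.csv
patternspec fit-slopes manifest.csv --out slopes.csv
patternspec stats cohort.csv --out posterior.csv
```

Pipeline stage order is fixed and embedded in every report: dark-subtract →
computational filter → saturated-pixel repair → normalize → excitation →
crop → taper → FFT → rotational average → range select/harmonize → bin → fit.

## Python API sketch

```python
import numpy as np
from patternspec.synthetic import PowerLawSpec, gen_powerlaw_image
from patternspec import measure_slope

img = gen_powerlaw_image(PowerLawSpec(beta=-1.0, size_px=512, seed=0))
fit = measure_slope(img)          # taper -> FFT -> radial avg -> bin -> OLS
print(fit.slope, fit.r2)          # ~ -1.0, > 0.99
```
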