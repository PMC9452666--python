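# canopyagb

Estimation of potato above-ground biomass (AGB, kg/hm²) from UAV RGB imagery,
combining image texture features with canopy height.

Optical vegetation indices saturate under dense canopies, so AGB is chronically
underestimated across the growth cycle when spectra alone drive the regression.
This package implements an alternative workflow that mines the *spatial*
information of ultrahigh-resolution RGB orthomosaics instead:

* **Multi-resolution GLCM textures** — the eight classic gray-level
  co-occurrence statistics (Mea, Var, Hom, Con, Dis, Ent, Sec, Cor), computed
  per channel in a moving window (default 45°, 5×5) on images resampled from
  1 cm ground sampling distance (GDS) up to coarse grids by the
  nearest-neighbour method.
* **Multiscale Gabor textures** — a 4-orientation × 5-scale Gabor wavelet bank
  (k_max = π/2, f = √2, σ = 2π) produces magnitude images per channel; the
  same eight statistics summarise each magnitude image.
* **Crop height model (CHM)** — per-period DSM minus the bare-soil DSM; plot
  height is the ROI mean in cm.
* **Feature pruning and regression** — redundant columns removed by pairwise
  correlation elimination (caret-style `findCorrelation`, cutoff 0.99), then
  LSSVM (RBF kernel, single linear system), ELM (random hidden layer +
  pseudo-inverse) and PLSR fitted on replicate blocks 2–3 (32 plots/period)
  and validated on block 1 (16 plots/period). Accuracy: R², RMSE, MAE, NRMSE,
  plus NRMSE stratified at 1000 kg/hm².

The field data behind the original study are not public, so the package ships
a first-class **synthetic field generator**: 48 plots in 3 replicate blocks,
0.6 m row spacing, three growth periods (tuber formation P1, tuber growth P2,
starch storage P3) with rise-then-fall cover/height/AGB dynamics, a documented
generative AGB model, and procedural canopy rendering with realistic spatial
frequency structure. Every pipeline stage is exercised and tested against it.

## Worked example

```bash
python analysis/01_simulate_field.py     # simulate the campaign
python analysis/02_height_recovery.py    # CHM residual diagnostic
python analysis/03_extract_features.py   # texture + height feature table
python analysis/04_fit_scenarios.py      # all scenarios x LSSVM/ELM/PLSR
python analysis/05_height_fusion_sweep.py
```

`02_height_recovery.py` prints (full 32.5 m² plots, GDS 1 cm, seed 5):

```
plots x periods: 144
height RMSE: 1.62 cm (diagnostic bound: 3 cm)
relative residuals < 20%: 94.4% of plots
```

i.e. DSM differencing recovers plot-mean canopy height to well under the 3 cm
diagnostic bound, and height correlates positively with AGB in every period —
the precondition for using height as a regression feature.

`04_fit_scenarios.py` (desk-scale field, seed 0) ends with:

```
height fusion (LSSVM validation NRMSE):
  GLCM-all: 12.82%  ->  GLCM-all+H: 12.61%
  Gabor-all: 15.05%  ->  Gabor-all+H: 13.12%
  all: 13.37%  ->  all+H: 13.22%
```

Adding the CHM height column lowers validation NRMSE for every texture family;
the LSSVM on all textures + height reaches validation R² ≈ 0.97 on the
synthetic field. Single-scale Gabor scenarios degrade monotonically from S1 to
S5, and GDS1 is the strongest single ground resolution — the same qualitative
orderings the texture analysis is designed to expose.

A CLI wraps the two end-to-end entry points:

```bash
canopyagb simulate --config field.yaml --out scene/ --seed 7
canopyagb run-all  --config pipeline.yaml --out results/ --seed 7
```

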