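# srh — high-content stimulated Raman histology at desk scale

Label-free histology by stimulated Raman scattering (SRS) microscopy images
unstained tissue at a series of Raman shifts and turns the resulting
hyperspectral cube into chemical concentration maps. In the crowded C-H
stretch window (≈2820–3030 cm⁻¹) the spectra of the five major tissue
components — saturated lipids, unsaturated lipids, cellular protein,
extracellular matrix (ECM) and water — overlap heavily, so separating them
requires sparsity-penalized spectral unmixing rather than simple band
ratios. This package implements that computational pipeline for researchers
working with hyperspectral SRS (or other linearly-mixed multichannel
microscopy) data:

- **Non-negative LASSO unmixing.** Each pixel spectrum *y* (length *M*) is
  modeled as a linear mixture of *K* reference spectra (rows *aₖ* of the
  library matrix *A*), and the concentrations *c* solve

  &nbsp;&nbsp;&nbsp;&nbsp;min<sub>c ≥ 0</sub> ‖y − Aᵀc‖₂² + λ‖c‖₁,&nbsp;&nbsp; λ = 0.01,

  with reference spectra unit-L2-normalized and *y* left unscaled (the λ
  convention matters; it is documented in `srh.unmix`). The solver is
  deterministic cyclic coordinate descent.
- **Channel selection for fast acquisition.** Recursive feature elimination
  discards, one at a time, the spectral channel whose removal least changes
  the unmixing result on a 2100-pixel component-balanced sample, reducing
  45 channels to 5 and acquisition time by 9×.
- **Supporting stages.** Spectral total-variation denoising, tile-grid
  fusion with feather blending and offset refinement, SSIM/PSNR quality
  metrics, pseudo-color histology rendering (yellow = unsaturated lipid,
  red = cellular protein, blue = ECM, cyan = saturated lipid, grey =
  water), and TIFF/CSV/JSON readers and writers.
- **A synthetic tissue-phantom generator** producing cubes with known
  ground truth (ducts, necrotic cores, ECM fibers, adipocyte rings over a
  water background), so every stage is testable end to end.

## Worked example

```python
import srh

# fit the linear mixing model on the default synthetic scene
model = srh.MixtureModel.from_phantom()     # 64×64 px, 45 channels, 5 components
results = model.fit()
print(results.summary())

# select 5 of 45 channels on a balanced 2100-pixel sample
sample = srh.sample_balanced_pixels(model.cube, results.maps, srh.SamplerParams())
subset = srh.rfe_select(sample, model.library, srh.UnmixParams(), target_k=5)
report = srh.evaluate_subset(model.cube, model.library, srh.UnmixParams(),
                             subset, results.maps)
print([round(s) for s in subset.shifts], round(report.mean_ssim, 3))

rgb = results.render()                      # H×W×3 pseudo-color histology image
```

The fit summary prints:

```
Non-negative LASSO spectral unmixing
====================================================
pixels: 4096   channels: 45   components: 5
lambda: 0.01   nonneg: True   converged: True (874 sweeps)
mean RSS / pixel: 1.2570e-02
----------------------------------------------------
component              mean abund.    zero frac.
unsaturated_lipid           0.2706         0.376
cellular_protein            0.2791         0.665
ecm                         0.4220         0.537
saturated_lipid             0.2669         0.664
water                       0.9918         0.000
```

Mean abundance is the average fitted concentration per component (water ≈ 1
everywhere, as constructed); the zero fraction shows the sparsity the λ
penalty induces — most pixels contain only a few components. The channel
selection step then prints the five surviving Raman shifts (here 2877,
2925, 2973, 3006, 3030 cm⁻¹) and the fidelity of the 5-channel maps
against the 45-channel reference (mean SSIM 0.798, mean PSNR 30.4 dB),
while the acquisition cost model reports the 9.0× speed-up.

The same pipeline is scriptable from the shell:

```bash
srh simulate --out sim/
srh unmix --cube sim/cube.tif --sidecar sim/cube.json \
          --library sim/library.csv --lam 0.01 --out maps/
srh select-channels --cube sim/cube.tif --sidecar sim/cube.json \
          --library sim/library.csv --target-k 5 --n-pixels 2100 --out subset.json
srh render --maps maps/ --out merged.png
```

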