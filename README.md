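# shgmetrics

Quantitative collagen-architecture metrics for second-harmonic generation
(SHG) microscopy of 3D fibrosis models — e.g. lung-fibroblast spheroids grown
under collagen-crosslink promotion or inhibition. Collagen fibrils are strong
endogenous SHG emitters, and polarization-resolved SHG probes their structure
below the optical resolution limit. This package implements, as one tested
pipeline, the metric suite such studies use to compare treatment groups across
structural size scales:

* **P-SHG pixel fitting** (`shgmetrics.pshg`) — each pixel's SHG intensity as
  the excitation linear polarization rotates follows, for a cylindrically
  symmetric harmonophore under Kleinman symmetry,

  `I(θ) = A·{ sin²[2(θ−φ)] + [ sin²(θ−φ) + b·cos²(θ−φ) ]² } + c`

  with tensor ratio `b = χ_ZZZ/χ_ZXX` and in-plane fiber orientation φ. The
  effective α-helical pitch angle of the emitting peptide dipoles is
  `θ_p = arctan√(2/b)` (b = 2 ⇒ θ_p = 45°).
* **Signal anisotropy** (`shgmetrics.anisotropy`) —
  `β = (I∥ − I⊥)/(I∥ + 2·I⊥)` per pixel: 1 for perfectly aligned dipoles,
  0 for random, analytic floor −0.5.
* **SHG circular dichroism** (`shgmetrics.chirality`) —
  `|I_LHCP − I_RHCP| / [(I_LHCP + I_RHCP)/2]` per pixel above a noise-background
  threshold mask, reporting net chirality in [0, 2].
* **Depth attenuation** (`shgmetrics.attenuation`) — self-normalized
  intensity-vs-depth decay of a z-series; a flatter slope means relatively
  higher SHG conversion efficiency.
* **Fiber morphology** (`shgmetrics.fibers`) — per-fiber straightness, length
  and width from a ridge-enhancement/skeletonization extractor.
* **Group statistics** (`shgmetrics.stats`, `shgmetrics.pipeline`) — one-way
  ANOVA with post hoc Student's t-tests, significance stars, and
  crosslink-per-collagen normalization (300 hydroxyprolines and 300 kDa per
  triple helix).
* **Synthetic acquisitions** (`shgmetrics.synth`) — every input geometry with
  known ground truth (polarization sweeps, analyzed channel pairs, LHCP/RHCP
  pairs, attenuated z-series, fiber phantoms), so the whole pipeline is
  testable end to end without microscope data.

Stacks live on disk as plain multi-page TIFF plus a small YAML sidecar
(`shgmetrics.io`); all tabular output is CSV.

## Worked example

Recover the pitch angle from a synthetic polarization sweep at photon-counting
noise levels (~1000 peak counts):

```python
import numpy as np
from shgmetrics import SyntheticScene, gen_pshg_stack, fit_pshg, pitch_map

scene = SyntheticScene(b_true=2.0, phi_deg=30.0, amplitude=250.0,
                       shape=(32, 32), noise="poisson", seed=202)
stack = gen_pshg_stack(scene)          # 18 frames, 0–170° in 10° steps
fit = fit_pshg(stack, min_mean_intensity=0.0)
pm = pitch_map(fit)
print(f"median b = {np.median(fit.b_map[fit.valid_mask]):.4f}")
print(f"pitch = {pm.mean_deg:.3f} ± {pm.sem_deg:.3f} deg (n={pm.n_valid})")
```

prints

```
median b = 2.0107
pitch = 44.883 ± 0.010 deg (n=1024)
```

i.e. the injected tensor ratio b = 2 (pitch 45°) is recovered with ~1% median
error per pixel under shot noise; with `noise="none"` the fit is exact to
numerical precision. The numbered drivers under `analysis/` walk through every
stage the same way (simulation, P-SHG fitting, anisotropy, SHG-CD,
attenuation, fiber morphology, and the full 4-group study) and write their
tables under `results/analysis/`.

The command line mirrors the library:

```sh
shgmetrics simulate --config scene.yml --out scratch/scene
shgmetrics fit-pshg --stack scratch/scene.tif --sidecar scratch/scene.yml --out scratch/fit
shgmetrics pipeline --out results/study --seed 1
```

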