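# dvcqmri

Quantitative MRI mapping of the rat **discovertebral complex (DVC)** — the
functional unit of intervertebral disc (nucleus pulposus, NP; annulus
fibrosus, AF), vertebral endplate (cartilage endplate, CEP; growth plate,
GP) and subchondral bone (SB).

The package is a tested, reusable implementation of a small-animal
relaxometry protocol for monitoring degenerative disc disease (DDD):

* a **synthetic rat-tail phantom** — a labeled cylinder stack with the five
  DVC compartments in immature/mature variants, healthy or degenerative
  tissue states at three timepoints (D0, W1, W2), with a 4-element
  phased-array magnitude noise model (chi-distributed, 2L degrees of
  freedom);
* **T2 mapping** from a multi-slice multi-echo spin-echo (MSME) series
  (100 echoes, 3.8–378.6 ms) by pixel-wise fitting of the
  noise-floor model `S(t) = S0·exp(−t/T2) + 2·L·σ²`;
* **T1 mapping** from an MP2RAGE acquisition (TI1/TI2/TR =
  800/2200/6250 ms, 160-echo GRE readouts, 7° flips): the bias-free ratio
  `GRE1·GRE2/(GRE1²+GRE2²)` is inverted through a lookup table simulated
  from the sequence parameters (closed-form steady state of the per-cycle
  affine magnetization map);
* **ROI quantification** — SNR as ROI mean over σ, with σ estimated from a
  background ROI via the chi-mean relation (mean background magnitude
  divided by 2.74 for a 4-element coil), and CNR as the signed SNR
  difference of neighboring structures (AF/NP, AF/CEP, CEP/GP, GP/SB);
* **gated longitudinal statistics** — Shapiro normality and Bartlett
  variance gates selecting an unpaired Student t-test or a two-sided
  Mann–Whitney U test (exact for n ≤ 8), at α = 0.05.

Real data can enter the same pipeline as NIfTI-1 volumes (3D maps, 4D echo
series), integer label maps and JSON sequence-parameter sidecars.

## Worked example

```python
import numpy as np
from dvcqmri import (
    GeometrySpec, CoilNoiseModel, build_label_map, make_roi_set,
    tissue_params_for, simulate_msme_series, fit_t2_map,
    estimate_sigma_from_background,
)

geom = GeometrySpec.for_maturity("mature")          # 64x64x32, 2 vertebrae
label = build_label_map(geom)
rois = make_roi_set(label, erosion_vox=0)
table = tissue_params_for("mature", "healthy", "D0")

noise = CoilNoiseModel(sigma=0.2, n_channels=4, seed=17)
series = simulate_msme_series(label, table, noise=noise)

est = estimate_sigma_from_background(series.data[rois.background, :].ravel(), L=4)
t2map = fit_t2_map(series, rois["NP"] | rois["AF"], sigma=est.sigma, L=4)
for s in ("NP", "AF"):
    sel = rois[s] & t2map.valid
    print(f"{s}: fitted T2 = {t2map.values_ms[sel].mean():6.1f} ms "
          f"(truth {table.value(s, 't2_ms'):5.1f} ms)")
```

prints

```
NP: fitted T2 =  103.9 ms (truth 105.0 ms)
AF: fitted T2 =    5.9 ms (truth   6.0 ms)
```

i.e. the pixel-wise noise-floor fit recovers the NP ground truth to about
1% and the AF (whose 6 ms decay is sampled by only a handful of echoes
on the 3.8 ms grid) to a few percent.

The same study can be run end to end from the shell:

```sh
dvcqmri run-all --out study/          # phantom -> simulate -> fit -> quantify
dvcqmri stats --table study/quant_table.csv --out study/
```

which writes NIfTI volumes and maps per arm and seed, a long-form
`quant_table.csv` (one row per structure x metric x replicate), and
`stats_results.csv` with one gated comparison per contrast.

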