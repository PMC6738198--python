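# modespec

Frequency decomposition of resting-state BOLD fMRI time series.

The spontaneous BOLD signal in the 0.01–0.25 Hz band is a mixture of
oscillatory processes — respiratory and cardiac-rate variations,
metabolic and vasomotor fluctuations — whose relative contributions and
network signatures differ by frequency. Band-pass filter banks impose
their own band boundaries on this non-stationary signal; `modespec`
instead extracts the bands from the data itself with **variational mode
decomposition (VMD)** and quantifies what each recovered frequency
carries. The package is aimed at fMRI methods researchers who want a
tested, seedable implementation of the whole chain: decomposition,
mode-mixing benchmarking, whole-brain frequency clustering, fractional
amplitude mapping and frequency-resolved functional connectivity —
together with a synthetic 4D generator whose ground truth makes every
stage checkable.

## The model

VMD represents a series f(t) as K band-limited modes u_k with center
frequencies ω_k, chosen to minimize the summed modal bandwidth subject
to reconstruction:

    min_{u_k, ω_k}  Σ_k ‖ ∂_t [ (δ(t) + j/πt) · u_k(t) ] e^{−jω_k t} ‖²₂
    s.t.            Σ_k u_k = f

solved in the frequency domain by alternating (a) a Wiener-filter mode
update with penalty 1 + 2α(ω − ω_k)², (b) a center-frequency update as
the power-spectral center of mass of each mode, and (c) an optional
dual ascent on the reconstruction constraint. The bandwidth penalty α is
selected on a grid by minimizing the inter-modal spectral overlap while
keeping the relative reconstruction error under a cap. Classic EMD
(recursive sifting with cubic-spline envelopes) and complementary
ensemble EMD (CEEMD) are provided as baselines; their tendency to mix
and spread modes is what the Monte Carlo benchmark measures, as the
fraction of each mode's spectral power falling outside its assigned
ground-truth band.

Downstream, every voxel of a (band-passed) 4D dataset is decomposed and
each mode contributes its center-of-mass frequency — weighted by its
share of the voxel's modal power — to a pooled histogram. Gaussian
peaks fitted to that histogram define whole-brain *frequency clusters*
(labeled IMF1 for the highest-frequency cluster downward); per-voxel
cluster power fractions give fractional amplitude maps, and per-cluster
ROI-averaged mode time courses give one Pearson connectivity matrix per
frequency cluster.

## Worked example

```python
import numpy as np
from modespec import (BrainPhantomConfig, PipelineConfig, run_pipeline)

cfg = PipelineConfig(phantom=BrainPhantomConfig(seed=0), seed=0)
res = run_pipeline(cfg)

for lbl, c, s in zip(res.clusters.labels, res.clusters.centers,
                     res.clusters.sds):
    print(f"{lbl}: {c:.4f} Hz (sd {s:.4f})")
m = res.cluster_matrices["IMF4"]
print("IMF4 within-block ROI correlation:",
      round(float(np.nanmean(m.values[:4, :4][np.triu_indices(4, 1)])), 3))
```

prints

```
IMF4: 0.0287 Hz (sd 0.0036)
IMF3: 0.0796 Hz (sd 0.0085)
IMF2: 0.1501 Hz (sd 0.0101)
IMF1: 0.2194 Hz (sd 0.0102)
IMF4 within-block ROI correlation: 0.983
```

The default phantom plants four frequency clusters at 0.028, 0.080,
0.15 and 0.22 Hz with block-shared components only in the two lowest:
the pipeline recovers all four cluster centers to a few mHz, and the
lowest-frequency connectivity matrix shows the planted network blocks
at near-unit correlation while the high-frequency matrices stay flat —
the frequency dependence the package is built to measure.

The same stages are available from the shell:

```bash
modespec phantom --out data/ --seed 0
modespec run --bold data/phantom_bold.nii.gz \
             --tissue data/phantom_tissue.nii.gz \
             --rois data/phantom_rois.nii.gz --out runs/demo --seed 0
modespec benchmark --reps 50 --out runs/bench
```

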