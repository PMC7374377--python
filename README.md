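# saliencyfcm

Noise-robust segmentation of greyscale images by **feature-saliency fuzzy
Gaussian-mixture clustering with embedded neighbourhood information**.

Unsupervised clustering segmenters (fuzzy C-means and Gaussian-mixture
variants) label each pixel independently, so impulse or heavy Gaussian noise
shreds their segmentations. This package implements a spatially constrained
variant for 2-D 8-bit greyscale images — medical slices, cell images,
remote-sensing scenes, synthetic phantoms — that remains usable under
additive Gaussian noise (σ up to ~140 on the 0–255 scale), salt-and-pepper
noise (up to 45%), speckle, and Gaussian + impulse mixtures. It ships with
phantom/noise simulators and PSNR/MCR evaluation, so the whole pipeline runs
without any external data.

## The model

Pixel *i* carries a feature vector *x<sub>il</sub>* (by default *D* = 1, the
grey level). Each feature is either *salient* for class *j* — drawn from
N(μ<sub>jl</sub>, σ²<sub>jl</sub>) — or *background*, drawn from a
class-independent N(ε<sub>l</sub>, ν²<sub>l</sub>); ρ<sub>l</sub> is the prior
saliency of feature *l* and *s<sub>ijl</sub>* its posterior. Classification
memberships *z<sub>ij</sub>* minimise

```
J = Σ_ij z_ij d_ij
    + λ Σ_ij [ z_ij log(z_ij/π_ij) + G_ij log(G_ij/π_ij) ]
    + γ Σ_ij z_ij Σ_l KL( Bern(s_ijl) ‖ Bern(ρ_l) )
```

where *d<sub>ij</sub>* is the saliency-weighted negative log-likelihood and
the spatial machinery enters through the prior:

* **Markov neighbourhood weights** `h_ijl = (Σ_{t∈N_i} N(x_tl; μ_jl, σ²_jl))^α`
  — windowed sums of class likelihoods over a w×w window *N<sub>i</sub>*;
* the **noise smoothing factor**
  `G_ij = exp( β/(2N_i) · Σ_{t∈N_i} [z_tj + h̃_tj] )` with h̃ the
  class-normalised weights — an exponential vote for the locally dominant
  class that suppresses isolated noise pixels;
* the **combined prior** `π_ij = (z_ij + G_ij) / Σ_k (z_ik + G_ik)`.

The KL penalty (weight λ) replaces the classical fuzzifier exponent and ties
memberships to this prior. All blocks (s, z, μ, σ², ε, ν², ρ, G, π) are
updated in closed form by coordinate descent after a fuzzy C-means
initialisation; iteration stops when the objective decrease falls below δ.

## Worked example

```python
import numpy as np
from saliencyfcm import (SaliencyFuzzySegmenter, FuzzyCMeans, NoiseSpec,
                         corrupt, make_phantom, evaluate_segmentation)

ph = make_phantom("four_region", 128, 128, levels=(40, 100, 160, 220))
noisy = corrupt(ph.clean, NoiseSpec("salt_pepper", sp_fraction=0.35, seed=7))

seg = SaliencyFuzzySegmenter(n_clusters=4, random_state=7).fit(noisy)
report = evaluate_segmentation(seg.labels_, ph.truth, levels=ph.levels)
print(f"class means: {np.sort(seg.cluster_means_[:, 0]).round(1)}")
print(f"MCR: {report.mcr_percent:.2f}%  PSNR: {report.psnr_db:.2f} dB")

fcm = FuzzyCMeans(n_clusters=4, random_state=7).fit(noisy)
rep_fcm = evaluate_segmentation(fcm.labels_, ph.truth, levels=ph.levels)
print(f"plain FCM baseline  MCR: {rep_fcm.mcr_percent:.2f}%  PSNR: {rep_fcm.psnr_db:.2f} dB")
```

prints

```
class means: [ 73.9 109.8 149.8 187.3]
MCR: 3.65%  PSNR: 23.26 dB
plain FCM baseline  MCR: 26.17%  PSNR: 11.78 dB
```

With 35% of the pixels replaced by impulse noise, the spatially constrained
segmenter mislabels 3.65% of pixels where independent-pixel FCM mislabels
26% — the neighbourhood prior reassigns impulse pixels to the locally
dominant class. MCR is reported after optimally aligning cluster labels to
the ground truth (Hungarian assignment); PSNR compares grey renderings of
the aligned and true label maps. The estimated class means are pulled
toward mid-grey by the impulse contamination of the weighted moments; under
mild noise (σ = 10) they recover the true levels to within one grey level.

The same pipeline is available from a shell:

```bash
saliencyfcm simulate --kind four_region --noise salt_pepper --sp-fraction 0.35 --seed 7 --out sim/
saliencyfcm segment --image sim/noisy.png --clusters 4 --seed 7 --out seg/
saliencyfcm evaluate --pred seg/labels.png --truth sim/truth.png --levels 40,100,160,220
```

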