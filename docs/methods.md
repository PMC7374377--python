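# Methods

## Model and solver

The segmenter clusters per-pixel feature vectors into C classes under a
two-component generative story per feature: a *salient* component, Gaussian
with class-specific mean and variance (μ_jl, σ²_jl), and a *background*
component shared by all classes (ε_l, ν²_l). The saliency prior ρ_l and
posterior s_ijl let the model discount features that carry no class
information. The per-pixel, per-class dissimilarity is the saliency-weighted
negative log-likelihood

    d_ij = Σ_l [ −s_ijl log N(x_il; μ_jl, σ²_jl) − (1−s_ijl) log N(x_il; ε_l, ν²_l) ],

the unique form whose s-derivative yields the class/background log-ratio
that the closed-form saliency update inverts. Spatial context enters
through three fields computed on w×w windows (centre pixel included,
replicate padding):

1. windowed class-likelihood sums raised to exponent α (default 2),
2. their class-normalised form h̃ (the Markov neighbourhood prior), and
3. the noise smoothing factor G_ij = exp(β/(2N_i) Σ_t [z_tj + h̃_tj]),
   an exponential vote for the class that dominates the window,

which combine into the prior π_ij = (z_ij + G_ij)/Σ_k (z_ik + G_ik). The
objective adds λ·[KL(z‖π) + Σ G log(G/π)] and γ·Σ z·KL(s‖ρ) to the
dissimilarity term; every block update is the exact coordinate minimiser,
so with π and G frozen one sweep never increases the objective (a property
the test suite asserts). G and π are refreshed once per outer sweep
(ICM-style): G's dependence on neighbouring memberships is not
back-propagated through the z update.

Iteration order per sweep: G → π → s → z → (μ, σ²) → (ε, ν²) → ρ, after a
fuzzy C-means initialisation (fuzzifier m = 2, centres drawn seeded from
the distinct feature rows; class moments z-weighted, background moments
global, ρ = 1/D, s = 1/2, π = 1/C). Convergence is declared when the
absolute objective decrease drops below δ; otherwise the loop stops at
`max_iter`. Labels are the per-pixel membership argmax, ties to the lowest
class index.

## Parameters

| name | default | units / range | role |
|---|---|---|---|
| `n_clusters` (C) | 2 | ≥ 2 | number of classes; not selected automatically |
| `window` (w) | 5 | {3,5,7} pixels | neighbourhood side; 3 suits low noise, 5 heavy noise |
| `lam` (λ) | 150 | – | weight of the KL membership/prior coupling |
| `gamma` (γ) | 15 | – | saliency tempering; likelihoods enter the s update as Φ^(1/γ) |
| `beta` (β) | 12 | – | smoothing-factor weight; G ∈ [1, e^β] |
| `alpha` (α) | 2 | – | exponent on the windowed likelihood sum |
| `delta` (δ) | 1e−4 | objective units | absolute-decrease stopping threshold |
| `max_iter` | 400 | sweeps | iteration cap |
| `variance_floor` | 1e−4 | grey² | lower bound on all variances |
| `rho_floor` | 1e−3 | – | ρ clipped to [ρ_floor, 1−ρ_floor] |
| `features` | "intensity" | – | D = 1 raw grey level; "intensity_mean" adds the 3×3 window mean (D = 2), a package extension for texture-free smoothing |

β deserves a note. The smoothing exponent is read as β/(2N_i)·Σ_t[z+h̃],
each bracketed term in [0, 2], so G ∈ [1, e^β]. With β ≲ 1 the combined
prior (z+G)/Σ(z+G) cannot concentrate — its largest entry is bounded near
0.73 for C = 2 — and the λ-weighted KL anchor then drags the memberships
toward uniform: on a two-region phantom with σ = 10 noise the class means
collapse to the global mean while only the label argmax survives. With the
default β = 12 (e^12 ≈ 1.6·10⁵, well inside double range) the factor is
sharply class-discriminative, the prior concentrates on the locally
dominant class, memberships sharpen and the weighted moments recover the
true class parameters. The exponent is clipped to [0, β] so the stated
range of G is exact under box-filter round-off.

λ = 150 and γ = 15 make the data term a gentle, accumulating tiebreak
against the spatial prior: each sweep multiplies the membership odds by
exp(−Δ(d+γK)/λ), so likelihood evidence compounds across sweeps while the
prior enforces spatial coherence within a window. The saliency KL term
bounds how cheaply a class can "opt out" of a bad likelihood by sending
s → 0 (cost γ·log(1/(1−ρ)) per feature); with wide windows this lets a
strong local majority overrule the likelihood at extreme boundary corners,
which is why noise-free input is best segmented with w = 3.

## Numerical choices

* All densities are evaluated in log space; the saliency update is a
  logistic of log-odds, and the z update is a softmax with a per-pixel
  log-sum-exp shift, so no pixel row can underflow to zero.
* Probabilities are clipped at 1e−10, log arguments at 1e−300, windowed
  likelihood weights floored at 1e−300 after exponentiation.
* Weighted-moment updates guard against vanishing mass (Σ weights <
  1e−12): the affected class/feature keeps its previous parameters and a
  RuntimeWarning is emitted.
* Windowed sums are computed with a uniform box filter in "nearest"
  (replicate) mode and agree with explicit nested loops to floating-point
  accuracy; borders therefore see a full window.
* FCM initial centres are drawn without replacement from the *unique*
  feature rows, so discrete grey-level data cannot produce coincident
  centres; a constant feature raises an error naming the feature, and an
  image with fewer distinct grey levels than classes is rejected.
* The solver is fully deterministic given the seed: identical runs produce
  bit-identical label maps and objective traces.

## What the simulators emulate — and what they do not

`make_phantom` produces piecewise-constant scenes: a centred disk
(two classes), quadrants with inset rectangles of the diagonally opposite
class (four classes, so every class appears in several places), and equal
vertical stripes (2–4 classes). `corrupt` applies additive Gaussian noise
(std on the 0–255 scale), Bernoulli salt-and-pepper impulses (equal
probability 0/255), speckle I + I·n with n ~ N(0, (std/255)²), or a
Gaussian-then-impulse mixture with independent substreams of one seed; all
outputs are clipped to [0, 255] and rounded. Noise "levels" quoted on the
0–255 scale are standard deviations.

These phantoms have exactly constant regions, straight or circular
boundaries, and i.i.d. noise. Real images add texture, shading gradients,
partial-volume boundary pixels and spatially correlated noise, none of
which the generators model — so passing tests demonstrate noise
robustness of the clustering machinery, not performance on natural
scenes. Class grey levels for the study conditions (60/180 two-region;
40/100/160/220 four-region) were fixed once as evenly spread, realistic
8-bit levels.

## Evaluation conventions

Cluster labels are arbitrary, so MCR first aligns predicted to true labels
by maximising the matched pixel count over label assignments (Hungarian
algorithm; equal to brute-force enumeration for C ≤ 4). PSNR =
10·log10(255²/MSE) is computed between grey renderings of the aligned
predicted and true label maps using the phantom's class levels, so it
measures spatial disagreement; the `segment` command additionally writes a
class-mean reconstruction (each pixel replaced by its class's converged
mean) for visual inspection. Identical images report PSNR = ∞.

## Problem sizes

The recovery study uses a 96×96 two-region phantom (Gaussian σ = 10, five
seeds); the robustness study a 128×128 four-region phantom under Gaussian
σ = 58 and 35% salt-and-pepper noise (five seeds each), with plain FCM on
the same images as the baseline. A full 128×128 run with the default
400-sweep cap takes a few seconds on one CPU core.

## Known limitations

* Greyscale only; multi-channel input is rejected rather than converted.
* C must be supplied; there is no automatic model-order selection.
* Under heavy impulse noise the class means are biased toward mid-grey
  because the impulse pixels enter the weighted moments; labels remain
  accurate but reported means should not be read as radiometric estimates.
* The absolute convergence threshold δ = 1e−4 is rarely reached on large
  noisy images before the iteration cap; results are then reported with
  `converged = False` and are still usable (the objective has plateaued).
* Very wide windows erode single-pixel structures and extreme boundary
  corners, the usual bias of neighbourhood-vote smoothing.
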