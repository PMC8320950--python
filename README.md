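# fdagseg

Anisotropic edge strength and edge-aware superpixel hierarchies for 2-D
biological and natural images.

Superpixel algorithms that merge regions greedily are only as good as the
edge evidence that tells them where *not* to merge. `fdagseg` measures that
evidence with a bank of **normalized first-derivative-of-anisotropic-Gaussian
(FDAG) kernels**: directional derivative filters whose anisotropy adapts to
their scale, so small (noise-prone) scales are elongated along the edge while
large scales stay isotropic. The normalized multiscale response lets the
filter bank identify each edge's *characteristic scale* — the blur scale of
the edge itself — and compensate for it, producing an edge-strength map that
reflects contrast rather than sharpness. That map then drives a
**Borůvka minimum-spanning-tree region-merging hierarchy** from which a
superpixel partition at any granularity can be extracted, plus the standard
evaluation metrics (ASA, UE, MAE) and Friedman/Nemenyi rank statistics used
to compare segmentation methods.

## The model

A scaled edge is a step of contrast `c0` on base level `b0`, blurred by an
isotropic Gaussian of scale `ω0`:

    f(x) = [c0·H([cosθ0, sinθ0]·x) + b0] ∗ g(x; ω0).

The directional anisotropic Gaussian at scale `σ`, anisotropy `φ ≥ 1` and
orientation `θ` is

    g(x; σ, φ, θ) = 1/(2π φ σ²) · exp(−½σ⁻² xᵀ Rθᵀ diag(1, φ⁻²) Rθ x),

its derivative along the orientation axis is
`g′(x) = −([cosθ, sinθ]·x / σ²)·g(x)`, and the scale-normalized FDAG kernel
is `g̃′(x) = 2√π·σ^½·g′(x)`. Convolving `g̃′` with the scaled edge at the
matched direction gives the response

    E_norm(σ) = √2·c0·σ^½ / √(ω0² + σ²),

which peaks in scale space exactly at `σ* = ω0` with value `c0/√ω0` — so the
argmax over a scale set recovers the edge's blur scale, and multiplying the
thinned (non-maxima-suppressed) response by `√S` recovers its contrast:

    Ie(m) = max(E(m), E_nms(m)·√S(m)).

The anisotropy of each bank member is `φ(σ) = max((σ_con/σ)², 1)`: filtered
white noise of level `ε0` comes out with standard deviation
`ε0/(σ·√(2φσ))`, so elongating the small scales buys noise robustness
without losing their scale selectivity.

For segmentation, the image is a 4-connected pixel graph. Each Borůvka round
merges every tree with its nearest neighbor — first (τ = 4 rounds) under the
minimum color-arc distance, then under the region distance
`D(T1,T2) = De·Dc`, where `De` is the mean `Ie` over the shared border and
`Dc` the χ² distance between the trees' color histograms (20 bins/channel),
optionally blended with a size regularizer. Every merge is recorded, so one
run yields the whole hierarchy.

## Worked example

```bash
python examples/edge_strength_demo.py
```

```
true edge blur scale omega0 = 1.3, contrast c0 = 0.6
selected scale on centerline      : 1.40
peak response (expected c0/sqrt(omega0) = 0.5262) : 0.5252
scale-compensated edge strength   : 0.6215
```

The bank (scales 0.8–1.8) selects the edge's blur scale to within one grid
step, the peak response matches `c0/√ω0` to a fraction of a percent, and the
`√S` compensation returns the true contrast 0.6. Similarly,

```bash
python examples/superpixel_demo.py
```

```
pixels: 16384, trees after preliminary grouping: 59
n =  50 superpixels:  ASA = 0.9967   UE = 0.0066
```

segments a noisy 5-region scene at 50 superpixels with 99.7% achievable
segmentation accuracy and 0.7% undersegmentation error. The other examples
cover the kernel bank itself (`kernel_bank_demo.py`) and the Friedman/Nemenyi
method comparison (`rank_statistics_demo.py`).

A thin CLI exposes the same pipeline for files on disk:

```bash
fdagseg synth scene -o scene                 # synthetic fixture
fdagseg edges scene.png -o out               # Ie / scale / direction maps
fdagseg superpixels scene.png -n 10,50 -o out
fdagseg evaluate out/scene_sp50.png --gt scene_gt.png -o report.csv
```

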