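# gelfit

Detection and model-based quantification of protein spots in
two-dimensional gel electrophoresis (2-DE) and immunoblot images.

Proteins separated by 2-DE appear as smooth, roughly Gaussian intensity
spots. Quantifying how much protein sits in each spot is hard when spots
overlap (one pixel carries signal from several spots) or differ widely
in intensity (any fixed threshold cuts away a larger share of a dim
spot's tails than of a bright one's). `gelfit` addresses both by
fitting sums of circular 2-D Gaussians

```
f(x, y) = Σ_j I_j · exp(−½ ((x − x0_j)² + (y − y0_j)²) / σ_j²) + μ_bg
```

and quantifying each spot by the volume under its fitted surface,
**VUS = 2π I σ²**, which is proportional to the collected photon count
and hence to protein amount. So that fitting stays fast, detected peaks
are grouped into *compounds* — connected groups of peaks whose square
neighborhoods of edge `d` touch (found via transitive closure of the
peak adjacency matrix) — and each compound is fitted independently on
its own pixels.

The package also implements the two classical comparator methods
(optical density = peak-pixel intensity; threshold-area volume with
perpendicular-bisector splitting of merged regions), a synthetic gel
simulator with exact ground truth (Gaussian, Lorentz-shaped and
diffusion-model spots, controlled noise and saturation), and
quantification-quality metrics (α, α_mean, exposure-series CV). It is
aimed at proteomics labs quantifying immunoblots or 2-DE gels, and at
anyone benchmarking spot-quantification methods on simulated data.

## Worked example

```python
import gelfit

# two overlapping spots (centers 24 px apart), faint noise, known truth
image, truth = gelfit.simulate_pair(
    "gaussian", I_P=1000, I_Q=600, width_P=3, width_Q=3,
    ipd=24.0, noise_sd=0.5, seed=9, background=30, dims=(112, 112),
)
result = gelfit.run_pipeline(image, gelfit.RunConfig(w=10, t=10))
for fit, true_sig in zip(sorted(result.fits, key=lambda f: f.x0),
                         truth.true_signals):
    print(f"VUS {fit.vus:9.1f}  true {true_sig:9.1f}  "
          f"sigma {fit.sigma:.3f}  discarded {fit.discarded}")
```

prints

```
VUS   56539.8  true   56548.7  sigma 3.000  discarded False
VUS   33940.2  true   33929.2  sigma 3.001  discarded False
```

Both spots are recovered within 0.05 % of their true volumes; fitted
widths match the generating σ = 3; neither is flagged as a false
positive (spots fitted with σ ≤ 1 px would be — single-pixel camera
noise has no broad base).

The same pipeline is available from the shell:

```sh
gelfit pipeline gel.tif --ipd 21 --out-dir out/   # w = ⌊IPD/2⌋ = 10
gelfit detect gel.tif --w 10 --t 10 --out peaks.csv
gelfit quantify gel.tif peaks.csv --method area --threshold auto
```

`--ipd` is the inter-peak distance of the two closest spots you want
resolved; the detection radius is `w = ⌊IPD/2⌋`. `t` (default 10)
scales the estimated background-noise SD into the detection threshold.

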