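# mese-relaxo

Quantitative T2 relaxometry for multi-echo spin-echo (MESE) magnitude
images of plant tissue, built for low-field scanners where the
signal-to-noise ratio is poor and falls echo by echo.

The package targets the workflow used to study water status in fruit
(e.g. tomato ripening): acquire one magnitude image per echo time,
assign voxels to tissue structures with a label map, and invert the
per-structure (or per-voxel) decay curves into relaxation times and
amplitudes. It provides

* a **phantom simulator** — multi-exponential decay on a TE grid,
  rendered onto geometric label maps, with Rician noise from independent
  Gaussian channel noise and magnitude reconstruction;
* an **echo-aware 3D non-local-means denoiser** whose patches extend
  along the echo axis and whose smoothing bandwidth h(TE) grows with the
  per-echo noise power, next to the classical layer-by-layer filter;
* a **chaotic immune particle-swarm inversion engine** with adaptive
  per-component search intervals, for mono- to four-exponential fits;
* structure-level and voxel-level analysis: region curve extraction
  (with Rician bias correction when the noise level is known), echo
  exclusion, R²/RMSE fit metrics, water-state classification, T2 and
  amplitude maps, CSV/JSON/TIFF reporting, and a CLI.

## Model

Under a long repetition time (TR >> T1) the voxel signal is proportional
to proton density times pure T2 decay. Each decay curve is modelled as

    S(θ, t) = Σₑ Aₑ · exp(−t / T2ₑ),      θ = (A₁, T2₁, …, A_e, T2_e),

and fitted by minimising the least-squares criterion

    C(θ) = 1/(2σ²) · Σₜ (yₜ − S(θ, t))².

For e = 3 the components, in ascending T2 order, are read as bound
(T21), semi-bound (T22) and free water (T23); their normalised
amplitudes A01/A02/A03 are the relative water contents. The optimizer is
a particle swarm whose stochastic coefficients evolve by the logistic
map r′ = 4r(1 − r), augmented with immune clonal selection
(clone/mutate/crossover of high-affinity particles), receptor-correction
probes of the incumbent best, and adaptive compression of the
per-component search intervals around the incumbent.

## Worked example

```python
import numpy as np
from mese_relaxo import *
from mese_relaxo.optimizer import OptimizerConfig

# three-ring phantom: A = 250 everywhere, T2 = 80/200/600 ms, TE = 30..1830 ms
spec = three_ring_phantom_spec(shape=(128, 128))
stack, labels = generate_phantom(spec, n_echo=61)
noisy = add_rician_noise(stack, sigma=5.0, seed=1)

curves = extract_region_curves(noisy, labels)
fit = invert(curves[1], e=1, config=OptimizerConfig(seed=1))
print("inner ring mono fit: A = %.2f, T2 = %.2f ms, R2 = %.4f, RMSE = %.4f"
      % (fit.theta.amplitudes[0], fit.theta.t2s[0], fit.r2, fit.rmse))

mix = DecayCurve(stack.te_grid, np.mean([curves[k].y for k in (1, 2, 3)], axis=0))
tri = invert(mix, e=3, config=OptimizerConfig(seed=1))
for name, vals in classify_components(tri.theta).items():
    print("%s: T2 = %6.1f ms  proportion = %.3f" % (name, vals["t2_ms"], vals["proportion"]))
```

Output:

```
inner ring mono fit: A = 250.03, T2 = 80.01 ms, R2 = 0.9993, RMSE = 0.0044
T21: T2 =   79.4 ms  proportion = 0.330
T22: T2 =  203.2 ms  proportion = 0.352
T23: T2 =  621.8 ms  proportion = 0.318
```

The mono fit recovers the inner ring's generating parameters (A = 250,
T2 = 80 ms) from the noisy stack to within 0.02%; RMSE is on the
first-echo-normalised 0–1 scale. The tri-exponential fit of the
three-ring mixture curve separates the three water pools at roughly
equal proportions with T2s within a few percent of the generating
values — the residual deviation is what channel noise at σ = 5 leaves
behind after region averaging.

The same steps are available from the shell:

```bash
mese-relaxo simulate --shape 128 128 --n-echo 61 --sigma 5 --seed 1 --out stack.tif
mese-relaxo invert-regions --stack stack.tif --labels stack_labels.tif --out results/
mese-relaxo run --config pipeline.yaml     # full simulate→denoise→invert→report run
```

## Layout

| module | contents |
| --- | --- |
| `mese_relaxo.acquisition` | protocols, phantom specs, decay simulation, Rician noise, per-echo SNR |
| `mese_relaxo.denoise` | NL-means configs, 2D/3D filters, bandwidth schedule, PSNR/RMSE/SSIM |
| `mese_relaxo.relaxometry` | decay curves, fit criterion, echo exclusion, metrics, water states |
| `mese_relaxo.optimizer` | chaos map, swarm updates, immune operators, interval adaptation, `invert` |
| `mese_relaxo.structures` | templates, region curves, structure fit tables, voxel-wise maps, reports |
| `mese_relaxo.pipeline` / `cli` / `io` | end-to-end runs, YAML config, provenance, formats |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical design choices.
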