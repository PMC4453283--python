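# agecsf

An **age-dependent analytical model of the human contrast sensitivity
function (CSF)**, for vision scientists, display/image-coding engineers and
lighting researchers who need a closed-form prediction of how grating
visibility changes across adulthood.

The CSF gives the reciprocal of the contrast detection threshold for a
sinusoidal grating as a function of its spatial frequency *u* (cycles per
degree). `agecsf` implements a physiological CSF of the form

```
                 M_opt(A, u)        ┌        X · Y · T          ┐ ½
CSF(A, u)  =  ───────────────  ×    │ ─────────────────────────── │
                   k(A)             │ 2 (Φ_opt(A) + Φ_neu(A)/M_lat²(A, u)) │
                                    └                            ┘
```

where every stage is an explicit function of observer age *A* (years):

- **M_opt** — Gaussian optical MTF, `exp(−2π²σ_opt²(u/u_opt)²)`, with
  `σ_opt = √(σ₀(A)² + (C_ab·d(A))²)`; the pupil diameter *d* follows a
  unified luminance formula plus a linear senile-miosis age correction;
- **Φ_opt** — photon noise `1/(η(A)·p·E(A))`, with retinal illuminance *E*
  (trolands, Stiles–Crawford corrected) driven by the ageing pupil and
  quantum efficiency η declining with age;
- **Φ_neu** — neural noise, constant (3·10⁻⁸ s·deg²) in the fovea at every
  age and inflated off-fovea by an age-dependent ganglion-cell density
  model (tied 3:1 to an ageing cone-density model);
- **M_lat** — lateral-inhibition high-pass MTF `√(1−exp(−(u/u_inh)²))`
  with foveal drop-off `u_inh = 7` cpd;
- **k, u_opt, σ₀, η** — the four fitted parameters, provided as analytical
  age curves (smooth saturating curves for σ₀ and η, piecewise-constant
  steps at 50 years for k and u_opt);
- `X, Y` field size (deg), `T = min(Te, To)` the effective summation time.

A spatiotemporal extension multiplies the criterion by a fitted temporal
factor `k*(w)` and filters the neural term through pluggable temporal
filters `H1(w)`, `H2(w)`.

The package also ships the **grid-search fitting engine** used to estimate
(η, σ₀, u_opt, k) from tabulated CSF data — exhaustive or staged
coarse-to-fine search over the protocol grid (η step 10⁻⁴, σ₀ step 0.01,
u_opt step 2.5 cpd, k step 0.25) — plus a per-age-group RMSE model
comparison, CSV data I/O and a synthetic-data generator.

## Worked example

Predict photopic CSF curves (100 cd/m², 5.5° binocular field) for a
30- and a 70-year-old observer:

```bash
agecsf curve --age 70 --luminance 100 --field 5.5 --binocular \
       --freqs 0.5,1,2,4,8,16,22
```

```
frequency_cpd,sensitivity,log10_sensitivity
0.5,125.87673451481334,2.099945467951126
1.0,246.37871926716736,2.391603193330181
2.0,453.27701581202064,2.6563636979709293
4.0,671.3953359236388,2.8269783199479446
8.0,518.2216839584607,2.7145155812211685
16.0,57.01051017142119,1.7559549274037405
22.0,3.7877570335148967,0.5783821133122377
```

The same command with `--age 30` peaks at 1136 (8 cpd) instead of 671
(4 cpd). The curves illustrate the model's core phenomenology: sensitivity
is band-pass in frequency, and ageing depresses it everywhere but most
strongly at high spatial frequencies (at 16 cpd the 70-year-old retains
16% of the 30-year-old's sensitivity; at 0.5 cpd, 75%) — the fingerprint
of senile miosis, increased intraocular scatter and reduced quantum
efficiency.

The same results are available from Python:

```python
import numpy as np
from agecsf import ViewingConditions, csf_spatial

cond = ViewingConditions(luminance=100, field_x=5.5, eyes=2)
csf_spatial(70, np.array([0.5, 2, 8, 22]), cond)
# array([125.87673451, 453.27701581, 518.22168396,   3.78775703])
```

Other subcommands: `agecsf densities` (retinal cell densities and the
inhibition cut-off vs eccentricity), `agecsf synth` (synthetic CSF
tables), `agecsf fit` (grid-search parameter estimation), `agecsf
compare` (age-dependent vs age-independent baseline RMSE).

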