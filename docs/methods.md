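# Methods

## Model

`agecsf` predicts contrast sensitivity `CSF(A, u)` for an observer of age
`A` (years) viewing a sinusoidal grating of spatial frequency `u` (cpd)
under photopic conditions. The detection criterion is signal-to-noise:
the threshold modulation is proportional (factor `k`) to the modulation of
internal noise, after the stimulus has passed an optical low-pass stage
and a neural (lateral-inhibition) high-pass stage. The closed form
implemented is

    CSF(u) = M_opt(u) / k * sqrt( X*Y*T / (2 * (Phi_opt + Phi_neu / M_lat(u)^2)) )

with `X`, `Y` the field sizes in degrees and `T = min(Te, To)` the
effective summation time (`Te = 0.1` s photopic integration time; `To` the
presentation time, unbounded by default).

Two renderings of this expression circulate: one with the neural noise
divided by `M_lat` unsquared and one with a `1/(2k)` prefactor. The
noise-composition algebra (`Phi_n = Phi_opt * M_lat^2 + Phi_neu` referred
through the two MTFs) forces the squared form, which is used everywhere;
the prefactor convention is reachable through the global `gain` constant
(default 1; `1/sqrt(2)` reproduces the alternative). Absolute sensitivity
scale is therefore a convention; the model's tested content is the curve
shape and its age dependence.

### Age-resolved stages

* **Pupil.** `D = 7.75 - 5.75 x/(x+2)`, `x = (L*S*F(n)/846)^0.41`,
  `F(1)=0.1`, `F(2)=1` (luminance `L` in cd/m^2, stimulus area `S` in
  deg^2, `n` eyes); then senile miosis
  `d = D + (A - 28.58)(0.02132 - 0.009562 D)`. For photopic `D > 2.23` mm
  the slope is negative: the pupil shrinks with age. An extrapolation
  yielding `d <= 0` raises an error rather than clamping — a clamped pupil
  would silently corrupt the illuminance and noise terms downstream.
* **Retinal illuminance.** `E = (pi L d^2/4)(1 - (d/9.7)^2 + (d/12.4)^4)`
  trolands (Stiles-Crawford correction).
* **Optical MTF.** `M_opt = exp(-2 pi^2 sigma_opt^2 (u/u_opt)^2)` with
  `sigma_opt = sqrt(sigma0^2 + (Cab d)^2)`, `Cab = 0.08`/mm at every age.
  `sigma0`, `Cab*d` and `sigma_opt` are treated as dimensionless numbers
  and the frequency normalisation is carried entirely by `u_opt` (cpd);
  this convention reproduces the fitted `sigma0` scale (0.42-0.68).
* **Photon noise.** `Phi_opt = 1/(eta p E)`. The photon conversion factor
  is `p = 1.285e6` photons s^-1 deg^-2 Td^-1: the commonly quoted
  coefficient 1.285 must carry a 1e6 scale for `Phi_opt` to be
  commensurate with `Phi_neu = 3e-8` s*deg^2 and yield sensitivities of
  order 10^2; `p` is config-overridable.
* **Neural stage.** Foveal anchors at every age: `u_inh(A,0) = 7` cpd,
  `Phi_neu(A,0) = 3e-8` s*deg^2. Off fovea both scale with the normalised
  ganglion-cell density
  `N_g(A,e)/N_g(A,0) = 0.85/(1+(e/a(A))^2) + 0.15/(1+(e/7.3)^2)`,
  `a(A) = -0.404 e^{-0.01246A} - 0.1792 e^{0.01525A}` (only `a^2` is
  consumed; the sign is an artefact of the fit). Ganglion cells are tied
  3:1 to cones, whose density is
  `N_c(A,e) = (6952.7 - 38.70A) e^{-0.35e} + 300` in relative units (the
  sources use cells/mm^2; only ratios enter the CSF). The peripheral
  inhibition cut-off is
  `u_inh = u0 * ratio * bracket^{-1/2}` with the age-independent
  receptive-field bracket `0.85/(1+(e/4)^2) + 0.13/(1+(e/20)^2) + 0.02`
  (exactly 1 at `e = 0`). This reading reduces exactly to the classical
  `u0 * bracket^{1/2}` when the density ratio coincides with the bracket;
  an alternative reading with the ratio to the power 0.5 sits behind the
  `inhibition_sqrt_ratio` config switch.

### Fitted age curves

    sigma0(A) = 0.42 + 0.26 (1 - exp(-((A-17)/27.1837)^1.547))
    eta(A)    = 0.019 + 0.023 (1 - exp(-((A-17)/13.0645)^-1.753))
    k(A)      = 3 (A <= 50), 4 (A > 50)
    u_opt(A)  = 35 cpd (A <= 50), 30 cpd (A > 50)

The printed groupings of these formulas are ambiguous; the parses above
are validated by tests reproducing the per-group grid estimates they were
fitted to (sigma0 rounds to 0.42/0.59/0.65 at ages 17/45/62; eta to
0.040/0.030 at 25/34; deviations at the other tabulated ages stay within
0.02 for sigma0 and 0.001 for eta). The model domain starts at 17 years
(fractional powers of negative numbers below; `eta(17)` is defined as its
right limit 0.042). At the 50-year boundary the younger branch applies.
Numerically, `eta(A)` is flat at 0.042 to machine precision up to ~18.7
years because the inner exponential underflows; this is the correct
limiting behaviour of the formula, not an implementation artefact.

The age-independent baseline (`csf_barten`) uses the classical photopic
defaults `sigma0 = 0.5`, `eta = 0.03`, `k = 3` with the luminance-only
pupil. The split parameterisation needs a baseline `u_opt`; 60 cpd is
used, pairing `sigma0 = 0.5` (arcmin scale) with the ~60 cpd foveal
resolution limit so the Gaussian MTF matches the classical 0.5-arcmin
blur.

### Spatiotemporal extension

`CSF(A, u, w)` replaces `k` by `k(A) * k*(w)` — age and temporal frequency
assumed independent — with

    k*(w) = 1.0835 + 3.1045 (1 - exp(-((w-0.5)/8.4785)^2.497))

clamped to 1.0835 below 0.5 Hz, and filters the neural term through
`(H1(w) (1 - H2(w)(1 - M_lat(u))))^2`. The squaring mirrors the spatial
term (the literal unsquared rendering is available via
`temporal_denominator_squared = False`). No functional forms for `H1`/`H2`
are prescribed; they default to identity and are pluggable callables.

## Fitting engine

"Optimisation" here means deterministic minimisation of the RMSE (linear
sensitivity scale — the scale on which published model-vs-data RMSEs of
order 10-100 live) over the finite protocol grid: eta in [0.005, 0.150]
step 1e-4 (the printed "0.01%" sampling read on the fractional scale,
matching 4-decimal fitted values), sigma0 in [0.01, 2.00] step 0.01,
u_opt in [1, 100] step 2.5 cpd, k in [0.5, 20] step 0.25 — about 9.2e8
cells. Ties are broken towards the lexicographically smallest
(eta, sigma0, u_opt, k).

For fixed optics the model is `P(u) * N(u) / k` with `P` the optical MTF
(depends on sigma0, u_opt) and `N` the noise envelope (depends on eta), so
the SSE at any cell expands as `A/k^2 - 2B/k + C` where `A`, `B` contract
the frequency axis once per (eta, sigma0, u_opt) cell. The exhaustive
strategy scans every cell exactly this way; the full default grid is gated
behind `allow_full_exhaustive=True` (it costs tens of seconds and ~hundreds
of MB).

The default **staged** strategy stages over the eta axis only: a coarse
pass on every 10th eta value (with sigma0, u_opt, k always exhaustive via
the contraction) profiles the SSE, then full-resolution eta windows around
the best coarse candidates are searched exactly. Staging over all four
axes is deliberately avoided: the optical MTF depends on (sigma0, u_opt)
only through sigma_opt/u_opt, an exact ridge on which a coarse 2-D stage
can land far from the global optimum. Staged and exhaustive argmins agree
on the test fixtures (verified over multiple noise seeds on reduced
grids).

### Identifiability

The sigma_opt/u_opt ridge means individual optical parameters are not
identifiable from a single noisy curve: only their ratio is (recovered to
a few percent at 5% measurement noise), while sigma0 and u_opt themselves
wander along the ridge. Likewise eta trades against the scale set by k:
eta's grid step is 0.3% of a typical value while 5% noise moves the
fitted scale by ~2%, so eta cannot be pinned to one grid step from seven
noisy points. Noise-free on-grid data is recovered exactly; under noise
the stable outcomes are k (within one step), the optical ratio, and the
fitted curve itself. Published per-group estimates of u_opt (27-45 cpd)
and k (3.0-4.2) across comparable groups show the same pattern. Tests
assert exactly these identifiable quantities, with bounds verified
empirically and frozen.

## Synthetic data generator

`synthesize_dataset` emulates the published photopic CSF tables the age
curves were fitted to: frequencies on the 0.5-22 cpd ladder
{0.5, 1, 2, 4, 8, 16, 22}, photopic luminances (the bundled fixtures use
100 cd/m^2 with a 5.5 deg binocular field and 60 cd/m^2 with a 7 deg
monocular field), adult age-group means, one sensitivity per frequency.
Noise is multiplicative lognormal with mean exactly 1 and CV 5% by default
(thresholds are ratio-scale; sensitivities stay positive). It does **not**
emulate between-observer variance structure, frequency-correlated errors,
staircase/forced-choice quantisation, or optical pathologies — so passing
recovery tests show the estimator is correct for the stated noise model,
not that real data constrain the parameters more tightly.

## Numerical choices

* `CSF(0) = 0` is produced by zeroing the expression where `M_lat = 0`
  (the neural noise diverges there); high-frequency decay to 0 follows
  from the Gaussian optical MTF.
* Grid axes are generated as `lo + step*arange(n)` with `n` from a
  floor with 1e-9 slack, so the printed endpoints are exact.
* The SSE expansion's cancellation error (~1e-9 absolute at sensitivities
  of order 10^3) is orders of magnitude below the SSE difference between
  neighbouring grid cells; the reported RMSE is nonetheless recomputed
  through the public model at the returned optimum.
* CSV reading pins `float_precision="round_trip"` so write/read cycles
  are lossless.
* Degenerate inputs fail loudly: non-positive luminances, fields,
  sensitivities or frequencies, ages below 17, pupil extrapolation to
  non-positive diameters, heterogeneous conditions within one fit.

## Limitations

* Photopic only; no mesopic/scotopic regime, rod pathway or dark
  adaptation; no binocular summation beyond the pupil field factor.
* The baseline-vs-age-model RMSE comparison machinery is validated on
  synthetic data; the historical per-dataset RMSE figures require the
  original digitized measurement tables, which are not redistributed here.
* Temporal filters `H1`/`H2` are user-supplied; with identity defaults the
  spatiotemporal model's temporal dependence reduces to `1/k*(w)`.
* Eccentricity handling of the age-independent baseline uses the
  classical receptive-field bracket, not the age-dependent density model.
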