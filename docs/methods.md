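# Methods

## The three-state activation/bleaching model

A caged fluorophore under the 515 nm activation laser is modelled with three
states — caged `N_i`, fluorescent `N_f`, bleached `N_b` — and two
first-order transitions, both driven by the activation laser only:

    dN_i/dt = −k_act N_i
    dN_f/dt = +k_act N_i − k_bl N_f

Rates are expressed per activation scan ("1/frame"): the acquisition
alternates an activation scan (detector off) with a readout scan, and one
activation scan advances the kinetics by one time unit. Readout scans are
assumed not to change state populations; repeated excitation-only scanning
is observed to leave the signal unchanged, and the assumption is switchable
in the protocol simulators for sensitivity analysis. No conversion of
frame-rates to absolute 1/s rates is attempted, since it would presuppose a
dwell-time/repetition-rate model the data does not constrain.

The closed form

    N_f(t) = k_act/(k_act − k_bl) (e^(−k_bl t) − e^(−k_act t))

has a removable singularity at `k_act = k_bl`; the implementation switches
to the limit `k t e^(−kt)` when |k_act − k_bl| < 1e−9·max(k_act, k_bl). The
signal maximum sits at `t* = ln(k_act/k_bl)/(k_act − k_bl)` (`1/k` in the
degenerate case).

### Fitting and identifiability

`fit_frame_series` fits `A·N_f(t)` to per-frame mean signals by bounded
nonlinear least squares (uniform weighting by default; `1/sqrt(y)` Poisson
weighting as an option). Standard errors come from the Jacobian at the
solution. Initial values are data-driven (k_act from the early rise, k_bl
from the log-slope of the tail, A from the series maximum), and the fit is
multi-start — the data-driven guess plus several spread k_act values, best
SSE kept — because the SSE surface develops local minima when the signal
peak falls near the first or last frame.

The model is *exactly* invariant under
`(k_act, k_bl, A) → (k_bl, k_act, A·k_act/k_bl)`: the two rate labels
cannot be distinguished from a single frame series. The fitter therefore
canonicalises to `k_act ≥ k_bl`, the regime the experiments operate in
(activation several-fold faster than bleaching at working powers). Results
for data genuinely in the opposite regime would carry swapped labels; this
is a convention, not an inference.

`fit_power_law` fits `k = c·P^n` by least squares in log–log space, where
the model is exactly linear; supplied rate standard errors enter as
`1/(stderr/rate)²` weights (the variance of `log k`). This matters in
power-scan analyses: at the extremes of a 1–8 mW scan (rates spanning 64×)
a 39-frame window identifies the rate poorly, and the Jacobian standard
errors propagate exactly that information into the exponent fit.

### Pulse-duration scaling

At constant average power, an ideal n-photon rate scales with pulse
duration as `τ^−(n−1)`. `theoretical_duration_scaling` tabulates
`(τ₀/τᵢ)^(n−1)`; `relative_rate_scaling` normalises measured rates to the
shortest-pulse condition, propagating relative uncertainties in quadrature
(the reference entry is exactly 1 with zero error). `classify_process_order`
picks the candidate order minimising the summed squared log-ratio between
measured and ideal tables, ties toward the smaller order. Log-ratios are
used because the relative rates span an order of magnitude; a linear metric
would be dominated by the first column.

Report rounding follows two rules: measured relative rates print with
2 decimals at ≥ 0.2 and 3 decimals below (where two decimals would lose the
leading digits); theoretical scalings print with 2 significant figures.

## Synthetic data

`generate_filament_phantom` draws smooth random curves (random-walk heading
with Gaussian curvature increments, sub-pixel stepping, border reflection)
and deposits `labels_per_length` fluorophores per nm of arc length into the
nearest pixel; the summed arc length is retained so the deposited mass is
checkable exactly. This emulates the geometry and line-density character of
immunostained microtubules, not their diffraction-limited image: no PSF
blurring is applied at this stage (optical confinement lives in the optics
and protocol layers), so tests passing on phantoms say nothing about
resolution-limited real images. `generate_volume_sample` provides 3D
filament tangles or 1-voxel-thick spherical shells (nuclear-envelope-like)
with all state mass caged.

`simulate_activation_series` evolves every pixel's state populations by one
frame unit per activation scan and draws readout frames as Poisson counts
with mean `photons_per_fluorophore · density · N_f(t) + background`. Shot
noise is the only noise source: detection is photon-counting, and dark
counts are folded into the constant expected background (magnitude a free
parameter — the reference measurements only establish that the
pre-activation signal is negligible). Pixels are independent; fixed-cell
samples justify the absence of diffusion. Defaults follow the
characterisation protocol: 100 µs activation dwell, 30 µs readout dwell,
8 mW excitation, 39 activation/readout cycles, working activation power
4 mW.

Randomness: one integer seed; each stage derives an independent substream
from `SeedSequence([seed, crc32(stage_name)])`, so adding stages never
perturbs existing streams and identical configurations are bit-reproducible.

## Beam model and sectioning

The activation beam is a scalar paraxial Gaussian beam: on-axis intensity
`I(z) = 1/(1 + ((z − Δz)/z_R)²)` with Rayleigh range `z_R` and chromatic
focal offset `Δz`. For a full-plane scan, the lateral integral of `I` is
z-independent (order 1: every plane in the column receives the same dose),
while the lateral integral of `I²` carries the Lorentzian (order 2:
plane dose FWHM = `2 z_R`). High-NA vectorial corrections are out of scope;
the sectioning argument is driven by the order of the nonlinearity, and
`z_R` stays a calibratable parameter. The value `z_R = 350 nm` used in the
drivers is an assumption standing in for a diffraction-limited visible
focus, not a measured quantity; UV-beam aberrations are representable only
as a chromatic offset plus an optionally inflated `z_R`.

`sectioning_fwhm` interpolates half-maximum crossings linearly and raises
an explicit no-sectioning error on flat (order-1) profiles rather than
returning a number. `two_layer_experiment` accumulates the plane dose of
the beam refocused at each target depth and counts resolvable layers as
local maxima exceeding twice the minimum between adjacent peaks — an
invented, deliberately simple criterion standing in for qualitative
distinguishability; layer separations below one sectioning FWHM attach a
warning. Scattering and depth-dependent attenuation in tissue are ignored.

## Protocol simulators

STED imaging is abstracted to a per-scan `bleach_fraction` applied to
*active* fluorophores, weighted by an axial crosstalk profile (default: the
order-2 Lorentzian dose evaluated at layer offsets). Caged fluorophores are
inert to imaging light — that is the entire protection mechanism, and the
reason the simulators track per-voxel state fractions exactly (they sum to
1 to 1e−12 at every step). A per-molecule binomial Monte-Carlo mode
cross-checks the deterministic expectations.

In the protection experiment the two-photon activation kernel is confined
to the targeted layer: at the 600 nm layer spacing used (≈ one sectioning
FWHM) the activated slab does not reach the neighbouring layers, and the
protected layer above must stay exactly caged — which is what the
experiment demonstrates. The raw Lorentzian at 600 nm would still carry
~25% relative dose; a soft kernel is available for sensitivity analysis,
but the confined kernel is the model of the observed behaviour (the
unactivated layer recovers full fluorescence). One-photon activation
deposits dose along the whole column, activating every layer at once.

The frame-based vs pixel-based comparison uses a row-major raster with
uniform pixel time; a pixel at raster phase `t_i` is activated in one pass
and read in the next, so its activation-to-readout delay is one frame
period minus its phase, and its signal is attenuated by
`exp(−fade_rate·delay)`. Pixel-based activation reads each pixel
immediately (zero delay). The gain of pixel-based activation is then
`N / Σ exp(−fade_rate·delay_i)` — 1 for a stable dye, monotone in the fade
rate, e.g. 3 when the raster-averaged attenuation is 1/3. No timing
diagram for the real controller is modelled beyond this.

## Image measurements

"Above noise level" is formalised as `mean + k·std` of the pre-activation
reference frame with default `k = 3` (the threshold definition is a
convention; the reference only pins down that pre-activation signal is
negligible). The mask is recomputed per frame by default; a fixed-mask mode
exists because per-frame masking preferentially selects bright pixels at
low signal and can bias mean-signal curves. An empty mask returns a flagged
no-signal result, never a silent zero.

FWHM estimation fits a Gaussian (optionally Lorentzian) peak plus constant
background, robust at realistic sampling; raw half-crossing interpolation
is available as a cross-check. Profiles with no peak above
background + 3·noise raise an explicit no-peak error. SBR is
`(peak − background)/background` with the background taken as the median of
the profile's outer fifths, ε-regularised and flagged near zero.

## Problem sizes and numerical choices

The shipped drivers and checks use 96×96 phantoms, 39-cycle series, seven
powers (1–8 mW) with `k_act = P²/32` per frame (0.5/frame at the 4 mW
working power, bleaching 5-fold slower with exponent 1.54), 50-replicate
recovery studies with per-frame means over 256-pixel uniform regions at
per-pixel amplitude 500, 1 nm axial grids for FWHM measurements, and 1e5
molecules for Monte-Carlo cross-checks. These sizes make every quantity
statistically stable at the tolerances asserted while keeping full runs in
tens of seconds. Fit tolerances are scipy `curve_fit` defaults; bounded
restarts guard against non-convergence, and a fit that still fails raises a
diagnostic-carrying error rather than returning garbage.

## Known limitations

* No photophysical micro-mechanism: intermediate/triplet states, multistep
  absorption, and mixed-order bleaching are not modelled; the bleaching
  power exponent is simply fitted with the same power-law machinery.
* The beam model is paraxial and scalar; STED depletion physics is reduced
  to (bleach fraction, crosstalk profile).
* Phantoms are unblurred label densities; conclusions about resolution on
  real, PSF-limited images are outside what the tests establish.
* Spontaneous (thermal) uncaging, buffer chemistry and sample ageing are
  not modelled beyond an optional constant-rate hook.
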