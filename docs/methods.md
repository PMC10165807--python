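# Methods

This note records the models the package implements, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the underlying analysis
left details open.

## System and observables

The system is a quasi-2D microtubule network driven by light-dimerizing
kinesin clusters. Under illumination the clusters cross-link and slide
filaments, producing extensile active stress; in the dark the clusters
disassemble and the network behaves as a passive elastic solid held
together by depletion. The pipeline works entirely from fluorescence
time-lapse images plus the illumination schedule (on/off intervals,
intensity, activated region geometry). All analysis treats the system
as two-dimensional in the image plane; out-of-plane motion is ignored.

Three scalar observables summarize the dynamics:

- ⟨|v|⟩(t), the mean PIV speed, for photoswitching kinetics;
- ⟨θ⟩(t), the mean absolute nematic deviation of the filament
  orientation from the initial alignment, for the bend instability;
- γ_xx(t), γ_yy(t), region-averaged cumulative normal strains, for
  regime classification and threshold detection.

## Kinetics models

Activation follows a bounded exponential, v(t) = v_max(1 − e^(−t/τ_on)),
fitted by nonlinear least squares jointly over (v_max, τ_on),
initialized at max(v) and (time to half-max)/ln 2. A fixed-v_max mode
exists; the joint fit is the default. A constant trace is returned as a
degenerate fit with τ_on at its zero bound rather than an error.

Deactivation is fitted on the trace normalized by the mean of the last
three on-state points before the transition, with the decaying logistic
v̂(t) = 2/(1 + e^(+t/τ_off)), which satisfies v̂(0) = 1 and decays to 0.
The source analysis prints this logistic with the opposite sign in the
exponent, which grows from 1 to 2 and cannot describe a decay; the
decaying sign is used here and treated as the intended form.

Per-cycle plateau and dark speeds are medians over the last half of each
on/off interval (medians for robustness to PIV spikes); the dark-speed
trend is an ordinary regression over cycle start times and is undefined
(None) with a single cycle. The intensity–speed response reports the
mean ± s.e. per tested intensity and defines the saturation intensity
as the smallest intensity reaching 95% of the sweep maximum — the
saturation fraction is exposed because the underlying observation is
descriptive, not rule-based.

## Orientation and the bend relaxation

The orientation field comes from the structure tensor: Gaussian
derivative gradients (σ_grad = 1.5 px), tensor components smoothed with
σ_window = 5 px, filament angle = dominant gradient direction rotated a
quarter turn, coherence = eigenvalue contrast (λ₁−λ₂)/(λ₁+λ₂). Pixels
below a coherence threshold (default 0.3) are excluded from ⟨θ⟩; the
deviation is the mean of |θ − θ₀| after nematic wrapping to
[−π/2, π/2). The absolute value is used because bend is sign-symmetric,
making ⟨θ⟩ a nonnegative deviation magnitude. A signed mean would
average antisymmetric bend lobes to zero.

During activation ⟨θ⟩ grows linearly at γ̇ (ordinary least-squares
slope). When measuring γ̇ on rendered image sequences, the fit window
starts after the bend amplitude clears the texture's intrinsic
orientation spread (the |·| statistic has a floor of order the angular
texture dispersion, ~0.08 rad for the default generator texture, which
flattens the early trace).

After deactivation,

    ⟨θ⟩(t) = e^(−t/τ) · γ̇ t + C · e^(−t/r),

where the first factor models exponential unbinding of the optogenetic
clusters (damping the residual activity-driven growth) and the second
the elastic relaxation of the passive network. γ̇ is fixed to its
independently measured value; (τ, r, C) are fitted with initialization
τ = 24 s (the literature photodissociation time of the optogenetic
domain), r = 20 s, C = the trace value at deactivation. C is refit per
interval — continuity with the angle at deactivation is used only as
the initial guess. With γ̇ = 0 the τ term vanishes identically, so only
(r, C) are fitted and τ is reported unidentifiable; when the fitted
τ–r covariance correlation exceeds 0.99 the result carries an
identifiability warning.

## PIV

Single-pass windowed cross-correlation (default 32 px windows, 16 px
overlap, chosen for textures with 4–8 px correlation length): linear
(zero-padded) correlation of stationary-mean-subtracted windows, three
numerical safeguards, then a per-axis three-point Gaussian sub-pixel
fit (parabolic fallback for non-positive samples). The safeguards, each
adopted after quantifying its bias on synthetic rigid shifts:

1. the correlation is divided by the per-lag overlap area — linear
   correlation otherwise biases the peak toward zero lag by several
   percent per pixel of displacement;
2. the frame mean, not the window mean, is subtracted — window-mean
   subtraction couples the correlation tails to the lag and shrinks
   sub-pixel displacements by 1–3%;
3. the correlation plane is smoothed with a σ = 1.2 px Gaussian before
   peak finding — filamentous textures give narrow, side-lobed peaks
   whose raw three-point fit is biased by up to 15% at small sub-pixel
   displacements.

The search is capped at one third of the window (where the overlap
division would amplify edge noise), peaks without interior neighbours
for the sub-pixel fit are flagged invalid, as are flat (zero-variance)
windows. Outliers
are handled by the ε-regularized normalized-median test (3×3
neighbourhood, ε = 0.1, threshold 2) with replacement by the
neighbourhood median and a `replaced` flag. Invalid nodes are excluded
from ⟨|v|⟩ rather than zero-filled, which would bias it downward. Pair
timestamps sit at the pair midpoint. No multi-pass or window
deformation is attempted; accuracy on the synthetic benchmarks is
~0.01–0.08 px (mean over windows) for displacements up to a few pixels.

## Strain

Displacements accumulate on the fixed PIV grid (Eulerian):
u(t_k) = Σ_{j<k} v_j Δt, first snapshot zero, invalid nodes
contributing zero increments and flagged. This matches the PIV output
structure and is accurate for the small-to-moderate strains the
classifier operates on; for the >100% strains of deep buckling it is an
approximation (the gradient sum, not the Lagrangian strain). Strains
are central differences of u on the grid, averaged over the activation
region eroded by one grid node so windows straddling the mask edge are
excluded. Classification: buckling if net Δγ_yy > 0.5% over the
activation window (transverse growth is the instability signature and
takes precedence), else sliding if final γ_xx > 0.5%, else quiescent.
The depletion-contraction baseline (γ_yy drifting negative) is not
subtracted; thresholds act on the raw net change. The activation window
defaults to 17 min as a configuration value. The threshold intensity is
the smallest tested intensity whose Δγ_yy exceeds the buckling bound;
`None` is the explicit "not reached" sentinel.

## Confinement threshold

The instability bound α_eff(L, W, H) is implemented piecewise exactly as
written above, with the tie at 1/L² = 1/W² + 1/H² resolved to the
saturated branch (the branches coincide there). α_eff carries units of
µm⁻² as written; the activity coefficient a is therefore reported in
the dataset's intensity unit per µm⁻², and any conversion to a
power-based display unit is left to the caller because the published
unit convention does not reconcile dimensionally from the main-text
quantities alone. The fit I* = a·α_eff is least squares through the
origin (the model has a single parameter), inverse-variance weighted
when per-point standard errors are present; the generic comparison fit
I* = g_A/L² + g_C is plain linear least squares. Both fits describe a
noiseless square-sweep dataset closely over the measured L range, so
the generic form is a comparison, not a discriminator.

## Synthetic data generator

The generator produces every input the pipeline consumes, under the
study conditions used throughout the tests:

- **Textures**: anisotropic band-pass-filtered Gaussian random fields,
  streaks elongated 10:1 along the director at the requested
  correlation length (default 6 µm at 1 µm/px), blended with an equal-
  amplitude isotropic fine speckle. The speckle emulates intensity
  variation along bundles; without it the along-streak displacement
  component is unobservable to PIV (the aperture problem). A `speckle`
  parameter scales it; ~0.2 emulates a tightly shear-aligned network
  for orientation analyses. Explicit filament rendering was rejected as
  needless for PIV/structure-tensor testability.
- **Advection**: backward-mapping warp (cubic interpolation) of the
  time-integrated flow, applied only inside the activated region and
  only during on-episodes. Constant-strain-rate extension uses the
  exact exponential backward displacement (x−x_c)(1−e^(−rt)) so the
  Eulerian strain increment per frame is exactly r·Δt; the bend mode
  uses a triangle-wave transverse profile with uniform slope magnitude
  tan(γ̇ t_on) so the mean absolute tilt grows at exactly γ̇ (a
  sinusoidal profile compresses the mean through the arctangent at
  large amplitude); turbulence is the curl of a smoothed random stream
  function, divergence-free by construction.
- **Traces**: speed traces follow the activation/deactivation models
  piecewise with continuity at transitions; angle traces grow linearly
  while lit and follow the two-timescale decay from each deactivation
  with C set to the angle at that moment. Noiseless traces satisfy the
  models to ≤10⁻¹⁰ relative error. Noise is additive Gaussian, seeded;
  the default level in tests is 10% of the plateau (speed) and
  0.005 rad (angle), read off the visual roughness of the published
  traces since their noise statistics are not stated. Poisson shot
  noise is omitted — the PIV and structure-tensor operators are
  insensitive to the distinction at the tested SNR. Optional slow
  drifts (linear dark-speed creep, off by default) emulate sample
  ageing.
- **Threshold datasets**: I* = a·α_eff(L,W,H)(1+ε), ε ~ N(0, rel_noise),
  over caller-specified geometry sweeps.

What the generator does **not** emulate: genuinely turbulent
time-evolving flow histories, filament-scale structure and its
remodelling, photobleaching, out-of-plane motion, depletion mechanics
(only its empirical strain drift), and hysteresis. Passing tests
therefore demonstrate that the estimators recover programmed ground
truth under realistic texture statistics and noise — not that the flow
physics itself is reproduced.

## Problem sizes and determinism

Image-based checks use 192–320 px frames, 8–20 frame pairs, and 3–9
seeded replicates; these sizes were chosen as the smallest at which the
estimator noise floors sit comfortably inside the tolerances being
checked, so the suite runs in seconds. Every stochastic step takes an
explicit integer seed (numpy default_rng); re-running any generator,
test, or the acceptance script with the same seed is bit-reproducible.

## Known limitations

- Single-pass PIV without window deformation limits accuracy for
  strongly sheared windows and displacements beyond ~window/3.
- Eulerian strain accumulation underestimates Lagrangian strain at
  large deformation.
- ⟨θ⟩ as a mean absolute deviation has a noise floor set by the
  texture's orientation dispersion; growth rates should be fitted after
  the signal clears that floor.
- The τ–r decomposition of the relaxation is poorly identified when the
  two timescales coincide and γ̇ t is small relative to C; the fit
  reports this rather than hiding it.
- The quasi-2D assumption is adopted wholesale; no out-of-plane
  estimation is attempted.
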