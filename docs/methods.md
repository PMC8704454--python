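# Methods

This note documents the model implemented by `gaborlift`, the numerical
choices behind it, and what the bundled synthetic data can and cannot show.

## Model

### Receptive profiles and lifting

Each simple cell is a linear filter with complex Gabor impulse response

    Psi(dx, dy) = 1/(2 sigma^2) * exp(-i (r . (dx,dy) + phi)) * G_sigma(dx,dy),

with wave vector `r = (-f sin theta, f cos theta)` and Gaussian envelope
`G_sigma` of scale `sigma` (pixels).  Frequencies are **angular** (radians per
pixel): the carrier wavelength is `2 pi / f`, and the resolvable band on the
pixel grid ends at `f = pi`.  The exponent grouping is one fixed convention —
the phase enters as the factor `exp(-i phi)`; the opposite sign convention
would conjugate every channel and cancels in the lift/invert round trip, so
it is not configurable.

The lift evaluates, for every pixel and channel, the cross-correlation of the
(DC-removed) image with the channel window.  Channels with `f > 0` carry
essentially no DC only when `f sigma` is large enough: the DC leakage of a
Gabor is `exp(-(f sigma)^2 / 2)`, about 84% at `f sigma = 0.6` but 2% at
`f sigma = 2.8`.  The default band `[1.4, 2.6]` with `sigma = 2` keeps all
channels genuinely band-pass; this matters for completion because a zero-valued
occluder is a large DC feature, and leaky channels would encode (and then
freeze, via the Dirichlet boundary data) the occluder's darkness.  The image
mean is subtracted before lifting, stored, and restored after inversion.

### Inverse transform

The inverse sums conjugate-kernel correlations over all channels with
per-frequency weight `f / ||Psi_f||^2`.  The discrete, truncated Gabor frame
is only approximately tight, so a single scalar gain is calibrated per
(grid, sigma, N, boundary) by least squares on a stack of plane waves — one
per sampled frequency at rotating orientations.  Typical in-band round-trip
error is 3–5% relative L2.  For a single-frequency grid the inverse is not
defined (out-of-band content is lost in the lift); the readout is then the
real channel sum over orientations and phases, affinely rescaled to [0, 1].

### Geometry

The contact form `Theta = -f sin(theta) dx + f cos(theta) dy - ds` has the
horizontal frame X1..X4 in its kernel; nonzero commutators are
`[X1,X2] = sin dx - cos dy`, `[X2,X3] = -cos dx - sin dy`, `[X3,X4] = -ds`,
and `{X1..X4, [X1,X2]}` has rank 5 everywhere (bracket-generating), which is
the structural reason hypoelliptic diffusion can join any two cortical
states.  Horizontal curves integrate `c1 X1 + c2 X2 + c3 X3 + c4 X4` with
constant coefficients (RK4, default step `T/1000`); the `X1 + c2 X2` family
projects to circles of curvature `|c2|`, the association-field pattern.

### Diffusion

The diffusion operator is `L = X1^2 + b2^2 X2^2 + b3^2 X3^2 + b4^2 X4^2` with
unit-coherence coefficients `b2 = K/N^2`, `b3 = L/N^2`, `b4 = M/N^2`
(overridable).  With realistic sizes these make the orientation, frequency
and phase terms numerically small against X1X1, so the operator is dominated
by diffusion along each channel's preferred orientation — which is also why
the exact 5D mode and the per-channel SE(2) approximation
(`L~ = X1^2 + b2^2 X2^2`) produce near-identical completions.

Discretization: spatial second differences use unit offsets along the rotated
directions `e_xi = (cos, sin)`, `e_eta = (-sin, cos)`, sampled off-grid by
tensor-product B-spline interpolation (orders 1–3, default 3; replicate
spatial boundary).  The interpolation is implemented as a separable
prefilter plus a 4-tap kernel evaluation, vectorized over the feature axes,
and is cross-checked against `scipy.ndimage.map_coordinates`.  The
orientation axis wraps with period pi, the phase axis wraps, and the
frequency axis wraps by default (a `reflect` option exists because wrapping
couples the extreme scales).  `X3^2` is implemented as the consistent
expansion `D_eta_eta + 2 f D_{eta,s} + f^2 D_ss` with centered and
centered-mixed differences; a combined-offset directional stencil along the
full X3 direction serves as an independent cross-check and agrees at second
order when all stencil scales are refined together.

Time stepping is explicit Euler with `dt = 0.1` and Dirichlet restoration of
all uncorrupted responses after every step.  No formal CFL bound is enforced;
with unit spatial offsets the dominant X1X1 term is stable for `dt < 0.5`,
a NaN guard aborts with a suggestion to reduce `dt`, and the solver records
the worst amplitude amplification (a near-maximum-principle diagnostic that
stays at 1.0 in practice).  The corrupted sub-region `Pi` is every channel
above a corrupted pixel; the spatial mask is a required input.

## Synthetic data and the scaled protocol

All experiments run on generated inputs at 64x64 with the scaled grid
K=16 orientations, L=6 frequencies, M=5 phases (`Delta_s = pi/8`),
`sigma = 2`, `T = 10`, `dt = 0.1`.  These sizes keep the full protocol in the
minutes range on one CPU while preserving the structure of the full-size
setting (128x128, K=32, L=12).  The generators:

- **Chirped arcs**: concentric sinusoidal arcs about the top-left corner with
  radial frequency rising linearly (defaults 0.23 to 0.40 cycles/pixel,
  angular 1.4 to 2.5 — matched to the default filter band).  Occluding arcs
  circle the opposite corner (3 bands, width 3 by default; the figure-style
  originals do not state their occluder geometry numerically, so these are
  visual approximations).
- **Crossing bars**: unions of vertical and horizontal occluder bars.
- **Oriented gratings**: plane waves in cycles/pixel (carrier written with an
  explicit `2 pi`; the matching channel frequency is `2 pi f_cyc`), used for
  channel-selectivity and gap-completion fixtures.  The gap-anisotropy
  measurement fills the gap with the image mean so that it isolates
  directional propagation rather than occluder-edge responses.

Real texture photographs are not redistributed; multi-frequency synthetic
patterns stand in for them.  Passing tests therefore demonstrate the
propagation and reconstruction machinery on controlled band-limited content;
they do not certify performance on natural images, where receptive-field
nonlinearities (normalization, cross-orientation suppression) and broadband
spectra matter.

## Numerical choices and edge cases

- Round-trip fidelity is measured with periodic spatial convolution and
  lattice-commensurate test gratings: it isolates frame tightness from
  padding artifacts.  Completion uses reflect padding by default to avoid
  wrap-around ghosts near borders.
- A constant projection (single-frequency readout of a constant field) maps
  to mid-gray 0.5.
- Grids with L = 1 refuse `invert` and use `project`; `make_feature_grid`
  requires `f_min == f_max` in that case.
- A fully corrupted mask is rejected (no boundary data); an empty mask
  short-circuits to the identity.
- Outputs are clipped to [0, 1] after DC restoration (diffusion plus a
  truncated frame can overshoot slightly).
- Determinism: the pipeline contains no randomness; identical inputs and
  configuration give bit-identical outputs.

## Known limitations

- The occluded region's reconstruction remains amplitude-attenuated near wide
  occluders: boundary responses whose receptive fields overlap the occluder
  are themselves degraded, and they are held fixed by design.
- Frequencies above the pixel-grid Nyquist (`f >= pi`) cannot be represented;
  bands should sit well inside `(0, pi)` and satisfy `f sigma >~ 2`.
- Geodesic (length-minimizing) connectivity, concentration/motion-by-curvature
  post-processing, color images and non-square inputs are out of scope.
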