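# gaborlift

Cortically-inspired completion of occluded grayscale images.

The package models the orientation-, spatial-frequency- and phase-selective
simple cells of the primary visual cortex (V1) and uses that model to restore
missing image regions the way the visual system performs *amodal completion*:
structure visible around an occluder is propagated along model neural
connections until the occluded part is filled in.

## The model

A grayscale image `I : R^2 -> [0,1]` is lifted into a five-dimensional
cortical geometry `Q = R^2 x S^1 x R^+ x S^1` with coordinates
`(q1, q2, theta, f, phi)` by a bank of complex Gabor receptive profiles

```
Psi(dx, dy) = 1/(2 sigma^2) exp(-i (r . (dx,dy) + phi)) exp(-(dx^2+dy^2)/(2 sigma^2)),
r = (-f sin theta, f cos theta),
```

one per sampled orientation `theta_k = k pi/K`, angular frequency
`f_l in [f_min, f_max]` and reference phase `phi_m = m Delta_s`.  The channel
responses `O_I(q, z)` (the *lifted image*) are cross-correlations of the image
with each profile.

The geometry carries the contact one-form
`Theta = -f sin(theta) dx + f cos(theta) dy - ds`, whose kernel is spanned by
the horizontal frame

```
X1 = cos(theta) dx + sin(theta) dy      X3 = -sin(theta) dx + cos(theta) dy + f ds
X2 = d_theta                            X4 = d_f
```

The frame is bracket-generating (`{X1..X4, [X1,X2]}` spans the full tangent
space), so sub-Riemannian diffusion

```
du/dt = L u,   L = X1^2 + b2^2 X2^2 + b3^2 X3^2 + b4^2 X4^2,
b2 = K/N^2,  b3 = L/N^2,  b4 = M/N^2,
```

propagates known responses into the occluded sub-region `Pi` while the
responses outside `Pi` are re-imposed after every explicit Euler step
(Dirichlet data).  A per-channel SE(2) approximation `L~ = X1^2 + b2^2 X2^2`
is also provided.  Finally the evolved responses are mapped back to the image
plane by the frequency-weighted inverse Gabor transform (weight
`f / ||Psi_f||^2` per frequency, with one calibrated scalar gain), or by an
orientation/phase channel sum when only a single frequency was lifted.

## Worked example

```python
import numpy as np
from gaborlift import CompletionConfig, complete_image, evaluate_completion
from gaborlift import synth

truth = synth.chirped_arcs_image(64)            # arcs with rising frequency
mask = synth.occluding_arcs_mask(64)            # occluding arcs, ~13% of pixels
corrupted = np.where(mask, 0.0, truth)

result = complete_image(corrupted, mask, CompletionConfig(mode="exact"))
print("corrupted RMSE :", evaluate_completion(corrupted, truth, mask))
print("completed RMSE :", evaluate_completion(result, truth, mask))
```

prints

```
corrupted RMSE : 0.6087133997248081
completed RMSE : 0.3320506940502798
```

i.e. the masked-pixel root-mean-square error against the ground truth roughly
halves: the diffusion has re-extended the sinusoidal arcs through the
occluders.  The exact (5D) and approximate (per-channel SE(2)) modes give
nearly identical completions; running the same protocol with the frequency
axis collapsed to one fixed value (`single_frequency_ablation`) loses the
chirp's other scales and scores strictly worse.

Short narrative scripts for each capability live in `examples/`.  A thin CLI
is included:

```
gaborlift demo fig10 --size 64 --out demo_out
gaborlift complete --input img.png --mask mask.png --out run_out
gaborlift curves --out fan.png
```

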