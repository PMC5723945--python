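# entroseg

Joint two-phase segmentation and bias-field correction of grey-scale
images with an entropy-weighted local Gaussian fitting level set.

Microscopy and MR images are frequently corrupted by a smooth
multiplicative shading (*bias field* / intensity inhomogeneity) that
defeats global thresholding: the same tissue appears brighter on one side
of the image than the other.  `entroseg` targets the analyst who needs a
foreground/background mask *and* an estimate of that shading from a
single 2-D image, with no training data.

## Model

The observed image is modelled as `I = b·J + n`: a piecewise-constant
true image `J` (intensity `c_i` in region *i*), a smooth positive bias
field `b`, additive Gaussian noise `n`.  A level-set function φ splits
the domain into two regions via the smoothed Heaviside H_ε(φ), and the
energy scores, for every neighbourhood, the negative log-likelihood of
the intensities under per-class Gaussians with bias-modulated means
`b(x)·c_i` and variances σ_i², weighted by a truncated Gaussian kernel K
and by the **local entropy** E_r(x) ∈ [0, 1] of the intensity-mass
distribution in the radius-r window around x:

    F(φ, c, σ², b) = Σ_i λ_i ∫ E_r(x) ∫ K(x−y) [ log(√(2π)σ_i)
                     + (I(y) − b(x)c_i)²/(2σ_i²) ] M_i(φ(y)) dy dx
                     + ν·∫|∇H_ε(φ)| + μ·∫½(|∇φ| − 1)² dx

Minimization alternates closed-form updates of c_i, b and σ_i² with a
gradient-flow step on φ; the outputs are the binary mask {φ > 0}, the
estimated bias field, and the corrected image `J = I/b`.  The local
entropy weight discounts structured or degenerate neighbourhoods, which
is what makes the fit robust to noise.  Details, parameter tables and
numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a shaded, noisy disk phantom, segment it, and score the result:

```python
import numpy as np
from entroseg import make_phantom, segment, js, dsc

# 64×64 disk, fg 120 / bg 40, 30% Gaussian-bump shading, noise std 0.05·255
ph = make_phantom("disk", 64, 120, 40, bias_kind="gaussian_bump",
                  bias_amplitude=0.3, noise_level=0.05, seed=0)

res = segment(ph.observed)          # default ModelParams()

print(f"converged after {res.iterations_run} iterations")
print(f"JS  = {js(res.mask, ph.mask):.4f}")
print(f"DSC = {dsc(res.mask, ph.mask):.4f}")
be = res.bias / res.bias.mean(); bt = ph.bias / ph.bias.mean()
print(f"bias correlation = {np.corrcoef(be.ravel(), bt.ravel())[0, 1]:.4f}")
```

prints

```
converged after 133 iterations
JS  = 0.9709
DSC = 0.9852
bias correlation = 0.9975
```

i.e. the mask overlaps the ground truth at Jaccard 0.97 / Dice 0.99, and
the estimated shading field matches the true Gaussian bump at correlation
0.997 (both fields mean-normalized, since the model identifies the bias
only up to a global scale).  `res.corrected` holds the shading-corrected
image `I/b`.

The same pipeline is available from the shell:

```sh
entroseg phantom -o ph --noise-level 0.05 --seed 0
entroseg segment ph/observed.png -o out
entroseg evaluate out/mask.png ph/mask.png     # prints: mask  DSC  JS
```

`segment` writes `mask.png`, `bias.txt`, `corrected.png`,
`energy_trace.txt` and a parameter echo into the output directory.

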