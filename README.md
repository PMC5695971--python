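# qpatmi

Mutual-information-regularized model-based inversion for quantitative
photoacoustic tomography (QPAT).

## The problem

Multiwavelength photoacoustic images measure the initial acoustic pressure
`p = S Γ Φ μa`, the product of the light fluence `Φ` and the optical
absorption `μa = Σₖ αₖ(λ) cₖ` of the chromophores `cₖ` — not the
concentrations themselves.  Model-based inversion recovers the `cₖ` by
fitting a fluence model, minimizing the data error

```
ε_d(c₁…c_K) = Σₙ Σₘ [p_model(m, λₙ) − p_meas(m, λₙ)]²
```

with a gradient-based optimizer.  Any error in the fluence model (beam
geometry, scattering amplitude, domain truncation) biases the minimizer.
When two chromophores are known to be statistically independent — a
contrast agent and the background tissue, or the CuCl₂/NiCl₂ salts of a
tissue-mimicking phantom — that independence is information the fluence
model cannot corrupt.  This package implements the regularized functional

```
ε_d+MI = ε_d + γ · Ĭ(c_CuCl₂, c_NiCl₂)
```

where `Ĭ` is a kernel-density estimate of the mutual information
(Gaussian kernels, normal-reference bandwidth `h = (4/(3M))^{1/5} σ`,
trapezium-rule entropies in nats) with a fully analytic gradient, so the
whole functional can be minimized with limited-memory BFGS.  The fluence
model is a 2D diffusion approximation (5-point finite volumes, Robin
boundaries, banded Cholesky solves) with the data-error gradient computed
by the discrete adjoint method.

The package is aimed at researchers studying fluence-model robustness in
QPAT: it ships the complete numerical tissue-mimicking phantom (six
CuCl₂/NiCl₂ insertions in an ink + Intralipid background, eight
wavelengths over 750–890 nm, 10% Gaussian noise), a surrogate spectral
library, both inversion functionals, and the beam-diameter and
scattering-amplitude model-mismatch case studies.

## Worked example

Simulate the phantom, then invert with a +37.5% error in the model's
scattering amplitude, with and without the MI term:

```python
import numpy as np
from qpatmi import (InversionConfig, NoiseModel, PhantomSpec, SourceModel,
                    build_numerical_phantom, invert, simulate_images,
                    surrogate_spectra)
from qpatmi.experiments_io import insertion_errors
from qpatmi.fluence_forward import DomainGrid

spec = PhantomSpec(grid=DomainGrid(40, 40, 0.125))   # 5 x 5 mm^2
phantom = build_numerical_phantom(spec)
spectra = surrogate_spectra()
source = SourceModel()                               # 3 mm 1/e beam, top edge

measured = simulate_images(phantom, spectra, source, noise=NoiseModel(0.1, seed=1))

wavelengths = measured.wavelengths
mus_true = np.stack([phantom.mus_prime(spectra, lam) for lam in wavelengths])
mus_wrong = 1.375 * mus_true   # +37.5% scattering-amplitude model error

for gamma, label in ((0.0, "eps_d"), ("auto", "eps_d+MI")):
    config = InversionConfig(total_iterations=300, mi_activation=150, gamma=gamma)
    result = invert(measured, spectra, source, config, mus_wrong)
    errors = insertion_errors(result, phantom)
    print(f"{label:9s} insertion error {errors['roi_error_pct']:5.2f}%  "
          f"outside {errors['outside_error_pct']:.2f}%  gamma {result.gamma_value:.2e}")
```

Output:

```
eps_d     insertion error 26.89%  outside 1.77%  gamma 0.00e+00
eps_d+MI  insertion error 21.31%  outside 1.41%  gamma 5.32e-04
```

The data-error inversion misquantifies the salt insertions by ~27% under
the scattering mismatch; adding the MI term (weight auto-scaled to 10% of
the data error when it activates at iteration 150) removes Cu/Ni
cross-talk and reduces the error to ~21%.  The numbers outside the
insertions are the mean error in percent of each salt's maximum true
concentration.

A command-line interface covers the same workflow
(`qpatmi simulate`, `qpatmi invert --mi/--no-mi`, `qpatmi mismatch`,
`qpatmi mi`); see `qpatmi --help`.

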