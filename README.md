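# irrevkin

Voxel-level kinetic quantification of irreversibly binding PET
radioligands (e.g. ¹¹C-labelled covalent enzyme inhibitors such as FAAH
tracers) from dynamic scans with an arterial input function.

At the noise level of a single high-resolution-scanner voxel, nonlinear
fits of the irreversible two-tissue compartment model (2TCMi, k4 = 0) are
impractical and the standard Patlak plot is very noisy. `irrevkin`
implements the basis-function linearization of the 2TCMi: for each decay
constant θ_j on a log-spaced grid, the model

    CT(t) = (1−VB)·(K1k3/θ)·∫Ca + (1−VB)·(K1k2/θ)·e^{−θt}⊗Ca + VB·Cb,  θ = k2+k3

is linear in φ1 = (1−VB)K1k3/θ and φ2 = (1−VB)K1k2/θ, so fitting reduces
to n small weighted least-squares solves (QR-factorized once, reused for
every voxel) plus a one-dimensional search over θ. Rate constants are
recovered as K1 = (φ1+φ2)/(1−VB), k2 = φ2θ/(φ1+φ2), k3 = φ1θ/(φ1+φ2),
and the macroparameters of interest are the net influx rate
Ki = K1k3/(k2+k3) and the flow-insensitive binding index λk3 = (K1/k2)k3.

The package bundles everything needed to validate the estimator without
access to subject data: a synthetic bolus input function and whole-blood
curve, the 22-frame acquisition schedule, the Gaussian frame-noise model
SD_i = sf·e^{λc·t̄_i}·√(C_i/Δt_i), a Monte Carlo engine with distribution
diagnostics (bias, CoV, skewness, kurtosis, error-of-the-mean), a Patlak
comparator, a weighted nonlinear reference fitter, a 4D digital phantom,
and voxelwise parametric mapping with a CLI.

## Worked example

```python
import numpy as np
from irrevkin import (
    PUTAMEN, NoiseModel, add_noise, build_basis, default_study_inputs,
    fit_bafpic_fixed_vb, fit_patlak, frame_noise_sd, macroparameters,
    model_weights, simulate_tac,
)

ca, cb, schedule = default_study_inputs()          # synthetic Ca, Cb, 22 frames
tac = simulate_tac(PUTAMEN, ca, cb, schedule)      # noise-free gray-matter TAC
sd = frame_noise_sd(NoiseModel(sf=20), tac)        # very-small-ROI noise level
noisy = add_noise(tac, sd, np.random.default_rng(1))

basis = build_basis(ca, cb, schedule, theta_min=0.06, theta_max=3.0,
                    n=50, weights=model_weights(sd))
fit = fit_bafpic_fixed_vb(noisy, basis, vb=0.05)
print(f"Ki    {fit.Ki:.4f}  (truth {macroparameters(PUTAMEN).Ki:.4f})")
print(f"K1    {fit.K1:.3f}   k2 {fit.k2:.3f}   k3 {fit.k3:.4f}")
print(f"theta {fit.theta_hat:.3f}")
print(f"Patlak Ki {fit_patlak(noisy, ca, cb).Ki:.4f}")
```

prints

```
Ki    0.0981  (truth 0.1019)
K1    0.314   k2 0.099   k3 0.0452
theta 0.144
Patlak Ki 0.0791
```

The basis-function fit lands within a few percent of the true net influx
rate on this single small-ROI-noise realization, recovering all three rate
constants; the Patlak estimate from the same noisy curve is much further
off, illustrating the variability gap that motivates the method.

The same estimator runs voxelwise:

```sh
irrevkin phantom --shape 32 32 8 --sf 100 --seed 1 --out-dir phantom/
irrevkin map --image phantom/phantom_4d.nii.gz --sidecar phantom/phantom_4d.json \
             --labels phantom/phantom_labels.nii.gz --out-dir maps/
```

which writes Ki, λk3, K1, k2, k3, θ̂, WRSS and fit-flag maps plus a
per-region summary CSV. `irrevkin mc` runs scenario grids (noise levels,
θ ranges, basis sizes, k3 multipliers, blood-volume mismatches) to a tidy
CSV; see `irrevkin --help`.

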