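# ivimkit

Intravoxel incoherent motion (IVIM) diffusion MRI separates Brownian water
diffusion from perfusion-driven incoherent microvascular flow by sampling the
diffusion-weighted signal over a range of b-values and fitting the
biexponential model

```
S(b) / S0 = f · exp(−b·D*) + (1 − f) · exp(−b·D)
```

where *f* is the pseudo-diffusion (perfusion) signal fraction, *D* the tissue
diffusion coefficient and *D\** the pseudo-diffusion coefficient (b in
s/mm², D and D* in mm²/s). The estimation problem is notoriously
ill-conditioned, and results in the literature are hard to pool because
acquisition protocols and fitting procedures vary widely.

`ivimkit` is a toolkit for researchers who want to run (or plan) IVIM studies
along harmonised, consensus-style lines. It provides:

* the biexponential forward model, Gaussian/Rician noise generation, and
  scalar utilities (T2-corrected perfusion fraction, pseudo-diffusion
  suppression threshold b = ln 20 / D*);
* the recommended **segmented fit** — iterative weighted linear least squares
  on log-signal above the b-threshold for D and the intercept-based f,
  then a constrained nonlinear step for D* initialised at 10·D — plus a full
  4-parameter nonlinear least-squares estimator, per curve or per voxel;
* **organ presets** for brain, breast, kidney, liver, muscle and pancreas:
  nested abbreviated/minimal/advanced b-value tiers, acquisition minima,
  fat-suppression expectations and literature parameter priors, with a
  protocol compliance checker and a study-reporting checklist;
* **Cramér-Rao lower-bound design**: Fisher-information uncertainty
  prediction and an exhaustive b-value-set optimizer minimising
  σ_D/D + σ_D*/D* + σ_f averaged over a prior grid;
* a **Monte Carlo SNR planner** (bias/dispersion/total relative error versus
  SNR, minimal SNR for a target error);
* **digital phantoms** with ground-truth parameter maps, NIfTI +
  FSL `.bval`/`.bvec` I/O, ROI statistics (mean, SD, median, IQR) and a CLI.

## Worked example

Fit one kidney ROI decay curve (minimal tier, Rician noise at SNR 80,
truth f = 0.18, D = 1.7·10⁻³ mm²/s, D* = 30·10⁻³ mm²/s):

```python
import numpy as np
from ivimkit import IVIMModel, IVIMParams, NoiseSpec, add_noise, get_preset, ivim_signal

kidney = get_preset("kidney")
truth = IVIMParams(f=0.18, D=1.7e-3, Dstar=30e-3, S0=100.0)
b = np.array(kidney.minimal_b, float)          # [0, 30, 70, 100, 200, 800]
signal = add_noise(ivim_signal(truth, b), NoiseSpec("rician", snr=80, seed=7), s0=100.0)

res = IVIMModel(b, signal).fit()               # recommended segmented fit
print(res.summary())
```

```
IVIM biexponential fit
======================================================
method: segmented_fix_df    n_obs: 6    converged: True
RSS: 1.19    residual sigma: 0.7714
------------------------------------------------------
 param     estimate      std err  unit
    S0          100       0.7674  a.u.
     f      0.17326      0.01451  
     D    0.0017858     6.18e-05  mm^2/s
 Dstar     0.031344     0.005782  mm^2/s
------------------------------------------------------
D x1e-3 = 1.786, D* x1e-3 = 31.34 mm^2/s, f = 0.173
```

All three IVIM parameters are recovered close to truth; the standard errors
are Cramér-Rao predictions at the residual noise level. The same estimators
run voxelwise over 4D volumes (`fit_volume`, or `ivimkit fit` from the
shell), and `generate_phantom` builds seeded digital phantoms whose ground
truth lets you validate a whole pipeline:

```sh
ivimkit simulate-phantom --organ kidney --snr 50 --seed 1 --out phantom/
ivimkit fit --dwi phantom/phantom.nii.gz --mask phantom/phantom_mask.nii.gz \
            --organ kidney --out fitted/
ivimkit optimize-bvalues --organ kidney --out design/
ivimkit check-protocol --protocol my_protocol.yaml
```

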