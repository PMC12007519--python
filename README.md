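# mrsynth

A synthetic in-vivo ¹H magnetic-resonance-spectroscopy (MRS) data engine for
developing and benchmarking spectral processing and machine-learning tools,
with a complete treatment of out-of-voxel (OOV) "spurious echo" artifacts:
simulation, detection, model-based characterization, and subtraction.

It is aimed at MRS methods researchers who need large, parameterized,
fully-labeled training and evaluation data — every example carries the exact
ground truth of every component and sampled parameter.

## What it does

**Basis simulation** (`mrsynth.spinsim`). Metabolite responses are computed
by density-matrix simulation of the PRESS double spin echo
(90°–TE/4–180°–TE/2–180°–acquire) with ideal pulses and exact evolution under
the rotating-frame Hamiltonian

    H = Σ_k 2π ν_k I_z^k + Σ_{k<l} 2π J_kl (I_k · I_l),
    ν_k = (δ_k − 4.7 ppm) · f₀ · 10⁻⁶,

so strong-coupling effects are included. The default grid spans 18 field
strengths (1.4–3.1 T) × 15 echo times (10–80 ms) = 270 basis cells; each
per-spin basis row has 16684 complex points (300 pre-echo slots + 16384
post-echo points; spectral width 63.62 ppm centered on water at 4.7 ppm,
i.e. 8 kHz at 3 T). Spin systems larger than 8 coupled protons are split at
their weakest scalar couplings.

**Example assembly** (`mrsynth.assembly`). Each synthetic example holds four
separate complex FID components: metabolites (22, concentrations uniform
within ±2.5 SD of meta-analysis means, Voigt relaxation targeting an NAA
singlet linewidth of 3–18 Hz), a 14-singlet macromolecule background,
residual water (0–5 Voigt components, scaled 1–20× the metabolite spectrum
maximum), and complex Gaussian noise at an NAA SNR of 5–80. Frequency/phase
shifts (±0.313 ppm, ±180°, ±19.5°/ppm) are stored but not applied, so the
components can be recombined freely.

**OOV echoes** (`mrsynth.oov`, `mrsynth.oovfit`). Echoes follow the
five-parameter Gaussian model

    s(t) = a · exp(−W (t−τ)²) · exp(−iωt) · exp(−iΦ),

injected into 85 % of examples with τ ∈ 10–400 ms, W ∈ 500–8000 s⁻²
(envelope FWHM 18–74 ms), position 1–4 ppm, amplitude 0.1–20 % of the maximum
time-domain point. Ground-truth masks mark where the envelope exceeds 5 % of
its peak. A three-stage Nelder–Mead procedure recovers all five parameters —
(τ, W, a) on time-domain magnitudes, ω on frequency-domain magnitudes, then
everything including Φ on the complex residual — enabling subtraction.

**Metrics** (`mrsynth.metrics`). Dice overlap with a +1 denominator guard,
fractional OOV remaining Σ|M−E|²/Σ|E|² (reported as log₁₀), fractional
reduction in standard deviation 1 − σ(D−M)/σ(D), detection confusion counts,
and medians/IQRs over eight echo-time bins.

**Networks** (`mrsynth.networks`). Pure-NumPy encoder–decoder CNNs (batch
norm, leaky ReLU, residual connections, he-normal init, Adam) with a sigmoid
detection head trained with a Dice loss and a linear prediction head trained
with a 10×-mask-weighted MSE. CPU-only, fully deterministic, intended for
smoke-scale experiments.

## Worked example

```python
import numpy as np
from mrsynth.spinsim import AcquisitionGrid
from mrsynth.assembly import simulate_basis_set, build_example
from mrsynth.oov import inject, simulate_oov
from mrsynth.oovfit import fit_oov
from mrsynth.metrics import fractional_oov_remaining

grid = AcquisitionGrid(b0=3.0, te=0.035)          # 3 T, TE 35 ms
basis = simulate_basis_set(grid)                   # ~10 s, 24 spin systems
rng = np.random.default_rng(7)

record = build_example(grid, basis, rng)           # one labeled example
injection = inject(record, rng, p_oov=1.0)         # add one OOV echo
print(f"echo top at {injection.params.tau*1e3:.1f} ms, "
      f"{injection.params.omega_ppm:.2f} ppm")

fit = fit_oov(injection.input_fid, injection.mask, record.axis)
model = simulate_oov(fit.params, record.axis, warn=False)
frac, log10 = fractional_oov_remaining(model, injection.target_fid,
                                       injection.mask, return_log10=True)
print(f"converged={fit.converged}, log10 fractional remaining = {log10:.2f}")
```

Output:

```
echo top at 232.7 ms, 2.70 ppm
converged=True, log10 fractional remaining = -5.87
```

i.e. the fitted model removes all but ~10⁻⁶ of the injected echo energy
within its ground-truth extent — subtracting it leaves the spectrum
effectively artifact-free.

The same pipeline is available from the shell:

```bash
mrsynth simulate-basis --b0 3.0 --te 35 --out basis.npz
mrsynth build-dataset --config cfg.yaml --seed 7
mrsynth inject-oov --in shard.npz --p 0.85 --seed 3 --out shard_oov.npz
mrsynth fit-oov --in shard_oov.npz --out fits.npz --report fits.csv
mrsynth train-net --task detection --data shard_oov.npz --smoke
```

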