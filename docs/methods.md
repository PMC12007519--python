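# Methods

This note documents the models, sampling conditions, numerical choices, and
known limitations of `mrsynth`.

## Spin simulation

Each metabolite is a set of protons with chemical shifts δ_k (ppm) and scalar
couplings J_kl (Hz), evolved under the rotating-frame isotropic Hamiltonian
H = Σ_k 2π ν_k I_z^k + Σ_{k<l} 2π J_kl (I_k·I_l) with
ν_k = (δ_k − 4.7) · f₀ · 10⁻⁶ Hz and f₀ = γ̄ B₀, γ̄ = 42.5774 MHz/T. The full
isotropic coupling is kept, so strong-coupling evolution is exact; evolution
is computed by diagonalizing H once per fragment and synthesizing the signal
as a sum over single-quantum transitions (a per-row amplitude tail
contributing < 10⁻⁹ of the total is discarded).

PRESS is simulated with instantaneous pulses: 90°(x) — TE/4 — 180°(y) — TE/2
— 180°(y) — acquire, with TE1 = TE2. Acquisition starts at the last pulse,
TE/4 before the echo maximum. Rows are laid out as
`[zeros(300 − n_pre), n_pre pre-echo samples, 16384 post-echo samples]` with
n_pre = round((TE/4)/dwell). Because TE/4 is generally not an integer number
of dwell periods, the sample clock is anchored on the echo maximum: index 300
falls exactly at the echo top (phase-refocused to machine precision) and the
first acquired sample sits within half a dwell of the pulse end. The
initial state is Σ_k I_z^k (high-temperature equilibrium, unit polarization
per spin) and detection uses the per-spin operator 2i·I₊^k, so an uncoupled
proton produces a row of unit amplitude — this per-spin normalization is a
declared convention, chosen so relaxation can be applied spin by spin.

Sign convention: a resonance at δ evolves as exp(+i 2π ν t); after FFT the
ppm axis is carrier + f/(f₀·10⁻⁶). A round-trip test pins this down.

Systems larger than `max_spins` (default 8) are partitioned by connected
components of the |J| ≥ 0.2 Hz coupling graph; oversized components are cut
at the weakest link whose removal leaves valid fragment sizes. Couplings
below the cut are neglected — for the shipped table this only severs
couplings that are zero or sub-0.2 Hz (e.g. between moieties of GSH or the
nine equivalent choline methyl protons).

Default grid: B₀ ∈ {1.4, 1.5, …, 3.1} T × TE ∈ {10, 15, …, 80} ms
(270 cells); spectral width 63.62 ppm centered at 4.7 ppm (8 kHz at 3 T);
`subsample` decimates anchored on the echo so arbitrary in-vivo spectral
widths can be derived without re-simulation.

The spin-system table (`data/spin_systems.json`), concentration means/SDs,
and Lorentzian T₂ ranges are editable configuration assembled from standard
literature compilations; they are representative, not canonical.

## Example assembly

Examples are stored as four separate complex FIDs of 4096 points (subsample
factor 4, FID starting at the echo maximum; training tensors use the first
2048 points):

* **Metabolites** — 22 metabolites; concentrations uniform in mean ± 2.5 SD
  (clipped at 0) per cohort (healthy/clinical, equal probability); one GABA
  spin-system enumeration and one glucose anomer chosen with probability ½.
  Relaxation is Voigt: exp(−|t−t_echo|/T₂ − γ (t−t_echo)²) with T₂ drawn per
  metabolite from 1.5 T literature ranges (kept field-independent) and the
  Gaussian rate solved so the NAA 2.008 ppm singlet reaches a target
  linewidth drawn uniformly from 3–18 Hz.
* **Gaussian-rate jitter.** Every metabolite draws a jitter u_m uniform in
  20–100 s⁻²; metabolite m gets rate max(γ_solved + u_m − u_NAA, 0). The
  re-centering on NAA's own draw keeps the NAA linewidth exactly on target
  (the package asserts 0.2 Hz agreement) while other metabolites decay
  similarly but not identically — adding raw jitter on top of the solved
  rate would contradict the targeting.
* **Linewidth measurement.** FWHM is measured on the real (absorption) part
  of the phased, zero-filled spectrum with linearly interpolated half-maximum
  crossings, for which the closed forms FWHM_L = 1/(πT₂) and
  FWHM_G = 2√(γ ln2)/π hold exactly (the magnitude spectrum of a one-sided
  FID is ~√3 broader and would bias the targeting). The solver is Brent's
  method; an infeasible target (below the Lorentzian floor) raises.
* **Macromolecules** — 14 Voigt singlets at 0.92–4.03 ppm, positions
  jittered ±0.03 ppm, amplitudes/T₂ from an editable template (T₂ 25–50 ms,
  target linewidths 16–42 Hz via the closed-form Voigt width approximation
  f_V ≈ 0.5346 f_L + √(0.2166 f_L² + f_G²)).
* **Residual water** — k ~ uniform{0…5} Voigt components taken in template
  row order (location/phase/amplitude ranges per row; row 1 fixed amplitude
  1.00 at 4.679–4.711 ppm), Voigt rates chosen to give ~10–60 Hz lines
  (T₂ 20–100 ms, Gaussian 100–2000 s⁻²), then the composite is scaled so its
  magnitude-spectrum maximum is s × the metabolite maximum, s ~ U(1, 20).
  Magnitude (not real-part) maxima are used; k = 0 stores scale 0.
* **Noise** — i.i.d. complex Gaussian. SNR is defined as the NAA magnitude
  peak height divided by the standard deviation of the real part of the
  frequency-domain noise; with an unnormalized n-point FFT the time-domain
  per-component std is σ_t = height/(SNR·√n). Targets are uniform in 5–80.
* **Shifts** — frequency (±0.313 ppm), zero-order phase (±180°), first-order
  phase (±19.5°/ppm, pivot at the 4.7 ppm carrier, applied in the frequency
  domain) are sampled and stored per example but not applied to the stored
  components.

Every sampled value is recorded in `params`, and per-example generators are
derived from (seed, cell index, example index), so archives regenerate
byte-identically: the NPZ writer fixes zip timestamps (1980-01-01) and sorts
keys, and artifact provenance embeds only content-determining config fields.

## OOV echoes and fitting

Echo model: a·exp(−W(t−τ)²)·exp(−iωt)·exp(−iΦ) with
ω = 2π(4.7 − ppm)·f₀·10⁻⁶, matching the basis sign convention so a 2 ppm
echo overlays 2 ppm signal. Sampling: τ ~ U(10, 400) ms, W ~ U(500, 8000) s⁻²
(envelope FWHM 2√(ln2/W): 74.5 down to 18.6 ms), position U(1, 4) ppm,
Φ ~ U(0°, 360°), amplitude U(0.1 %, 20 %) of the maximum time-domain
magnitude of the combined noiseless signal (noise excluded from the
reference). Injection probability 0.85; the input is the component sum plus
echo with the stored shifts applied, normalized so max(|Re|, |Im|) = 1.
Because all three shift operations are linear, the stored target is the
shifted echo — exactly what the input contains — preserving additivity. The
ground-truth mask is |t − τ| ≤ √(ln 20 / W) (the 5 % envelope level); network
post-processing zeroes detected runs shorter than 5 samples.

Fitting is three sequential Nelder–Mead stages on a window equal to the
detected run dilated 25 % per side: (1) (τ, log W, log a) on time-domain
magnitudes; (2) ω on windowed frequency-domain magnitudes, seeded by a
121-point scan of the 1–4 ppm band and kept in band by a sine
reparameterization (this avoids aliased minima and makes the
carrier-initialized start irrelevant); (3) all five parameters on the complex
residual, starting from the stage-1/2 values with Φ initialized by closed-form
projection Φ̂ = −arg Σ d·m̄₀. Stage 3 is accept-only: if the optimizer
returns worse than its start, the start is kept. Settings: xatol = fatol =
1e-8, ≤ 2000 iterations per stage, one restart from a perturbed simplex on
failure; log-exponents are clipped (|log a| ≤ 50, log W ∈ [−20, 30]) so
degenerate flat-envelope fits stay finite. Convergence requires optimizer
success in all stages and a final amplitude within [0, 2·max|data|].
Initialization from a mask uses τ₀ = run center, W₀ = 4 ln20/d² (inverting
the 5 % width), a₀ = std of |data| in the run.

## Metrics

* Dice = 2|pred ∧ truth| / (|pred| + |truth| + 1); the +1 keeps the empty
  case defined. This is the cardinality-sum denominator: a literal set-union
  reading would not be a Dice coefficient.
* Fractional OOV remaining = Σ|M−E|²/Σ|E|² over the ground-truth echo range,
  reported as log₁₀ floored at −12 for exact recovery; log₁₀ = 0 (M = 0) is
  the no-intervention baseline and positive values are worse than doing
  nothing.
* Fractional std reduction = 1 − σ(D−M)/σ(D) with σ the complex standard
  deviation √E|x−μ|², which treats real and imaginary parts jointly and is
  invariant under adding a constant to D and M together (a pooled
  real/imaginary concatenation would not be). The window is caller-supplied.
* Echo-time bins: {10–20, 20–40, 40–60, 60–80, 80–120, 120–200, 200–300,
  300–400} ms, half-open on the right except the last (closed at 400 ms), so
  they partition the sampling range.

### Monotone-difficulty evaluation

Fit quality declines sharply for early echoes (they truncate the left half of
the echo and are indistinguishable from broad in-voxel components). With
ground-truth masks the fits saturate near log₁₀ ≈ −5 in the three latest
bins, so at 400 examples adjacent late-bin medians are statistical ties and a
strict non-increasing comparison would flip with the seed. The test suite
therefore checks the trend in its statistically meaningful form: a one-sided
Mann–Whitney test per adjacent bin pair (no bin significantly worse than its
predecessor, α = 0.01) plus a first-to-last median drop of at least two
orders of magnitude.

## Networks

Both CNNs share a fully-convolutional encoder–decoder: a stem convolution
(2 real/imaginary channels → 16), two stride-2 encoder blocks (→ 32 → 64),
a bottleneck block with a residual add, two upsample+convolution decoder
blocks with residual connections from the encoder, and a task head — sigmoid
(1 channel) for point-wise detection, linear (2 channels) for predicting the
10×-amplified echo. All convolutions use kernel 3, batch normalization
(momentum 0.9), leaky ReLU (α = 0.1), he-normal init. Losses: 1 − Dice
(soft, with the +1 guard) for detection; MSE with weight 10 inside the
ground-truth mask for prediction. Optimizer: Adam, default learning rate
3e-4; validation is scored every `eval_every` steps (default 7200) and
weights are checkpointed only on improvement.

The implementation is pure NumPy with hand-written forward/backward passes
(verified against central finite differences in the test suite), so training
is CPU-only, deterministic given a seed, and intended for smoke-scale runs:
the shipped configuration (channels 8/16/32, batch 8, learning rate 3e-3,
150 steps on 96 easy late echoes, ~25 s on one CPU) reaches a held-out median
Dice above 0.9 after cluster thresholding. Full-scale training (millions of
parameters, tens of thousands of steps) is out of scope.

## Problem sizes

Defaults reproduce the full study conditions (270 cells × 960 examples =
259,200 planned examples); tests and the acceptance script run one cell
(3 T, TE 35 ms) with 200–400 examples, which the fitting evaluation shows is
ample for stable medians in all but the saturated late bins.

## Limitations

* Ideal pulses only: no real RF shapes, spatial localization,
  chemical-shift displacement, or relaxation during pulses; PRESS only (no
  STEAM/LASER/semi-LASER/editing).
* The concentration, T₂, macromolecule, and water tables are representative
  configuration, not fitted to any single cohort.
* The OOV generative model and the fitting model coincide, so fit quality
  here is an upper bound on what identical code achieves on real data.
* Stored examples keep only the post-echo FID; pre-echo samples exist in the
  basis archives.
* The NumPy networks are for smoke-scale validation; they make no attempt to
  match GPU-scale training throughput or capacity.
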