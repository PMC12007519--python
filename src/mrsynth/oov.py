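"""Out-of-voxel (OOV) echo simulation, injection, and ground-truth masks.

An OOV ("spurious"/"ghost") echo is a gradient echo refocused at an
unintended time tau inside the acquisition window.  It is modeled as a
Gaussian-envelope complex signal

    s(t) = a * exp(-W (t - tau)^2) * exp(-i omega t) * exp(-i Phi),

with omega the angular frequency offset placing the echo at a chosen ppm
position (sign convention matching the basis simulation, so a 2 ppm echo
overlays 2 ppm metabolite signal), Phi a global phase, and the amplitude a
expressed as a fraction of the maximum time-domain point of the underlying
(noiseless) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import constants as C
from .assembly import ExampleRecord, TimeAxis, apply_frequency_phase

__all__ = [
    "OOVParams",
    "simulate_oov",
    "sample_oov_params",
    "ground_truth_mask",
    "inject",
    "Injection",
    "normalize_example",
    "cluster_threshold",
    "envelope_fwhm",
]


@dataclass(frozen=True)
class OOVParams:
    """The five OOV echo parameters."""

    tau: float  # echo-top time, s
    w: float  # Gaussian decay rate, s^-2
    omega_ppm: float  # spectral position, ppm
    phi_deg: float  # global phase, degrees
    amp: float  # absolute time-domain amplitude

    def as_dict(self) -> dict:
        return asdict(self)


def envelope_fwhm(w: float) -> float:
    """FWHM duration (s) of the Gaussian envelope exp(-w (t - tau)^2)."""
    if w <= 0:
        raise ValueError("w must be positive")
    return 2.0 * np.sqrt(np.log(2.0) / w)


def simulate_oov(params: OOVParams, axis: TimeAxis, warn: bool = True) -> np.ndarray:
    """Evaluate the OOV echo model on the example time axis.

    ``warn=False`` suppresses the truncation warning (used by fitting code
    that legitimately explores out-of-window candidates).
    """
    t = axis.times
    if warn and not (t[0] <= params.tau <= t[-1]):
        import warnings

        warnings.warn(
            f"OOV echo top tau={params.tau:.4f}s lies outside the acquisition "
            "window; the echo is truncated",
            stacklevel=2,
        )
    omega = 2.0 * np.pi * (axis.carrier_ppm - params.omega_ppm) * axis.f0 * 1e-6
    return (
        params.amp
        * np.exp(-params.w * (t - params.tau) ** 2)
        * np.exp(-1j * omega * t)
        * np.exp(-1j * np.deg2rad(params.phi_deg))
    )


def sample_oov_params(
    reference: np.ndarray,
    rng: np.random.Generator,
    tau_range=C.OOV_TAU_RANGE_S,
    w_range=C.OOV_W_RANGE,
    ppm_range=C.OOV_PPM_RANGE,
    amp_range=C.OOV_AMP_RANGE,
    phi_range=C.OOV_PHI_RANGE_DEG,
) -> OOVParams:
    """Draw the five parameters uniformly; the amplitude fraction is resolved
    against the maximum time-domain magnitude of ``reference`` (the combined
    noiseless signal)."""
    ref_max = float(np.abs(reference).max())
    if ref_max == 0.0:
        raise ValueError("amplitude reference signal is identically zero")
    return OOVParams(
        tau=rng.uniform(*tau_range),
        w=rng.uniform(*w_range),
        omega_ppm=rng.uniform(*ppm_range),
        phi_deg=rng.uniform(*phi_range),
        amp=rng.uniform(*amp_range) * ref_max,
    )


def ground_truth_mask(
    params: OOVParams, axis: TimeAxis, level: float = C.OOV_MASK_LEVEL
) -> np.ndarray:
    """Boolean mask: true where the Gaussian envelope is >= ``level`` of its
    maximum, i.e. |t - tau| <= sqrt(ln(1/level) / W), clipped to the window."""
    half = np.sqrt(np.log(1.0 / level) / params.w)
    t = axis.times
    return np.abs(t - params.tau) <= half


def normalize_example(fid: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale so the absolute maximum over real and imaginary values is 1."""
    scale = max(np.abs(fid.real).max(), np.abs(fid.imag).max())
    if scale == 0.0:
        raise ValueError("cannot normalize an identically-zero fid")
    return fid / scale, float(scale)


def cluster_threshold(mask: np.ndarray, min_run: int = C.OOV_CLUSTER_MIN_RUN) -> np.ndarray:
    """Zero every run of consecutive true points shorter than ``min_run``."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s < min_run:
            out[s:e] = False
    return out


@dataclass
class Injection:
    """One training example after (possible) OOV injection.

    ``input_fid`` is the normalized combination of all components (plus the
    echo when present) with the stored frequency/phase shifts applied;
    ``target_fid`` is the echo as it appears in the input (zeros for clean
    examples), on the same normalized scale; ``target_amplified`` is the
    10x echo used as the prediction-network target.
    """

    input_fid: np.ndarray
    target_fid: np.ndarray
    target_amplified: np.ndarray
    mask: np.ndarray
    label: bool
    scale: float
    params: OOVParams | None


def inject(
    example: ExampleRecord,
    rng: np.random.Generator,
    p_oov: float = C.OOV_INJECTION_PROBABILITY,
    apply_shifts: bool = True,
    amplification: float = 10.0,
    **sample_ranges,
) -> Injection:
    """Combine an example's components, add an OOV echo with probability
    ``p_oov``, apply the stored shifts, and normalize.

    The amplitude reference for the echo excludes the noise component.  The
    shift operations are linear, so the returned target is the shifted echo
    and input_with_echo - target equals the clean input exactly.

    ``sample_ranges`` (tau_range, w_range, ppm_range, amp_range, phi_range)
    override the default parameter sampling, e.g. to build restricted
    difficulty subsets.
    """
    axis = example.axis
    clean = example.combined(with_noise=False)
    signal = clean + example.noise_fid

    has_oov = bool(rng.uniform() < p_oov)
    if has_oov:
        params = sample_oov_params(clean, rng, **sample_ranges)
        echo = simulate_oov(params, axis)
        mask = ground_truth_mask(params, axis)
    else:
        params = None
        echo = np.zeros(axis.n_points, dtype=complex)
        mask = np.zeros(axis.n_points, dtype=bool)

    combined = signal + echo
    if apply_shifts:
        shifts = example.shifts
        combined = apply_frequency_phase(combined, shifts, axis)
        echo = apply_frequency_phase(echo, shifts, axis) if has_oov else echo
    normalized, scale = normalize_example(combined)
    target = echo / scale
    return Injection(
        input_fid=normalized,
        target_fid=target,
        target_amplified=amplification * target,
        mask=mask,
        label=has_oov,
        scale=scale,
        params=params,
    )
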