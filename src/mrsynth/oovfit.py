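"""Model-based OOV echo characterization and subtraction.

Fits the five-parameter Gaussian-echo model to a detected time window with
three sequential Nelder-Mead optimizations:

1. (tau, W, a) on the magnitude residual in the time domain — frequency and
   phase drop out of |model|;
2. omega on the magnitude residual in the frequency domain (windowed data);
3. all five parameters, including Phi, on the complex time-domain residual.

Positivity of W and a is enforced by optimizing their logarithms; omega is
kept inside the 1-4 ppm search band by a sine reparameterization.  Stage 3
starts from the stage-1/2 solution (with a closed-form phase projection), so
it can only improve the complex residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import constants as C
from .assembly import TimeAxis
from .oov import OOVParams, simulate_oov

__all__ = [
    "FitResult",
    "NoDetectionError",
    "initialize_from_mask",
    "detection_window",
    "fit_stage1",
    "fit_stage2",
    "fit_stage3",
    "fit_oov",
    "subtract",
]

_LN20 = np.log(20.0)
_PPM_LO, _PPM_HI = C.OOV_PPM_RANGE
_PPM_MID = 0.5 * (_PPM_LO + _PPM_HI)
_PPM_HALF = 0.5 * (_PPM_HI - _PPM_LO)

#: Nelder-Mead settings: parameter/function tolerance and iteration cap.
NM_OPTIONS = {"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000, "maxfev": 4000}
#: Window dilation on each side, as a fraction of the detected run length.
WINDOW_DILATION = 0.25


class NoDetectionError(ValueError):
    """Raised when a detection mask has too few points to initialize a fit."""


@dataclass
class FitResult:
    params: OOVParams
    converged: bool
    stage_losses: tuple[float, float, float]
    n_evals: tuple[int, int, int]
    window: tuple[int, int]  # [start, end) sample indices


def _ppm_to_u(ppm: float) -> float:
    x = np.clip((ppm - _PPM_MID) / _PPM_HALF, -1.0, 1.0)
    return float(np.arcsin(x))


def _u_to_ppm(u: float) -> float:
    return _PPM_MID + _PPM_HALF * np.sin(u)


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    padded = np.concatenate(([False], np.asarray(mask, bool), [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    if len(starts) == 0:
        raise NoDetectionError("empty detection mask")
    i = int(np.argmax(ends - starts))
    return int(starts[i]), int(ends[i])


def initialize_from_mask(
    data: np.ndarray, mask: np.ndarray, axis: TimeAxis, min_points: int = 5
) -> OOVParams:
    """Initial parameter values inferred from a detection mask.

    tau0 = center time of the detected run; W0 inverts the 5 % mask width
    (half-width sqrt(ln 20 / W)); a0 = std of |data| within the run; the
    frequency starts at the carrier and the phase at zero.
    """
    start, end = _longest_run(mask)
    if end - start < min_points:
        raise NoDetectionError(
            f"detected run has {end - start} points; need >= {min_points}"
        )
    t = axis.times
    tau0 = 0.5 * (t[start] + t[end - 1])
    duration = (end - start) * axis.dwell
    w0 = 4.0 * _LN20 / duration**2
    a0 = float(np.std(np.abs(data[start:end])))
    return OOVParams(tau=tau0, w=w0, omega_ppm=axis.carrier_ppm, phi_deg=0.0, amp=a0)


def detection_window(
    mask: np.ndarray, n_points: int, dilation: float = WINDOW_DILATION
) -> tuple[int, int]:
    """Detected run dilated by ``dilation`` of its length on each side."""
    start, end = _longest_run(mask)
    pad = int(round(dilation * (end - start)))
    return max(start - pad, 0), min(end + pad, n_points)


def _model(axis, tau, w, ppm, phi_deg, amp) -> np.ndarray:
    return simulate_oov(
        OOVParams(tau=tau, w=w, omega_ppm=ppm, phi_deg=phi_deg, amp=amp), axis, warn=False
    )


def _run_nm(fun, x0):
    res = minimize(fun, x0, method="Nelder-Mead", options=NM_OPTIONS)
    if not res.success:
        # one restart from a perturbed simplex
        res2 = minimize(fun, res.x * (1 + 1e-3) + 1e-6, method="Nelder-Mead", options=NM_OPTIONS)
        if res2.fun <= res.fun:
            res2.nfev += res.nfev
            return res2
    return res


def fit_stage1(data: np.ndarray, window: tuple[int, int], init: OOVParams, axis: TimeAxis):
    """Fit (tau, W, a) on the magnitude time-domain residual."""
    s, e = window
    t = axis.times[s:e]
    mag = np.abs(data[s:e])

    def loss(x):
        tau, logw, loga = x
        w = np.exp(np.clip(logw, -20.0, 30.0))
        env = np.exp(np.clip(loga, -50.0, 50.0)) * np.exp(-w * (t - tau) ** 2)
        return float(np.sum((env - mag) ** 2))

    res = _run_nm(loss, np.array([init.tau, np.log(init.w), np.log(max(init.amp, 1e-12))]))
    # clip to the loss's own exponent range so downstream logs stay finite
    tau = res.x[0]
    w = float(np.exp(np.clip(res.x[1], -20.0, 30.0)))
    amp = float(np.exp(np.clip(res.x[2], -50.0, 50.0)))
    return OOVParams(tau=tau, w=w, omega_ppm=init.omega_ppm, phi_deg=init.phi_deg, amp=amp), res


def fit_stage2(
    data: np.ndarray,
    window: tuple[int, int],
    partial: OOVParams,
    axis: TimeAxis,
    n_scan: int = 121,
):
    """Fit omega on the magnitude frequency-domain residual.

    A coarse scan over the 1-4 ppm band chooses the basin; Nelder-Mead then
    refines within it (sine-bounded), avoiding aliased minima.
    """
    s, e = window
    masked = np.zeros_like(data)
    masked[s:e] = data[s:e]
    data_spec = np.abs(np.fft.fft(masked))

    def loss_ppm(ppm):
        model = np.zeros_like(data)
        seg = _model(axis, partial.tau, partial.w, ppm, 0.0, partial.amp)
        model[s:e] = seg[s:e]
        return float(np.sum((np.abs(np.fft.fft(model)) - data_spec) ** 2))

    scan = np.linspace(_PPM_LO, _PPM_HI, n_scan)
    best = scan[int(np.argmin([loss_ppm(p) for p in scan]))]
    res = _run_nm(lambda u: loss_ppm(_u_to_ppm(u[0])), np.array([_ppm_to_u(best)]))
    ppm = _u_to_ppm(res.x[0])
    return (
        OOVParams(tau=partial.tau, w=partial.w, omega_ppm=ppm, phi_deg=partial.phi_deg, amp=partial.amp),
        res,
    )


def _project_phase(data, window, partial, axis) -> float:
    """Closed-form phase minimizing the complex residual at fixed shape."""
    s, e = window
    m0 = _model(axis, partial.tau, partial.w, partial.omega_ppm, 0.0, partial.amp)[s:e]
    corr = np.sum(data[s:e] * np.conj(m0))
    return float(np.rad2deg(-np.angle(corr))) % 360.0


def fit_stage3(data: np.ndarray, window: tuple[int, int], partial: OOVParams, axis: TimeAxis):
    """Refine all five parameters on the complex time-domain residual."""
    s, e = window
    d = data[s:e]
    t = axis.times[s:e]
    phi0 = _project_phase(data, window, partial, axis)

    def loss(x):
        tau, logw, u, phi, loga = x
        omega = 2.0 * np.pi * (axis.carrier_ppm - _u_to_ppm(u)) * axis.f0 * 1e-6
        w = np.exp(np.clip(logw, -20.0, 30.0))
        model = (
            np.exp(np.clip(loga, -50.0, 50.0))
            * np.exp(-w * (t - tau) ** 2)
            * np.exp(-1j * (omega * t + phi))
        )
        return float(np.sum(np.abs(model - d) ** 2))

    x0 = np.array(
        [
            partial.tau,
            np.log(max(partial.w, 1e-9)),
            _ppm_to_u(partial.omega_ppm),
            np.deg2rad(phi0),
            np.log(max(partial.amp, 1e-12)),
        ]
    )
    res = _run_nm(loss, x0)
    if res.fun > loss(x0):  # accept-only refinement
        res.x, res.fun = x0, loss(x0)
    tau, logw, u, phi, loga = res.x
    params = OOVParams(
        tau=float(tau),
        w=float(np.exp(np.clip(logw, -20.0, 30.0))),
        omega_ppm=float(_u_to_ppm(u)),
        phi_deg=float(np.rad2deg(phi) % 360.0),
        amp=float(np.exp(np.clip(loga, -50.0, 50.0))),
    )
    return params, res


def fit_oov(
    data: np.ndarray,
    mask: np.ndarray,
    axis: TimeAxis,
    dilation: float = WINDOW_DILATION,
) -> FitResult:
    """Run the three sequential fits from a detection mask."""
    init = initialize_from_mask(data, mask, axis)
    window = detection_window(mask, len(data), dilation)
    p1, r1 = fit_stage1(data, window, init, axis)
    p2, r2 = fit_stage2(data, window, p1, axis)
    p3, r3 = fit_stage3(data, window, p2, axis)
    converged = bool(
        r1.success and r2.success and r3.success and 0.0 <= p3.amp <= 2.0 * np.abs(data).max()
    )
    return FitResult(
        params=p3,
        converged=converged,
        stage_losses=(float(r1.fun), float(r2.fun), float(r3.fun)),
        n_evals=(int(r1.nfev), int(r2.nfev), int(r3.nfev)),
        window=window,
    )


def subtract(data: np.ndarray, params: OOVParams, axis: TimeAxis) -> np.ndarray:
    """Remove a fitted echo from the data."""
    return data - simulate_oov(params, axis)
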