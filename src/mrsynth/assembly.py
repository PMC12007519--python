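"""Assembly of synthetic MRS examples from simulated basis functions.

Each example is built as four separate complex time-domain components on a
common decimated FID axis (default 4096 points starting at the echo
maximum):

* **metabolite** — concentration-weighted sum of relaxed basis functions,
  with the Gaussian decay solved so the NAA 2.008 ppm singlet hits a target
  linewidth (3–18 Hz uniform);
* **macromolecule** — 14 Voigt singlets with jittered positions;
* **residual water** — 0–5 Voigt components scaled 1–20x the metabolite
  spectrum maximum;
* **noise** — i.i.d. complex Gaussian scaled to a target NAA SNR (5–80).

Frequency/phase shifts are sampled and stored with each example but not
applied to the components, so consumers may combine them freely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from . import constants as C
from .archive import ArchiveError, load_npz, require_keys, savez_deterministic
from .spinsim import AcquisitionGrid, BasisFunction, simulate_metabolite, spin_system_from_table

__all__ = [
    "TimeAxis",
    "ShiftParams",
    "ExampleRecord",
    "DatasetConfig",
    "InfeasibleTargetError",
    "sample_concentrations",
    "solve_gaussian_broadening",
    "gaussian_rate_for_fwhm",
    "apply_relaxation",
    "assemble_metabolite_component",
    "assemble_mm_component",
    "assemble_water_component",
    "generate_noise",
    "sample_shifts",
    "apply_frequency_phase",
    "simulate_basis_set",
    "build_example",
    "generate_dataset",
    "write_archive",
    "read_archive",
    "measure_fwhm",
]

LN2 = np.log(2.0)
NAA_SINGLET_PPM = 2.008


class InfeasibleTargetError(ValueError):
    """Target linewidth narrower than the Lorentzian component allows."""


@dataclass(frozen=True)
class TimeAxis:
    """Uniform complex-FID time axis of an assembled example."""

    b0: float
    dwell: float
    n_points: int
    carrier_ppm: float = 4.7

    @property
    def f0(self) -> float:
        return C.GAMMA_BAR_MHZ_PER_T * 1e6 * self.b0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell

    def offset_hz(self, ppm: float) -> float:
        return (ppm - self.carrier_ppm) * self.f0 * 1e-6

    def ppm_axis(self) -> np.ndarray:
        """ppm value of each FFT bin (fftshift order)."""
        f = np.fft.fftshift(np.fft.fftfreq(self.n_points, self.dwell))
        return self.carrier_ppm + f / (self.f0 * 1e-6)

    @classmethod
    def from_grid(cls, grid: AcquisitionGrid, factor: int, n_points: int) -> "TimeAxis":
        return cls(
            b0=grid.b0,
            dwell=grid.dwell * factor,
            n_points=n_points,
            carrier_ppm=grid.carrier_ppm,
        )


@dataclass(frozen=True)
class ShiftParams:
    """Frequency / zero-order / first-order phase shifts stored per example."""

    df_ppm: float
    ph0_deg: float
    ph1_deg_per_ppm: float


@dataclass
class ExampleRecord:
    """One synthetic example: separate component FIDs plus all sampled
    parameters (sufficient to regenerate the example from its seed)."""

    metab_fid: np.ndarray
    mm_fid: np.ndarray
    water_fid: np.ndarray
    noise_fid: np.ndarray
    params: dict
    b0: float
    te: float
    dwell: float
    carrier_ppm: float = 4.7

    @property
    def axis(self) -> TimeAxis:
        return TimeAxis(
            b0=self.b0,
            dwell=self.dwell,
            n_points=len(self.metab_fid),
            carrier_ppm=self.carrier_ppm,
        )

    @property
    def shifts(self) -> ShiftParams:
        return ShiftParams(**self.params["shifts"])

    def combined(self, with_noise: bool = True) -> np.ndarray:
        out = self.metab_fid + self.mm_fid + self.water_fid
        if with_noise:
            out = out + self.noise_fid
        return out


# --- sampling --------------------------------------------------------------


def sample_concentrations(
    table: dict | None,
    cohort: str,
    rng: np.random.Generator,
    width_sd: float = 2.5,
) -> dict[str, float]:
    """Sample per-metabolite concentrations uniformly within
    mean +- ``width_sd`` standard deviations, clipped at zero.

    Metabolites with several basis variants (GABA spin-system enumerations,
    glucose anomers) have one variant chosen with equal probability; the
    returned map is keyed by basis name.
    """
    table = table if table is not None else C.CONCENTRATION_TABLE
    if cohort not in table:
        raise LookupError(f"unknown cohort {cohort!r}; have {sorted(table)}")
    out = {}
    for name in sorted(table[cohort]):
        mean, sd = table[cohort][name]
        value = max(rng.uniform(mean - width_sd * sd, mean + width_sd * sd), 0.0)
        variants = C.BASIS_VARIANTS.get(name)
        key = name if variants is None else variants[int(rng.integers(len(variants)))]
        out[key] = value
    return out


def sample_shifts(
    rng: np.random.Generator,
    df_range=C.FREQ_SHIFT_RANGE_PPM,
    ph0_range=C.PHASE0_RANGE_DEG,
    ph1_range=C.PHASE1_RANGE_DEG_PER_PPM,
) -> ShiftParams:
    """Draw frequency / phase shift parameters (stored, not applied)."""
    return ShiftParams(
        df_ppm=rng.uniform(*df_range),
        ph0_deg=rng.uniform(*ph0_range),
        ph1_deg_per_ppm=rng.uniform(*ph1_range),
    )


# --- lineshape -------------------------------------------------------------


def measure_fwhm(
    fid: np.ndarray, dwell: float, zero_fill: int = 8, part: str = "real"
) -> float:
    """FWHM (Hz) of the spectrum of ``fid``, by linear interpolation of the
    half-maximum crossings around the highest peak.

    ``part="real"`` (default) measures the absorption-mode linewidth of a
    phased one-sided FID — for which the Lorentzian and Gaussian closed
    forms 1/(pi*T2) and 2*sqrt(gamma*ln2)/pi hold exactly.  ``part="abs"``
    measures the magnitude spectrum instead (broader for one-sided FIDs).
    """
    n = len(fid)
    raw = np.fft.fftshift(np.fft.fft(fid, n * zero_fill))
    spec = np.real(raw) if part == "real" else np.abs(raw)
    freq = np.fft.fftshift(np.fft.fftfreq(n * zero_fill, dwell))
    i_pk = int(np.argmax(spec))
    half = spec[i_pk] / 2.0

    # walk outward to the left and right half-maximum crossings
    i = i_pk
    while i > 0 and spec[i] > half:
        i -= 1
    frac = (spec[i + 1] - half) / (spec[i + 1] - spec[i] + 1e-300)
    left = freq[i + 1] - frac * (freq[i + 1] - freq[i])
    i = i_pk
    while i < len(spec) - 1 and spec[i] > half:
        i += 1
    frac = (spec[i - 1] - half) / (spec[i - 1] - spec[i] + 1e-300)
    right = freq[i - 1] + frac * (freq[i] - freq[i - 1])
    return float(right - left)


def gaussian_fwhm_from_rate(gamma: float) -> float:
    """FWHM (Hz) of the FT of exp(-gamma*t^2)."""
    return 2.0 * np.sqrt(gamma * LN2) / np.pi


def gaussian_rate_for_fwhm(target_fwhm: float, lorentz_fwhm: float = 0.0) -> float:
    """Closed-form Gaussian decay rate (s^-2) so a Voigt line with Lorentzian
    width ``lorentz_fwhm`` reaches ``target_fwhm``, using the standard Voigt
    width approximation fV = 0.5346 fL + sqrt(0.2166 fL^2 + fG^2)."""
    rem = (target_fwhm - 0.5346 * lorentz_fwhm) ** 2 - 0.2166 * lorentz_fwhm**2
    if rem <= 0.0:
        if target_fwhm < lorentz_fwhm:
            raise InfeasibleTargetError(
                f"target {target_fwhm} Hz below Lorentzian width {lorentz_fwhm} Hz"
            )
        return 0.0
    fg = np.sqrt(rem)
    return (np.pi * fg / 2.0) ** 2 / LN2


def solve_gaussian_broadening(
    target_fwhm: float,
    lorentzian_rate: float,
    grid: AcquisitionGrid,
    naa_singlet: BasisFunction | None = None,
    tol_hz: float = 0.01,
) -> float:
    """Gaussian decay rate (s^-2) such that the NAA 2.008 ppm singlet, after
    multiplying by exp(-t/T2 - gamma*t^2) (t from the echo maximum), has a
    absorption-mode FWHM of ``target_fwhm`` Hz.

    Measured on the real part of the phased, zero-filled spectrum of the
    post-echo FID with interpolated half-maximum crossings (equivalently,
    the magnitude spectrum of the full symmetric echo); solved with Brent's
    method to ``tol_hz``.
    """
    if naa_singlet is not None:
        base = naa_singlet.rows.sum(axis=0)[naa_singlet.echo_index :]
    else:
        t = np.arange(grid.n_post) * grid.dwell
        base = np.exp(2j * np.pi * grid.offset_hz(NAA_SINGLET_PPM) * t)
    t = np.arange(len(base)) * grid.dwell
    lorentz = np.exp(-lorentzian_rate * t)

    def width(gamma: float) -> float:
        return measure_fwhm(base * lorentz * np.exp(-gamma * t**2), grid.dwell)

    w0 = width(0.0)
    if target_fwhm < w0 - tol_hz:
        raise InfeasibleTargetError(
            f"target {target_fwhm:.3f} Hz below the pure-Lorentzian width "
            f"{w0:.3f} Hz"
        )
    if abs(target_fwhm - w0) <= tol_hz:
        return 0.0
    hi = 4.0 * gaussian_rate_for_fwhm(target_fwhm) + 200.0
    while width(hi) < target_fwhm:
        hi *= 2.0
    return float(brentq(lambda g: width(g) - target_fwhm, 0.0, hi, xtol=1e-4 * hi))


def apply_relaxation(
    rows: np.ndarray,
    t2: float,
    gamma_g: float,
    echo_index: int,
    dwell: float,
    jitter_range: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Voigt decay exp(-|t - t_echo|/T2 - (gamma_g + u)(t - t_echo)^2),
    symmetric about the echo maximum; ``u`` is one uniform jitter draw from
    ``jitter_range`` (shared by all rows of the metabolite)."""
    if gamma_g < 0:
        raise ValueError("gamma_g must be non-negative")
    u = 0.0
    if jitter_range != (0.0, 0.0):
        if rng is None:
            raise ValueError("jitter_range requires an rng")
        u = rng.uniform(*jitter_range)
    rows = np.asarray(rows)
    n = rows.shape[-1]
    t = (np.arange(n) - echo_index) * dwell
    env = np.exp(-np.abs(t) / t2 - (gamma_g + u) * t**2) if np.isfinite(t2) else np.exp(
        -(gamma_g + u) * t**2
    )
    return rows * env


# --- components ------------------------------------------------------------


def simulate_basis_set(
    grid: AcquisitionGrid, names=None, table: dict | None = None
) -> dict[str, BasisFunction]:
    """Simulate basis functions for every named metabolite on ``grid``."""
    table = table if table is not None else C.load_spin_systems()
    names = list(table) if names is None else list(names)
    return {n: simulate_metabolite(spin_system_from_table(n, table), grid) for n in names}


def _canonical(name: str) -> str:
    for canon, variants in C.BASIS_VARIANTS.items():
        if name in variants:
            return canon
    return name


def assemble_metabolite_component(
    basis_set: dict[str, BasisFunction],
    concentrations: dict[str, float],
    relaxation: dict[str, tuple[float, float]],
    grid: AcquisitionGrid,
) -> np.ndarray:
    """Concentration-weighted sum of relaxed basis rows, full grid length.

    ``relaxation`` maps basis name -> (T2 seconds, total Gaussian rate).
    """
    out = np.zeros(grid.n_total, dtype=complex)
    for name, conc in concentrations.items():
        if name not in basis_set:
            raise LookupError(f"no basis function for metabolite {name!r}")
        t2, gamma = relaxation[name]
        bf = basis_set[name]
        relaxed = apply_relaxation(bf.combined(), t2, gamma, bf.echo_index, bf.dwell)
        out += conc * relaxed
    return out


def _voigt_singlet(
    axis: TimeAxis, ppm: float, amp: float, t2: float, gamma: float, phase_rad: float = 0.0
) -> np.ndarray:
    t = axis.times
    return (
        amp
        * np.exp(1j * phase_rad)
        * np.exp(2j * np.pi * axis.offset_hz(ppm) * t - t / t2 - gamma * t**2)
    )


def assemble_mm_component(
    template,
    axis: TimeAxis,
    rng: np.random.Generator,
    jitter_ppm: float = C.MM_JITTER_PPM,
) -> tuple[np.ndarray, list[dict]]:
    """Macromolecule background: one Voigt singlet per template entry with
    jittered position and sampled amplitude / T2 / target linewidth."""
    fid = np.zeros(axis.n_points, dtype=complex)
    drawn = []
    for entry in template:
        ppm = entry["ppm"] + rng.uniform(-jitter_ppm, jitter_ppm)
        amp = rng.uniform(*entry["amp"])
        t2 = rng.uniform(*entry["t2"])
        fwhm = rng.uniform(*entry["fwhm"])
        gamma = gaussian_rate_for_fwhm(fwhm, lorentz_fwhm=1.0 / (np.pi * t2))
        fid += _voigt_singlet(axis, ppm, amp, t2, gamma)
        drawn.append({"ppm": ppm, "amp": amp, "t2": t2, "fwhm": fwhm, "gamma": gamma})
    return fid, drawn


def assemble_water_component(
    template,
    metab_fid: np.ndarray,
    axis: TimeAxis,
    rng: np.random.Generator,
    scale_range=C.WATER_SCALE_RANGE,
    n_max: int = C.WATER_MAX_COMPONENTS,
) -> tuple[np.ndarray, dict]:
    """Residual water: k ~ uniform{0..n_max} Voigt components (template rows
    in order), scaled so the magnitude-spectrum maximum is s times the
    metabolite spectrum maximum, s ~ uniform(scale_range)."""
    k = int(rng.integers(0, n_max + 1))
    drawn = []
    fid = np.zeros(axis.n_points, dtype=complex)
    for row in template[:k]:
        ppm = rng.uniform(*row["ppm"])
        phase = rng.uniform(*row["phase"])
        amp = rng.uniform(*row["amp"])
        t2 = rng.uniform(*C.WATER_T2_RANGE_S)
        gamma = rng.uniform(*C.WATER_GAUSS_RANGE)
        fid += _voigt_singlet(axis, ppm, amp, t2, gamma, np.deg2rad(phase))
        drawn.append(
            {"ppm": ppm, "phase_deg": phase, "amp": amp, "t2": t2, "gamma": gamma}
        )
    if k == 0:
        return fid, {"n_components": 0, "scale": 0.0, "components": []}
    s = rng.uniform(*scale_range)
    metab_max = np.abs(np.fft.fft(metab_fid)).max()
    water_max = np.abs(np.fft.fft(fid)).max()
    fid *= s * metab_max / water_max
    return fid, {"n_components": k, "scale": s, "components": drawn}


def naa_peak_height(metab_fid: np.ndarray, axis: TimeAxis, window_ppm: float = 0.15) -> float:
    """Height of the NAA singlet in the magnitude spectrum."""
    spec = np.abs(np.fft.fftshift(np.fft.fft(metab_fid)))
    ppm = axis.ppm_axis()
    sel = np.abs(ppm - NAA_SINGLET_PPM) <= window_ppm
    return float(spec[sel].max())


def generate_noise(
    reference_fid: np.ndarray,
    snr_target: float,
    axis: TimeAxis,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Complex Gaussian noise scaled so SNR_NAA (magnitude-spectrum NAA
    height over the frequency-domain real-part noise std) equals
    ``snr_target`` in expectation.  Returns (noise fid, time-domain std)."""
    if snr_target <= 0:
        raise ValueError(f"snr_target must be positive, got {snr_target}")
    height = naa_peak_height(reference_fid, axis)
    sigma_t = height / (snr_target * np.sqrt(axis.n_points))
    noise = sigma_t * (
        rng.standard_normal(axis.n_points) + 1j * rng.standard_normal(axis.n_points)
    )
    return noise, float(sigma_t)


def apply_frequency_phase(
    fid: np.ndarray, shifts: ShiftParams, axis: TimeAxis
) -> np.ndarray:
    """Apply frequency shift, zero-order and first-order phase.

    Frequency shift multiplies by exp(+2i*pi*df_hz*t); zero-order phase by
    exp(i*ph0); first-order phase is applied in the frequency domain as
    exp(i*ph1*(ppm - carrier)) about the 4.7 ppm pivot.
    """
    df_hz = shifts.df_ppm * axis.f0 * 1e-6
    out = fid * np.exp(2j * np.pi * df_hz * axis.times) * np.exp(
        1j * np.deg2rad(shifts.ph0_deg)
    )
    if shifts.ph1_deg_per_ppm != 0.0:
        freq = np.fft.fftfreq(axis.n_points, axis.dwell)
        ppm_off = freq / (axis.f0 * 1e-6)  # ppm offset from the carrier
        ramp = np.exp(1j * np.deg2rad(shifts.ph1_deg_per_ppm) * ppm_off)
        out = np.fft.ifft(np.fft.fft(out) * ramp)
    return out


# --- example / dataset construction ---------------------------------------


@dataclass
class DatasetConfig:
    """Configuration of the synthetic dataset generator.

    Defaults reproduce the study conditions: the full 18 x 15 grid with 960
    examples per cell (259,200 total), 4096 stored points at subsample
    factor 4, cohorts mixed with equal probability.
    """

    b0_values: tuple = C.DEFAULT_B0_TESLA
    te_values: tuple = C.DEFAULT_TE_SECONDS
    examples_per_cell: int = C.DEFAULT_EXAMPLES_PER_CELL
    cohorts: tuple = ("healthy", "clinical")
    subsample_factor: int = 4
    n_points: int = 4096
    n_points_train: int = 2048
    metabolites: tuple = tuple(sorted(C.CONCENTRATION_TABLE["healthy"]))
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.b0_values) * len(self.te_values)

    @property
    def n_examples_planned(self) -> int:
        return self.n_cells * self.examples_per_cell

    def cells(self) -> list[AcquisitionGrid]:
        return [
            AcquisitionGrid(b0=b0, te=te)
            for b0 in self.b0_values
            for te in self.te_values
        ]


def build_example(
    grid: AcquisitionGrid,
    basis_cache: dict[str, BasisFunction],
    rng: np.random.Generator,
    config: DatasetConfig | None = None,
    naa_fwhm_range=C.NAA_FWHM_RANGE_HZ,
) -> ExampleRecord:
    """Sample one complete example on ``grid``.

    All randomness flows through ``rng``; the sampled parameters are stored
    in ``params`` so the example can be regenerated deterministically.
    """
    config = config if config is not None else DatasetConfig()
    cohort = config.cohorts[int(rng.integers(len(config.cohorts)))]
    conc = sample_concentrations(C.CONCENTRATION_TABLE, cohort, rng)

    t2_draws, jitters = {}, {}
    for name in sorted(conc):
        lo, hi = C.T2_TABLE[_canonical(name)]
        t2_draws[name] = rng.uniform(lo, hi)
        jitters[name] = rng.uniform(*C.GAUSSIAN_JITTER_RANGE)

    naa_key = "NAA"
    target_fwhm = rng.uniform(*naa_fwhm_range)
    gamma_solved = solve_gaussian_broadening(
        target_fwhm, 1.0 / t2_draws[naa_key], grid
    )
    # per-metabolite jitter, re-centered so NAA hits the target exactly
    relaxation = {
        name: (t2_draws[name], max(gamma_solved + jitters[name] - jitters[naa_key], 0.0))
        for name in conc
    }

    metab_full = assemble_metabolite_component(basis_cache, conc, relaxation, grid)
    factor = config.subsample_factor
    metab_fid = metab_full[grid.echo_index :: factor][: config.n_points]
    axis = TimeAxis.from_grid(grid, factor, config.n_points)

    mm_fid, mm_drawn = assemble_mm_component(C.MM_TEMPLATE, axis, rng)
    water_fid, water_drawn = assemble_water_component(
        C.WATER_TEMPLATE, metab_fid, axis, rng
    )
    snr_target = rng.uniform(*C.SNR_RANGE)
    noise_fid, sigma_t = generate_noise(metab_fid, snr_target, axis, rng)
    shifts = sample_shifts(rng)

    params = {
        "cohort": cohort,
        "concentrations": conc,
        "t2": t2_draws,
        "gaussian_jitter": jitters,
        "naa_target_fwhm_hz": target_fwhm,
        "gamma_solved": gamma_solved,
        "snr_target": snr_target,
        "noise_sigma_t": sigma_t,
        "mm": mm_drawn,
        "water": water_drawn,
        "shifts": asdict(shifts),
        "subsample_factor": factor,
    }
    return ExampleRecord(
        metab_fid=metab_fid,
        mm_fid=mm_fid,
        water_fid=water_fid,
        noise_fid=noise_fid,
        params=params,
        b0=grid.b0,
        te=grid.te,
        dwell=axis.dwell,
        carrier_ppm=grid.carrier_ppm,
    )


def example_rng(seed: int, cell_index: int, example_index: int) -> np.random.Generator:
    """Deterministic per-example generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cell_index, example_index))
    )


def generate_dataset(
    config: DatasetConfig,
    out_dir,
    basis_cache_factory=None,
    progress=None,
) -> list[str]:
    """Generate one archive shard per (B0, TE) cell; returns written paths.

    ``basis_cache_factory(grid)`` may supply precomputed basis sets; by
    default each cell's basis is simulated on the fly.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    table = C.load_spin_systems()
    basis_names = _expand_variants(config.metabolites)
    paths = []
    for ci, grid in enumerate(config.cells()):
        if basis_cache_factory is not None:
            cache = basis_cache_factory(grid)
        else:
            cache = simulate_basis_set(grid, basis_names, table)
        records = [
            build_example(grid, cache, example_rng(config.seed, ci, ei), config)
            for ei in range(config.examples_per_cell)
        ]
        path = os.path.join(
            out_dir, f"shard_b{grid.b0:.1f}_te{1000 * grid.te:.0f}.npz"
        )
        write_archive(records, path, config=config)
        paths.append(path)
        if progress is not None:
            progress(ci, grid, path)
    return paths


def _expand_variants(metabolites) -> list[str]:
    names = []
    for m in metabolites:
        names.extend(C.BASIS_VARIANTS.get(m, (m,)))
    return names


# --- archive I/O -----------------------------------------------------------

_COMPONENT_KEYS = ("metab", "mm", "water", "noise")


def write_archive(records: list[ExampleRecord], path, config: DatasetConfig | None = None) -> None:
    """Write records to a deterministic NPZ archive (lossless round-trip)."""
    arrays = {}
    if records:
        for key, attr in zip(_COMPONENT_KEYS, ("metab_fid", "mm_fid", "water_fid", "noise_fid")):
            arrays[key] = np.stack([getattr(r, attr) for r in records]).astype(complex)
        meta = {
            "b0": records[0].b0,
            "te": records[0].te,
            "dwell": records[0].dwell,
            "carrier_ppm": records[0].carrier_ppm,
            "n_examples": len(records),
        }
    else:
        for key in _COMPONENT_KEYS:
            arrays[key] = np.zeros((0, 0), dtype=complex)
        meta = {"n_examples": 0}
    if config is not None:
        meta["config"] = {
            k: v for k, v in asdict(config).items() if not isinstance(v, np.ndarray)
        }
    arrays["params"] = np.array([json.dumps(r.params) for r in records])
    arrays["meta"] = np.array(json.dumps(meta))
    savez_deterministic(path, **arrays)


def read_archive(path) -> list[ExampleRecord]:
    """Read an archive written by :func:`write_archive`."""
    data = load_npz(path)
    require_keys(data, _COMPONENT_KEYS + ("params", "meta"), context=str(path))
    meta = json.loads(str(data["meta"]))
    n = int(meta.get("n_examples", 0))
    records = []
    for i in range(n):
        params = json.loads(str(data["params"][i]))
        records.append(
            ExampleRecord(
                metab_fid=data["metab"][i],
                mm_fid=data["mm"][i],
                water_fid=data["water"][i],
                noise_fid=data["noise"][i],
                params=params,
                b0=meta["b0"],
                te=meta["te"],
                dwell=meta["dwell"],
                carrier_ppm=meta["carrier_ppm"],
            )
        )
    return records
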