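"""Ideal-pulse PRESS density-matrix simulation of coupled proton spin systems.

A spin system is a set of protons with chemical shifts (ppm) and scalar
couplings (Hz).  The PRESS double spin echo (90x - TE/4 - 180y - TE/2 - 180y -
acquire) is simulated with instantaneous pulses and exact unitary evolution
under the rotating-frame isotropic Hamiltonian

    H = sum_k 2*pi*nu_k Iz_k + sum_{k<l} 2*pi*J_kl (I_k . I_l),

with nu_k = (delta_k - carrier_ppm) * f0 * 1e-6 Hz, so strong-coupling
effects are included.  Acquisition starts immediately after the last pulse
(TE/4 before the echo maximum); each basis row holds the signal detected with
the per-spin operator 2i*I+_k, normalized to unit amplitude per proton, laid
out as [zeros, pre-echo samples, 16384 post-echo samples] with the echo
maximum at a fixed index (300 by default).

Sign convention: a spin at chemical shift delta evolves as exp(+i*2*pi*nu*t)
in the time domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DEFAULT_B0_TESLA,
    DEFAULT_TE_SECONDS,
    GAMMA_BAR_MHZ_PER_T,
    load_spin_systems,
)

__all__ = [
    "SpinSystem",
    "AcquisitionGrid",
    "BasisFunction",
    "larmor_frequency",
    "build_hamiltonian",
    "simulate_press",
    "simulate_metabolite",
    "subsample",
    "split_large_spin_system",
    "default_grid_cells",
    "spin_system_from_table",
    "SpinSystemTooLarge",
]

DEFAULT_MAX_SPINS = 8
DEFAULT_J_CUT_HZ = 0.2


def save_basis_archive(basis: dict, path) -> None:
    """Write a basis set (name -> BasisFunction, one grid) to an NPZ archive.

    Keys: one complex (n_spins x n_total) array per metabolite plus a JSON
    ``meta`` entry (b0, te, sw_ppm, carrier_ppm, dwell, echo_index,
    gamma_bar).
    """
    import json

    from .archive import savez_deterministic

    if not basis:
        raise ValueError("empty basis set")
    grids = {(bf.grid.b0, bf.grid.te) for bf in basis.values()}
    if len(grids) != 1:
        raise ValueError("all basis functions in one archive must share a grid")
    grid = next(iter(basis.values())).grid
    meta = {
        "b0": grid.b0,
        "te": grid.te,
        "sw_ppm": grid.sw_ppm,
        "carrier_ppm": grid.carrier_ppm,
        "dwell": grid.dwell,
        "echo_index": grid.echo_index,
        "gamma_bar_mhz_per_t": GAMMA_BAR_MHZ_PER_T,
        "metabolites": sorted(basis),
    }
    arrays = {f"basis/{name}": bf.rows for name, bf in basis.items()}
    arrays["meta"] = np.array(json.dumps(meta))
    savez_deterministic(path, **arrays)


def load_basis_archive(path) -> dict:
    """Read a basis archive back into name -> BasisFunction."""
    import json

    from .archive import ArchiveError, load_npz, require_keys

    data = load_npz(path)
    require_keys(data, ("meta",), context=str(path))
    meta = json.loads(str(data["meta"]))
    grid = AcquisitionGrid(
        b0=meta["b0"],
        te=meta["te"],
        sw_ppm=meta["sw_ppm"],
        carrier_ppm=meta["carrier_ppm"],
    )
    out = {}
    for name in meta["metabolites"]:
        key = f"basis/{name}"
        if key not in data:
            raise ArchiveError(f"{path} is missing required key {key!r}")
        out[name] = BasisFunction(metabolite=name, rows=data[key], grid=grid)
    return out


class SpinSystemTooLarge(ValueError):
    """Raised when a spin system exceeds the configured maximum size."""


def larmor_frequency(b0: float) -> float:
    """Proton Larmor frequency in Hz for field strength ``b0`` (tesla)."""
    if b0 < 0:
        raise ValueError(f"field strength must be non-negative, got {b0}")
    return GAMMA_BAR_MHZ_PER_T * 1e6 * b0


@dataclass(frozen=True)
class SpinSystem:
    """Chemical shifts (ppm) and scalar couplings (Hz) of one metabolite."""

    name: str
    shifts: tuple
    j: np.ndarray
    #: Original spin indices when this system is a fragment of a larger one.
    indices: tuple | None = None

    def __post_init__(self):
        shifts = tuple(float(s) for s in self.shifts)
        j = np.asarray(self.j, dtype=float)
        n = len(shifts)
        if n < 1:
            raise ValueError("spin system needs at least one spin")
        if not np.all(np.isfinite(shifts)):
            raise ValueError(f"{self.name}: non-finite chemical shift")
        if j.shape != (n, n):
            raise ValueError(f"{self.name}: J matrix must be {n}x{n}")
        if not np.allclose(j, j.T):
            raise ValueError(f"{self.name}: J matrix must be symmetric")
        if not np.allclose(np.diag(j), 0.0):
            raise ValueError(f"{self.name}: J matrix must have zero diagonal")
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "j", j)

    @property
    def n_spins(self) -> int:
        return len(self.shifts)


def spin_system_from_table(name: str, table: dict | None = None) -> SpinSystem:
    """Build a :class:`SpinSystem` from the packaged constants table."""
    table = table if table is not None else load_spin_systems()
    try:
        entry = table[name]
    except KeyError:
        raise KeyError(f"unknown metabolite {name!r}") from None
    shifts = entry["shifts"]
    n = len(shifts)
    j = np.zeros((n, n))
    for a, b, val in entry["j"]:
        j[a, b] = j[b, a] = val
    return SpinSystem(name=name, shifts=tuple(shifts), j=j)


@dataclass(frozen=True)
class AcquisitionGrid:
    """Fixed acquisition geometry for one (B0, TE) cell.

    The spectral width is expressed in ppm so the dwell time scales with
    field strength; rows are ``n_pre_slots + n_post`` points with the echo
    maximum pinned at index ``n_pre_slots``.
    """

    b0: float
    te: float
    sw_ppm: float = 63.62
    carrier_ppm: float = 4.7
    n_pre_slots: int = 300
    n_post: int = 16384

    def __post_init__(self):
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.te <= 0:
            raise ValueError(f"te must be positive, got {self.te}")
        if self.sw_ppm <= 0:
            raise ValueError("sw_ppm must be positive")
        if self.n_pre > self.n_pre_slots:
            raise ValueError(
                f"TE/4 spans {self.n_pre} dwell points but only "
                f"{self.n_pre_slots} pre-echo slots exist"
            )

    @property
    def f0(self) -> float:
        """Larmor frequency, Hz."""
        return larmor_frequency(self.b0)

    @property
    def sw_hz(self) -> float:
        return self.sw_ppm * 1e-6 * self.f0

    @property
    def dwell(self) -> float:
        """Time-domain sampling interval, seconds."""
        return 1.0 / self.sw_hz

    @property
    def n_total(self) -> int:
        return self.n_pre_slots + self.n_post

    @property
    def echo_index(self) -> int:
        return self.n_pre_slots

    @property
    def n_pre(self) -> int:
        """Number of acquired pre-echo samples (acquisition starts TE/4
        before the echo maximum)."""
        return int(round((self.te / 4.0) / self.dwell))

    def offset_hz(self, ppm: float) -> float:
        """Rotating-frame offset of a resonance at ``ppm``, Hz."""
        return (ppm - self.carrier_ppm) * self.f0 * 1e-6


@dataclass
class BasisFunction:
    """Per-spin complex time-domain basis rows for one metabolite."""

    metabolite: str
    rows: np.ndarray  # (n_spins, n_total) complex
    grid: AcquisitionGrid
    echo_index: int = field(default=None)  # type: ignore[assignment]
    dwell: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.echo_index is None:
            self.echo_index = self.grid.echo_index
        if self.dwell is None:
            self.dwell = self.grid.dwell

    @property
    def n_spins(self) -> int:
        return self.rows.shape[0]

    def combined(self) -> np.ndarray:
        """Sum of the per-spin rows."""
        return self.rows.sum(axis=0)


def default_grid_cells(
    b0_values=DEFAULT_B0_TESLA, te_values=DEFAULT_TE_SECONDS
) -> list[AcquisitionGrid]:
    """Enumerate the default B0 x TE grid (18 x 15 = 270 cells)."""
    return [AcquisitionGrid(b0=b0, te=te) for b0 in b0_values for te in te_values]


# --- product operators -----------------------------------------------------

_SIGMA_X = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SIGMA_Y = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SIGMA_Z = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
_SIGMA_P = np.array([[0, 1.0], [0, 0]], dtype=complex)
_EYE2 = np.eye(2, dtype=complex)


def _single_spin_op(op: np.ndarray, k: int, n: int) -> np.ndarray:
    """Embed a single-spin operator at position k in an n-spin space."""
    out = np.array([[1.0 + 0j]])
    for i in range(n):
        out = np.kron(out, op if i == k else _EYE2)
    return out


def _spin_ops(n: int):
    ix = [_single_spin_op(_SIGMA_X, k, n) for k in range(n)]
    iy = [_single_spin_op(_SIGMA_Y, k, n) for k in range(n)]
    iz = [_single_spin_op(_SIGMA_Z, k, n) for k in range(n)]
    ip = [_single_spin_op(_SIGMA_P, k, n) for k in range(n)]
    return ix, iy, iz, ip


def build_hamiltonian(
    system: SpinSystem,
    grid: AcquisitionGrid,
    max_spins: int = DEFAULT_MAX_SPINS,
) -> np.ndarray:
    """Rotating-frame Hamiltonian (rad/s) of ``system`` on ``grid``.

    Full isotropic coupling (Ix.Ix + Iy.Iy + Iz.Iz), so strong-coupling
    evolution is exact.
    """
    n = system.n_spins
    if n > max_spins:
        raise SpinSystemTooLarge(
            f"{system.name}: {n} spins exceeds max_spins={max_spins}; "
            "use split_large_spin_system first"
        )
    ix, iy, iz, _ = _spin_ops(n)
    h = np.zeros((2**n, 2**n), dtype=complex)
    for k in range(n):
        nu = grid.offset_hz(system.shifts[k])
        h += 2 * np.pi * nu * iz[k]
    for k in range(n):
        for l in range(k + 1, n):
            jkl = system.j[k, l]
            if jkl != 0.0:
                h += (2 * np.pi * jkl) * (
                    ix[k] @ ix[l] + iy[k] @ iy[l] + iz[k] @ iz[l]
                )
    return h


def _rotation(ops, angle: float) -> np.ndarray:
    """exp(-i*angle*sum(ops)) via Hermitian eigendecomposition."""
    gen = sum(ops)
    evals, vecs = np.linalg.eigh(gen)
    return (vecs * np.exp(-1j * angle * evals)) @ vecs.conj().T


def simulate_press(
    system: SpinSystem,
    grid: AcquisitionGrid,
    max_spins: int = DEFAULT_MAX_SPINS,
) -> BasisFunction:
    """Simulate ideal-pulse PRESS (TE1 = TE2) for one spin system.

    Returns per-spin rows of length ``grid.n_total`` with the echo maximum
    at ``grid.echo_index``; an uncoupled on-resonance proton yields a row of
    unit amplitude.
    """
    n = system.n_spins
    h = build_hamiltonian(system, grid, max_spins=max_spins)
    ix, iy, iz, ip = _spin_ops(n)

    evals, vecs = np.linalg.eigh(h)
    vdag = vecs.conj().T

    def evolve(rho: np.ndarray, t: float) -> np.ndarray:
        u = (vecs * np.exp(-1j * evals * t)) @ vdag
        return u @ rho @ u.conj().T

    rho = sum(iz)  # high-temperature equilibrium, unit polarization per spin
    u90 = _rotation(ix, np.pi / 2)
    u180 = _rotation(iy, np.pi)

    rho = u90 @ rho @ u90.conj().T
    rho = evolve(rho, grid.te / 4.0)
    rho = u180 @ rho @ u180.conj().T
    rho = evolve(rho, grid.te / 2.0)
    rho = u180 @ rho @ u180.conj().T
    # acquisition starts here, TE/4 before the echo maximum

    n_pre = grid.n_pre
    n_acq = n_pre + grid.n_post
    # Sample times anchored on the echo maximum (exactly TE/4 after the last
    # pulse) so that index echo_index refocuses exactly; n_pre rounding moves
    # the acquisition start by at most half a dwell.
    t_acq = (np.arange(n_acq) - n_pre) * grid.dwell + grid.te / 4.0

    rho_e = vdag @ rho @ vecs  # density matrix in the eigenbasis
    omega = evals[:, None] - evals[None, :]  # transition frequencies, rad/s

    # Transition amplitudes per detected spin; the exp(-i*omega*t) synthesis
    # is shared across rows, so keep the union of each row's dominant
    # transitions (discarding a < 1e-9 amplitude tail per row).
    om_flat = omega.ravel()
    amps = np.empty((n, om_flat.size), dtype=complex)
    union = np.zeros(om_flat.size, dtype=bool)
    for k in range(n):
        det = vdag @ (2j * ip[k]) @ vecs
        amp = (det.T * rho_e).ravel()
        amps[k] = amp
        order = np.argsort(np.abs(amp))[::-1]
        cum = np.cumsum(np.abs(amp[order]))
        n_keep = int(np.searchsorted(cum, (1.0 - 1e-9) * cum[-1]) + 1)
        union[order[:n_keep]] = True
    coeff = amps[:, union]
    om = om_flat[union]

    rows = np.zeros((n, grid.n_total), dtype=complex)
    start = grid.echo_index - n_pre
    chunk = 4096
    for i0 in range(0, n_acq, chunk):
        t = t_acq[i0 : i0 + chunk]
        basis = np.exp(-1j * om[:, None] * t[None, :])
        rows[:, start + i0 : start + i0 + len(t)] = coeff @ basis
    return BasisFunction(metabolite=system.name, rows=rows, grid=grid)


def split_large_spin_system(
    system: SpinSystem,
    max_spins: int = DEFAULT_MAX_SPINS,
    j_cut: float = DEFAULT_J_CUT_HZ,
) -> list[SpinSystem]:
    """Partition a spin system into weakly-connected fragments.

    Spins are grouped by |J| >= ``j_cut``; any group larger than
    ``max_spins`` is split at the weakest link whose removal yields valid
    fragment sizes (falling back to the globally weakest link).  The union
    of the returned fragments covers every spin exactly once; each fragment
    records its original spin ``indices``.
    """
    if max_spins < 2:
        raise ValueError("max_spins must be >= 2")
    n = system.n_spins
    adj = np.abs(system.j) >= j_cut

    def components(mask: np.ndarray, nodes: list[int]) -> list[list[int]]:
        seen, comps = set(), []
        for s in nodes:
            if s in seen:
                continue
            stack, comp = [s], []
            seen.add(s)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in nodes:
                    if v not in seen and mask[u, v]:
                        seen.add(v)
                        stack.append(v)
            comps.append(sorted(comp))
        return comps

    work = [sorted(c) for c in components(adj, list(range(n)))]
    done: list[list[int]] = []
    adj = adj.copy()
    while work:
        comp = work.pop()
        if len(comp) <= max_spins:
            done.append(comp)
            continue
        edges = [
            (abs(system.j[a, b]), a, b)
            for i, a in enumerate(comp)
            for b in comp[i + 1 :]
            if adj[a, b]
        ]
        edges.sort()
        choice = None
        for _, a, b in edges:
            adj[a, b] = adj[b, a] = False
            parts = components(adj, comp)
            adj[a, b] = adj[b, a] = True
            if len(parts) > 1 and all(len(p) <= max_spins for p in parts):
                choice = (a, b)
                break
        if choice is None:
            # no single cut suffices: drop the weakest link and recurse
            choice = (edges[0][1], edges[0][2])
        a, b = choice
        adj[a, b] = adj[b, a] = False
        work.extend(components(adj, comp))
    done.sort()

    out = []
    for comp in done:
        idx = np.asarray(comp)
        out.append(
            SpinSystem(
                name=system.name,
                shifts=tuple(system.shifts[i] for i in comp),
                j=system.j[np.ix_(idx, idx)],
                indices=tuple(comp),
            )
        )
    return out


def simulate_metabolite(
    system: SpinSystem,
    grid: AcquisitionGrid,
    max_spins: int = DEFAULT_MAX_SPINS,
    j_cut: float = DEFAULT_J_CUT_HZ,
) -> BasisFunction:
    """Simulate a metabolite of any size, splitting large systems first.

    Rows are returned in the original spin order of ``system``.
    """
    rows = np.zeros((system.n_spins, grid.n_total), dtype=complex)
    for frag in split_large_spin_system(system, max_spins=max_spins, j_cut=j_cut):
        bf = simulate_press(frag, grid, max_spins=max_spins)
        idx = frag.indices if frag.indices is not None else range(frag.n_spins)
        for local, orig in enumerate(idx):
            rows[orig] = bf.rows[local]
    return BasisFunction(metabolite=system.name, rows=rows, grid=grid)


def subsample(
    rows: np.ndarray, factor: int, echo_index: int
) -> tuple[np.ndarray, int]:
    """Keep every ``factor``-th point anchored at the echo maximum.

    Sampling runs forward and backward from ``echo_index`` so the echo
    maximum is always retained; the effective spectral width is divided by
    ``factor``.  Returns the decimated rows and the new echo index.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"subsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return np.array(rows, copy=True), echo_index
    rows = np.asarray(rows)
    n = rows.shape[-1]
    start = echo_index % factor
    out = rows[..., start::factor]
    return out, (echo_index - start) // factor
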