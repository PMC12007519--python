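"""Example assembly: parameter sampling, Voigt linewidth targeting,
component synthesis, shift application, and archive round-trips."""

import json

import numpy as np
import pytest

import mrsynth.constants as C
from mrsynth.archive import ArchiveError, savez_deterministic
from mrsynth.assembly import (
    DatasetConfig,
    InfeasibleTargetError,
    ShiftParams,
    TimeAxis,
    apply_frequency_phase,
    apply_relaxation,
    assemble_metabolite_component,
    assemble_mm_component,
    assemble_water_component,
    build_example,
    example_rng,
    generate_noise,
    measure_fwhm,
    read_archive,
    sample_concentrations,
    sample_shifts,
    solve_gaussian_broadening,
    write_archive,
)
from mrsynth.spinsim import BasisFunction


@pytest.fixture(scope="module")
def axis3t(grid3t):
    return TimeAxis.from_grid(grid3t, factor=4, n_points=4096)


def analytic_singlet(axis, ppm=2.008, t2=np.inf, gamma=0.0):
    t = axis.times
    decay = np.exp(-gamma * t**2) if not np.isfinite(t2) else np.exp(-t / t2 - gamma * t**2)
    return np.exp(2j * np.pi * axis.offset_hz(ppm) * t) * decay


class TestConcentrationSampling:
    def test_zero_sd_returns_mean(self, rng):
        table = {"c": {"NAA": (10.0, 0.0)}}
        assert sample_concentrations(table, "c", rng)["NAA"] == 10.0

    def test_bounds_and_clipping(self):
        table = {"c": {"X": (10.0, 2.0), "Y": (0.5, 1.0)}}
        rng = np.random.default_rng(0)
        draws = [sample_concentrations(table, "c", rng) for _ in range(5000)]
        xs = np.array([d["X"] for d in draws])
        ys = np.array([d["Y"] for d in draws])
        assert xs.min() >= 5.0 and xs.max() <= 15.0
        assert ys.min() == 0.0  # negative draws clipped
        assert ys.max() <= 3.0

    def test_determinism(self):
        a = sample_concentrations(None, "healthy", np.random.default_rng(3))
        b = sample_concentrations(None, "healthy", np.random.default_rng(3))
        assert a == b

    def test_variant_choice(self):
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(50):
            keys = set(sample_concentrations(None, "healthy", rng))
            seen |= keys & {"GABA_1", "GABA_2", "Glc_A", "Glc_B"}
        assert seen == {"GABA_1", "GABA_2", "Glc_A", "Glc_B"}

    def test_unknown_cohort(self, rng):
        with pytest.raises(LookupError, match="cohort"):
            sample_concentrations(None, "nope", rng)


class TestGaussianBroadening:
    def test_closed_form_3hz(self, grid3t):
        # FT of exp(-gamma t^2) has FWHM 2*sqrt(gamma ln2)/pi
        gamma = solve_gaussian_broadening(3.0, 0.0, grid3t)
        assert gamma == pytest.approx((np.pi * 1.5) ** 2 / np.log(2), rel=0.01)

    def test_closed_form_18hz(self, grid3t):
        gamma = solve_gaussian_broadening(18.0, 0.0, grid3t)
        assert gamma == pytest.approx((np.pi * 9.0) ** 2 / np.log(2), rel=0.01)

    def test_pure_lorentzian_boundary(self, grid3t):
        t2 = 0.3
        t = np.arange(grid3t.n_post) * grid3t.dwell
        base = analytic_singlet(TimeAxis.from_grid(grid3t, 1, grid3t.n_post), t2=t2)
        w0 = measure_fwhm(base, grid3t.dwell)
        assert solve_gaussian_broadening(w0, 1.0 / t2, grid3t) == 0.0

    def test_infeasible_target(self, grid3t):
        with pytest.raises(InfeasibleTargetError):
            solve_gaussian_broadening(1.0, 1.0 / 0.05, grid3t)  # Lorentzian ~6.4 Hz


class TestRelaxation:
    def test_identity(self, rng):
        rows = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        out = apply_relaxation(rows, np.inf, 0.0, echo_index=10, dwell=1e-4)
        assert np.array_equal(out, rows)

    def test_e_folding(self):
        rows = np.ones(4096, complex)
        dwell = 1e-4
        out = apply_relaxation(rows, 0.1, 0.0, echo_index=0, dwell=dwell)
        assert abs(out[1000]) == pytest.approx(np.exp(-1.0), rel=1e-10)

    def test_symmetric_about_echo(self):
        rows = np.ones(201, complex)
        out = apply_relaxation(rows, 0.05, 30.0, echo_index=100, dwell=1e-3)
        assert np.allclose(out[:100], out[101:][::-1])

    def test_jitter_determinism(self):
        rows = np.ones(64, complex)
        a = apply_relaxation(rows, 0.2, 10.0, 0, 1e-4, (20, 100), np.random.default_rng(5))
        b = apply_relaxation(rows, 0.2, 10.0, 0, 1e-4, (20, 100), np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestMetaboliteComponent:
    @pytest.fixture()
    def toy_basis(self, grid3t):
        rows = np.ones((2, grid3t.n_total), complex)
        return {
            "A": BasisFunction("A", rows.copy(), grid3t),
            "B": BasisFunction("B", 2 * rows.copy(), grid3t),
        }

    def test_linearity_in_concentration(self, toy_basis, grid3t):
        relax = {"A": (np.inf, 0.0)}
        one = assemble_metabolite_component(toy_basis, {"A": 1.0}, relax, grid3t)
        two = assemble_metabolite_component(toy_basis, {"A": 2.0}, relax, grid3t)
        assert np.allclose(two, 2 * one)

    def test_superposition(self, toy_basis, grid3t):
        relax = {"A": (np.inf, 0.0), "B": (np.inf, 0.0)}
        both = assemble_metabolite_component(toy_basis, {"A": 1.0, "B": 0.5}, relax, grid3t)
        a = assemble_metabolite_component(toy_basis, {"A": 1.0}, relax, grid3t)
        b = assemble_metabolite_component(toy_basis, {"B": 0.5}, relax, grid3t)
        assert np.allclose(both, a + b)

    def test_zero_concentrations(self, toy_basis, grid3t):
        relax = {"A": (np.inf, 0.0)}
        out = assemble_metabolite_component(toy_basis, {"A": 0.0}, relax, grid3t)
        assert np.all(out == 0)

    def test_missing_basis(self, toy_basis, grid3t):
        with pytest.raises(LookupError, match="NAA"):
            assemble_metabolite_component(toy_basis, {"NAA": 1.0}, {"NAA": (0.3, 0.0)}, grid3t)


class TestMMComponent:
    def test_peaks_at_nominal_positions_without_jitter(self, axis3t, rng):
        """Each of the 14 singlets lands at its listed ppm position."""
        ppm_axis = axis3t.ppm_axis()
        for entry in C.MM_TEMPLATE:
            solo = [dict(entry, amp=(1.0, 1.0))]
            fid, _ = assemble_mm_component(solo, axis3t, rng, jitter_ppm=0.0)
            spec = np.abs(np.fft.fftshift(np.fft.fft(fid)))
            peak_ppm = ppm_axis[np.argmax(spec)]
            assert peak_ppm == pytest.approx(entry["ppm"], abs=0.01)

    def test_time_zero_value_matches_total_amplitude(self, axis3t, rng):
        """At t=0 every Voigt singlet contributes exactly its amplitude."""
        template = [dict(e, amp=(1.0, 1.0)) for e in C.MM_TEMPLATE]
        fid, drawn = assemble_mm_component(template, axis3t, rng)
        assert fid[0] == pytest.approx(sum(d["amp"] for d in drawn), rel=1e-12)

    def test_jitter_bounds(self, axis3t):
        rng = np.random.default_rng(2)
        for _ in range(100):
            _, drawn = assemble_mm_component(C.MM_TEMPLATE, axis3t, rng)
            for entry, d in zip(C.MM_TEMPLATE, drawn):
                assert abs(d["ppm"] - entry["ppm"]) <= 0.03
                assert entry["amp"][0] <= d["amp"] <= entry["amp"][1]


@pytest.fixture(scope="module")
def metab_ref(axis3t):
    return analytic_singlet(axis3t, t2=0.3, gamma=50.0)


@pytest.fixture(scope="module")
def metab_ref_scaled(axis3t):
    return 5.0 * analytic_singlet(axis3t, t2=0.3, gamma=50.0)


class TestWaterComponent:

    def test_zero_components(self, metab_ref, axis3t):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            fid, info = assemble_water_component(C.WATER_TEMPLATE, metab_ref, axis3t, rng)
            if info["n_components"] == 0:
                assert np.all(fid == 0) and info["scale"] == 0.0
                return
        pytest.fail("no seed produced k = 0 within 40 tries")

    def test_single_component_location(self, metab_ref, axis3t):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            fid, info = assemble_water_component(C.WATER_TEMPLATE, metab_ref, axis3t, rng)
            if info["n_components"] == 1:
                comp = info["components"][0]
                assert 4.679 <= comp["ppm"] <= 4.711
                assert comp["amp"] == 1.0
                return
        pytest.fail("no seed produced k = 1 within 40 tries")

    def test_scaling_definition(self, metab_ref, axis3t):
        rng = np.random.default_rng(11)
        while True:
            fid, info = assemble_water_component(C.WATER_TEMPLATE, metab_ref, axis3t, rng)
            if info["n_components"] > 0:
                break
        ratio = np.abs(np.fft.fft(fid)).max() / np.abs(np.fft.fft(metab_ref)).max()
        assert ratio == pytest.approx(info["scale"], rel=1e-9)

    def test_scale_within_range(self, metab_ref, axis3t):
        rng = np.random.default_rng(13)
        for _ in range(50):
            _, info = assemble_water_component(C.WATER_TEMPLATE, metab_ref, axis3t, rng)
            if info["n_components"]:
                assert 1.0 <= info["scale"] <= 20.0


class TestNoise:
    def test_snr_definition_monte_carlo(self, metab_ref_scaled, axis3t):
        """Measured SNR over 100 realizations averages within 2% of target."""
        from mrsynth.assembly import naa_peak_height

        height = naa_peak_height(metab_ref_scaled, axis3t)
        rng = np.random.default_rng(21)
        measured = []
        for _ in range(100):
            noise, _ = generate_noise(metab_ref_scaled, 40.0, axis3t, rng)
            measured.append(height / np.std(np.real(np.fft.fft(noise))))
        assert np.mean(measured) == pytest.approx(40.0, abs=1.0)

    def test_doubling_target_halves_sigma(self, metab_ref_scaled, axis3t, rng):
        _, s1 = generate_noise(metab_ref_scaled, 20.0, axis3t, rng)
        _, s2 = generate_noise(metab_ref_scaled, 40.0, axis3t, rng)
        assert s1 == pytest.approx(2 * s2, rel=1e-12)

    def test_determinism(self, metab_ref_scaled, axis3t):
        n1, _ = generate_noise(metab_ref_scaled, 30.0, axis3t, np.random.default_rng(9))
        n2, _ = generate_noise(metab_ref_scaled, 30.0, axis3t, np.random.default_rng(9))
        assert np.array_equal(n1, n2)

    def test_invalid_target(self, metab_ref_scaled, axis3t, rng):
        with pytest.raises(ValueError):
            generate_noise(metab_ref_scaled, 0.0, axis3t, rng)


class TestShifts:
    def test_sampling_bounds(self):
        rng = np.random.default_rng(17)
        draws = [sample_shifts(rng) for _ in range(10_000)]
        df = np.array([d.df_ppm for d in draws])
        p0 = np.array([d.ph0_deg for d in draws])
        p1 = np.array([d.ph1_deg_per_ppm for d in draws])
        assert df.min() >= -0.313 and df.max() <= 0.313
        assert p0.min() >= -180 and p0.max() <= 180
        assert p1.min() >= -19.5 and p1.max() <= 19.5

    def test_zero_width_ranges(self, rng):
        s = sample_shifts(rng, df_range=(0, 0), ph0_range=(0, 0), ph1_range=(0, 0))
        assert (s.df_ppm, s.ph0_deg, s.ph1_deg_per_ppm) == (0.0, 0.0, 0.0)

    def test_identity_application(self, axis3t):
        fid = analytic_singlet(axis3t, t2=0.2)
        out = apply_frequency_phase(fid, ShiftParams(0.0, 0.0, 0.0), axis3t)
        assert np.allclose(out, fid)

    def test_phase0_180_negates(self, axis3t):
        fid = analytic_singlet(axis3t, t2=0.2)
        out = apply_frequency_phase(fid, ShiftParams(0.0, 180.0, 0.0), axis3t)
        assert np.allclose(out, -fid, atol=1e-12)

    def test_frequency_shift_moves_peak(self, axis3t):
        """0.1 ppm at 3 T moves the peak by 12.77 Hz."""
        fid = analytic_singlet(axis3t, t2=0.2, gamma=30.0)
        out = apply_frequency_phase(fid, ShiftParams(0.1, 0.0, 0.0), axis3t)
        zf = 8

        def peak(x):
            spec = np.abs(np.fft.fft(x, zf * x.size))
            return np.fft.fftfreq(zf * x.size, axis3t.dwell)[np.argmax(spec)]

        res = 1.0 / (zf * fid.size * axis3t.dwell)
        assert peak(out) - peak(fid) == pytest.approx(12.77, abs=2 * res)

    def test_shifts_are_linear(self, axis3t, rng):
        a = analytic_singlet(axis3t, ppm=2.0, t2=0.1)
        b = analytic_singlet(axis3t, ppm=3.5, t2=0.05)
        s = ShiftParams(0.2, 45.0, 10.0)
        both = apply_frequency_phase(a + b, s, axis3t)
        assert np.allclose(
            both,
            apply_frequency_phase(a, s, axis3t) + apply_frequency_phase(b, s, axis3t),
        )


class TestNAALinewidthTargeting:
    def test_fwhm_within_tolerance_across_range(self, grid3t, basis_cache):
        """Over random examples spanning 3-18 Hz targets, the measured NAA
        singlet FWHM stays within 0.2 Hz of the requested value."""
        naa = basis_cache["NAA"]
        ch3 = naa.rows[:3].sum(axis=0)
        for i in range(100):
            rng = example_rng(500, 0, i)
            target = rng.uniform(*C.NAA_FWHM_RANGE_HZ)
            t2 = rng.uniform(*C.T2_TABLE["NAA"])
            gamma = solve_gaussian_broadening(target, 1.0 / t2, grid3t)
            relaxed = apply_relaxation(ch3, t2, gamma, naa.echo_index, naa.dwell)
            measured = measure_fwhm(relaxed[naa.echo_index :], grid3t.dwell)
            assert measured == pytest.approx(target, abs=0.2)


class TestBuildExample:
    def test_components_share_length_and_dwell(self, records16):
        rec = records16[0]
        n = len(rec.metab_fid)
        assert all(
            len(getattr(rec, f)) == n
            for f in ("mm_fid", "water_fid", "noise_fid")
        )
        assert rec.dwell == pytest.approx(4 * 1.0 / (63.62e-6 * 127.7322e6))

    def test_all_sampled_parameters_within_ranges(self, records16):
        for rec in records16:
            p = rec.params
            assert 3.0 <= p["naa_target_fwhm_hz"] <= 18.0
            assert 5.0 <= p["snr_target"] <= 80.0
            s = p["shifts"]
            assert abs(s["df_ppm"]) <= 0.313
            assert abs(s["ph0_deg"]) <= 180.0
            assert abs(s["ph1_deg_per_ppm"]) <= 19.5
            for v in p["gaussian_jitter"].values():
                assert 20.0 <= v <= 100.0
            if p["water"]["n_components"]:
                assert 1.0 <= p["water"]["scale"] <= 20.0

    def test_deterministic_regeneration(self, grid3t, basis_cache):
        a = build_example(grid3t, basis_cache, example_rng(77, 0, 0))
        b = build_example(grid3t, basis_cache, example_rng(77, 0, 0))
        assert np.array_equal(a.metab_fid, b.metab_fid)
        assert np.array_equal(a.noise_fid, b.noise_fid)
        assert a.params == b.params

    def test_measured_example_naa_linewidth_hits_target(self, grid3t, basis_cache, records16):
        """The stored parameters reproduce the targeted NAA linewidth."""
        naa = basis_cache["NAA"]
        for rec in records16[:4]:
            p = rec.params
            relaxed = apply_relaxation(
                naa.rows[:3].sum(axis=0),
                p["t2"]["NAA"],
                p["gamma_solved"],
                naa.echo_index,
                naa.dwell,
            )
            measured = measure_fwhm(relaxed[naa.echo_index :], grid3t.dwell)
            assert measured == pytest.approx(p["naa_target_fwhm_hz"], abs=0.2)


class TestDatasetConfig:
    def test_default_grid_closure(self):
        cfg = DatasetConfig()
        assert cfg.n_cells == 270
        assert cfg.examples_per_cell == 960
        assert cfg.n_examples_planned == 259_200


class TestArchive:
    def test_round_trip(self, records16, tmp_path):
        path = tmp_path / "shard.npz"
        write_archive(records16[:3], path)
        loaded = read_archive(path)
        assert len(loaded) == 3
        for orig, back in zip(records16[:3], loaded):
            assert np.array_equal(orig.metab_fid, back.metab_fid)
            assert np.array_equal(orig.water_fid, back.water_fid)
            assert orig.params == back.params

    def test_byte_identical_rewrite(self, records16, tmp_path):
        p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
        write_archive(records16[:2], p1)
        write_archive(records16[:2], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_key_raises(self, records16, tmp_path):
        path = tmp_path / "broken.npz"
        savez_deterministic(
            path,
            metab=np.zeros((1, 8), complex),
            mm=np.zeros((1, 8), complex),
            noise=np.zeros((1, 8), complex),
            params=np.array([json.dumps({})]),
            meta=np.array(json.dumps({"n_examples": 1})),
        )
        with pytest.raises(ArchiveError, match="water"):
            read_archive(path)

    def test_empty_archive(self, tmp_path):
        path = tmp_path / "empty.npz"
        write_archive([], path)
        assert read_archive(path) == []
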