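import numpy as np
import pytest

import phycoexciton as px
from phycoexciton.lineshape import (LineshapeError, _tail_window,
                                    read_spectrum_csv, write_spectrum_csv)
from phycoexciton.units import KB_CM1, TWO_PI_C


def half_fourier_oracle(f_t, time_fs, stick, grid):
    """Independent direct quadrature of Re int f(t) exp(i(w - stick) t) dt."""
    out = np.empty(len(grid))
    for i, nu in enumerate(grid):
        out[i] = np.trapezoid(
            (f_t * np.exp(1j * TWO_PI_C * (nu - stick) * time_fs)).real, time_fs
        )
    return out


class TestSpectralDensity:
    def test_obo_closed_form_at_gamma(self):
        sd = px.SpectralDensity(lambda_c=100.0, gamma_c=50.0)
        assert px.evaluate_J(sd, [50.0])[0] == pytest.approx(100.0)

    def test_empty_sd_zero(self):
        sd = px.SpectralDensity(lambda_c=0.0, gamma_c=50.0)
        np.testing.assert_allclose(px.evaluate_J(sd, np.linspace(0, 2000, 50)), 0.0)

    def test_J_zero_at_origin(self):
        sd = px.SpectralDensity(100.0, 50.0, [px.VibronicMode(600.0, 0.5, 10.0)])
        assert px.evaluate_J(sd, [0.0])[0] == 0.0

    def test_negative_frequency_rejected(self):
        with pytest.raises(LineshapeError):
            px.evaluate_J(px.SpectralDensity(100.0, 50.0), [-1.0])

    def test_mode_peak_and_area(self):
        mode = px.VibronicMode(600.0, 0.5, 10.0)
        sd = px.SpectralDensity(0.0, 50.0, [mode])
        grid = np.linspace(1e-3, 6000.0, 400_000)
        J = px.evaluate_J(sd, grid)
        assert abs(grid[np.argmax(J)] - 600.0) < 1.0
        lam = np.trapezoid(J / grid, grid) / np.pi
        assert lam == pytest.approx(300.0, rel=5e-3)

    def test_reorganization_energy(self):
        mode = px.VibronicMode(600.0, 0.5, 10.0)
        assert px.reorganization_energy(px.SpectralDensity(100.0, 50.0)) == 100.0
        assert px.reorganization_energy(px.SpectralDensity(0.0, 50.0, [mode])) == 300.0
        assert px.reorganization_energy(px.SpectralDensity(100.0, 50.0, [mode])) == 400.0

    def test_json_roundtrip(self, tmp_path):
        sd = px.SpectralDensity(120.0, 40.0, [px.VibronicMode(660.0, 0.3, 5.0)])
        path = tmp_path / "sd.json"
        from phycoexciton.lineshape import read_spectral_density, write_spectral_density

        write_spectral_density(sd, path)
        assert read_spectral_density(path) == sd


class TestStokesCalibrate:
    def test_no_modes(self):
        assert px.stokes_calibrate(400.0) == pytest.approx(200.0)

    def test_with_vibronic_part(self):
        modes = [px.VibronicMode(600.0, 0.25)]  # lambda_v = 150
        assert px.stokes_calibrate(400.0, modes) == pytest.approx(50.0)

    def test_infeasible(self):
        with pytest.raises(LineshapeError, match="infeasible"):
            px.stokes_calibrate(200.0, [px.VibronicMode(600.0, 0.25)])


class TestLineshapeFunction:
    def test_g_zero_at_origin(self, obo_table):
        assert obo_table.g[0] == 0.0

    def test_re_g_nondecreasing_short_times(self, obo_table):
        re = obo_table.g.real[:500]
        assert np.all(np.diff(re) >= -1e-12)

    def test_im_g_slope_limit(self, obo_table):
        t = obo_table.time
        slope = (obo_table.g.imag[-1] - obo_table.g.imag[-300]) / (t[-1] - t[-300])
        assert slope / TWO_PI_C == pytest.approx(-100.0, rel=5e-3)

    def test_high_temperature_classical_limit(self):
        # kT >= 10 h gamma: Re g ~ (2 lambda kT / gamma^2)(exp(-gamma t) + gamma t - 1)
        lam, gam, T = 80.0, 5.0, 300.0
        tab = px.lineshape_function(px.SpectralDensity(lam, gam), T)
        kt = KB_CM1 * T
        assert kt > 10 * gam
        gt = gam * TWO_PI_C * tab.time
        classical = (2 * lam * kt / gam**2) * (np.exp(-gt) + gt - 1.0)
        sel = tab.time > 100.0
        np.testing.assert_allclose(tab.g.real[sel], classical[sel], rtol=1e-2)

    def test_undamped_mode_analytic(self):
        S, w, T = 0.4, 600.0, 300.0
        tab = px.lineshape_function(
            px.SpectralDensity(0.0, 53.0, [px.VibronicMode(w, S, 0.0)]), T
        )
        coth = 1.0 / np.tanh(w / (2 * KB_CM1 * T))
        phi = TWO_PI_C * w * tab.time
        expected = S * (coth * (1 - np.cos(phi)) + 1j * (np.sin(phi) - phi))
        np.testing.assert_allclose(tab.g, expected, atol=1e-10)

    def test_derivatives_consistent(self, obo_table):
        num = np.gradient(obo_table.g, obo_table.time)
        np.testing.assert_allclose(num[5:-5], obo_table.gdot[5:-5], rtol=2e-3, atol=1e-7)

    def test_bad_time_grid(self):
        with pytest.raises(LineshapeError):
            px.lineshape_function(px.SpectralDensity(100.0, 50.0), 300.0,
                                  np.array([1.0, 2.0]))

    def test_temperature_validation(self):
        with pytest.raises(ValueError):
            px.lineshape_function(px.SpectralDensity(100.0, 50.0), -5.0)


class TestModifiedRedfieldRates:
    def test_zero_coupling_dimer_no_transfer(self, obo_table):
        st_ = px.diagonalize(px.gen_dimer_fixture(gap=500.0, coupling=0.0))
        K = px.modified_redfield_rates(st_, obo_table)
        np.testing.assert_allclose(K, 0.0)

    def test_downhill_faster_than_uphill(self, obo_table):
        st_ = px.diagonalize(px.gen_dimer_fixture(gap=500.0, coupling=100.0))
        K = px.modified_redfield_rates(st_, obo_table)
        assert K[0, 1] > K[1, 0] > 0.0

    def test_detailed_balance_weak_mixing(self, obo_table):
        st_ = px.diagonalize(px.gen_dimer_fixture(gap=500.0, coupling=100.0))
        K = px.modified_redfield_rates(st_, obo_table)
        gap = st_.energies[1] - st_.energies[0]
        assert K[1, 0] / K[0, 1] == pytest.approx(np.exp(-gap / 208.51), rel=0.02)

    def test_column_sums_on_diagonal(self, obo_table):
        st_ = px.diagonalize(px.gen_dimer_fixture(gap=300.0, coupling=150.0))
        K = px.modified_redfield_rates(st_, obo_table)
        np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-15)

    def test_independent_quadrature_oracle(self, obo_table):
        """Rate equals a direct Simpson quadrature of the same integrand."""
        from scipy.integrate import simpson

        st_ = px.diagonalize(px.gen_dimer_fixture(gap=400.0, coupling=120.0))
        K = px.modified_redfield_rates(st_, obo_table)
        C, eps, t = st_.coefficients, st_.energies, obo_table.time
        g, gd, gdd = obo_table.g, obo_table.gdot, obo_table.gddot
        lam = obo_table.reorganization

        def theta(a, b, c, d):
            return float(np.sum(C[:, a] * C[:, b] * C[:, c] * C[:, d]))

        k, kp = 1, 0  # downhill
        phase = (
            1j * TWO_PI_C * (eps[k] - eps[kp]) * t
            - 2j * TWO_PI_C * (theta(k, k, k, k) - theta(k, k, kp, kp)) * lam * t
        )
        env = np.exp(
            phase - (theta(k, k, k, k) + theta(kp, kp, kp, kp) - 2 * theta(k, k, kp, kp)) * g
        )
        bracket = theta(k, kp, kp, k) * gdd - (
            theta(k, kp, k, k) * gd - theta(k, kp, kp, kp) * gd
            + 2j * TWO_PI_C * theta(k, kp, k, k) * lam
        ) ** 2
        oracle = 2.0 * simpson((env * bracket).real, x=t)
        assert K[kp, k] == pytest.approx(oracle, rel=1e-2)

    def test_tail_criterion(self):
        # undamped mode never decays -> integrand cannot converge
        tab = px.lineshape_function(
            px.SpectralDensity(0.0, 53.0, [px.VibronicMode(600.0, 0.6, 0.0)]), 300.0
        )
        st_ = px.diagonalize(px.gen_dimer_fixture(gap=500.0, coupling=100.0))
        with pytest.raises(LineshapeError, match="decayed"):
            px.modified_redfield_rates(st_, tab)


class TestSpectra:
    @pytest.mark.parametrize("theory", ["modified_redfield", "cumulant"])
    def test_monomer_equals_direct_oracle(self, monomer, obo_table, theory):
        st_ = px.diagonalize(monomer)
        grid = np.arange(13500.0, 16500.0, 3.0)
        spec = px.absorption_spectrum(st_, monomer, obo_table, theory=theory,
                                      wavenumber_grid=grid)
        f_t = _tail_window(len(obo_table.time)) * np.exp(-obo_table.g)
        oracle = 4.0 * half_fourier_oracle(f_t, obo_table.time, 15000.0, grid[::17])
        scale = np.max(np.abs(oracle))
        np.testing.assert_allclose(spec.od[::17], oracle, atol=1e-6 * scale)

    def test_degenerate_h_dimer_sticks(self, obo_table):
        sys_ = px.gen_dimer_fixture(gap=0.0, coupling=238.0, mean_energy=15000.0)
        st_ = px.diagonalize(sys_)
        np.testing.assert_allclose(st_.energies, [14762.0, 15238.0])
        grid = np.arange(13000.0, 17000.0, 2.0)
        spec = px.absorption_spectrum(st_, sys_, obo_table, wavenumber_grid=grid)
        # dark lower state: stick at 14762 carries no intensity of its own,
        # only the broadened wing of the bright upper stick
        at_lower = spec.od[np.searchsorted(grid, 14762.0)]
        at_upper = spec.od[np.searchsorted(grid, 15238.0)]
        assert at_upper > 10 * at_lower
        assert abs(grid[np.argmax(spec.od)] - 15238.0) < 30.0

    def test_zero_coupling_additivity(self, obo_table):
        sys_ = px.gen_dimer_fixture(gap=500.0, coupling=0.0)
        grid = np.arange(13500.0, 17000.0, 2.0)
        both = px.homogeneous_spectra(sys_, obo_table, wavenumber_grid=grid)
        parts = []
        for s in sys_.sites:
            mono = px.build_system([s], [[0.0]])
            parts.append(px.homogeneous_spectra(mono, obo_table, wavenumber_grid=grid).od)
        np.testing.assert_allclose(both.od, parts[0] + parts[1], atol=1e-9 * both.od.max())

    def test_uniform_shift_translates_spectrum(self, obo_table):
        grid = np.arange(13500.0, 17000.0, 2.0)
        delta = 500.0
        a = px.homogeneous_spectra(px.gen_dimer_fixture(gap=400.0, coupling=120.0),
                                   obo_table, wavenumber_grid=grid)
        b = px.homogeneous_spectra(
            px.gen_dimer_fixture(gap=400.0, coupling=120.0, mean_energy=15000.0 + delta),
            obo_table, wavenumber_grid=grid + delta)
        np.testing.assert_allclose(a.od, b.od, atol=1e-9 * a.od.max())
        np.testing.assert_allclose(a.cd, b.cd, atol=1e-9 * np.abs(a.cd).max() if np.abs(a.cd).max() else 1e-12)
        np.testing.assert_allclose(a.flu, b.flu, atol=1e-9 * a.flu.max())

    def test_integrated_intensity_conserved_vs_zero_coupling(self, obo_table):
        grid = np.arange(12000.0, 19000.0, 2.0)
        full = px.homogeneous_spectra(px.gen_dimer_fixture(gap=300.0, coupling=238.0),
                                      obo_table, wavenumber_grid=grid)
        zero = px.homogeneous_spectra(px.gen_dimer_fixture(gap=300.0, coupling=0.0),
                                      obo_table, wavenumber_grid=grid)
        a = np.trapezoid(full.od, grid)
        b = np.trapezoid(zero.od, grid)
        assert a == pytest.approx(b, rel=0.01)

    def test_od_nonnegative(self, obo_table, rng):
        from phycoexciton.synth import gen_random_system

        grid = np.arange(12000.0, 19000.0, 4.0)
        for _ in range(3):
            sys_ = gen_random_system(4, rng)
            res = px.homogeneous_spectra(sys_, obo_table, wavenumber_grid=grid)
            assert np.all(res.od >= 0.0)
            assert np.all(res.flu >= 0.0)

    def test_monomer_zero_cd(self, monomer, obo_table):
        st_ = px.diagonalize(monomer)
        spec = px.cd_spectrum(st_, monomer, obo_table,
                              wavenumber_grid=np.arange(14000.0, 16000.0, 4.0))
        np.testing.assert_allclose(spec.cd, 0.0, atol=1e-12)

    def test_chiral_dimer_bisignate_couplet(self, obo_table):
        sys_ = px.gen_dimer_fixture(gap=0.0, coupling=150.0, geometry="chiral")
        st_ = px.diagonalize(sys_)
        grid = np.arange(12500.0, 17500.0, 2.0)
        # symmetric broadening: suppress lifetime damping and use a narrow
        # low-skew bath so both lobes carry the same symmetric lineshape
        tab = px.lineshape_function(px.SpectralDensity(20.0, 2.0), 300.0)
        res = px.cd_spectrum(st_, sys_, tab, rates=np.zeros((2, 2)),
                             wavenumber_grid=grid)
        assert res.cd.max() > 0 and res.cd.min() < 0
        assert abs(res.cd.max() + res.cd.min()) < 0.02 * res.cd.max()
        assert abs(np.trapezoid(res.cd, grid)) < 0.02 * np.trapezoid(np.abs(res.cd), grid)
        # with lifetime broadening the couplet survives qualitatively
        full = px.homogeneous_spectra(sys_, obo_table, wavenumber_grid=grid)
        assert full.cd.max() > 0 and full.cd.min() < 0

    def test_monomer_stokes_shift(self, monomer, slow_obo_table):
        grid = np.arange(13000.0, 17000.0, 4.0)
        st_ = px.diagonalize(monomer)
        od = px.absorption_spectrum(st_, monomer, slow_obo_table, wavenumber_grid=grid)
        flu = px.fluorescence_spectrum(st_, monomer, slow_obo_table, 300.0,
                                       wavenumber_grid=grid)
        stokes = grid[np.argmax(od.od)] - grid[np.argmax(flu.flu)]
        assert abs(stokes - 400.0) <= 4.0  # 2 lambda, to grid resolution

    def test_emission_boltzmann_weights(self, obo_table):
        # population ratio for a 500 cm^-1 gap at 300 K
        kt = KB_CM1 * 300.0
        assert np.exp(-500.0 / kt) == pytest.approx(0.0909, abs=2e-4)
        sys_ = px.gen_dimer_fixture(gap=500.0, coupling=0.0)
        st_ = px.diagonalize(sys_)
        # narrow slow bath: Gaussian-like lines whose wings do not bleed into
        # the other state's emission band
        tab = px.lineshape_function(px.SpectralDensity(20.0, 2.0), 300.0)
        grid = np.arange(12500.0, 17000.0, 2.0)
        flu = px.fluorescence_spectrum(st_, sys_, tab, 300.0, wavenumber_grid=grid)
        # localized states, identical lineshapes: emission heights at the two
        # band maxima scale exactly with the Boltzmann populations
        low_peak = flu.flu[(grid > 14500) & (grid < 14900)].max()
        high_peak = flu.flu[(grid > 15100) & (grid < 15400)].max()
        assert high_peak / low_peak == pytest.approx(np.exp(-500.0 / kt), rel=0.02)

    def test_low_temperature_single_emitter(self, obo_table):
        sys_ = px.gen_dimer_fixture(gap=800.0, coupling=0.0)
        st_ = px.diagonalize(sys_)
        tab10 = px.lineshape_function(px.SpectralDensity(100.0, 53.0), 10.0)
        grid = np.arange(12500.0, 17500.0, 2.0)
        flu = px.fluorescence_spectrum(st_, sys_, tab10, 10.0, wavenumber_grid=grid)
        assert flu.flu[grid > 15000.0].max() < 1e-6 * flu.flu.max()

    def test_missing_lineshape_for_site(self, obo_table):
        sys_ = px.gen_dimer_fixture(gap=100.0, coupling=50.0)
        st_ = px.diagonalize(sys_)
        with pytest.raises(LineshapeError, match="one lineshape per site"):
            px.absorption_spectrum(st_, sys_, [obo_table], wavenumber_grid=np.arange(14000.0, 16000.0, 4.0))


def test_spectrum_csv_roundtrip(tmp_path, monomer, obo_table):
    res = px.homogeneous_spectra(monomer, obo_table,
                                 wavenumber_grid=np.arange(14000.0, 16000.0, 4.0))
    res.metadata["theory"] = "modified_redfield"
    path = tmp_path / "spec.csv"
    write_spectrum_csv(res, path)
    back = read_spectrum_csv(path)
    np.testing.assert_allclose(back.wavenumber, res.wavenumber)
    np.testing.assert_allclose(back.od, res.od, rtol=1e-6, atol=1e-12)
    assert back.metadata["theory"] == "modified_redfield"


def test_grid_must_increase():
    with pytest.raises(LineshapeError):
        px.SpectrumResult(wavenumber=np.array([2.0, 1.0]))
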