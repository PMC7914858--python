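"""Unit tests for the dielectric-formalism cross sections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iondamage import (
    ANGSTROM_UNITS,
    DrudeParameters,
    IonSpecies,
    beta_from_T,
    elf,
    ion,
    ionization_stopping,
    sdcs,
    tics,
    tics_peak_energy,
    w_average,
    xsec_table,
    zeff,
)
from iondamage.constants import E2_EV_NM, HBARC_EV_NM

from _oracles import sdcs_k_integral_quad

DRUDE = DrudeParameters()


class TestElf:
    def test_value_at_drude_peak(self):
        # at k=0, E=Ep0 the denominator collapses to gamma_w^2 E^2
        expected = DRUDE.alpha / (DRUDE.gamma_w**2 * DRUDE.Ep0)
        assert elf(0.0, DRUDE.Ep0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.758, abs=5e-4)

    def test_vanishes_at_small_E(self):
        # numerator is linear in E, so the optical ELF -> 0 as E -> 0+
        assert elf(0.0, 1e-6) < 1e-7
        assert elf(0.0, 1e-6) < elf(0.0, 1e-3) < elf(0.0, 1.0)

    def test_dispersion_shifts_peak_up(self):
        # at fixed E = Ep0 the k>0 value sits below the optical one
        assert elf(1.0, DRUDE.Ep0) < elf(0.0, DRUDE.Ep0)

    def test_nonnegative_and_single_optical_maximum(self):
        E = np.linspace(0.5, 200.0, 2000)
        v = elf(0.0, E)
        assert np.all(v >= 0)
        # the broad Drude width shifts the maximum slightly below Ep0
        i = int(np.argmax(v))
        assert abs(E[i] - DRUDE.Ep0) < 2.0
        assert np.all(np.diff(v[:i]) > 0) and np.all(np.diff(v[i:]) < 0)

    def test_nonpositive_E_rejected(self):
        with pytest.raises(ValueError):
            elf(0.0, 0.0)


class TestZeff:
    def test_saturation_and_low_velocity(self):
        assert zeff(1, 0.5) == pytest.approx(1.0, abs=1e-12)
        assert zeff(6, 0.02) == pytest.approx(3.185, abs=5e-3)
        assert zeff(6, 1e-9) < 1e-5

    def test_domain_and_monotonicity(self):
        with pytest.raises(ValueError):
            zeff(6, 0.0)
        with pytest.raises(ValueError):
            zeff(6, -0.1)
        betas = np.linspace(1e-4, 0.9, 50)
        assert np.all(np.diff(zeff(6, betas)) > 0)

    @given(st.integers(1, 30), st.floats(1e-6, 0.999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_by_charge(self, z, beta):
        assert 0.0 < zeff(z, beta) <= z


class TestSdcs:
    def test_zeff_squared_scaling_at_equal_velocity(self, carbon):
        # same T/A means same beta; k-integrals coincide, so the ratio is
        # exactly the effective-charge ratio squared
        oxy = ion("16O")
        W = np.array([5.0, 30.0, 120.0])
        r = sdcs(carbon, 12.0, W) / sdcs(oxy, 16.0, W)
        zc = zeff(6, beta_from_T(12.0, carbon))
        zo = zeff(8, beta_from_T(16.0, oxy))
        # tiny residual from the mass-dependent kinematic limits
        assert r == pytest.approx((zc / zo) ** 2 * np.ones(3), rel=1e-6)

    def test_forbidden_transfer_is_zero(self, carbon):
        # W + B beyond the kinematic maximum
        assert sdcs(carbon, 1e-4, np.array([200.0]))[0] == 0.0

    def test_negative_W_rejected(self, carbon):
        with pytest.raises(ValueError):
            sdcs(carbon, 12.0, -1.0)

    @pytest.mark.parametrize(
        "ion_name,T,W",
        [("proton", 1.0, 10.0), ("12C", 12.0, 10.0), ("12C", 120.0, 500.0)],
    )
    def test_against_adaptive_quadrature_oracle(self, ion_name, T, W):
        sp = ion(ion_name)
        ze = zeff(sp.z, beta_from_T(T, sp))
        pref = E2_EV_NM * sp.M * ze**2 / (2 * np.pi * T * 1e6 * HBARC_EV_NM**2)
        oracle = pref * sdcs_k_integral_quad(W, T, sp.M)
        assert sdcs(sp, T, W)[0] == pytest.approx(oracle, rel=1e-3)


class TestMoments:
    def test_tics_unimodal_on_log_grid(self, carbon):
        Ts = np.geomspace(0.05 * 12, 300 * 12, 25)
        vals = np.array([tics(carbon, float(t)) for t in Ts])
        i = int(np.argmax(vals))
        assert 0 < i < len(Ts) - 1
        assert np.all(np.diff(vals[: i + 1]) > 0)
        assert np.all(np.diff(vals[i:]) < 0)

    def test_tics_peak_shifts_with_ion_mass(self):
        peaks = [
            tics_peak_energy(ion(nm), (0.05, 10.0), n=25)
            for nm in ("11B", "20Ne", "56Fe")
        ]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_w_average_matches_independent_moment_ratio(self, carbon):
        from scipy.integrate import quad

        T = 12.0
        num = quad(lambda W: W * sdcs(carbon, T, W)[0], 0, 3e3, limit=200)[0]
        den = quad(lambda W: sdcs(carbon, T, W)[0], 0, 3e3, limit=200)[0]
        assert w_average(carbon, T) == pytest.approx(num / den, rel=2e-3)

    def test_w_average_requires_nonvanishing_tics(self, carbon):
        with pytest.raises(ValueError):
            w_average(carbon, 2e-5)

    def test_stopping_unimodal_and_charge_scaling(self, carbon):
        Ts = np.geomspace(0.05 * 12, 300 * 12, 20)
        vals = np.array([ionization_stopping(carbon, float(t)) for t in Ts])
        i = int(np.argmax(vals))
        assert 0 < i < len(Ts) - 1
        assert np.all(np.diff(vals[: i + 1]) > 0) and np.all(np.diff(vals[i:]) < 0)
        # Z_eff^2 scaling at matched velocity
        oxy = ion("16O")
        zc = zeff(6, beta_from_T(12.0, carbon))
        zo = zeff(8, beta_from_T(16.0, oxy))
        # the ratio is exact in the continuum; the two moment grids end at
        # different kinematic maxima, leaving a small discretization residual
        assert ionization_stopping(oxy, 16.0) / ionization_stopping(carbon, 12.0) == (
            pytest.approx((zo / zc) ** 2, rel=5e-3)
        )

    def test_unit_system_invariance(self, carbon):
        # eV/nm/fs vs eV/Angstrom/fs bookkeeping agrees to 6 significant figures
        assert tics(carbon, 12.0, units=ANGSTROM_UNITS) == pytest.approx(
            tics(carbon, 12.0), rel=1e-6
        )
        assert w_average(carbon, 12.0, units=ANGSTROM_UNITS) == pytest.approx(
            w_average(carbon, 12.0), rel=1e-6
        )

    def test_w_grid_convergence(self, carbon):
        # doubling the moment grid moves TICS by far less than 0.1%
        assert tics(carbon, 12.0, n_w=600) == pytest.approx(
            tics(carbon, 12.0, n_w=300), rel=1e-3
        )


class TestTypes:
    def test_ion_validation(self):
        with pytest.raises(ValueError):
            IonSpecies("bad", 0, 1)
        with pytest.raises(ValueError):
            IonSpecies("bad", 6, 5)
        with pytest.raises(KeyError):
            ion("unobtainium")

    def test_drude_validation(self):
        with pytest.raises(ValueError):
            DrudeParameters(alpha=-1.0)

    def test_xsec_table_columns(self, carbon):
        df = xsec_table(carbon, [12.0, 120.0])
        assert list(df.columns) == ["T_MeV", "TICS_per_nm", "Wavg_eV"]
        assert (df["TICS_per_nm"] > 0).all()
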