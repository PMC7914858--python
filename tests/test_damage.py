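"""Damage-calculus tests: cluster probabilities, lesion counts, lethal yield."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iondamage import (
    CellNucleus,
    DamageParams,
    electron_lesions,
    lethal_yield_per_length,
    p_complex,
    radical_lesions,
    site_density,
)

from _oracles import poisson_tail_series


class TestPComplex:
    def test_boundary_values(self):
        assert p_complex(0.0) == 0.0
        assert p_complex(1e3) == pytest.approx(0.15, rel=1e-12)

    def test_against_bruteforce_series(self):
        assert p_complex(2.0, 0.15, 3) == pytest.approx(
            poisson_tail_series(2.0, 3, 0.15), abs=1e-12
        )

    @given(st.floats(0.0, 50.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_closed_form_equals_series_everywhere(self, N):
        # 200 terms keep the series' own truncation error below the band
        assert abs(p_complex(N, 0.15, 3) - poisson_tail_series(N, 3, 0.15, 200)) < 1e-12

    def test_monotone_and_bounded(self):
        N = np.linspace(0.0, 30.0, 200)
        v = p_complex(N)
        assert np.all(np.diff(v) >= 0)
        assert np.all((v >= 0) & (v <= 0.15 + 1e-15))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            p_complex(-0.1)
        with pytest.raises(ValueError):
            p_complex(1.0, nu_min=0)


class TestLesionCounts:
    def test_electron_lesions_arithmetic(self):
        assert electron_lesions(0.0, 0.03) == 0.0
        assert electron_lesions(10.0, 0.03) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            electron_lesions(-1.0, 0.03)

    def test_gamma_preset_coupling(self):
        assert DamageParams.for_gamma(1e-4).Gamma_ssb == 0.03
        assert DamageParams.for_gamma(1e-2).Gamma_ssb == 1.0
        with pytest.raises(ValueError):
            DamageParams.for_gamma(5e-3)

    def test_radical_lesions_hand_value(self):
        p = DamageParams()
        # 15e-3 nm^-2 * 15.64 nm^2 * 0.13 at rho < 10
        assert radical_lesions(5.0, p) == pytest.approx(0.0305, rel=2e-3)
        assert radical_lesions(12.0, p) == 0.0

    def test_hypoxia_halves_radical_term(self):
        p = DamageParams()
        h = p.with_oxygen("hypoxic")
        assert radical_lesions(5.0, h) == pytest.approx(
            0.5 * radical_lesions(5.0, p), rel=1e-12
        )


class TestSiteDensity:
    def test_linear_in_genome_size(self):
        a = site_density(CellNucleus("a", 172.3, 3.2e9))
        b = site_density(CellNucleus("b", 172.3, 6.4e9))
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_human_fibroblast_hand_value(self, human_cell):
        assert site_density(human_cell) == pytest.approx(3.1e-4, rel=2e-2)

    def test_cell_line_ordering(self):
        # fibroblast vs glioblastoma: larger nucleus but many more
        # chromosomes shifts the site density upward
        nb1rgb = CellNucleus("NB1RGB", 172.3, 3.2e9)
        ks1 = CellNucleus("KS-1", 221.4, 3.2e9 * 83.3 / 46.3)
        assert site_density(ks1) > site_density(nb1rgb)

    def test_derived_diameter(self):
        c = CellNucleus("c", 172.3, 3.2e9)
        assert c.diameter_um == pytest.approx(14.81, rel=1e-3)
        explicit = CellNucleus("c", 172.3, 3.2e9, Dn=10.0)
        assert explicit.diameter_um == 10.0


class TestParamsValidation:
    def test_nu_min_locked_at_three(self):
        with pytest.raises(ValueError, match="nu_min"):
            DamageParams(nu_min=2)
        with pytest.raises(ValueError, match="nu_min"):
            DamageParams(nu_min=4)

    def test_bounds(self):
        with pytest.raises(ValueError):
            DamageParams(Nrk=0.02)
        with pytest.raises(ValueError):
            DamageParams(lam=0.3)
        with pytest.raises(ValueError):
            DamageParams(Gamma_ssb=1.5)
        with pytest.raises(ValueError):
            DamageParams(oxygen="anoxic")


class TestLethalYield:
    def test_zero_radical_degeneracy(self, human_cell, model_hard):
        # with Nrk = 0 the two radial pieces merge into one electron-only
        # integral, so oxygen no longer matters
        pn = DamageParams(Gamma_ssb=1.0, Nrk=0.0, oxygen="normoxic")
        ph = DamageParams(Gamma_ssb=1.0, Nrk=0.0, oxygen="hypoxic")
        yn = lethal_yield_per_length(human_cell, 2.0, pn, 1e-2, model_hard)
        yh = lethal_yield_per_length(human_cell, 2.0, ph, 1e-2, model_hard)
        assert yn == pytest.approx(yh, rel=1e-12)

    def test_bounded_by_saturated_disc(self, human_cell, model_hard):
        p = DamageParams(Gamma_ssb=1.0)
        y = lethal_yield_per_length(human_cell, 5.0, p, 1e-2, model_hard, rho_max=200.0)
        bound = site_density(human_cell) * 0.15 * np.pi * 200.0**2
        assert 0.0 < y < bound

    def test_monotonicity_in_drivers(self, human_cell, model_hard):
        base = dict(cell=human_cell, gamma_coeff=1e-2, fluence_model=model_hard)
        y0 = lethal_yield_per_length(
            dNe_dz=2.0, params=DamageParams(Gamma_ssb=0.5), **base
        )
        assert lethal_yield_per_length(
            dNe_dz=4.0, params=DamageParams(Gamma_ssb=0.5), **base
        ) > y0
        assert lethal_yield_per_length(
            dNe_dz=2.0, params=DamageParams(Gamma_ssb=1.0), **base
        ) > y0
        assert (
            lethal_yield_per_length(
                dNe_dz=2.0, params=DamageParams(Gamma_ssb=0.5, Nrk=0.0), **base
            )
            < y0
        )
        assert (
            lethal_yield_per_length(
                dNe_dz=2.0, params=DamageParams(Gamma_ssb=0.5, lam=0.2), **base
            )
            > y0
        )

    def test_oxygen_ordering(self, human_cell, model_hard):
        pn = DamageParams(Gamma_ssb=1.0, oxygen="normoxic")
        ph = DamageParams(Gamma_ssb=1.0, oxygen="hypoxic")
        yn = lethal_yield_per_length(human_cell, 2.0, pn, 1e-2, model_hard)
        yh = lethal_yield_per_length(human_cell, 2.0, ph, 1e-2, model_hard)
        assert yh < yn

    def test_radial_truncation_stability(self, human_cell, model_hard):
        p = DamageParams(Gamma_ssb=1.0)
        y1 = lethal_yield_per_length(
            human_cell, 2.0, p, 1e-2, model_hard, rho_max=100.0, tail_rtol=0.0
        )
        y2 = lethal_yield_per_length(
            human_cell, 2.0, p, 1e-2, model_hard, rho_max=200.0, tail_rtol=0.0
        )
        assert y2 == pytest.approx(y1, rel=5e-3)

    def test_diagnostic_table(self, model_hard):
        from iondamage.damage import diagnostic_table

        df = diagnostic_table(model_hard, 1.0, DamageParams(), [1.0, 5.0, 12.0])
        assert list(df.columns) == ["rho_nm", "N_e", "N_r", "P_e", "P_l"]
        assert df.loc[2, "N_r"] == 0.0  # beyond the 10 nm radical zone
        assert (df["P_l"] >= df["P_e"] - 1e-15).all()
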