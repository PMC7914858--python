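"""Physical constants and the internal unit system.

Everything downstream works in eV for energy, nm for length and fs for
time; all of the liquid-water parameters used by the model are printed in
those units.  A :class:`UnitSystem` expresses the handful of dimensional
constants in a rescaled length unit so that unit-system invariance of the
cross sections can be exercised directly (nm vs Angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass

#: hbar in eV fs
HBAR_EV_FS = 0.6582119569

#: hbar*c in eV nm
HBARC_EV_NM = 197.3269804

#: electron rest energy in eV
ME_C2_EV = 510_998.95

#: atomic mass unit in eV
AMU_EV = 931.494_102_42e6

#: e^2 = alpha * hbar * c in eV nm (Gaussian convention)
E2_EV_NM = HBARC_EV_NM / 137.035_999_084

#: elementary charge in J (for the Gy dose conversion of the traversal count)
E_CHARGE_J = 1.6e-19

#: molecular number density of liquid water, nm^-3  (0.033 molecule/A^3)
WATER_N_PER_NM3 = 33.0

#: electrons per water molecule
WATER_Z = 10

#: mean excitation energy of liquid water for Bethe stopping, eV
WATER_I_EV = 78.0


@dataclass(frozen=True)
class UnitSystem:
    """Dimensional constants expressed in a chosen length unit.

    Parameters
    ----------
    length_nm:
        Size of the internal length unit in nm (1.0 -> nm, 0.1 -> Angstrom).
    """

    length_nm: float = 1.0

    @property
    def hbarc(self) -> float:
        """hbar*c in eV * L."""
        return HBARC_EV_NM / self.length_nm

    @property
    def e2(self) -> float:
        """e^2 in eV * L."""
        return E2_EV_NM / self.length_nm

    @property
    def n_water(self) -> float:
        """Water molecular density in L^-3."""
        return WATER_N_PER_NM3 * self.length_nm**3


NM_UNITS = UnitSystem(1.0)
ANGSTROM_UNITS = UnitSystem(0.1)
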