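"""Stopping-power (LET) tables: loading, interpolation, inversion, fixtures.

The pipeline's independent variable is usually the electronic stopping
power S_e (treated as synonymous with LET).  Converting an S_e value into
the ion kinetic energy T -- needed because the electron source term
dN_e/dzeta is a function of T -- requires an S_e(T) table.  Users supply
their own (ICRU/SRIM exports converted to a two-column CSV); for
self-contained runs a synthetic table is generated from the package's own
stopping models.

A stopping curve has a single Bragg maximum, so the inversion is
branch-wise: ``"high"`` (T above the Bragg-peak energy; the
therapy-relevant distal branch and the default) or ``"low"``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import E2_EV_NM, ME_C2_EV, WATER_I_EV, WATER_N_PER_NM3, WATER_Z
from .dielectric import IonSpecies, beta_from_T, ionization_stopping, zeff

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("T_MeV", "Se_keV_um")


class StoppingTableError(ValueError):
    """Malformed stopping-table input."""


@dataclass(frozen=True)
class StoppingTable:
    """Ordered (T, S_e) pairs for one ion in liquid water.

    T in MeV (strictly increasing, >= 5 rows), S_e in keV/um (> 0,
    unimodal with one Bragg maximum).  Interpolation is log-log linear.
    """

    ion: str
    T: np.ndarray
    Se: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        Se = np.asarray(self.Se, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "Se", Se)
        if T.ndim != 1 or T.size < 5 or T.size != Se.size:
            raise StoppingTableError("need >= 5 (T, Se) rows of equal length")
        if not np.all(np.isfinite(T)) or not np.all(np.isfinite(Se)):
            raise StoppingTableError("non-numeric cells in stopping table")
        if np.any(np.diff(T) <= 0):
            raise StoppingTableError("T must be strictly increasing (no duplicates)")
        if np.any(T <= 0) or np.any(Se <= 0):
            raise StoppingTableError("T and Se must be > 0")
        # unimodality: the sign of dSe may switch from + to - at most once
        s = np.sign(np.diff(Se))
        s = s[s != 0]
        if np.any(np.diff(s) > 0) or (np.sum(np.diff(s) != 0) > 1):
            raise StoppingTableError("Se(T) must be unimodal (one Bragg maximum)")

    # -- basic queries ---------------------------------------------------

    @property
    def bragg_index(self) -> int:
        return int(np.argmax(self.Se))

    @property
    def bragg_T(self) -> float:
        """Ion energy (MeV) of the tabulated Bragg maximum."""
        return float(self.T[self.bragg_index])

    @property
    def bragg_Se(self) -> float:
        """Tabulated Bragg-maximum stopping power (keV/um)."""
        return float(self.Se[self.bragg_index])

    def se_at(self, T_MeV: float) -> float:
        """S_e at an energy inside the table range (log-log linear)."""
        if not (self.T[0] <= T_MeV <= self.T[-1]):
            raise ValueError(
                f"T = {T_MeV} MeV outside table range [{self.T[0]}, {self.T[-1]}]"
            )
        return float(
            np.exp(np.interp(np.log(T_MeV), np.log(self.T), np.log(self.Se)))
        )

    def t_at_se(self, Se: float, branch: str = "high") -> float:
        """Invert S_e -> T on one monotone branch of the Bragg curve.

        ``branch="high"`` uses the distal (T > Bragg energy) branch where
        S_e decreases with T; ``"low"`` the proximal one.
        """
        if Se > self.bragg_Se:
            raise ValueError(
                f"Se = {Se} keV/um exceeds the tabulated Bragg maximum "
                f"{self.bragg_Se:.6g} keV/um (at T = {self.bragg_T:.6g} MeV)"
            )
        i = self.bragg_index
        if branch == "high":
            Tb, Sb = self.T[i:], self.Se[i:]
            if Se < Sb[-1]:
                raise ValueError(
                    f"Se = {Se} below the high-branch minimum {Sb[-1]:.6g} keV/um"
                )
            # reverse so Se is increasing for interp
            return float(
                np.exp(np.interp(np.log(Se), np.log(Sb[::-1]), np.log(Tb[::-1])))
            )
        if branch == "low":
            Tb, Sb = self.T[: i + 1], self.Se[: i + 1]
            if Se < Sb[0]:
                raise ValueError(
                    f"Se = {Se} below the low-branch minimum {Sb[0]:.6g} keV/um"
                )
            return float(np.exp(np.interp(np.log(Se), np.log(Sb), np.log(Tb))))
        raise ValueError("branch must be 'high' or 'low'")

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame({"T_MeV": self.T, "Se_keV_um": self.Se}).to_csv(path, index=False)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode()


def load_stopping_table(path, ion: str = "") -> StoppingTable:
    """Read a ``T_MeV,Se_keV_um`` CSV into a validated table."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize to a format error
        raise StoppingTableError(f"cannot parse stopping CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise StoppingTableError(f"stopping CSV lacks columns {missing}")
    for col in CSV_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            raise StoppingTableError(f"non-numeric cells in column {col}")
    return StoppingTable(ion=ion, T=df["T_MeV"].to_numpy(), Se=df["Se_keV_um"].to_numpy())


# ----------------------------------------------------------------------
# synthetic tables


def bethe_stopping(species: IonSpecies, T_MeV: float) -> float:
    """Bethe electronic stopping with Barkas effective charge, keV/um.

    Standard relativistic Bethe formula for liquid water (I = 78 eV,
    unit density) with Z_eff(beta) quenching the charge at low velocity,
    which reproduces the Bragg-peak shape.  Shell and Barkas-correction
    terms are omitted; accuracy degrades below ~0.3 MeV/u, which is ample
    for the distal high-energy branch the pipeline uses.
    """
    if T_MeV <= 0:
        raise ValueError("kinetic energy must be > 0")
    beta = beta_from_T(T_MeV, species)
    b2 = beta**2
    g2 = 1.0 / (1.0 - b2)
    ne = WATER_Z * WATER_N_PER_NM3  # electrons / nm^3
    pref = 4.0 * np.pi * E2_EV_NM**2 * ne / (ME_C2_EV * b2)
    stopping_number = np.log(2.0 * ME_C2_EV * b2 * g2 / WATER_I_EV) - b2
    ze = zeff(species.z, beta)
    return float(pref * ze**2 * max(stopping_number, 0.0))  # eV/nm == keV/um


def make_synthetic_table(
    species: IonSpecies,
    T_grid,
    model: str = "bethe",
) -> StoppingTable:
    """Deterministically generate a fixture S_e(T) table.

    ``model="bethe"`` (default) uses the Bethe/effective-charge stopping,
    which carries realistic keV/um magnitudes and reaches the full carbon
    LET range; ``model="ionization"`` uses the single-Drude
    ionization-only first moment (self-consistent with the cross-section
    module but a documented underestimate of total stopping).
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0 or np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be non-empty and strictly increasing")
    if model == "bethe":
        Se = np.array([bethe_stopping(species, t) for t in T_grid])
    elif model == "ionization":
        Se = np.array([ionization_stopping(species, t) for t in T_grid])
    else:
        raise ValueError("model must be 'bethe' or 'ionization'")
    return StoppingTable(ion=species.name, T=T_grid, Se=Se)


def default_table(species: IonSpecies, n: int = 60, model: str = "bethe") -> StoppingTable:
    """Internal synthetic table spanning 0.05-600 MeV/u.

    Used when the caller supplies S_e without a measured table; a warning
    marks the documented approximation.
    """
    logger.warning(
        "no stopping table supplied for %s: falling back to the internal "
        "synthetic %s table (documented approximation)",
        species.name,
        model,
    )
    grid = np.geomspace(0.05 * species.A, 600.0 * species.A, n)
    return make_synthetic_table(species, grid, model=model)
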