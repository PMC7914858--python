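"""OER and RBE at the 10% survival level, and LET scans.

OER = d10(hypoxic) / d10(normoxic) at matched LET; since ln S is linear
in dose it reduces to the inverse ratio of lethal yields, is >= 1, and
equals 1 exactly when the radical term vanishes (N_rk = 0).

RBE_10% = d10(X-ray reference) / d10(ion).  The model has no photon
mode, so the 200 kVp X-ray reference d10 is always a user-supplied
experimental number.  Because d10 = ln10 / (dN_l/dzeta * chord * N_ion/d)
and N_ion/d = A_n/(1.6e-4 * Se), the RBE is proportional to
(dN_l/dzeta)/Se times cell- and reference-dependent constants only, so
the LET position of the RBE maximum is the argmax of (dN_l/dzeta)/Se --
independent of A_n, N_g and the X-ray reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .damage import CellNucleus, DamageParams, HUMAN_CELL, lethal_yield_per_length
from .dielectric import IonSpecies, tics
from .fluence import FluenceModel
from .stopping import StoppingTable, default_table
from .survival import yc_slope_per_gray

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LetScanResult:
    """Per-LET d10s and derived ratios for one ion and cell."""

    Se: np.ndarray
    d10_normoxic: np.ndarray
    d10_hypoxic: np.ndarray
    oer: np.ndarray
    rbe: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.oer < 1.0 - 1e-9):
            raise ValueError("OER must be >= 1")
        if np.any(~np.isfinite(self.d10_normoxic)) or np.any(self.d10_normoxic <= 0):
            raise ValueError("d10 must be finite and positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "Se_keV_um": self.Se,
                "d10_normoxic_Gy": self.d10_normoxic,
                "d10_hypoxic_Gy": self.d10_hypoxic,
                "OER": self.oer,
            }
        )
        if self.rbe is not None:
            df["RBE"] = self.rbe
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _yield_at_se(
    ion: IonSpecies,
    Se: float,
    params: DamageParams,
    gamma_coeff: float,
    cell: CellNucleus,
    table: StoppingTable,
    model: FluenceModel,
) -> float:
    T = table.t_at_se(Se, branch="high")
    dne = tics(ion, T)
    return lethal_yield_per_length(cell, dne, params, gamma_coeff, fluence_model=model)


def d10_at_se(
    cell: CellNucleus,
    ion: IonSpecies,
    Se: float,
    params: DamageParams,
    gamma_coeff: float = 1e-4,
    table: StoppingTable | None = None,
    model: FluenceModel | None = None,
) -> float:
    """10%-survival dose (Gy) at one LET."""
    table = table or default_table(ion)
    model = model or FluenceModel(gamma_coeff)
    dnl = _yield_at_se(ion, Se, params, gamma_coeff, cell, table, model)
    slope = yc_slope_per_gray(cell, Se, dnl)
    if slope <= 0:
        raise ValueError("lethal yield vanishes: d10 undefined")
    return math.log(10.0) / slope


def oer10(
    cell: CellNucleus,
    ion: IonSpecies,
    Se: float,
    params: DamageParams,
    gamma_coeff: float = 1e-4,
    table: StoppingTable | None = None,
    model: FluenceModel | None = None,
) -> float:
    """Oxygen enhancement ratio d10_hypoxic / d10_normoxic at 10% survival."""
    table = table or default_table(ion)
    model = model or FluenceModel(gamma_coeff)
    d_n = d10_at_se(cell, ion, Se, params.with_oxygen("normoxic"), gamma_coeff, table, model)
    d_h = d10_at_se(cell, ion, Se, params.with_oxygen("hypoxic"), gamma_coeff, table, model)
    return d_h / d_n


def rbe10(
    cell: CellNucleus,
    ion: IonSpecies,
    Se: float,
    params: DamageParams,
    d10_xray_ref: float,
    gamma_coeff: float = 1e-4,
    table: StoppingTable | None = None,
    model: FluenceModel | None = None,
) -> float:
    """RBE at 10% survival against a user-supplied X-ray reference d10 (Gy).

    The reference must come from experiment (e.g. 200 kVp X-rays under
    aerobic conditions); the model cannot predict photon response.
    """
    if d10_xray_ref is None or d10_xray_ref <= 0:
        raise ValueError(
            "rbe10 needs an experimental X-ray reference d10 (> 0 Gy): the "
            "model has no photon mode and cannot supply one"
        )
    return d10_xray_ref / d10_at_se(cell, ion, Se, params, gamma_coeff, table, model)


def let_scan(
    cell: CellNucleus,
    ion: IonSpecies,
    Se_values,
    params: DamageParams,
    gamma_coeff: float = 1e-4,
    d10_xray_ref: float | None = None,
    table: StoppingTable | None = None,
) -> LetScanResult:
    """d10 (both oxygen conditions), OER and optional RBE on an LET grid."""
    table = table or default_table(ion)
    model = FluenceModel(gamma_coeff)
    Se_values = np.asarray(Se_values, dtype=float)
    d_n, d_h = [], []
    for s in Se_values:
        d_n.append(d10_at_se(cell, ion, float(s), params.with_oxygen("normoxic"),
                             gamma_coeff, table, model))
        d_h.append(d10_at_se(cell, ion, float(s), params.with_oxygen("hypoxic"),
                             gamma_coeff, table, model))
    d_n = np.array(d_n)
    d_h = np.array(d_h)
    rbe = d10_xray_ref / d_n if d10_xray_ref else None
    return LetScanResult(Se_values, d_n, d_h, d_h / d_n, rbe)


def rbe_peak_let(
    ion: IonSpecies,
    params: DamageParams,
    Se_range: tuple[float, float] = (10.0, 500.0),
    gamma_coeff: float = 1e-4,
    cell: CellNucleus = HUMAN_CELL,
    table: StoppingTable | None = None,
    n_coarse: int = 16,
    refine_tol: float = 0.01,
) -> float:
    """LET (keV/um) maximizing (dN_l/dzeta)/Se, the RBE-proportional ratio.

    Coarse log-grid search followed by golden-section refinement; the
    result does not depend on the cell parameters (they enter as a
    multiplicative constant) nor on the X-ray reference.  If the coarse
    scan is not unimodal -- including a maximum pinned at a scan edge --
    a warning is emitted and the global maximum is returned.
    """
    table = table or default_table(ion)
    model = FluenceModel(gamma_coeff)

    def ratio(s: float) -> float:
        return _yield_at_se(ion, s, params, gamma_coeff, cell, table, model) / s

    grid = np.geomspace(Se_range[0], Se_range[1], n_coarse)
    vals = np.array([ratio(float(s)) for s in grid])
    i = int(np.argmax(vals))
    s = np.sign(np.diff(vals))
    s = s[s != 0]
    unimodal_interior = 0 < i < n_coarse - 1 and np.sum(np.diff(s) != 0) <= 1
    if not unimodal_interior:
        logger.warning(
            "(dN_l/dzeta)/Se scan is not unimodal with an interior maximum "
            "over Se = [%g, %g]; returning the global maximum at %g keV/um",
            Se_range[0], Se_range[1], grid[i],
        )
        return float(grid[i])

    # golden-section refinement on log Se in the bracketing interval
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = math.log(grid[i - 1]), math.log(grid[i + 1])
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = ratio(math.exp(c)), ratio(math.exp(d))
    while (b - a) > refine_tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = ratio(math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = ratio(math.exp(d))
    return float(math.exp(0.5 * (a + b)))
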