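"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (explicit series, generic adaptive
quadrature, direct stochastic simulation) and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from iondamage.constants import ME_C2_EV
from iondamage.dielectric import DrudeParameters, WaterMedium


def poisson_tail_series(N: float, nu_min: int, lam: float, terms: int = 100) -> float:
    """lam * sum_{nu=nu_min}^{terms} N^nu e^-N / nu! by explicit summation."""
    total = 0.0
    term = 1.0  # N^nu / nu!, running product to avoid overflow
    for nu in range(1, terms + 1):
        term *= N / nu
        if nu >= nu_min:
            total += term
    return lam * total * math.exp(-N)


def poisson_mean_series(mean: float, terms: int = 200) -> float:
    """sum_{nu=1}^{terms} nu * mean^nu e^-mean / nu! by explicit summation."""
    total = 0.0
    term = 1.0
    for nu in range(1, terms + 1):
        term *= mean / nu
        total += nu * term
    return total * math.exp(-mean)


def sdcs_k_integral_quad(
    W: float,
    T_MeV: float,
    M_eV: float,
    params: DrudeParameters = DrudeParameters(),
    medium: WaterMedium = WaterMedium(),
) -> float:
    """int ELF/k dk via scipy adaptive quadrature in the recoil variable.

    Splits at the Bethe-ridge resonance; relative accuracy ~1e-9.
    """
    T = T_MeV * 1e6
    E = W + medium.B_mean
    Qm = (M_eV / ME_C2_EV) * (math.sqrt(T) - math.sqrt(T - E)) ** 2
    Qp = (M_eV / ME_C2_EV) * (math.sqrt(T) + math.sqrt(T - E)) ** 2

    def f(Q):
        Ep = params.Ep0 + params.disp_coeff * Q
        elf = params.alpha * E / ((E**2 - Ep**2) ** 2 + params.gamma_w**2 * E**2)
        return elf / (2.0 * Q)

    Qr = E - params.Ep0
    pieces = sorted({Qm, Qp, *(q for q in (Qr, 10 * Qr, 1e5) if Qm < q < Qp)})
    total = 0.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign roundoff reports on wide panels
        for a, b in zip(pieces[:-1], pieces[1:]):
            total += quad(f, a, b, limit=400, epsrel=1e-10, epsabs=0)[0]
    return total


def radial_integral(rho: np.ndarray, values: np.ndarray) -> float:
    """int f(rho) 2 pi rho drho by trapezoid on the given grid."""
    return float(np.trapezoid(values * 2.0 * np.pi * rho, rho))


def mc_first_crossing_fluence(
    rho: float,
    gamma: float,
    rng: np.random.Generator,
    n_walk: int = 100_000,
    zeta_half: float = 10.0,
    mfp: float = 0.2,
    R: float = 5.75,
    half_height: float = 1.15,
    half_angle: float = 0.591,
    max_steps: int = 900,
) -> tuple[float, int]:
    """First-crossing count of the cylinder-surface patch by killed walks.

    Walkers start uniformly on the ion-path segment |zeta| <= zeta_half at
    radial offset rho, take isotropic fixed steps of length ``mfp`` with
    per-step survival e^-gamma, and terminate at their first crossing of
    the two-twist patch.  Returns (fluence estimate per unit dNe/dz,
    raw hit count) so callers can attach Poisson errors.
    """
    pos = np.zeros((n_walk, 3))
    pos[:, 0] = rho
    pos[:, 1] = rng.uniform(-zeta_half, zeta_half, n_walk)
    life = np.minimum(rng.geometric(1.0 - math.exp(-gamma), n_walk), max_steps)
    alive = np.ones(n_walk, bool)
    hits = 0
    step = 0
    while alive.any() and step < max_steps:
        step += 1
        idx = np.flatnonzero(alive)
        u = rng.normal(size=(idx.size, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        p0 = pos[idx]
        p1 = p0 + mfp * u
        s0 = np.hypot(p0[:, 0], p0[:, 1])
        s1 = np.hypot(p1[:, 0], p1[:, 1])
        crossed = (s0 - R) * (s1 - R) < 0
        if crossed.any():
            ci = np.flatnonzero(crossed)
            f = (R - s0[ci]) / (s1[ci] - s0[ci])
            pc = p0[ci] + f[:, None] * (p1[ci] - p0[ci])
            phi = np.arctan2(pc[:, 1], pc[:, 0])
            hit = (np.abs(pc[:, 2]) <= half_height) & (np.abs(phi) <= half_angle)
            hits += int(hit.sum())
            alive[idx[ci[hit]]] = False
        pos[idx] = p1
        alive[idx] &= np.linalg.norm(p1, axis=1) < 80.0
        alive[idx] &= life[idx] > step
    return hits / n_walk * 2.0 * zeta_half, hits


def mc_oh_radial_profile(
    dne: float,
    rng: np.random.Generator,
    n_walk: int = 100_000,
    t_int: float = 50.0,
    D1: float = 0.265,
    D2: float = 0.057,
    tau1: float = 0.64,
    tau2: float = 15.3,
    edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D random-walk/decay simulation of the two-generation chain.

    Electrons start on the axis; each generation diffuses with its
    coefficient and decays exponentially with its lifetime; a hydroxyl
    radical is recorded at every decay position (two second-generation
    electrons per first-generation decay, matching the model's
    convolution normalization).  Returns (bin edges, expected OH count
    per walker per radial bin) at time ``t_int``.
    """
    if edges is None:
        edges = np.linspace(0.0, 8.0, 17)
    # generation 1: decay times and positions (exact sampling: diffusion
    # displacement at the decay time is Gaussian with variance 2 D t)
    t1 = rng.exponential(tau1, n_walk)
    ok1 = t1 < t_int
    x1 = rng.normal(size=(n_walk, 2)) * np.sqrt(2.0 * D1 * t1)[:, None]
    oh_pos = [np.hypot(x1[ok1, 0], x1[ok1, 1])]
    # generation 2: two electrons per decay, starting at the decay point
    for _ in range(2):
        t2 = rng.exponential(tau2, n_walk)
        born = t1
        ok2 = ok1 & (born + t2 < t_int)
        x2 = x1 + rng.normal(size=(n_walk, 2)) * np.sqrt(2.0 * D2 * t2)[:, None]
        oh_pos.append(np.hypot(x2[ok2, 0], x2[ok2, 1]))
    r = np.concatenate(oh_pos)
    counts, _ = np.histogram(r, bins=edges)
    return edges, counts / n_walk * dne
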