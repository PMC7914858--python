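# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, and — importantly — the
places where the implemented equations provably cannot reproduce
behaviour claimed for the original formulation, so that users know what
the package's outputs do and do not establish.

## Track structure (dielectric formalism)

Liquid water stands in for tissue.  Its energy-loss function is a
single-Drude fit to the measured optical limit
(α = 3856.3 eV³, E_p(0) = 23.192 eV, γ_w = 14.811 eV), extended to
finite momentum transfer by the Ritchie–Howie dispersion with unit
dispersion coefficient.  The macroscopic SDCS for a heavy charged
projectile is

    dΛ/dW = e² M Z_eff² / (2π T ħ²) · ∫_{k−}^{k+} Im[−1/ε](k, W+B) dk/k,

with B = 18.13 eV the mean outer-shell binding energy and
k± = (√(2MT) ± √(2M(T−E)))/ħc the non-relativistic kinematic limits.
The ELF is a *macroscopic* medium property (the Drude fit absorbs the
molecular density), so no separate density factor multiplies the
formula; the resulting Λ(T) for carbon peaks at ≈ 0.5 Å⁻¹ near
0.25 MeV/u, the expected scale.  β entering Z_eff is computed
relativistically; the kinematics of the integration limits are not —
adequate below a few hundred MeV/u, and consistent with the rest of the
model.

Internal units are eV/nm/fs (the parameters are printed in them); a
`UnitSystem` abstraction lets the test suite re-run the cross sections
in Å-based bookkeeping and verify 10⁻⁶-level invariance.

**Numerics.**  Substituting the recoil energy Q = (ħk)²/2mₑ makes the
k-integral dimensionless with integrable 1/Q weight and a Bethe-ridge
resonance at Q ≈ E − E_p(0) of width ~γ_w.  Three log-scale
Gauss–Legendre panels (48/96/32 nodes, split at the ridge, tail cut
where the integrand has fallen as Q⁻⁵ to negligible size) reproduce
adaptive quadrature to ≲ 10⁻⁴ relative.  W-moments (Λ, W̄, ionization
stopping) use a 300-point log W grid and trapezoids; doubling the grid
moves Λ by < 0.1%.  W̄(T) has its maximum inside a decade of the Λ(T)
peak for every studied ion; the implementation's "peak-region" scan is
one decade either side of the TICS maximum.

## Stopping tables and the S_e ↔ T mapping

The damage pipeline needs the ion energy T behind a quoted LET.  Users
supply a measured table (`T_MeV,Se_keV_um` CSV, strictly increasing T,
one Bragg maximum; log–log-linear interpolation; branch-wise inversion
with the distal high-energy branch as default, matching therapy
usage).  Self-contained runs use a synthetic table.

The synthetic generator's default is the relativistic Bethe formula for
water (I = 78 eV, unit density) with the same Barkas effective charge,
which gives ≈ 650 keV/μm for carbon at 1 MeV/u and a Bragg maximum of
≈ 770 keV/μm — realistic magnitudes covering the full 10–500 keV/μm
carbon scan.  The alternative `model="ionization"` uses the
single-Drude ionization-only first moment N∫(W+B)(dσ/dW)dW, which is
self-consistent with the cross-section module but roughly 3× below
total electronic stopping (no excitation channel, soft Drude tail) and
tops out near 280 keV/μm for carbon; it is retained for studies of the
model's internal consistency, not as a stopping reference.  This choice
of default is the package's own: a mapping that cannot reach the
published LET range would make LET scans meaningless.

## Radical stage

All secondary electrons start on the track axis (the point source is
the initial condition of the first generation, not a separate radical
term — the dimensionally consistent reading).  First generation:
closed-form 2-D Gaussian × e^(−t/τ₁).  Second generation: the printed
time convolution, whose prefactor corresponds to two second-generation
electrons per first-generation capture; the Monte-Carlo oracle in the
test suite confirms the implemented profile is exactly the law of that
branching-diffusion process.  OH• production integrates both decay
channels to t_int = 50 fs.  The 0–10 nm average is area-weighted
(2πρ dρ), matching its later use as a surface density.  The density
diverges logarithmically on the axis; profiles are evaluated from
0.01 nm outward and the average closes the ρ→0 end analytically
(ρ·n → 0).  Hypoxia does not act here; the factor ½ is applied to the
radical lesion count downstream.

## Target fluence

The target is two DNA twists, 2.3 × 6.8 nm² (15.64 nm²), on a histone
cylinder of radius R = 5.75 nm perpendicular to the track (other
orientations change results little and are not implemented).  Electron
transport is an isotropic fixed-step walk, step l = 0.2 nm (literature
corridor 0.1–0.45 nm), attenuated per step by e^(−γk):
γ = 10⁻⁴ keeps every electron above the water ionization threshold in
play, γ = 10⁻² only those above the ~17.5 eV strand-break threshold
(then Γ_SSB = 1).

The step-summed kernel K(r) = ∫_{r/l}^∞ (r²/k)(3/(2πkl²))^{3/2}
exp(−3r²/(2kl²) − γk) dk is tabulated on a log grid (60 points/decade)
and spline-interpolated; the geometric factor multiplying it is the
flux-projection cosine |R − ρcosφ − ζsinφ|/r.  The absolute value is a
deliberate choice: the printed signed expression is negative on the
entire visible arc for outside emission points, so a convention is
unavoidable.  For emission points inside the cylinder radius
(√(ρ²+ζ²) < R), where the visible-arc limits are undefined, the full
patch is used.  The azimuthal limits clip to the arc visible from the
emission point; the ζ-integrand switches branch where the emission
point crosses the cylinder radius, and the quadrature panels split
there (without the split, Gauss nodes straddle the kink and the result
oscillates by ~10%).  Cutoffs: ζ ∈ [−60, 60] nm and a k-cut where both
the attenuation and the Gaussian weight are < 10⁻¹² of peak; doubling
either moves F_e by < 0.5%.

**Fluence vs first-passage.**  The kernel is a diffusive *flux* count.
Asymptotically it scales as r^(−1/2)e^(−νr) (ν = √(6γ)/l), whereas the
probability that a killed walk *first* reaches a small target at
distance r scales as r^(−1)e^(−νr).  Both decay constants are measured
to agree in the test suite's Monte-Carlo oracle, but the ~√r prefactor
mismatch means the first-crossing oracle and the implemented formula
differ systematically in shape (a factor ~2 across ρ = 8–11 nm at
γ = 10⁻²).  The formula is the model; the oracle test documents the
discrepancy and fails at its stated 3σ band — retained deliberately as
a red flag rather than weakened.

## Damage calculus and survival

P(N) = λ·P[Pois(N) ≥ 3] with λ = 0.15 (SSB→DSB conversion, corridor
0.1–0.2), evaluated as λ·Q(3, N) via the regularized incomplete gamma
function (exact; the test suite checks it against brute-force series to
10⁻¹²).  The complexity threshold is locked at ν = 3 (a DSB plus two
further lesions): lower orders count readily repaired damage and ν = 4
discards lethal clusters, so other values are rejected at validation.
Radical lesions N_r = N_rk·15.64·Γ_r,SSB within 10 nm of the track
(N_rk ≤ 15×10⁻³ nm⁻², Γ_r,SSB = 0.13), halved under hypoxia — the only
oxygen dependence in the model.  The lethal yield integrates P_l inside
10 nm and the electron-only P_e outside, extending the outer radius in
doublings until the tail adds < 0.1% (cap 200 nm); the F_e interpolant
uses a fixed 48-point log grid so truncation studies do not move the
nodes.

Survival: Y_c = (dN_l/dζ)·(πD_n/4)·N_ion with
N_ion = A_n·10⁶·10⁻²⁴·d/(S_e·1.6·10⁻¹⁹) at unit water density; the
traversal-number series collapses exactly to the Poisson mean, making
ln S linear in dose through the origin, with d10 = ln10/slope computed
analytically (a bisection cross-check runs in the tests).  D_n is
derived from A_n via a circular cross-section when not supplied.  OER
reduces to the inverse yield ratio; RBE requires an experimental X-ray
d10 — the model never predicts photon response.  The RBE-peak locator
uses the exact factorization RBE ∝ (dN_l/dζ)/S_e, making the peak
position independent of A_n, N_g and the reference.

## What the implemented equations do and do not reproduce

With the parameters above, carbon at 140 keV/μm gives d10 ≈ 2.9 Gy for
a 172 μm², 3.2 Gbp nucleus — the experimentally sensible scale — and
OER declines monotonically toward 1 with increasing LET.  However, in
this regime the electron lesion count N_e = Γ_SSB·F_e stays well below
the cluster threshold ν = 3 at every LET in the 10–500 keV/μm scan, so
the lethality probability sits in its ~N³ growth regime.  Three
consequences follow necessarily, and the acceptance suite reports them
as failures rather than hiding them:

- the two (γ, Γ_SSB) variants differ by orders of magnitude in lethal
  yield instead of agreeing within 10%;
- the yield is strongly (roughly cubically) sensitive to Γ_SSB across
  10⁻⁴–8×10⁻², not insensitive;
- (dN_l/dζ)/S_e rises monotonically over 10–500 keV/μm, so the
  RBE-proportional maximum sits at the scan edge rather than near
  140 keV/μm (an overkill turnover exists, but only beyond the physical
  carbon LET range).

Conversely, making F_e large enough to saturate the cluster threshold
would push d10 to the millagray scale for any radially flat fluence
profile — the published sensitivity claims would require a fluence
decaying on ~1 nm, which no normalization of the implemented kernel
(attenuation length l/√(6γ) ≈ 8 nm at γ = 10⁻⁴) can produce.  These
claims are therefore treated as unreachable by this formulation as
printed, not as targets to be tuned toward.

## Synthetic data and scope

The package generates every input it needs: stopping tables come from
closed-form physics (Bethe or the model's own first moment), not from
bundled measurements, so absolute stopping values carry those models'
known biases (Bethe: no shell/Barkas corrections below ~0.3 MeV/u).
Passing tests establish internal consistency of the pipeline and
agreement with its own oracles — not agreement with measured survival
data, which would require experimental stopping tables and reference
d10 values supplied by the user.  Dose fractionation, DNA repair
kinetics, shock-wave transport, δ-electrons (> 100 eV), bystander
effects and photon response are out of scope.
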