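# iondamage

Predicting clonogenic cell survival for ion irradiation from first
principles is a central problem of hadron-therapy planning and space
radiation protection: the relative biological effectiveness (RBE) of a
carbon or iron beam changes several-fold along its range, and empirical
dose-response fits (the linear-quadratic model) carry no information
about *why*.  `iondamage` implements a forward mechanistic pipeline that
needs only three physical inputs — the ion's LET (or kinetic energy) and
two cell parameters, the nucleus cross-sectional area A_n and the genome
size N_g — and produces complex-DNA-damage yields, survival curves, d10
doses, OER and RBE for ions from protons to ⁵⁶Fe in liquid water.

It is a library plus a thin CLI, aimed at radiation biophysicists who
want a transparent, fully inspectable implementation of each stage.

## The model

1. **Track structure.**  The liquid-water energy-loss function is a
   single Drude oscillator, Im[−1/ε](k,E) = αE/([E²−E_p(k)²]² + γ_w²E²)
   with Ritchie–Howie dispersion E_p(k) = E_p(0) + ħ²k²/2mₑ.  The
   macroscopic singly-differential ionization cross section of an ion
   (mass M, kinetic energy T, Barkas effective charge Z_eff(β)) is

       dΛ/dW = e²·M·Z_eff²/(2π T ħ²) ∫_{k−}^{k+} Im[−1/ε](k, W+B) dk/k ,

   whose moments give the electron source density dN_e/dζ = Λ(T) (nm⁻¹)
   and the mean ejected-electron energy W̄(T) < 45 eV.
2. **Radiolysis.**  Two generations of sub-50-eV electrons diffuse
   cylindrically (D₁ = 0.265, D₂ = 0.057 nm²/fs; lifetimes 0.64 and
   15.3 fs); each capture seeds one OH• radical.  Integrating the decay
   channels to 50 fs gives the initial OH• radial density, averaged over
   the 0–10 nm cylinder where the radicals act.
3. **Target fluence.**  Electrons random-walk (step 0.2 nm, attenuation
   e^(−γk)) onto a two-DNA-twist target (2.3 × 6.8 nm², area 15.64 nm²)
   wrapped on a histone cylinder of radius 5.75 nm, giving the fluence
   F_e(ρ) per ion at radial distance ρ from the path.
4. **Damage calculus.**  Lesion counts N_e = Γ_SSB·F_e and
   N_r = N_rk·area·Γ_r,SSB (radicals, within 10 nm; halved under
   hypoxia) feed a Poisson cluster model: a site is potentially lethal
   with probability λ·P[Pois(N) ≥ 3] (a DSB plus at least two further
   lesions within two DNA twists).  Radial integration yields the lethal
   yield per track length dN_l/dζ.
5. **Survival.**  With N_ion = A_n·d/S_e traversals per nucleus and mean
   chord πD_n/4, the expected lethal lesions are
   Y_c = (dN_l/dζ)·(πD_n/4)·N_ion and survival is S = e^(−Y_c) — exactly
   linear ln S vs dose.  d10, OER = d10_hypoxic/d10_normoxic and
   RBE = d10_X-ray/d10_ion follow analytically.

Two published variants are supported: (γ = 10⁻⁴, Γ_SSB = 0.03) and
(γ = 10⁻², Γ_SSB = 1).  See `docs/methods.md` for assumptions, numerics
and known limitations — including a quantitative analysis of where this
implementation's behaviour departs from claims made for the original
formulation.

## Worked example

Generate a self-contained carbon stopping table (Bethe + effective
charge; or convert an ICRU/SRIM export to the same two-column CSV), then
run a survival prediction for a normal human fibroblast:

```bash
iondamage fixtures --ion 12C -o carbon_stopping.csv
# wrote 60 rows to carbon_stopping.csv (Bragg max 768.4 keV/um at 4.053 MeV)

cat > run.yaml <<'YAML'
cell: {name: NB1RGB, An_um2: 172.3, Ng_bp: 3.2e9}
ion: {name: 12C}
exposure: {Se_keV_um: 140.0, doses_Gy: [0.0, 1.0, 2.0, 4.0], oxygen: normoxic}
model: {gamma: 1.0e-4}
paths: {stopping_table: carbon_stopping.csv, output_dir: out}
YAML

iondamage survive run.yaml
```

prints

```json
{
  "Se_keV_um": 140.0,
  "cell": "NB1RGB",
  "d10_Gy": 2.9231476990425986,
  "gamma": 0.0001,
  "ion": "12C",
  "oxygen": "normoxic"
}
```

i.e. 10% of these cells survive 2.92 Gy of 140 keV/μm carbon ions, and
`out/survival.csv` holds the strictly linear ln S curve
(`lnS = -0.788·d`).  The oxygen effect and the biological effectiveness
at the same LET (the X-ray reference d10 is an experimental input — the
model has no photon mode):

```bash
iondamage oer --ion 12C --se 140 --table carbon_stopping.csv
# OER(10%) = 1.2579
iondamage rbe --ion 12C --se 140 --xray-d10 5.0 --table carbon_stopping.csv
# RBE(10%) = 1.7105
```

`iondamage xsec / radicals / fluence / scan` export the intermediate
stages (cross-section tables, OH• profiles, F_e(ρ), LET scans) as CSV.

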