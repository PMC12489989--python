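# Methods

## Model

### Nonlocal dielectric response

The solvent is described in linear response by a longitudinal,
wavevector-dependent dielectric function

    ε(k) = 1 / [ 1/ε* − (1/ε* − 1/ε) F̃(k) ],

which interpolates between the macroscopic constant ε at k→0 and the
short-range (electronic/IR) constant ε* at k→∞. The structure factor is a
hybrid of two correlation channels,

    F̃(k) = γ/(1+Λ1²k²)
          + (1−γ)(1+Λ2²Q²)² / [(1+Λ2²(k−Q)²)(1+Λ2²(k+Q)²)] ,

with a Lorentzian channel (purely exponential polarization correlations,
decay length Λ1) and an oscillatory channel (decaying oscillating
correlations, decay Λ2, period Λo = 2π/Q), mixed by γ ∈ [0,1]. The
numerator constant of the oscillatory channel is chosen as (1+Λ2²Q²)² so
that F̃(0) = 1 *exactly*; any other normalization breaks the physical
requirement ε(0) = ε. Where F̃ exceeds (1/ε*)/(1/ε*−1/ε), ε(k) is negative:
the overscreening regime. At the sign-change poles the code returns signed
infinities (never NaN) so that root scans across the pole remain usable.

Electrolyte enters through the interpolation ε_c(k) = ε(k)(1+κ²/k²), valid
when the Debye length κ⁻¹ is large compared to Λ1, Λ2 and Λo. Consistently
with that assumption, the propagator refuses κ ≥ 1/Λ1 (≈0.27 Å⁻¹, i.e.
molar-range salt) rather than extrapolate. A stability scan (`dkm_check`)
verifies ε_c(k) ∉ (0, 1] on a dense grid up to 20 Å⁻¹.

Parameter defaults (preset `tip3p`): ε = 94, ε* = 5.75, Λ1 = 3.67 Å,
Λ2 = 1.77 Å, Λo = 2.13 Å, γ = 0.05 — the parametrization of the rigid
three-site water model used by the companion simulations. ε* is treated
strictly as an input; a second preset with ε* → 1 is shipped for
bare-spectrum illustrations. κ is computed in Gaussian units,
κ² = 4π λ_B Σ nᵢzᵢ², λ_B = e²/(ε k_BT), with e² = 332.06 kcal mol⁻¹ Å and
k_BT(300 K) = 0.5961 kcal/mol; 0.154 M 1:1 salt gives κ = 0.118 Å⁻¹.

### Ion models

The hard Born sphere localizes Ze on a shell of radius a
(ρ̃ = Ze sin(ka)/(ka)); the smeared Born sphere spreads it as
exp(−|r−a|/η), normalized by N = 1/[2η(a²+η²(2−e^{−a/η}))]. The potential
is the spherical inverse transform φ(r) = (2/π)∫ sinc(kr) ρ̃(k)/ε_c(k) dk
and the hydration energy W = (1/π)∫ ρ̃²(1−1/ε(k)) dk. Both assume the
*embedded-charge approximation* (solvent penetrates the charge
distribution) and pure linear response, so values within one water
diameter (≈2.5 Å) of the charge shell are flagged "near-field caution" in
every output — reported, never censored. The hard shell combined with
overscreening produces a documented sign-inversion artefact of S(r) very
close to the surface; smearing with η ≈ 0.4 Å (default; each ion really
has its own η) suppresses it and lowers W toward experimental values.

### Helical charge model

All charge motifs are surface densities on coaxial cylinders obeying ideal
helical symmetry σ(z,ϕ) = σ(z+z′, ϕ+gz′), g = 2π/H. After Fourier
reduction each motif ν is a cosine series in the helical phase ϕ−gz with
real amplitudes A_ν(n):

* phosphates: A = σ̄ e^{−½n²g²Δeff²} cos(nϕ_s/2) — the Gaussian form
  factor absorbs finite group size and thermal/static disorder, the cosine
  is two-strand interference set by the minor-groove width ϕ_s;
* counterions: A = −Θσ̄ [f₁e^{−½n²g²δz₁²} + f₂(−1)ⁿe^{−½n²g²δz₂²}], the
  (−1)ⁿ encoding the half-pitch offset of the major groove. Optional
  on-strand (2f₃cos(nϕ_s/2)e^{−½n²g²δz₃²}) and uniform (f₄, n=0 only)
  sites extend the two-groove pattern; they are an implementation
  extension derived by the same Fourier steps;
* bound water ("spine of hydration"): a radial polarization density P̄₀ in
  the grooves whose surface bound charge enters the potential with
  opposite sign (ρ_b = −σ_b δ(r−a_w)).

σ̄ is stored signed (negative for DNA, default −16.3 μC/cm²; the geometric
estimate 2e/3.4 Å on a 10 Å cylinder gives ≈15 μC/cm² — the radius
convention behind the printed 16.3 is not resolvable, so σ̄ stays an
input). Θ ∈ [0,1] so the counterion density −Θσ̄ is positive. Defaults
follow the reference parameter set: H = 34 Å, ϕ_s = 2.2 rad (the 0.8π
value quoted elsewhere is documented but not the default), a_DNA = 10 Å,
Δeff = 0.25 Å, δa_DNA = 0.5 Å; Θ = 0.1, f₁ = 0.1, f₂ = 0.9,
δz = 0.75 Å, a_CC = 6 Å; P̄₀ = −8 μC/cm², w₁ = 1, w₂ = 0.75, a_W = 5 Å.

### Propagator and fields

Each harmonic propagates radially through

    W_n(R; a, κ) = ∫₀^∞ dK K J_n(KR)J_n(Ka) / [ε(√(K²+n²g²)) (K²+n²g²+κ²)].

Because ε(k) is rational in k², the integral evaluates by residues into
three channels (R > a; swap arguments otherwise):

    W_n = g̃κ K_n(κ̃n R) I_n(κ̃n a) + γ g̃L K_n(q̃d1n R) I_n(q̃d1n a)
        + (1−γ) Re[ g̃o H⁽²⁾_n(g̃n R) J_n(g̃n a) ],

with κ̃n = √(κ²+n²g²) (ionic), q̃d1n = √(1/Λ1²+n²g²) (Lorentzian, always
faster-decaying than the ionic channel), and g̃n = g̃nR − i g̃nI =
√((Q−i/Λ2)²−n²g²) (oscillatory; → Q−i/Λ2 as n→0). The weights follow from
the partial fractions:

    g̃κ = 1/ε(k)|_{k²=−κ²}      (→ 1/ε as κ→0),
    g̃L = (1/ε*−1/ε)/(1−Λ1²κ²),
    g̃o = −π(1/ε*−1/ε)(1+Λ2²Q²)² / [4QΛ2³((Q−i/Λ2)²+κ²)].

These coefficients were derived here by residue calculus and are *not*
taken on trust: the defining integral is evaluated numerically (composite
Gauss–Legendre on half-period panels with the 1/ε* part done analytically
through the textbook identity ∫K J_nJ_n/(K²+m²)dK = I_nK_n, plus a fine
panel zone resolving the Debye peak at K≈κ̃n) and the closed form must
match it to 1e-5 relative across n ≤ 10, a ∈ {5,6,10} Å, R−a ∈ [1,40] Å,
κ ∈ {0, 0.05, 0.118} Å⁻¹. Where the kernel is exponentially small
(|W| < 1e-9; e.g. n = 10, R−a = 40, values ~e^{−70}) float64 quadrature is
cancellation-limited and cannot certify a relative comparison at any
truncation; those corners are validated instead against an mpmath
arbitrary-precision quadrature (independent scheme and arithmetic) at
spot points. Complex Bessel/Hankel products use exponentially scaled
routines throughout, so no overflow occurs for any n·R in range.

The potential assembles as
φ = Σ_ν Σ_n 8π a_ν A_ν(n)/(1+δ_{n0}) cos(n(ϕ−gz)) W_n(R; a_ν, κ).
The 1/(1+δ_{n0}) half-weight of n=0 is fixed by requiring the
homogeneous-cylinder limit to reproduce the Debye–Hückel result
4πσ̄a I₀(κa)K₀(κR)/ε, which in turn →(2λ/ε)K₀(κR) for a thin line; any
alternative reading fails that limit. For κ=0 the n=0 term diverges
logarithmically (a charged cylinder in pure dielectric), so
`potential_total` raises and directs callers to the field/charge routines,
which stay finite: the κ→0 ionic-channel limits are taken analytically
(the radial kernel derivative → −g̃κ/R outside the shell, 0 inside; the
charge kernel → 0).

E = −∇φ uses termwise analytic Bessel derivative identities (cross-checked
against central differences at 1e-4 relative). The charge density follows
from Δφ = −4πϱ per mode: each residue channel is multiplied by the value
of (K²+n²g²) at its pole (−κ², −1/Λ1², (Q−i/Λ2)²), plus a contact term
(1/ε*−1)·(source density) representing the instantaneous short-range
compensation at the source location. `subtract_source=True` (default)
reports induced charge only; with `False` the total integrates to zero
over a large cylinder when κ > 0 — the electroneutrality identity
λ[1 + (1/ε*−1) − 1/ε*] = 0 holds analytically channel by channel and is
verified numerically to 1e-4.

### Radial smearing

Each shell radius is smeared with the truncated, renormalized Gaussian
ζ(a−ā, δa) = √(2/π) e^{−(a−ā)²/(2δa²)}/[δa(1+erf(ā/(√2δa)))] (unit mass on
a > 0), applied as φ̄ = ∫da ζ φ(·; a) by 24-node Gauss–Legendre on ā±5δa.
The shell prefactor a rides inside the smearing integral, so the smeared
n=0 far field corresponds to the ζ-weighted line charge. Sign bookkeeping
lives exclusively in the amplitude prefactors; the kernel is applied with
weight +1 (equivalent to carrying a per-motif sign in the kernel, but not
double-counting it). δa = 0 is the exact identity. Smearing strictly
damps the overscreening oscillation amplitudes, monotonically in δa.

### Screening regimes

Since K_n(x) ~ e^{−x}/√x, profiles are analyzed via the local decay
exponent λ_loc(R) = −d ln(f√R)/dR estimated by linear regression in 5 Å
sliding windows. Regime identification matches λ_loc against κ̃₁ = √(κ²+g²)
and κ within 10% (boundaries at the tolerance crossings, tie-broken
outward); whatever precedes the first match is the oscillatory interfacial
zone, and absent regimes are reported as absent. The two-regime fit
c(R) = A K₁(κ̃₁R) + B K₀(κR) is ordinary least squares in (A, B) — the
model is linear in its prefactors, so no log-space transform is used
(log-space residuals are available for diagnostics); an ill-conditioned
basis (window too narrow to separate the two decays) raises. For
concentration-like inputs the CLI subtracts the far-field mean (bulk
level) before fitting by default, exposed as `--baseline/--no-baseline`
since the choice is a convention.

With the default parameter set the computed potential shows the
renormalized-slope window at roughly 14–18 Å from the axis and plain Debye
decay (slope within 1% of κ) beyond ~42 Å. The n=0 (net-charge) term
dominates the tail beyond ~20 Å, so the renormalized regime does not
extend over 25–40 Å for these parameters; the regime *ordering*
(oscillatory → renormalized → Debye) is robust and is what the tests
assert quantitatively.

## Numerical choices

* Harmonic truncation: amplitudes fall off both through the Gaussian form
  factors and the Bessel ratio (a/R)ⁿ. With the default Δeff = 0.25 Å the
  form factor alone decays slowly, so the default cutoff is n_max = 50,
  for which doubling n_max changes the potential by < 1e-6 relative at
  R ≥ a+2 Å (measured: 1.7e-4 at n_max = 20, 8e-7 at 50);
  `harmonic_convergence` reports the tail estimate for other settings.
* Ion-potential quadrature: the 1/ε* baseline is evaluated analytically in
  real space (Gauss's law), leaving integrands that decay as k⁻⁴ and are
  integrated by vectorized composite Gauss–Legendre on half-period panels
  to k = 80 Å⁻¹.
* Propagator quadrature tail: beyond K_max (default 240 Å⁻¹) the truncated
  tail is bounded analytically by the envelope of the correction integrand;
  the bound and the float64 cancellation floor are reported in the
  diagnostics and can be escalated to an exception via `rtol_certify`.
* The synthetic-profile generator applies multiplicative Gaussian noise
  with a fixed seed (`numpy.random.default_rng`), making every fit test
  deterministic.
* Test problem sizes (grid densities, replicate counts, map sizes) are
  chosen so the full suite exercises every code path at interactive
  runtimes; all physical parameters are the defaults above.

## What the synthetic data do and do not show

Fit validation uses profiles generated from the two-Bessel-tail model plus
multiplicative noise. They emulate the radial decay structure and noise
level of z-averaged ion-concentration or potential profiles, but not
nonlinear ion correlations, dielectric saturation, sequence-dependent
helical distortions, or finite-box artefacts of simulated data. Passing
the recovery tests therefore demonstrates the estimator's correctness and
conditioning, not the physical accuracy of linear response for any
particular electrolyte.

## Known limitations

* Linear response and embedded charges: no excluded volume for the helix
  (no low-dielectric core) and no nonlinear Poisson–Boltzmann response;
  near-field values (within ≈2.5 Å of a charged surface) are flagged.
* The electrolyte interpolation requires scale separation κΛ1 < 1; the
  code refuses molar-range κ.
* The bound-water motif is a single polarization layer; its n=0 content
  carries net surface charge by construction of the model.
* No frequency dependence, no transverse dielectric tensor, no fitting of
  ε(k) to new simulation data (parameters are inputs).
* The uniform counterion fraction f₄ contributes only to n=0; its printed
  normalization in the source material is ambiguous beyond that term.
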