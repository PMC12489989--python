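"""Helical surface-charge model: phosphate strands, condensed counterions,
and the bound-water "spine" as per-harmonic Fourier amplitudes.

An ideal double helix with pitch H has the symmetry σ(z,ϕ) = σ(z+z', ϕ+gz')
for any z', with g = 2π/H.  Every surface-charge contribution ν placed on a
cylinder of radius a_ν therefore reduces, after the Fourier comb δ(q+ng)
collapses the axial wavevector, to a cosine series in the helical phase
(ϕ − gz):

    σ_ν(z,ϕ) = Σ_{n≥0} [2/(1+δ_{n0})] A_ν(n) cos(n(ϕ − gz)),

and the whole electrostatic problem is specified by the real amplitudes
A_ν(n) produced here:

  * phosphates:   A(n) = σ̄ ψ̃(n) cos(nϕ_s/2), with the Gaussian form factor
    ψ̃(n) = exp(−½ n²g²Δ_eff²) encoding finite group size and thermal or
    static disorder (Debye–Waller-like), and the two-strand interference
    factor cos(nϕ_s/2) set by the minor-groove width ϕ_s;
  * condensed counterions:  A(n) = −Θσ̄ [f₁ e^{−½n²g²δz₁²}
    + f₂(−1)ⁿ e^{−½n²g²δz₂²} + …], the (−1)ⁿ encoding the half-pitch offset
    of the major groove; Θ is the compensated charge fraction;
  * bound water:  A(n) = P̄₀ [w₁ e^{−½n²g²δz_{w1}²} + w₂(−1)ⁿ e^{−…}],
    a radial polarization density whose surface bound charge enters the
    potential with opposite sign (ρ_b = −σ_b δ(r−a_w)).

σ̄ is stored signed (negative for DNA phosphates).  Densities are entered in
μC/cm² (the conventional unit for DNA's mean surface charge, ≈ −16.3 μC/cm²)
and converted to e/Å² internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .units import surface_density_to_e_A2

__all__ = [
    "HelixGeometry",
    "PhosphatePattern",
    "CounterionPattern",
    "BoundWaterPattern",
    "HarmonicAmplitude",
    "HelixChargeModel",
    "form_factor",
    "phosphate_harmonic",
    "counterion_harmonic",
    "bound_water_harmonic",
    "default_dna_model",
]


@dataclass(frozen=True)
class HelixGeometry:
    """Ideal double-helix geometry.

    pitch H in Å (34 for B-DNA), rise per base pair (metadata), azimuthal
    minor-groove width ϕ_s in rad, number of strands.  Strand j sits at
    phase ϕ_j = ∓ϕ_s/2 relative to the minor-groove center (z=0, ϕ=0).
    """

    pitch: float = 34.0
    rise: float = 3.4
    phi_s: float = 2.2
    n_strands: int = 2

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if not 0 < self.phi_s < 2 * np.pi:
            raise ValueError("phi_s must lie in (0, 2π)")

    @property
    def g(self) -> float:
        """Reciprocal pitch g = 2π/H in Å⁻¹."""
        return 2.0 * np.pi / self.pitch


@dataclass(frozen=True)
class PhosphatePattern:
    """Fixed backbone charge: mean density σ̄ (μC/cm², signed, negative for
    DNA), effective axial half-width Δ_eff (Å) of the Gaussian form factor,
    strand radius and radial smearing half-width (Å)."""

    sigma_bar: float = -16.3
    delta_eff: float = 0.25
    radius: float = 10.0
    delta_a: float = 0.5

    def __post_init__(self) -> None:
        if self.delta_eff < 0 or self.delta_a < 0:
            raise ValueError("widths must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @property
    def sigma_e_A2(self) -> float:
        return surface_density_to_e_A2(self.sigma_bar)


@dataclass(frozen=True)
class CounterionPattern:
    """Condensed counterions: compensation fraction Θ and site fractions.

    f1 minor groove, f2 major groove, f3 on-strand (optional extension),
    f4 uniform (optional extension); Σf = 1.  δz are the Gaussian axial
    half-widths of each site.
    """

    theta: float = 0.1
    f1: float = 0.1
    f2: float = 0.9
    f3: float = 0.0
    f4: float = 0.0
    dz1: float = 0.75
    dz2: float = 0.75
    dz3: float = 0.75
    radius: float = 6.0
    delta_a: float = 0.75

    def __post_init__(self) -> None:
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must lie in [0, 1]")
        total = self.f1 + self.f2 + self.f3 + self.f4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site fractions must sum to 1 (got {total})")
        if min(self.dz1, self.dz2, self.dz3, self.delta_a) < 0:
            raise ValueError("widths must be >= 0")


@dataclass(frozen=True)
class BoundWaterPattern:
    """Bound-water spine: mean radial polarization density P̄₀ (μC/cm²,
    signed; negative when hydrogens point inward), groove fractions w1/w2
    and their axial half-widths, radius and radial half-width (Å)."""

    p0: float = -8.0
    w1: float = 1.0
    w2: float = 0.75
    dzw1: float = 0.75
    dzw2: float = 0.75
    radius: float = 5.0
    delta_a: float = 0.75

    def __post_init__(self) -> None:
        if min(self.dzw1, self.dzw2, self.delta_a) < 0:
            raise ValueError("widths must be >= 0")

    @property
    def p0_e_A2(self) -> float:
        return surface_density_to_e_A2(self.p0)


@dataclass(frozen=True)
class HarmonicAmplitude:
    """One contribution's harmonic: A(n) multiplying cos(n(ϕ−gz)).

    ``sigma_amp`` is the surface-density amplitude (e/Å²); ``potential_amp``
    is what enters the potential (bound charge flips sign).  ``kind`` is
    "free" or "bound".
    """

    name: str
    n: int
    sigma_amp: float
    radius: float
    delta_a: float
    kind: str

    @property
    def potential_amp(self) -> float:
        return self.sigma_amp if self.kind == "free" else -self.sigma_amp


def form_factor(n: int, pattern: PhosphatePattern, geom: HelixGeometry) -> float:
    """Gaussian form factor ψ̃(n) = exp(−½ n²g²Δ_eff²); 1 at n=0."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(np.exp(-0.5 * n**2 * geom.g**2 * pattern.delta_eff**2))


def phosphate_harmonic(n: int, pattern: PhosphatePattern,
                       geom: HelixGeometry) -> HarmonicAmplitude:
    """A(n) = σ̄ ψ̃(n) cos(nϕ_s/2); vanishes for odd n when ϕ_s = π."""
    amp = pattern.sigma_e_A2 * form_factor(n, pattern, geom) * np.cos(
        n * geom.phi_s / 2.0
    )
    return HarmonicAmplitude("phosphates", n, float(amp), pattern.radius,
                             pattern.delta_a, "free")


def counterion_harmonic(n: int, pattern: CounterionPattern,
                        geom: HelixGeometry,
                        sigma_bar_e_A2: float) -> HarmonicAmplitude:
    """A(n) = −Θσ̄ [f1 e^{−½n²g²δz1²} + f2(−1)ⁿ e^{−½n²g²δz2²} + ext.].

    The f3 (on-strand, 2f3 cos(nϕ_s/2) e^{−½n²g²δz3²}) and f4 (uniform,
    n=0 only) terms are optional extensions of the two-groove pattern.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    g2 = (n * geom.g) ** 2
    series = (pattern.f1 * np.exp(-0.5 * g2 * pattern.dz1**2)
              + pattern.f2 * (-1.0) ** n * np.exp(-0.5 * g2 * pattern.dz2**2))
    if pattern.f3:
        series += 2.0 * pattern.f3 * np.cos(n * geom.phi_s / 2.0) \
            * np.exp(-0.5 * g2 * pattern.dz3**2)
    if pattern.f4 and n == 0:
        series += pattern.f4
    amp = -pattern.theta * sigma_bar_e_A2 * series
    return HarmonicAmplitude("counterions", n, float(amp), pattern.radius,
                             pattern.delta_a, "free")


def bound_water_harmonic(n: int, pattern: BoundWaterPattern,
                         geom: HelixGeometry) -> HarmonicAmplitude:
    """σ_b harmonic of the water spine; enters φ with the bound-charge sign."""
    if n < 0:
        raise ValueError("n must be >= 0")
    g2 = (n * geom.g) ** 2
    series = (pattern.w1 * np.exp(-0.5 * g2 * pattern.dzw1**2)
              + pattern.w2 * (-1.0) ** n * np.exp(-0.5 * g2 * pattern.dzw2**2))
    amp = pattern.p0_e_A2 * series
    return HarmonicAmplitude("bound_water", n, float(amp), pattern.radius,
                             pattern.delta_a, "bound")


@dataclass
class HelixChargeModel:
    """Complete helical charge model: geometry + the three charge motifs.

    Counterion and bound-water contributions may be omitted (None).
    """

    geometry: HelixGeometry = field(default_factory=HelixGeometry)
    phosphates: PhosphatePattern = field(default_factory=PhosphatePattern)
    counterions: CounterionPattern | None = field(default_factory=CounterionPattern)
    bound_water: BoundWaterPattern | None = field(default_factory=BoundWaterPattern)

    def harmonics(self, n: int) -> Iterator[HarmonicAmplitude]:
        """Yield the HarmonicAmplitude of each active contribution at order n."""
        yield phosphate_harmonic(n, self.phosphates, self.geometry)
        if self.counterions is not None:
            yield counterion_harmonic(n, self.counterions, self.geometry,
                                      self.phosphates.sigma_e_A2)
        if self.bound_water is not None:
            yield bound_water_harmonic(n, self.bound_water, self.geometry)

    def reconstruct_sigma(self, z, phi, n_max: int = 40,
                          contribution: str | None = None):
        """Surface charge density σ(z, ϕ) in e/Å² rebuilt from the harmonics.

        Broadcasts over ``z`` and ``phi``.  ``contribution`` selects one
        motif by name; the default sums free charge and bound charge with
        their physical surface-density signs.
        """
        z = np.asarray(z, dtype=float)
        phi = np.asarray(phi, dtype=float)
        phase = phi - self.geometry.g * z
        total = np.zeros(np.broadcast(z, phi).shape)
        for n in range(n_max + 1):
            weight = 1.0 if n == 0 else 2.0
            for h in self.harmonics(n):
                if contribution is not None and h.name != contribution:
                    continue
                total = total + weight * h.sigma_amp * np.cos(n * phase)
        return total


def default_dna_model() -> HelixChargeModel:
    """B-DNA model with the package's default parameter set."""
    return HelixChargeModel()
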