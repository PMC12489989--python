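"""Wavevector-dependent dielectric response of water and electrolyte.

The longitudinal dielectric function of the pure solvent is modelled as

    ε(k) = 1 / [ 1/ε* − (1/ε* − 1/ε) F̃(k) ],

which interpolates between the macroscopic constant ε at k→0 and the
short-range constant ε* at k→∞.  The structure factor F̃(k) is a hybrid of a
Lorentzian channel (purely exponential polarization correlations, decay
length Λ1) and an oscillatory channel (decaying oscillating correlations,
decay length Λ2, period Λo = 2π/Q), mixed by a partition coefficient γ:

    F̃(k) = γ/(1+Λ1²k²)
          + (1−γ)(1+Λ2²Q²)² / [(1+Λ2²(k−Q)²)(1+Λ2²(k+Q)²)].

The numerator of the oscillatory channel is fixed to (1+Λ2²Q²)² so that
F̃(0) = 1 exactly and hence ε(0) = ε; see docs/methods.md.  Where F̃(k)
exceeds (1/ε*)/(1/ε* − 1/ε) the dielectric function is negative: this is the
overscreening regime responsible for alternating hydration shells.

Electrolyte is folded in through the interpolation ε_c(k) = ε(k)(1+κ²/k²),
with κ the inverse Debye length, valid when the Debye length is large
compared to the solvent correlation lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import E2_KCAL_MOL_A, KB_KCAL_MOL_K, MOLAR_TO_PER_A3

__all__ = [
    "WaterDielectricParams",
    "ElectrolyteSpec",
    "DielectricSpectrum",
    "lorentzian_form_factor",
    "hybrid_form_factor",
    "eps_water",
    "eps_electrolyte",
    "debye_kappa",
    "bjerrum_length",
    "match_debye_concentration",
    "pole_analysis",
    "dkm_check",
    "get_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class WaterDielectricParams:
    """Parameters of the hybrid ε(k) model of a polar solvent.

    Attributes
    ----------
    eps_bulk : macroscopic (static) dielectric constant ε.
    eps_star : short-range dielectric constant ε* (electronic/IR response).
    lambda1 : decay length Λ1 of the Lorentzian channel, Å.
    lambda2 : decay length Λ2 of the oscillatory channel, Å.
    q_osc : oscillation wavevector Q, Å⁻¹ (period Λo = 2π/Q).
    gamma : partition coefficient γ ∈ [0, 1] weighting the Lorentzian channel.
    """

    eps_bulk: float
    eps_star: float
    lambda1: float
    lambda2: float
    q_osc: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.eps_bulk > self.eps_star >= 1.0:
            raise ValueError("require eps_bulk > eps_star >= 1")
        if min(self.lambda1, self.lambda2, self.q_osc) <= 0:
            raise ValueError("correlation lengths and Q must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def lambda_osc(self) -> float:
        """Oscillation period Λo = 2π/Q in Å."""
        return 2.0 * np.pi / self.q_osc

    @property
    def chi(self) -> float:
        """Susceptibility-like combination 1/ε* − 1/ε used throughout."""
        return 1.0 / self.eps_star - 1.0 / self.eps_bulk

    @classmethod
    def from_lambda_osc(cls, eps_bulk, eps_star, lambda1, lambda2, lambda_osc, gamma):
        return cls(eps_bulk, eps_star, lambda1, lambda2, 2.0 * np.pi / lambda_osc, gamma)


# Named parameter sets.  ``tip3p`` reproduces the response function of TIP3P
# water with the estimated short-range constant ε*=5.75; ``tip3p-eps1`` is the
# same correlation spectrum with ε*=1 (used for bare-spectrum illustrations).
PRESETS = {
    "tip3p": dict(eps_bulk=94.0, eps_star=5.75, lambda1=3.67, lambda2=1.77,
                  lambda_osc=2.13, gamma=0.05),
    "tip3p-eps1": dict(eps_bulk=94.0, eps_star=1.0 + 1e-12, lambda1=3.67,
                       lambda2=1.77, lambda_osc=2.13, gamma=0.05),
}


def get_preset(name: str) -> WaterDielectricParams:
    """Return a named solvent parameter set (see :data:`PRESETS`)."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return WaterDielectricParams.from_lambda_osc(**p)


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Electrolyte composition: molarity of the salt, stoichiometry, temperature.

    ``species`` is a sequence of (valence, stoichiometric count) pairs, e.g.
    ``[(1, 1), (-1, 1)]`` for KCl or ``[(2, 1), (-1, 2)]`` for MgCl2.  The
    dielectric constant entering the Debye length is ``eps_for_screening``.
    """

    molarity: float
    species: Sequence[tuple[int, int]] = ((1, 1), (-1, 1))
    temperature: float = 300.0
    eps_for_screening: float = 94.0

    def __post_init__(self) -> None:
        if self.molarity < 0:
            raise ValueError("molarity must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if abs(sum(z * nu for z, nu in self.species)) > 1e-12:
            raise ValueError("stoichiometry is not electroneutral")

    @property
    def ionic_strength(self) -> float:
        """I = ½ Σ cᵢ zᵢ² in mol/L."""
        return 0.5 * self.molarity * sum(nu * z * z for z, nu in self.species)


def lorentzian_form_factor(k, lambda_corr):
    """Lorentzian structure factor F̃(k) = 1/(1+Λ²k²).

    Strictly decreasing in k, equal to 1 at k=0 and 1/2 at k=1/Λ.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    if lambda_corr <= 0:
        raise ValueError("correlation length must be > 0")
    return 1.0 / (1.0 + lambda_corr**2 * k * k)


def hybrid_form_factor(k, params: WaterDielectricParams):
    """Hybrid structure factor combining Lorentzian and oscillatory channels.

    Normalized so that F̃(0) = 1; decays to zero as k→∞.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    L1, L2, Q, g = params.lambda1, params.lambda2, params.q_osc, params.gamma
    lor = g / (1.0 + L1 * L1 * k * k)
    num = (1.0 + L2 * L2 * Q * Q) ** 2
    den = (1.0 + L2 * L2 * (k - Q) ** 2) * (1.0 + L2 * L2 * (k + Q) ** 2)
    return lor + (1.0 - g) * num / den


def _inv_eps_water(k, params: WaterDielectricParams):
    """1/ε(k); analytic continuation to k² < 0 is done in the propagator module."""
    return 1.0 / params.eps_star - params.chi * hybrid_form_factor(k, params)


def eps_water(k, params: WaterDielectricParams):
    """Dielectric function ε(k) of the pure solvent.

    ε(0) = ε (macroscopic constant), ε(∞) = ε*.  At intermediate k the
    function may be negative (overscreening); at the sign-change poles the
    reciprocal vanishes, and signed infinities are returned there rather than
    NaN so that root-finding across the pole remains well posed.
    """
    u = np.asarray(_inv_eps_water(k, params))
    with np.errstate(divide="ignore"):
        out = np.where(u != 0.0, 1.0 / np.where(u != 0.0, u, 1.0), np.inf)
    if out.ndim == 0:
        return float(out)
    return out


def eps_electrolyte(k, params: WaterDielectricParams, kappa: float):
    """Interpolated electrolyte dielectric function ε_c(k) = ε(k)(1+κ²/k²).

    Diverges at k=0 when κ>0 (perfect macroscopic screening); reduces to the
    pure-water ε(k) at large k or when κ=0.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    k = np.asarray(k, dtype=float)
    if kappa > 0 and np.any(k == 0):
        raise ValueError("eps_electrolyte diverges at k=0 for kappa > 0")
    factor = 1.0 + (kappa / np.where(k == 0, 1.0, k)) ** 2 if kappa > 0 else 1.0
    out = np.asarray(eps_water(k, params)) * factor
    if out.ndim == 0:
        return float(out)
    return out


def bjerrum_length(eps: float, temperature: float) -> float:
    """Bjerrum length λ_B = e²/(ε k_B T) in Å."""
    return E2_KCAL_MOL_A / (eps * KB_KCAL_MOL_K * temperature)


def debye_kappa(spec: ElectrolyteSpec) -> float:
    """Inverse Debye length κ in Å⁻¹ (Debye–Hückel, Gaussian units).

    κ² = 4π λ_B Σ nᵢ zᵢ², with number densities nᵢ from the molarity and
    stoichiometry.  Homogeneous of degree ½ in the concentration.
    """
    lb = bjerrum_length(spec.eps_for_screening, spec.temperature)
    sum_nz2 = spec.molarity * MOLAR_TO_PER_A3 * sum(
        nu * z * z for z, nu in spec.species
    )
    return float(np.sqrt(4.0 * np.pi * lb * sum_nz2))


def match_debye_concentration(
    reference: ElectrolyteSpec, target_species: Sequence[tuple[int, int]]
) -> float:
    """Molarity of the target salt having the same Debye length as ``reference``.

    Equality of ionic strength: c_target = I_ref / (½ Σ zᵢ²νᵢ).
    """
    if abs(sum(z * nu for z, nu in target_species)) > 1e-12:
        raise ValueError("target stoichiometry is not electroneutral")
    half_sum = 0.5 * sum(nu * z * z for z, nu in target_species)
    if half_sum == 0:
        raise ValueError("target stoichiometry carries no charge")
    return reference.ionic_strength / half_sum


def pole_analysis(params: WaterDielectricParams, kappa: float = 0.0,
                  n: int = 0, g: float = 0.0) -> dict:
    """Poles of the per-harmonic propagator integrand in the complex K plane.

    Returns the ionic pole ±i√(κ²+n²g²) together with the water-structure
    poles of ε(√(K²+n²g²)): the Lorentzian pair ±i·q̃d1n with
    q̃d1n = √(1/Λ1²+n²g²) and the oscillatory quadruple ±(g̃nR − i g̃nI) and
    conjugates.  For n=0 and κ=0 these reduce to ±i/Λ1 and ±Q±i/Λ2.
    """
    n2g2 = (n * g) ** 2
    kt = np.sqrt(kappa**2 + n2g2)
    qd = np.sqrt(1.0 / params.lambda1**2 + n2g2)
    c_bar = (params.q_osc - 1j / params.lambda2) ** 2  # (Q − i/Λ2)²
    gn = np.sqrt(c_bar - n2g2)  # principal root: Re>0, Im<0
    osc = [gn, -gn, np.conj(gn), -np.conj(gn)]
    return {
        "ionic": [1j * kt, -1j * kt],
        "lorentzian": [1j * qd, -1j * qd],
        "oscillatory": osc,
    }


def dkm_check(params: WaterDielectricParams, kappa: float = 0.0,
              k_grid=None) -> tuple[bool, tuple[float, float] | None]:
    """Stability (DKM) check: ε_c(k) must never lie in (0, 1].

    Scans a dense grid (default spacing 0.005 Å⁻¹ up to 20 Å⁻¹) and returns
    ``(True, None)`` on pass or ``(False, (k_lo, k_hi))`` with the first
    violating interval.
    """
    if k_grid is None:
        k_grid = np.arange(0.005, 20.0 + 1e-9, 0.005)
    k_grid = np.asarray(k_grid, dtype=float)
    eps = np.asarray(eps_electrolyte(k_grid, params, kappa))
    bad = (eps > 0.0) & (eps <= 1.0)
    if not bad.any():
        return True, None
    idx = np.flatnonzero(bad)
    return False, (float(k_grid[idx[0]]), float(k_grid[idx[-1]]))


@dataclass
class DielectricSpectrum:
    """ε(k) sampled on a wavevector grid, for export/inspection."""

    k_grid: np.ndarray
    eps_values: np.ndarray
    flags: dict = field(default_factory=dict)

    @classmethod
    def compute(cls, params: WaterDielectricParams, kappa: float = 0.0,
                k_grid=None) -> "DielectricSpectrum":
        if k_grid is None:
            k_grid = np.linspace(0.001, 20.0, 4000)
        k_grid = np.asarray(k_grid, dtype=float)
        if not np.all(np.diff(k_grid) > 0):
            raise ValueError("k_grid must be strictly increasing")
        eps = np.asarray(eps_electrolyte(k_grid, params, kappa))
        return cls(k_grid, eps, {"model": "hybrid", "kappa": kappa})

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"k_invA": self.k_grid, "eps": self.eps_values}).to_csv(
            path, index=False
        )
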