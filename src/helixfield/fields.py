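"""Assembly of φ, E and the charge density around the helical charge model.

The potential is a cosine series in the helical phase Δ = ϕ − gz,

    φ(R,ϕ,z) = Σ_ν Σ_{n≥0} 8π a_ν A_ν(n)/(1+δ_{n0})
               cos(nΔ) W_n(R; a_ν, κ),

where A_ν(n) are the surface-charge harmonics (:mod:`helixfield.helix`,
with the bound-water sign already folded in) and W_n the propagator
(:mod:`helixfield.propagator`).  The n=0 term is the homogeneously charged
cylinder: for a k-independent dielectric it reduces to the Debye–Hückel
result 4πσ̄a I₀(κa)K₀(κR)/ε, which fixes the 1/(1+δ_{n0}) weighting.

Radial smearing replaces each sharp cylindrical shell by a truncated
Gaussian distribution of shell radii (half-width δa),

    ζ(a−ā, δa) = √(2/π) e^{−(a−ā)²/(2δa²)} / [δa (1 + erf(ā/(√2 δa)))],

applied as φ̄(r) = ∫₀^∞ da ζ(a−ā) φ(r; a); it damps the overscreening
oscillations that an infinitely thin helical line would overemphasize.

The total potential diverges logarithmically in pure water (κ=0) through
its n=0 term; the electric field and charge density stay finite and remain
available there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

from .dielectric import WaterDielectricParams
from .helix import HelixChargeModel
from .propagator import (charge_kernel_closed_form, propagator_closed_form,
                         propagator_radial_derivative)
from .units import potential_to_kBT_e, potential_to_mV

__all__ = [
    "FieldMap",
    "potential_total",
    "electric_field",
    "charge_density",
    "radial_smearing",
    "zeta_kernel",
    "harmonic_convergence",
    "NEAR_FIELD_CAUTION_A",
]

NEAR_FIELD_CAUTION_A = 2.5

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def zeta_kernel(a, abar: float, delta_a: float):
    """Truncated, renormalized Gaussian smearing kernel ζ(a−ā, δa), Å⁻¹.

    Normalized so that ∫₀^∞ ζ da = 1; zero for a < 0.
    """
    if delta_a <= 0:
        raise ValueError("zeta_kernel requires delta_a > 0")
    a = np.asarray(a, dtype=float)
    norm = np.sqrt(2.0 / np.pi) / (
        delta_a * (1.0 + erf(abar / (np.sqrt(2.0) * delta_a)))
    )
    out = np.where(a >= 0, norm * np.exp(-((a - abar) ** 2) / (2 * delta_a**2)), 0.0)
    return out if out.ndim else float(out)


def radial_smearing(field_fn: Callable, abar: float, delta_a: float,
                    n_nodes: int = 24) -> Callable:
    """Smearing operator: returns r ↦ ∫₀^∞ da ζ(a−ā, δa) field_fn(r, a).

    ``field_fn(r, a)`` must accept a vector of r at a scalar shell radius a.
    δa = 0 returns the unsmeared function.  Gauss–Legendre over ±5δa about ā
    (clipped at zero); the kernel's own truncation normalization is kept, so
    total weight is conserved to the quadrature tolerance.
    """
    if delta_a < 0:
        raise ValueError("delta_a must be >= 0")
    if delta_a == 0:
        return lambda r: field_fn(r, abar)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    lo = max(1e-6, abar - 5.0 * delta_a)
    hi = abar + 5.0 * delta_a
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    a_j = mid + half * nodes
    w_j = half * weights * zeta_kernel(a_j, abar, delta_a)

    def smeared(r):
        acc = None
        for aj, wj in zip(a_j, w_j):
            term = wj * np.asarray(field_fn(r, aj))
            acc = term if acc is None else acc + term
        return acc

    return smeared


def _contribution_kernel(kind: str, n: int, water, kappa: float, g: float):
    """Radial kernel (potential / radial derivative / induced charge) at order n."""
    if kind == "potential":
        return lambda r, a: propagator_closed_form(n, r, a, kappa, water, g)
    if kind == "dphi_dR":
        return lambda r, a: propagator_radial_derivative(n, r, a, kappa, water, g)
    if kind == "charge":
        return lambda r, a: charge_kernel_closed_form(n, r, a, kappa, water, g)
    raise ValueError(kind)


def _radial_coefficients(model: HelixChargeModel, water, kappa, R, n_max,
                         kind: str, smearing: bool = True,
                         contributions: Sequence[str] | None = None,
                         skip_n0: bool = False):
    """C_n(R) such that the observable is Σ_n C_n(R)·{cos,sin}(nΔ)."""
    R = np.asarray(R, dtype=float)
    g = model.geometry.g
    coeffs = np.zeros((n_max + 1,) + R.shape)
    for n in range(n_max + 1):
        if skip_n0 and n == 0:
            continue
        weight = 8.0 * np.pi / (2.0 if n == 0 else 1.0)
        kern = _contribution_kernel(kind, n, water, kappa, g)
        for h in model.harmonics(n):
            if contributions is not None and h.name not in contributions:
                continue
            da = h.delta_a if smearing else 0.0
            # Eq.-45-style smearing of a·kernel (the shell prefactor rides along)
            fn = radial_smearing(lambda r, a: a * kern(r, a), h.radius, da)
            coeffs[n] += weight * h.potential_amp * np.asarray(fn(R))
    return coeffs


def _assemble(coeffs, n_max, phi, z, g, trig):
    phi = np.asarray(phi, dtype=float)
    z = np.asarray(z, dtype=float)
    phase = phi - g * z
    out = np.zeros(np.broadcast(coeffs[0], phase).shape)
    for n in range(n_max + 1):
        f = np.cos(n * phase) if trig == "cos" else np.sin(n * phase)
        out = out + coeffs[n] * f
    return out


def potential_total(R, phi, z, model: HelixChargeModel,
                    water: WaterDielectricParams, kappa: float,
                    n_max: int = 50, smearing: bool = True,
                    contributions: Sequence[str] | None = None):
    """Total electrostatic potential φ(R,ϕ,z) in e/Å (convert via units module).

    Broadcasts over the coordinate arrays (R against ϕ and z).  Requires
    κ > 0: in pure water the n=0 (charged-cylinder) term diverges
    logarithmically; use :func:`electric_field` or :func:`charge_density`
    there.  ``contributions`` restricts to a subset of
    {"phosphates", "counterions", "bound_water"}.
    """
    if kappa <= 0:
        raise ValueError(
            "the potential of a charged cylinder is undefined in pure water "
            "(kappa=0); compute the electric field or charge density instead"
        )
    coeffs = _radial_coefficients(model, water, kappa, R, n_max, "potential",
                                  smearing, contributions)
    return _assemble(coeffs, n_max, phi, z, model.geometry.g, "cos")


def electric_field(R, phi, z, model: HelixChargeModel,
                   water: WaterDielectricParams, kappa: float,
                   n_max: int = 50, smearing: bool = True,
                   contributions: Sequence[str] | None = None):
    """Electric field components (E_R, E_ϕ, E_z) in e/Å²; finite for κ=0.

    E = −∇φ termwise: E_R from the analytic radial Bessel derivatives,
    E_ϕ = Σ (n/R) C_n sin(nΔ), E_z = −Σ n g C_n sin(nΔ).
    """
    R = np.asarray(R, dtype=float)
    g = model.geometry.g
    dcoeffs = _radial_coefficients(model, water, kappa, R, n_max, "dphi_dR",
                                   smearing, contributions)
    # the n=0 potential kernel is divergent at κ=0 but unused (factor n)
    ccoeffs = _radial_coefficients(model, water, kappa, R, n_max, "potential",
                                   smearing, contributions, skip_n0=True)
    e_r = -_assemble(dcoeffs, n_max, phi, z, g, "cos")
    safe_R = np.where(R > 0, R, np.inf)
    nvec = np.arange(n_max + 1).reshape((-1,) + (1,) * np.ndim(ccoeffs[0]))
    e_phi = _assemble(ccoeffs * nvec / safe_R, n_max, phi, z, g, "sin")
    e_z = -_assemble(ccoeffs * nvec * g, n_max, phi, z, g, "sin")
    return e_r, e_phi, e_z


def charge_density(R, phi, z, model: HelixChargeModel,
                   water: WaterDielectricParams, kappa: float,
                   n_max: int = 50, smearing: bool = True,
                   subtract_source: bool = True,
                   contributions: Sequence[str] | None = None):
    """Charge density ϱ (e/Å³) induced around the helix; finite for κ=0.

    ϱ follows from Δφ = −4πϱ applied to the harmonic series.  It splits into
    a regular residue part plus a contact part proportional to the (smeared)
    source density: the medium instantaneously compensates a fraction
    (1 − 1/ε*) of the source at its own location.  With
    ``subtract_source=True`` (default) the external source density itself is
    removed, leaving the induced bound/ionic charge; with ``False`` the total
    (source + induced) is returned, which integrates to zero over a large
    volume when κ > 0.
    """
    R = np.asarray(R, dtype=float)
    g = model.geometry.g
    coeffs = _radial_coefficients(model, water, kappa, R, n_max, "charge",
                                  smearing, contributions)
    # C_n carries the full 8π a A(n)/(1+δ_{n0}) prefactor; ϱ_n = C_n/(4π)
    out = _assemble(coeffs, n_max, phi, z, g, "cos") / (4.0 * np.pi)
    contact = _source_density(R, phi, z, model, smearing, contributions, n_max)
    factor = (1.0 / water.eps_star - 1.0) if subtract_source else (1.0 / water.eps_star)
    return out + factor * contact


def _source_density(R, phi, z, model: HelixChargeModel, smearing: bool,
                    contributions=None, n_max: int = 50):
    """External (source) charge density on the grid, e/Å³.

    Sharp shells (δa=0 or smearing off) are delta distributions and
    contribute zero at off-shell grid points.
    """
    R = np.asarray(R, dtype=float)
    g = model.geometry.g
    coeffs = np.zeros((n_max + 1,) + R.shape)
    for n in range(n_max + 1):
        w = 2.0 / (2.0 if n == 0 else 1.0)
        for h in model.harmonics(n):
            if contributions is not None and h.name not in contributions:
                continue
            if not smearing or h.delta_a == 0:
                continue
            coeffs[n] += w * h.potential_amp * zeta_kernel(R, h.radius, h.delta_a)
    return _assemble(coeffs, n_max, phi, z, g, "cos")


def harmonic_convergence(model: HelixChargeModel, water, kappa, R,
                         n_max: int = 50, kind: str = "potential"):
    """Relative size of the last retained harmonic vs the accumulated sum.

    Returns max over R of |C_{n_max}(R)| / max(|Σ C_n(R)|): a cheap tail
    estimate for choosing n_max (the Gaussian form factors make it collapse
    rapidly).
    """
    coeffs = _radial_coefficients(model, water, kappa, np.asarray(R, float),
                                  n_max, kind, smearing=True)
    total = np.abs(coeffs.sum(axis=0))
    return float(np.max(np.abs(coeffs[n_max]) / np.maximum(total.max(), 1e-300)))


@dataclass
class FieldMap:
    """Evaluated fields on a cylindrical grid (R, ϕ, z).

    ``data`` maps names ("phi", "E_R", "E_phi", "E_z", "E_mag", "rho") to
    arrays of shape (len(R), len(phi), len(z)); φ in e/Å, E in e/Å², ϱ in
    e/Å³.  ``near_field_mask`` marks points within one water diameter of a
    charged surface where linear response is least trustworthy (values are
    reported, not censored).
    """

    R: np.ndarray
    phi: np.ndarray
    z: np.ndarray
    data: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def near_field_mask(self) -> np.ndarray:
        radii = self.meta.get("charge_radii", [])
        mask = np.zeros(len(self.R), dtype=bool)
        for a in radii:
            mask |= np.abs(self.R - a) < NEAR_FIELD_CAUTION_A
        return np.broadcast_to(
            mask[:, None, None], (len(self.R), len(self.phi), len(self.z))
        )

    def phi_mV(self):
        return potential_to_mV(self.data["phi"])

    def phi_kBT_e(self):
        return potential_to_kBT_e(self.data["phi"])

    @classmethod
    def compute(cls, model: HelixChargeModel, water: WaterDielectricParams,
                kappa: float, R, phi, z, n_max: int = 50,
                quantities: Sequence[str] = ("phi",),
                smearing: bool = True) -> "FieldMap":
        """Evaluate the requested quantities on the tensor grid R×ϕ×z."""
        R = np.atleast_1d(np.asarray(R, dtype=float))
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        Rc = R[:, None, None]
        pc = phi[None, :, None]
        zc = z[None, None, :]
        data = {}
        if "phi" in quantities:
            data["phi"] = potential_total(Rc, pc, zc, model, water, kappa,
                                          n_max, smearing)
        if any(q.startswith("E") for q in quantities):
            e_r, e_p, e_z = electric_field(Rc, pc, zc, model, water, kappa,
                                           n_max, smearing)
            data.update(E_R=e_r, E_phi=e_p, E_z=e_z,
                        E_mag=np.sqrt(e_r**2 + e_p**2 + e_z**2))
        if "rho" in quantities:
            data["rho"] = charge_density(Rc, pc, zc, model, water, kappa,
                                         n_max, smearing)
        radii = [h.radius for h in model.harmonics(0)]
        meta = dict(kappa=kappa, n_max=n_max, charge_radii=radii,
                    water=water, units={"phi": "e/A", "E": "e/A^2",
                                        "rho": "e/A^3"})
        return cls(R=R, phi=phi, z=z, data=data, meta=meta)
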