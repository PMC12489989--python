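"""Per-harmonic electrostatic propagator for cylindrical charge harmonics.

The potential of a helical surface-charge harmonic n placed on a cylinder of
radius a, observed at radius R, is governed by the kernel

    W_n(R; a, κ) = ∫₀^∞ dK K J_n(KR) J_n(Ka)
                    / [ ε(√(K²+n²g²)) (K²+n²g²+κ²) ],

where g = 2π/H couples the helical pitch to the radial decay and ε(k) is the
hybrid nonlocal dielectric function (:mod:`helixfield.dielectric`).  The
integrand is rational in K², so the integral evaluates by residues to a
three-channel closed form,

    W_n = g̃κ K_n(κ̃n R) I_n(κ̃n a)
        + γ g̃L K_n(q̃d1n R) I_n(q̃d1n a)
        + (1−γ) Re[ g̃o H⁽²⁾_n(g̃n R) J_n(g̃n a) ],          R > a,

(swap R and a for R < a) with

    κ̃n  = √(κ² + n²g²)                  ionic channel,
    q̃d1n = √(1/Λ1² + n²g²)              Lorentzian water channel,
    g̃n  = g̃nR − i g̃nI = √((Q − i/Λ2)² − n²g²)   oscillatory channel,

and residue weights (χ = 1/ε* − 1/ε, c̄ = (Q − i/Λ2)²):

    g̃κ = 1/ε* − χ [ γ/(1−Λ1²κ²)
                    + (1−γ)(1+Λ2²Q²)² / (Λ2⁴ |κ²+(Q+i/Λ2)²|²) ]
       = 1/ε evaluated at imaginary wavevector iκ,
    g̃L = χ / (1 − Λ1²κ²),
    g̃o = −π χ (1+Λ2²Q²)² / (4 Q Λ2³ (c̄ + κ²)).

The weights depend on κ only; the harmonic index enters through the Bessel
arguments.  Limits: n→0 gives g̃nR→Q and g̃nI→1/Λ2; κ→0 gives g̃κ→1/ε; for a
k-independent dielectric (ε*=ε) only the ionic channel survives with weight
1/ε, reproducing Debye–Hückel theory.

Ground truth is direct numerical quadrature (:func:`propagator_quadrature`,
float, and :func:`propagator_quadrature_mp`, arbitrary precision); the closed
form is required to agree with it and is used everywhere downstream for
speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from .dielectric import WaterDielectricParams, hybrid_form_factor

__all__ = [
    "PropagatorParams",
    "propagator_params",
    "propagator_closed_form",
    "propagator_radial_derivative",
    "charge_kernel_closed_form",
    "propagator_quadrature",
    "propagator_quadrature_mp",
    "QuadratureError",
    "QuadratureDiagnostics",
]


class QuadratureError(RuntimeError):
    """Raised when the quadrature cannot certify the requested accuracy."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class PropagatorParams:
    """Residue data of the closed-form propagator for one harmonic.

    All decay constants in Å⁻¹.  ``g_o`` is complex; the other weights real.
    """

    n: int
    kappa: float
    kappa_tilde: float     # ionic decay √(κ²+n²g²)
    q_d1: float            # Lorentzian decay √(1/Λ1²+n²g²)
    g_nR: float            # oscillation wavevector, →Q as n→0
    g_nI: float            # oscillatory decay, →1/Λ2 as n→0
    g_kappa: float
    g_L: float
    g_o: complex
    gamma: float

    @property
    def g_n(self) -> complex:
        return self.g_nR - 1j * self.g_nI


def propagator_params(n: int, kappa: float, water: WaterDielectricParams,
                      g: float) -> PropagatorParams:
    """Build the closed-form coefficients for harmonic ``n``.

    Parameters: ``kappa`` inverse Debye length (Å⁻¹), ``g`` = 2π/pitch (Å⁻¹).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    L1, L2, Q, gam = water.lambda1, water.lambda2, water.q_osc, water.gamma
    chi = water.chi
    n2g2 = (n * g) ** 2
    kt = float(np.sqrt(kappa**2 + n2g2))
    qd = float(np.sqrt(1.0 / L1**2 + n2g2))
    den_l = 1.0 - (L1 * kappa) ** 2
    if den_l <= 0:
        # κ beyond 1/Λ1 collapses the scale separation the interpolated
        # dielectric model assumes; refuse rather than return nonsense.
        raise ValueError("kappa >= 1/lambda1: outside the model's validity range")
    c1 = (Q + 1j / L2) ** 2
    cbar = (Q - 1j / L2) ** 2
    num = (1.0 + (L2 * Q) ** 2) ** 2
    g_kappa = (1.0 / water.eps_star
               - chi * (gam / den_l
                        + (1.0 - gam) * num / (L2**4 * abs(kappa**2 + c1) ** 2)))
    g_L = chi / den_l
    g_o = -np.pi * chi * num / (4.0 * Q * L2**3 * (cbar + kappa**2))
    gn = np.sqrt(cbar - n2g2)  # principal branch: Re>0, Im<0
    return PropagatorParams(
        n=n, kappa=kappa, kappa_tilde=kt, q_d1=qd,
        g_nR=float(gn.real), g_nI=float(-gn.imag),
        g_kappa=float(g_kappa), g_L=float(g_L), g_o=complex(g_o),
        gamma=gam,
    )


def _ik_product(n, m, r_small, r_large, deriv_on_large=False, deriv_on_small=False):
    """I_n(m r<) K_n(m r>) with exponential scaling; optional first derivatives.

    ``deriv_on_large`` differentiates the K factor w.r.t. its radius,
    ``deriv_on_small`` the I factor.  Only one may be set.
    """
    xs = m * r_small
    xl = m * r_large
    scale = np.exp(xs - xl)
    if deriv_on_large:
        kfac = -0.5 * m * (sp.kve(n - 1, xl) + sp.kve(n + 1, xl))
        return sp.ive(n, xs) * kfac * scale
    if deriv_on_small:
        ifac = 0.5 * m * (sp.ive(n - 1, xs) + sp.ive(n + 1, xs))
        return ifac * sp.kve(n, xl) * scale
    return sp.ive(n, xs) * sp.kve(n, xl) * scale


def _hj_product(n, z, r_small, r_large, deriv_on_large=False, deriv_on_small=False):
    """H⁽²⁾_n(z r>) J_n(z r<) for complex z with Im z < 0, scaled against overflow."""
    zl = z * r_large
    zs = z * r_small
    # hankel2(z) = hankel2e(z) exp(-i z); jv(z) = jve(z) exp(|Im z|)
    expo = -1j * zl + abs(np.imag(zs))
    scale = np.exp(expo)
    if deriv_on_large:
        hfac = 0.5 * z * (sp.hankel2e(n - 1, zl) - sp.hankel2e(n + 1, zl))
        return hfac * sp.jve(n, zs) * scale
    if deriv_on_small:
        jfac = 0.5 * z * (sp.jve(n - 1, zs) - sp.jve(n + 1, zs))
        return sp.hankel2e(n, zl) * jfac * scale
    return sp.hankel2e(n, zl) * sp.jve(n, zs) * scale


def _split_radii(R, a):
    R = np.asarray(R, dtype=float)
    return np.minimum(R, a), np.maximum(R, a)


def propagator_closed_form(n, R, a, kappa, water: WaterDielectricParams, g):
    """Closed-form W_n(R; a, κ).  Vectorized over ``R``; symmetric in (R, a).

    Raises for n=0 with κ=0, where the kernel (and the potential of a
    homogeneously charged cylinder) diverges logarithmically.
    """
    p = propagator_params(n, kappa, water, g)
    if n == 0 and p.kappa_tilde == 0.0:
        raise ValueError("W_0 diverges in pure water (kappa=0); "
                         "use the field/charge kernels instead")
    rs, rl = _split_radii(R, a)
    ionic = p.g_kappa * _ik_product(n, p.kappa_tilde, rs, rl)
    lor = p.gamma * p.g_L * _ik_product(n, p.q_d1, rs, rl)
    osc = (1.0 - p.gamma) * np.real(p.g_o * _hj_product(n, p.g_n, rs, rl))
    out = ionic + lor + osc
    return out if out.ndim else float(out)


def propagator_radial_derivative(n, R, a, kappa, water: WaterDielectricParams, g):
    """∂W_n/∂R, term-wise analytic Bessel derivatives.

    Finite for κ=0 (including n=0, where the ionic channel contributes the
    line-charge field −g̃κ/R outside the cylinder and zero inside).
    """
    p = propagator_params(n, kappa, water, g)
    R = np.asarray(R, dtype=float)
    rs, rl = _split_radii(R, a)
    outside = R >= a  # derivative acts on the R-dependent factor
    if n == 0 and p.kappa_tilde == 0.0:
        ionic = np.where(outside, -p.g_kappa / np.where(R > 0, R, np.inf), 0.0)
    else:
        d_out = _ik_product(n, p.kappa_tilde, rs, rl, deriv_on_large=True)
        d_in = _ik_product(n, p.kappa_tilde, rs, rl, deriv_on_small=True)
        ionic = p.g_kappa * np.where(outside, d_out, d_in)
    d_out = _ik_product(n, p.q_d1, rs, rl, deriv_on_large=True)
    d_in = _ik_product(n, p.q_d1, rs, rl, deriv_on_small=True)
    lor = p.gamma * p.g_L * np.where(outside, d_out, d_in)
    h_out = _hj_product(n, p.g_n, rs, rl, deriv_on_large=True)
    h_in = _hj_product(n, p.g_n, rs, rl, deriv_on_small=True)
    osc = (1.0 - p.gamma) * np.real(p.g_o * np.where(outside, h_out, h_in))
    out = ionic + lor + osc
    return out if out.ndim else float(out)


def charge_kernel_closed_form(n, R, a, kappa, water: WaterDielectricParams, g):
    """Regular part of the induced-charge kernel −ΔW_n/(4π)·4π (units Å⁻²).

    Each residue channel of W_n is multiplied by the value of (K²+n²g²) at
    its pole: −κ² (ionic), −1/Λ1² (Lorentzian), (Q−i/Λ2)² (oscillatory).  The
    δ-shell contact term (1/ε*)δ(R−a)/R is *not* included here; the field
    assembly layer handles it together with the source term.
    """
    p = propagator_params(n, kappa, water, g)
    L1, L2, Q = water.lambda1, water.lambda2, water.q_osc
    rs, rl = _split_radii(R, a)
    if p.kappa_tilde == 0.0 and n == 0:
        ionic = np.zeros(np.shape(rs))
    else:
        ionic = p.g_kappa * (-kappa**2) * _ik_product(n, p.kappa_tilde, rs, rl)
    lor = p.gamma * p.g_L * (-1.0 / L1**2) * _ik_product(n, p.q_d1, rs, rl)
    cbar = (Q - 1j / L2) ** 2
    osc = (1.0 - p.gamma) * np.real(p.g_o * cbar * _hj_product(n, p.g_n, rs, rl))
    out = ionic + lor + osc
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# quadrature oracles
# ---------------------------------------------------------------------------

@dataclass
class QuadratureDiagnostics:
    value: float
    kmax: float
    n_panels: int
    tail_bound: float          # analytic bound on the truncated tail
    cancellation_floor: float  # float64 round-off scale of the panel sums

    @property
    def abs_error_estimate(self) -> float:
        return self.tail_bound + self.cancellation_floor


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(10)


def _tail_bound(water, kmax, R, a, n2g2, kt2):
    """Envelope bound on |∫_kmax^∞ K JnJn (1/ε−1/ε*)/(K²+κ̃²) dK|."""
    chi = water.chi
    L1, L2, Q, gam = water.lambda1, water.lambda2, water.q_osc, water.gamma
    env_bessel = 2.0 / (np.pi * np.sqrt(R * a))
    lor = gam * chi / (L1**2 * 3.0 * kmax**3)
    num = (1.0 + (L2 * Q) ** 2) ** 2
    osc = (1.0 - gam) * chi * num / (L2**4 * 5.0 * kmax**5)
    return env_bessel * (lor + osc)


def propagator_quadrature(n, R, a, kappa, water: WaterDielectricParams, g,
                          kmax: float = 240.0, full: bool = False,
                          rtol_certify: float | None = None):
    """Direct numerical evaluation of W_n(R; a, κ) — the ground-truth oracle.

    The k-independent short-range part 1/ε* is integrated analytically
    through the identity ∫K J_n(KR)J_n(Ka)/(K²+m²)dK = I_n(m r<)K_n(m r>);
    the remainder, which decays as K⁻⁴, is integrated by composite
    Gauss–Legendre with panels short enough to resolve the fastest Bessel
    oscillation.  Returns the value, or (value, diagnostics) with
    ``full=True``.  With ``rtol_certify`` set, raises
    :class:`QuadratureError` if the certified error exceeds it.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    n2g2 = (n * g) ** 2
    kt2 = kappa**2 + n2g2
    kt = np.sqrt(kt2)
    if kt == 0.0:
        raise ValueError("W_0 diverges for kappa=0 (pure water)")
    R = float(R)
    a = float(a)
    rs, rl = min(R, a), max(R, a)
    analytic = _ik_product(n, kt, rs, rl) / water.eps_star

    # correction integrand: K JnJn * (1/ε(k) − 1/ε*) / (K²+κ̃²).  Two panel
    # zones: a fine zone resolving the narrow Debye peak at K ~ κ̃, then
    # half-period panels for the Bessel-product oscillation.
    width = min(np.pi / (R + a), 0.25)
    k1 = min(max(12.0 * kt, 4.0 * width), 4.0)
    w_fine = min(width, max(kt / 3.0, 1e-3))
    edges_a = np.arange(0.0, k1, w_fine)
    edges_b = np.arange(edges_a[-1], kmax + width, width)
    edges = np.concatenate([edges_a, edges_b[1:]])
    mids = 0.5 * (edges[1:] + edges[:-1])
    halves = 0.5 * np.diff(edges)
    n_panels = len(mids)
    K = (mids[:, None] + halves[:, None] * _GL_NODES[None, :]).ravel()
    w = (halves[:, None] * _GL_WEIGHTS[None, :]).ravel()
    k_full = np.sqrt(K * K + n2g2)
    dinv = -water.chi * hybrid_form_factor(k_full, water)
    f = K * sp.jv(n, K * R) * sp.jv(n, K * a) * dinv / (K * K + kt2)
    value = analytic + float(np.sum(w * f))
    diag = QuadratureDiagnostics(
        value=value,
        kmax=float(edges[-1]),
        n_panels=n_panels,
        tail_bound=_tail_bound(water, edges[-1], R, a, n2g2, kt2),
        cancellation_floor=float(np.finfo(float).eps * np.sum(np.abs(w * f))),
    )
    if rtol_certify is not None and diag.abs_error_estimate > rtol_certify * abs(value):
        raise QuadratureError(
            f"quadrature cannot certify rtol={rtol_certify:g}: "
            f"|W|={abs(value):.3e}, est. error={diag.abs_error_estimate:.3e}",
            diag,
        )
    return (value, diag) if full else value


def propagator_quadrature_mp(n, R, a, kappa, water: WaterDielectricParams, g,
                             kmax: float = 150.0, dps: int = 30):
    """Arbitrary-precision quadrature of W_n (slow; for spot validation).

    Independent of :func:`propagator_quadrature` in both arithmetic and
    scheme: mpmath adaptive Gauss–Legendre on half-period segments, with the
    ionic *and* Lorentzian channels removed through the real-order modified
    Bessel identity so the numerical part decays as K⁻⁶.
    """
    import mpmath as mp

    with mp.workdps(dps):
        L1, L2 = mp.mpf(water.lambda1), mp.mpf(water.lambda2)
        Q, gam = mp.mpf(water.q_osc), mp.mpf(water.gamma)
        chi = mp.mpf(1) / mp.mpf(water.eps_star) - mp.mpf(1) / mp.mpf(water.eps_bulk)
        n2g2 = (mp.mpf(n) * mp.mpf(g)) ** 2
        kt2 = mp.mpf(kappa) ** 2 + n2g2
        if kt2 == 0:
            raise ValueError("W_0 diverges for kappa=0 (pure water)")
        kt = mp.sqrt(kt2)
        rs, rl = min(R, a), max(R, a)

        def ik(m):
            return mp.besseli(n, m * rs) * mp.besselk(n, m * rl)

        # ionic channel at 1/ε* plus the exact Lorentzian-channel integral:
        #   -χγ/(1+Λ1²k²)/(K²+κ̃²) = -χγ/Λ1² · [1/(K²+κ̃²) − 1/(K²+q̃²)]/(q̃²−κ̃²)
        qd2 = 1 / L1**2 + n2g2
        analytic = ik(kt) / mp.mpf(water.eps_star)
        coeff = -chi * gam / (L1**2 * (qd2 - kt2))
        analytic += coeff * (ik(kt) - ik(mp.sqrt(qd2)))

        num = (1 + (L2 * Q) ** 2) ** 2

        def f(K):
            k2 = K * K + n2g2
            k = mp.sqrt(k2)
            den = (1 + L2**2 * (k - Q) ** 2) * (1 + L2**2 * (k + Q) ** 2)
            osc = -chi * (1 - gam) * num / den
            return K * mp.besselj(n, K * R) * mp.besselj(n, K * a) * osc / (K * K + kt2)

        width = mp.pi / (R + a)
        n_seg = int(mp.ceil(mp.mpf(kmax) / width))
        pts = [width * i for i in range(n_seg + 1)]
        val = analytic + mp.quad(f, pts, method="gauss-legendre")
        return float(val)
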