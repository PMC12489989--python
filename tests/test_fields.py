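"""Field assembly: classical limits, symmetry, gradients, charge bookkeeping,
radial smearing."""

import numpy as np
import pytest
import scipy.special as sp

from helixfield.fields import (charge_density, electric_field,
                               harmonic_convergence, potential_total,
                               radial_smearing, zeta_kernel, FieldMap)
from helixfield.helix import (BoundWaterPattern, CounterionPattern,
                              HelixChargeModel, HelixGeometry,
                              PhosphatePattern, default_dna_model)
from helixfield.units import surface_density_to_e_A2


def cylinder_model(delta_a=0.0, radius=10.0):
    """Homogeneous-cylinder limit: wide form factor, no counterions/water."""
    return HelixChargeModel(
        HelixGeometry(),
        PhosphatePattern(sigma_bar=-16.3, delta_eff=1e3, radius=radius,
                         delta_a=delta_a),
        None, None,
    )


class TestClassicalLimits:
    def test_homogeneous_cylinder_debye_huckel(self, const_eps, kappa_phys):
        """Δeff→∞, Θ=0, P̄0=0, ε const → φ = 4πσ̄a I0(κa)K0(κR)/ε."""
        m = cylinder_model()
        R = np.array([11.0, 15.0, 25.0, 40.0])
        phi = potential_total(R, 0.7, -3.0, m, const_eps, kappa_phys,
                              n_max=6, smearing=False)
        sig = surface_density_to_e_A2(-16.3)
        ref = 4 * np.pi * sig * 10 * sp.i0(kappa_phys * 10) \
            * sp.k0(kappa_phys * R) / 94.0
        np.testing.assert_allclose(phi, ref, rtol=1e-10)

    def test_thin_cylinder_line_charge_limit(self, const_eps, kappa_phys):
        """a→0 → (2λ/ε)K0(κR) with λ = 2πaσ̄."""
        m = cylinder_model(radius=0.01)
        phi = potential_total(np.array([5.0]), 0.0, 0.0, m, const_eps,
                              kappa_phys, n_max=4, smearing=False)
        lam = 2 * np.pi * 0.01 * surface_density_to_e_A2(-16.3)
        assert phi[0] == pytest.approx(2 * lam / 94.0 * sp.k0(kappa_phys * 5),
                                       rel=1e-5)

    def test_cylinder_field_bessel_k1(self, const_eps, kappa_phys):
        """E_R = 4πσ̄aκ I0(κa)K1(κR)/ε for the homogeneous cylinder."""
        m = cylinder_model()
        R = np.array([12.0, 20.0])
        e_r, e_p, e_z = electric_field(R, 0.0, 0.0, m, const_eps, kappa_phys,
                                       n_max=4, smearing=False)
        sig = surface_density_to_e_A2(-16.3)
        ref = 4 * np.pi * sig * 10 * kappa_phys * sp.i0(kappa_phys * 10) \
            * sp.k1(kappa_phys * R) / 94.0
        np.testing.assert_allclose(e_r, ref, rtol=1e-9)
        assert np.allclose(e_p, 0) and np.allclose(e_z, 0)

    def test_kappa_zero_potential_raises(self, tip3p, dna_model):
        with pytest.raises(ValueError, match="pure water"):
            potential_total(15.0, 0.0, 0.0, dna_model, tip3p, 0.0)


class TestSymmetryAndSuperposition:
    def test_helical_symmetry(self, tip3p, dna_model, kappa_phys):
        """φ(z,ϕ) = φ(z+z', ϕ+gz') for arbitrary z' (ideal helix)."""
        g = dna_model.geometry.g
        rng = np.random.default_rng(7)
        for _ in range(4):
            R, p, z, zp = 12.5, rng.uniform(0, 2 * np.pi), \
                rng.uniform(-30, 30), rng.uniform(-50, 50)
            a = potential_total(R, p, z, dna_model, tip3p, kappa_phys, 12)
            b = potential_total(R, p + g * zp, z + zp, dna_model, tip3p,
                                kappa_phys, 12)
            assert a == pytest.approx(b, rel=1e-12, abs=1e-18)

    def test_superposition_of_contributions(self, tip3p, dna_model,
                                            kappa_phys):
        """Linear theory: φtot = φ_phosphates + φ_counterions + φ_water."""
        args = (14.0, 1.0, 2.0, dna_model, tip3p, kappa_phys, 10)
        total = potential_total(*args)
        parts = sum(
            potential_total(*args, contributions=[name])
            for name in ("phosphates", "counterions", "bound_water"))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_field_matches_finite_difference_gradient(self, tip3p, dna_model,
                                                      kappa_phys):
        R0, p0, z0, h = 13.0, 0.9, 4.0, 1e-4
        e_r, e_p, e_z = electric_field(np.array([R0]), p0, z0, dna_model,
                                       tip3p, kappa_phys, 10)

        def phi(R, p, z):
            return potential_total(R, p, z, dna_model, tip3p, kappa_phys, 10)

        assert e_r[0] == pytest.approx(
            -(phi(R0 + h, p0, z0) - phi(R0 - h, p0, z0)) / (2 * h), rel=1e-4)
        assert e_p[0] == pytest.approx(
            -(phi(R0, p0 + h, z0) - phi(R0, p0 - h, z0)) / (2 * h * R0),
            rel=1e-4)
        assert e_z[0] == pytest.approx(
            -(phi(R0, p0, z0 + h) - phi(R0, p0, z0 - h)) / (2 * h), rel=1e-4)

    def test_field_finite_in_pure_water(self, tip3p, dna_model):
        e_r, e_p, e_z = electric_field(np.array([11.0, 15.0]), 0.4, 2.0,
                                       dna_model, tip3p, 0.0, n_max=8)
        assert np.isfinite(e_r).all() and np.isfinite(e_p).all() \
            and np.isfinite(e_z).all()
        assert np.abs(e_r).max() > 0


class TestChargeDensity:
    def test_vacuum_has_no_induced_charge(self, vacuum_eps, dna_model):
        rho = charge_density(np.array([8.0, 12.0, 16.0]), 0.3, 1.0,
                             dna_model, vacuum_eps, 0.0, n_max=6)
        np.testing.assert_allclose(rho, 0.0, atol=1e-12)

    def test_electroneutrality_in_electrolyte(self, tip3p, dna_model,
                                              kappa_phys):
        """∫(source+induced) dV = 0 over a large cylinder (Gauss's law)."""
        R = np.linspace(0.05, 150.0, 6000)
        rho = charge_density(R, 0.0, 0.0, dna_model, tip3p, kappa_phys,
                             n_max=0, subtract_source=False)
        q = np.trapezoid(2 * np.pi * R * rho, R)
        lam_src = 2 * np.pi * sum(h.radius * h.potential_amp
                                  for h in dna_model.harmonics(0))
        assert abs(q) < 1e-4 * abs(lam_src)

    def test_oscillation_period_tracks_lambda_o(self, tip3p, dna_model):
        """Induced charge in pure water: alternating shells with asymptotic
        period ≈ Λo (period read from zero crossings)."""
        R = np.linspace(14.0, 30.0, 6000)
        rho = charge_density(R, 0.0, 0.0, dna_model, tip3p, 0.0, n_max=12)
        cross = R[np.where(np.diff(np.sign(rho)) != 0)[0]]
        period = 2 * np.mean(np.diff(cross)[-6:])
        assert period == pytest.approx(2.13, rel=0.25)


class TestRadialSmearing:
    @pytest.mark.parametrize("ratio", [1.0, 5.0, 20.0])
    def test_zeta_normalization(self, ratio):
        """∫₀^∞ ζ da = 1 to 1e-10 across truncation regimes ā/δa."""
        da = 1.0
        abar = ratio * da
        a = np.linspace(0, abar + 12 * da, 400001)
        total = np.trapezoid(zeta_kernel(a, abar, da), a)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_delta_zero_is_identity(self, tip3p, dna_model, kappa_phys):
        fn = radial_smearing(lambda r, a: a * r, 10.0, 0.0)
        assert fn(3.0) == 30.0
        phi_ns = potential_total(13.0, 0.2, 0.0, dna_model, tip3p, kappa_phys,
                                 8, smearing=False)
        m0 = HelixChargeModel(
            dna_model.geometry,
            PhosphatePattern(-16.3, 0.25, 10.0, 0.0),
            CounterionPattern(delta_a=0.0), BoundWaterPattern(delta_a=0.0))
        phi_d0 = potential_total(13.0, 0.2, 0.0, m0, tip3p, kappa_phys, 8,
                                 smearing=True)
        assert phi_ns == pytest.approx(phi_d0, rel=1e-12)

    def test_smearing_monotonically_suppresses_oscillations(self, tip3p,
                                                            kappa_phys):
        """Larger δa → strictly smaller oscillation amplitude at matched
        positions (pure-water induced charge of the phosphate shell)."""
        R = np.linspace(11.5, 18.0, 800)
        amps = []
        for da in (0.0, 0.25, 0.5, 1.0):
            m = HelixChargeModel(HelixGeometry(),
                                 PhosphatePattern(-16.3, 0.25, 10.0, da),
                                 None, None)
            rho = charge_density(R, 0.0, 0.0, m, tip3p, 0.0, n_max=10)
            amps.append(np.max(np.abs(rho)))
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_smeared_far_field_preserves_n0_charge(self, const_eps,
                                                   kappa_phys):
        """Far outside the smeared shell the potential matches a sharp shell
        carrying the ζ-weighted line charge (n=0 charge bookkeeping)."""
        m = cylinder_model(delta_a=0.8)
        R = np.array([45.0])
        phi_sm = potential_total(R, 0.0, 0.0, m, const_eps, kappa_phys, 2)
        nodes, weights = np.polynomial.legendre.leggauss(48)
        lo, hi = 10 - 4, 10 + 4
        aj = 0.5 * (hi + lo) + 0.5 * (hi - lo) * nodes
        wj = 0.5 * (hi - lo) * weights * zeta_kernel(aj, 10.0, 0.8)
        sig = surface_density_to_e_A2(-16.3)
        ref = sum(w * 4 * np.pi * sig * a * sp.i0(kappa_phys * a)
                  for w, a in zip(wj, aj)) * sp.k0(kappa_phys * 45.0) / 94.0
        assert phi_sm[0] == pytest.approx(ref, rel=1e-6)


class TestConvergenceAndMaps:
    def test_harmonic_truncation_converged(self, tip3p, dna_model,
                                           kappa_phys):
        """Default n_max vs 2·n_max: identical at R ≥ a+2 to 1e-6 relative."""
        R = np.linspace(12.0, 30.0, 20)
        p50 = potential_total(R, 1.3, 0.0, dna_model, tip3p, kappa_phys, 50)
        p100 = potential_total(R, 1.3, 0.0, dna_model, tip3p, kappa_phys, 100)
        np.testing.assert_allclose(p50, p100, rtol=1e-6)
        assert harmonic_convergence(dna_model, tip3p, kappa_phys, R, 50) < 1e-6

    def test_field_map_regenerates_identically(self, tip3p, dna_model,
                                               kappa_phys):
        kw = dict(R=np.linspace(11, 20, 5), phi=[0.0, 1.1],
                  z=[0.0, 3.4], n_max=6, quantities=("phi",))
        m1 = FieldMap.compute(dna_model, tip3p, kappa_phys, **kw)
        m2 = FieldMap.compute(dna_model, tip3p, kappa_phys, **kw)
        np.testing.assert_array_equal(m1.data["phi"], m2.data["phi"])

    def test_near_field_mask_flags_charge_shells(self, tip3p, dna_model,
                                                 kappa_phys):
        m = FieldMap.compute(dna_model, tip3p, kappa_phys,
                             R=np.array([4.0, 9.0, 20.0]), phi=[0.0],
                             z=[0.0], n_max=4)
        mask = m.near_field_mask[:, 0, 0]
        assert mask.tolist() == [True, True, False]

    def test_positive_core_inside_dna(self, tip3p, dna_model, kappa_phys):
        """Counterions+bound water produce a positive potential core at
        physiological concentration."""
        phi = potential_total(np.array([1.0, 3.0]), 0.0, 0.0, dna_model,
                              tip3p, kappa_phys, 20)
        assert (phi > 0).all()
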