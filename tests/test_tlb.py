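"""Thermal lattice-Boltzmann solver: lattice identities, physics checks."""

import numpy as np
import pytest

from rhinoflow.tlb import (
    CS2,
    FluidProps,
    OPP,
    T_AMBIENT,
    T_BODY,
    ThermalLatticeSolver,
    UnitBridge,
    W,
    XI,
    equilibrium_f,
    equilibrium_h,
    macroscopic,
    saint_venant_wantzel_density,
    total_energy,
)
from rhinoflow.tlb.lattice import XI_F


def random_states(n=100, seed=0):
    rng = np.random.default_rng(seed)
    rho = rng.uniform(0.9, 1.1, n)
    v = rng.uniform(-0.05, 0.05, (3, n))
    T = rng.uniform(280.0, 320.0, n)
    return rho, v, T


class TestLatticeModel:
    def test_weight_identities(self):
        assert W.sum() == pytest.approx(1.0, abs=1e-15)
        np.testing.assert_allclose(np.einsum("i,ik->k", W, XI_F), 0, atol=1e-15)
        np.testing.assert_allclose(
            np.einsum("i,ik,il->kl", W, XI_F, XI_F), CS2 * np.eye(3), atol=1e-15
        )

    def test_opposites(self):
        np.testing.assert_array_equal(XI[OPP], -XI)

    def test_equilibrium_moments_random_states(self):
        rho, v, T = random_states()
        F = equilibrium_f(rho, v)
        np.testing.assert_allclose(F.sum(axis=0), rho, rtol=0, atol=1e-12)
        np.testing.assert_allclose(
            np.tensordot(XI_F.T, F, axes=(1, 0)), rho * v, atol=1e-12
        )
        H = equilibrium_h(rho, v, T, 1.0)
        E = total_energy(v, T, 1.0)
        np.testing.assert_allclose(H.sum(axis=0), rho * E, rtol=1e-12)

    def test_rest_equilibrium_is_weighted_density(self):
        F = equilibrium_f(np.array([2.0]), np.zeros((3, 1)))
        np.testing.assert_allclose(F[:, 0], 2.0 * W, atol=1e-15)

    def test_equilibrium_h_zero_velocity_flux_vanishes(self):
        H = equilibrium_h(np.array([1.0]), np.zeros((3, 1)), np.array([300.0]), 1.0)
        flux = np.tensordot(XI_F.T, H, axes=(1, 0))
        np.testing.assert_allclose(flux, 0.0, atol=1e-10)

    def test_single_direction_value_scalar_oracle(self):
        rho, v = 1.0, np.array([0.03, 0.0, 0.0])
        F = equilibrium_f(np.array([rho]), v[:, None])
        i = int(np.flatnonzero(np.all(XI == [1, 0, 0], axis=1))[0])
        # direct scalar evaluation
        xv = 0.03
        expected = rho * W[i] * (1 + xv / CS2 + xv**2 / (2 * CS2**2) - 0.03**2 / (2 * CS2))
        assert F[i, 0] == pytest.approx(expected, rel=1e-14)

    def test_macroscopic_matches_bruteforce_sums(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0.01, 0.1, (27, 2, 2, 2))
        h = rng.uniform(0.01, 0.1, (27, 2, 2, 2))
        m = macroscopic(f, h, R=1.0)
        rho_o = np.zeros((2, 2, 2))
        mom_o = np.zeros((3, 2, 2, 2))
        for i in range(27):
            rho_o += f[i]
            for k in range(3):
                mom_o[k] += XI[i, k] * f[i]
        np.testing.assert_allclose(m["rho"], rho_o, rtol=1e-14)
        np.testing.assert_allclose(m["v"], mom_o / rho_o, rtol=1e-13)
        np.testing.assert_allclose(m["p"], rho_o * CS2, rtol=1e-14)

    def test_moment_linearity(self):
        rng = np.random.default_rng(5)
        f1 = rng.uniform(0.01, 0.1, (27, 2, 2, 2))
        f2 = rng.uniform(0.01, 0.1, (27, 2, 2, 2))
        m1, m2, m12 = macroscopic(f1), macroscopic(f2), macroscopic(f1 + f2)
        np.testing.assert_allclose(m12["rho"], m1["rho"] + m2["rho"], rtol=1e-14)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            macroscopic(np.zeros((27, 1, 1, 1)))


class TestSaintVenantWantzel:
    def test_stagnation_density_one(self):
        assert saint_venant_wantzel_density(1.0, 0.0) == 1.0

    def test_small_velocity_taylor_expansion(self):
        # rho ~ 1 - (3/2) v^2 + O(v^4) for gamma = 1.4
        for v in (0.01, 0.02, 0.05):
            rho = saint_venant_wantzel_density(1.0, v**2)
            assert rho == pytest.approx(1 - 1.5 * v**2, abs=5 * v**4)

    def test_direct_formula_oracle(self):
        v, gamma = 0.05, 1.4
        expected = (1 - (gamma - 1) / (2 * gamma) * 3 * v**2) ** (gamma / (gamma - 1))
        assert saint_venant_wantzel_density(1.0, v**2) == pytest.approx(
            expected, rel=1e-14
        )

    def test_supersonic_rejected(self):
        with pytest.raises(ValueError, match="supersonic"):
            saint_venant_wantzel_density(1.0, 10.0)


class TestConservationAndFixedPoint:
    def test_periodic_box_mass_conserved_and_equilibrium_fixed_point(self):
        mask = np.ones((4, 4, 4), bool)
        s = ThermalLatticeSolver(
            mask, FluidProps(nu=0.1), periodic=(True, True, True), thermal=True
        )
        f0, h0 = s.f.copy(), s.h.copy()
        mass0 = s.f.sum()
        for _ in range(200):
            s.step()
            assert abs(s.f.sum() - mass0) / mass0 < 1e-12
        np.testing.assert_allclose(s.f, f0, atol=1e-12)
        np.testing.assert_allclose(s.h, h0, atol=1e-9)

    def test_perturbed_periodic_box_mass_still_conserved(self):
        rng = np.random.default_rng(0)
        mask = np.ones((4, 4, 4), bool)
        s = ThermalLatticeSolver(
            mask, FluidProps(nu=0.1), periodic=(True, True, True), thermal=False
        )
        v = 0.02 * rng.standard_normal((3, 4, 4, 4))
        s.f = equilibrium_f(np.full((4, 4, 4), 1.0), v)
        mass0 = s.f.sum()
        for _ in range(100):
            s.step()
        assert abs(s.f.sum() - mass0) / mass0 < 1e-12

    def test_zero_iterations_leave_fields_at_initialization(self):
        mask = np.ones((3, 3, 3), bool)
        s = ThermalLatticeSolver(mask, FluidProps(nu=0.1), thermal=True)
        res = s.run(n_iter=0)
        np.testing.assert_allclose(res.rho[mask], 1.0, atol=1e-14)
        np.testing.assert_allclose(res.T[mask], T_AMBIENT, atol=1e-10)

    def test_determinism(self):
        def run():
            mask = np.ones((1, 8, 1), bool)
            s = ThermalLatticeSolver(
                mask, FluidProps(nu=0.1), periodic=(True, False, True),
                force=(1e-6, 0, 0), thermal=False,
            )
            for _ in range(50):
                s.step()
            return s.f.copy()

        np.testing.assert_array_equal(run(), run())


class TestShearWaveDecay:
    def test_viscous_decay_rate_matches_navier_stokes(self):
        # transverse shear wave u_y(x) = A sin(2 pi x / L) decays as
        # exp(-nu k^2 t): analytic Navier-Stokes oracle
        L, nu, A = 32, 0.05, 0.005
        mask = np.ones((L, 1, 1), bool)
        s = ThermalLatticeSolver(
            mask, FluidProps(nu=nu), periodic=(True, True, True), thermal=False
        )
        x = np.arange(L)
        v = np.zeros((3, L, 1, 1))
        v[1, :, 0, 0] = A * np.sin(2 * np.pi * x / L)
        s.f = equilibrium_f(np.ones((L, 1, 1)), v)
        k = 2 * np.pi / L

        def amplitude():
            uy = s.moments()["v"][1, :, 0, 0]
            return 2 * np.abs(np.fft.rfft(uy)[1]) / L

        t1, t2 = 100, 300
        for _ in range(t1):
            s.step()
        a1 = amplitude()
        for _ in range(t2 - t1):
            s.step()
        a2 = amplitude()
        measured = -np.log(a2 / a1) / (t2 - t1)
        assert measured == pytest.approx(nu * k**2, rel=0.01)


class TestWalls:
    def test_halfway_bounceback_no_slip_channel_at_rest_stays_at_rest(self):
        mask = np.ones((1, 8, 1), bool)
        s = ThermalLatticeSolver(
            mask, FluidProps(nu=0.1), periodic=(True, False, True), thermal=False
        )
        for _ in range(50):
            s.step()
        assert np.abs(s.moments()["v"]).max() < 1e-14

    def test_wall_temperature_relaxes_fluid_to_body_temperature(self):
        # plane channel at rest, both walls at T_B, fluid starts at T_N
        H = 8
        mask = np.ones((1, H, 1), bool)
        props = FluidProps(nu=0.1)
        s = ThermalLatticeSolver(
            mask, props, periodic=(True, False, True), thermal=True,
            T_init=T_AMBIENT,
        )
        steps = int(10 * H**2 / props.alpha / np.pi**2)
        for _ in range(steps):
            s.step()
        T = s.moments()["T"][0, :, 0]
        np.testing.assert_allclose(T, T_BODY, atol=0.02)

    def test_steady_conduction_linear_profile(self):
        # plates at T_N (bottom) and T_B (top): linear profile within 1%
        H = 16
        mask = np.ones((1, H, 1), bool)
        props = FluidProps(nu=0.1)
        Twf = np.full((1, H, 1), T_BODY)
        Twf[0, : H // 2, 0] = T_AMBIENT
        s = ThermalLatticeSolver(
            mask, props, periodic=(True, False, True), thermal=True,
            T_init=T_AMBIENT, T_wall_field=Twf,
        )
        y = np.arange(H) + 0.5
        T_exact = T_AMBIENT + (T_BODY - T_AMBIENT) * y / H
        s.h = equilibrium_h(
            np.ones((1, H, 1)), np.zeros((3, 1, H, 1)),
            np.tile(T_exact[None, :, None], (1, 1, 1)), props.R,
        )
        steps = int(8 * H**2 / props.alpha / np.pi**2)
        for _ in range(steps):
            s.step()
        T = s.moments()["T"][0, :, 0]
        assert np.abs(T - T_exact).max() / (T_BODY - T_AMBIENT) < 0.01

    def test_poiseuille_profile_within_one_percent(self):
        # nu at the "magic" relaxation (tau-1/2)^2 = 3/16, where the
        # bounce-back Poiseuille solution is exact up to round-off slip
        H, nu, g = 16, np.sqrt(3) / 12, 1e-6
        mask = np.ones((1, H, 1), bool)
        s = ThermalLatticeSolver(
            mask, FluidProps(nu=nu), periodic=(True, False, True),
            force=(g, 0, 0), thermal=False,
        )
        y = np.arange(H) + 0.5
        u_exact = g / (2 * nu) * y * (H - y)
        v0 = np.zeros((3, 1, H, 1))
        v0[0, 0, :, 0] = u_exact
        s.f = equilibrium_f(np.ones((1, H, 1)), v0)
        for _ in range(int(8 * H**2 / nu / np.pi**2)):
            s.step()
        ux = s.moments()["v"][0, 0, :, 0]
        err = np.linalg.norm(ux - u_exact) / np.linalg.norm(u_exact)
        assert err < 0.01
        # slip at wall below 1e-3 of centerline velocity (quadratic
        # extrapolation to y=0, exact for the parabolic profile)
        u_wall = np.polyval(np.polyfit(y[:3], ux[:3], 2), 0.0)
        assert abs(u_wall) / ux.max() < 1e-3


class TestRunDriver:
    def test_monitors_and_time_averaging(self):
        from rhinoflow.tlb import Monitor

        mask = np.ones((4, 4, 4), bool)
        s = ThermalLatticeSolver(
            mask, FluidProps(nu=0.1), periodic=(True, True, True), thermal=False
        )
        mon = Monitor("mean_rho", lambda slv: slv.moments()["rho"].mean(), interval=10)
        res = s.run(n_iter=50, avg_iter=30, monitors=[mon])
        steps, values = res.monitors["mean_rho"]
        assert len(steps) == len(values) == 8  # every 10th of 80 steps
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in values)
        # at the equilibrium fixed point the time average equals the state
        np.testing.assert_allclose(res.avg["rho"], res.rho, atol=1e-12)
        np.testing.assert_allclose(res.avg["v"], res.v, atol=1e-12)


class TestUnits:
    def test_viscosity_bridge_roundtrip(self):
        b = UnitBridge.from_viscosity(dx=1e-4, nu_phys=1.63e-5, nu_lattice=0.05)
        assert b.nu_to_lattice(1.63e-5) == pytest.approx(0.05, rel=1e-12)

    def test_reynolds_number_preserved(self):
        # physical duct: D = 3.2 mm, U = 0.5 m/s -> Re ~ 98
        dx = 1e-4
        b = UnitBridge.from_viscosity(dx=dx, nu_phys=1.63e-5, nu_lattice=0.05)
        D_cells = 3.2e-3 / dx
        u_lat = b.velocity_to_lattice(0.5)
        re_lattice = u_lat * D_cells / 0.05
        re_phys = 0.5 * 3.2e-3 / 1.63e-5
        assert re_lattice == pytest.approx(re_phys, rel=1e-9)

    def test_omega_bounds_enforced(self):
        with pytest.raises(ValueError):
            FluidProps(nu=-0.1)

    def test_fluid_props_defaults(self):
        p = FluidProps(nu=0.05)
        assert 0 < p.omega < 2
        assert p.alpha == pytest.approx(0.05 / 0.72)
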