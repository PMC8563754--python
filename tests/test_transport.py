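"""Drug transport: plasma PK, Patlak flux limits, conservation, positivity,
the well-mixed ODE oracle, and exposure trends in drug parameters."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from chemocycle.coupling import FlowSolution
from chemocycle.tissue import build_domain
from chemocycle.transport import (
    DrugParams,
    concentration_auc,
    lymphatic_drug_sink,
    peclet_factor,
    plasma_concentration,
    simulate_delivery_phase,
    transvascular_drug_flux,
)

MONTH_S = 30.4375 * 86400.0


def uniform_flow(grid, phi_b=5e-4, phi_l=0.0):
    """A fabricated quiescent flow state with uniform exchange rates."""
    n = grid.n
    return FlowSolution(
        network=None,
        p_i=np.zeros((n, n)),
        p_b=np.full((n, n), 2000.0),
        phi_b=np.full((n, n), phi_b),
        phi_l=np.full((n, n), phi_l),
        vx=np.zeros((n + 1, n)),
        vy=np.zeros((n, n + 1)),
        iterations=1,
    )


def uniform_grid(n=8):
    grid = build_domain(0.5e-3, 2e-3, 2e-3 / n)
    grid.sv = np.full((n, n), 20000.0)
    grid.drug_perm_factor = np.ones((n, n))
    grid.receptor_factor = np.ones((n, n))
    return grid


class TestPlasmaPK:
    def test_half_life_identity(self):
        drug = DrugParams()
        cp = plasma_concentration(drug.half_life, [(0.0, 1.0)], drug)
        assert cp == pytest.approx(drug.c0 / 2.0, rel=1e-12)

    def test_zero_before_first_injection(self):
        drug = DrugParams()
        assert plasma_concentration(-1.0, [(0.0, 1.0)], drug) == 0.0

    def test_bolus_superposition(self):
        # two injections (1.0 at t=0, 0.2 at t=0.1 month); just after the
        # second, C_P = C0*(exp(-0.1 month/K_d) + 0.2) by the closed form
        drug = DrugParams()
        t2 = 0.1 * MONTH_S
        expected = drug.c0 * (np.exp(-t2 / drug.k_d) + 0.2)
        got = plasma_concentration(t2, [(0.0, 1.0), (t2, 0.2)], drug)
        assert got == pytest.approx(expected, rel=1e-12)


class TestTransvascularFlux:
    def test_diffusive_limit_at_zero_filtration(self):
        # phi_B = 0: Pe = 0, the Patlak factor -> 1, flux = PS/V (C_P - C_F)
        assert transvascular_drug_flux(2.0, 0.5, 0.0, 1e-3, 0.15) == pytest.approx(1.5e-3)

    def test_zero_at_equilibrium_with_full_reflection(self):
        assert transvascular_drug_flux(1.0, 1.0, 1e-4, 1e-3, 1.0) == pytest.approx(0.0)

    def test_unit_peclet_scalar_oracle(self):
        # Pe = 1, C_F = 0: flux = phi_B(1-sigma)C_P + (PS/V) C_P/(e-1)
        ps_v = 1e-3
        phi_b = ps_v / (1.0 - 0.15)  # makes Pe exactly 1
        got = transvascular_drug_flux(1.0, 0.0, phi_b, ps_v, 0.15)
        expected = ps_v * 1.0 + ps_v / (np.e - 1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_pure_convective_limit_without_permeability(self):
        got = transvascular_drug_flux(1.0, 0.3, 1e-4, 0.0, 0.15)
        assert got == pytest.approx(1e-4 * 0.85, rel=1e-12)

    def test_peclet_factor_limit_and_symmetry(self):
        assert peclet_factor(0.0) == pytest.approx(1.0)
        assert peclet_factor(1e-12) == pytest.approx(1.0, abs=1e-9)
        assert peclet_factor(2.0) == pytest.approx(2.0 / (np.e**2 - 1.0), rel=1e-12)
        assert peclet_factor(-2.0) == pytest.approx(-2.0 / (np.exp(-2.0) - 1.0), rel=1e-12)


def test_lymphatic_sink_bilinear():
    assert lymphatic_drug_sink(0.0, 1e-4) == 0.0
    assert lymphatic_drug_sink(2.0, 0.0) == 0.0
    assert lymphatic_drug_sink(2.0, 3e-4) == pytest.approx(2.0 * lymphatic_drug_sink(1.0, 3e-4))


class TestDeliveryPhase:
    def test_no_binding_means_no_bound_or_internalized(self):
        grid = uniform_grid()
        drug = DrugParams(k_on=0.0)
        res = simulate_delivery_phase(grid, uniform_flow(grid), drug, [(0.0, 1.0)], 3600.0)
        assert np.all(res.c_b == 0.0)
        assert np.all(res.c_int == 0.0)
        assert res.c_f.max() > 0.0

    def test_zero_injections_stay_zero(self):
        grid = uniform_grid()
        res = simulate_delivery_phase(grid, uniform_flow(grid), DrugParams(), [], 3600.0)
        assert np.all(res.c_f == 0.0) and np.all(res.c_int == 0.0)

    def test_well_mixed_matches_independent_ode_solve(self):
        # spatially uniform problem: the cell-mean trajectories must match a
        # 3-species well-mixed stiff-ODE reference within 1%
        grid = uniform_grid()
        drug = DrugParams()
        flow = uniform_flow(grid, phi_b=5e-4, phi_l=1e-5)
        horizon = 6 * 3600.0
        res = simulate_delivery_phase(grid, flow, drug, [(0.0, 1.0)], horizon)

        ps_v = drug.perm * 20000.0
        conv = 5e-4 * (1.0 - drug.sigma_f)
        pe = conv / ps_v
        diff = ps_v * pe / np.expm1(pe)
        kphi = drug.k_on / drug.phi

        def rhs(t, y):
            cf, cb, cint = y
            crec = max(drug.c_rec0 - cb - cint, 0.0)
            cp = drug.c0 * np.exp(-t / drug.k_d)
            bind = kphi * crec * cf
            return [
                conv * cp + diff * (cp - cf) - 1e-5 * cf - bind + drug.k_off * cb,
                bind - (drug.k_off + drug.k_int) * cb,
                drug.k_int * cb,
            ]

        ref = solve_ivp(rhs, (0.0, horizon), [0.0, 0.0, 0.0], method="BDF",
                        rtol=1e-10, atol=1e-16, t_eval=res.times)
        got = res.region_mean("internal")
        scale = ref.y[2, -1]
        assert np.max(np.abs(got - ref.y[2]) / scale) < 0.01
        got_b = res.region_mean("bound")
        assert np.max(np.abs(got_b - ref.y[1]) / max(ref.y[1].max(), 1e-12)) < 0.01

    def test_mass_balance_nonnegativity_monotonicity(self, default_flow):
        grid, flow = default_flow
        res = simulate_delivery_phase(grid, flow, DrugParams(), [(0.0, 1.0)], 24 * 3600.0)
        assert res.mass_balance_error() < 1e-3
        for arr in (res.c_f, res.c_b, res.c_int):
            assert arr.min() >= 0.0
        assert np.diff(res.c_int, axis=0).min() >= -1e-12 * res.c_int.max()

    def test_internalized_exposure_increases_with_diffusivity(self, default_flow):
        grid, flow0 = default_flow
        means = []
        for d in (1.7e-10, 3.4e-10, 10e-10):
            res = simulate_delivery_phase(grid, flow0, DrugParams(d_diff=d), [(0.0, 1.0)], 24 * 3600.0)
            means.append(res.c_int[-1][grid.tumor_mask].mean())
        assert means[0] <= means[1] <= means[2]

    def test_internalized_exposure_increases_with_half_life(self, default_flow):
        grid, flow0 = default_flow
        means = []
        for hl_min in (3.0, 6.0, 12.0):
            res = simulate_delivery_phase(grid, flow0, DrugParams(half_life=hl_min * 60.0), [(0.0, 1.0)], 24 * 3600.0)
            means.append(res.c_int[-1][grid.tumor_mask].mean())
        assert means[0] <= means[1] <= means[2]


class TestAUC:
    def test_constant_series(self):
        assert concentration_auc([0.0, 10.0], [2.0, 2.0]) == pytest.approx(20.0)

    def test_exponential_closed_form(self):
        tau = 100.0
        t = np.linspace(0, 30 * tau, 20000)
        assert concentration_auc(t, 3.0 * np.exp(-t / tau)) == pytest.approx(3.0 * tau, rel=1e-4)

    def test_needs_two_points_and_nonempty_mask(self, default_flow):
        with pytest.raises(ValueError):
            concentration_auc([0.0], [1.0])
        grid, flow = default_flow
        res = simulate_delivery_phase(grid, flow, DrugParams(), [], 100.0)
        with pytest.raises(ValueError):
            res.region_mean("free", np.zeros((grid.n, grid.n), dtype=bool))
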