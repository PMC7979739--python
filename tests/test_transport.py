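"""Grid geometry, diffusion, surface exchange and the moving boundary."""

import numpy as np
import pytest

from ferrad.chemistry import LightField, default_scheme, rhs_layer, apply_equilibria
from ferrad.microphysics import EnvironmentalState, PropertyModel
from ferrad.transport import (LayerGrid, advance, build_grid, diffusive_step,
                              surface_exchange, update_geometry,
                              equilibrium_concentrations)


def tracer_grid(geometry, size, n, uniform=False, **kw):
    g = build_grid(geometry, size, n, species=["X"], uniform=uniform, **kw)
    return g


class TestBuildGrid:
    @pytest.mark.parametrize("geometry,factor", [
        ("sphere", 4.0 / 3.0), ("half-sphere", 2.0 / 3.0)])
    def test_shell_volumes_sum_to_particle_volume(self, geometry, factor):
        r = 0.5e-6
        g = tracer_grid(geometry, r, 30)
        assert g.volumes.sum() == pytest.approx(factor * np.pi * r**3, rel=1e-12)

    def test_uniform_film_slabs(self):
        g = tracer_grid("planar-film", 1.1e-6, 11, uniform=True)
        assert np.allclose(g.volumes, 0.1e-6, rtol=1e-12)

    def test_surface_layer_is_finest(self):
        g = tracer_grid("sphere", 0.5e-6, 25)
        widths = np.diff(g.edges)
        assert widths[-1] == min(widths)
        assert widths[-1] <= 0.1e-9 * (1 + 1e-9)
        ratios = widths[:-1] / widths[1:]
        assert np.all(ratios <= 1.6 + 1e-9)

    def test_infeasible_refinement_fails(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_grid("sphere", 8e-6, 10, surface_refinement=0.1e-9,
                       species=["X"])

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_grid("sphere", -1.0, 10, species=["X"])
        with pytest.raises(ValueError):
            build_grid("cube", 1e-6, 10, species=["X"])


class TestDiffusiveStep:
    def test_uniform_profile_unchanged(self):
        g = tracer_grid("sphere", 1e-6, 20)
        g.concentrations[:] = 3.14
        out = diffusive_step(g, np.array([1e-12]), 1.0)
        assert np.allclose(out.concentrations, 3.14, rtol=1e-12)

    def test_moles_conserved(self):
        g = tracer_grid("sphere", 1e-6, 20)
        rng = np.random.default_rng(0)
        g.concentrations[0] = rng.uniform(0, 10, g.n_layers)
        before = g.total_moles()
        out = diffusive_step(g, np.array([1e-12]), 5.0)
        assert out.total_moles() == pytest.approx(before, rel=1e-12)

    def test_two_box_relaxation_rate(self):
        """A two-slab step profile decays at the analytic rate D*A/(V*dx)."""
        g = tracer_grid("planar-film", 2e-6, 2, uniform=True)
        g.concentrations[0] = [2.0, 0.0]
        d = 1e-12
        a_over_dx = 1.0 / 1e-6  # unit area, centre distance 1 um
        v = 1e-6
        lam = d * a_over_dx * (2.0 / v)  # symmetric two-box eigenvalue
        dt = 0.001 / lam
        c = g
        n = 800
        for _ in range(n):
            c = diffusive_step(c, np.array([d]), dt)
        diff = c.concentrations[0, 0] - c.concentrations[0, 1]
        assert diff == pytest.approx(2.0 * np.exp(-lam * n * dt), rel=0.01)

    def test_sphere_uptake_matches_series_solution(self):
        """Fixed-surface-concentration uptake follows the classical series.

        M(t)/M_inf = 1 - (6/pi^2) sum exp(-n^2 pi^2 D t / r^2) / n^2
        """
        r, d = 1e-6, 1e-13
        g = build_grid("sphere", r, 60, surface_refinement=4e-9, species=["X"])
        c_s = 1.0
        g.concentrations[0, -1] = c_s
        tau = r**2 / d
        t_half = 0.0306 * tau  # where the series gives M/M_inf = 0.5
        n_steps = 2000
        dt = t_half / n_steps
        c = g
        for _ in range(n_steps):
            c = diffusive_step(c, np.array([d]), dt)
            c.concentrations[0, -1] = c_s  # clamp the boundary
        v = c.volumes
        uptake = (c.concentrations[0, :-1] * v[:-1]).sum() / (c_s * v[:-1].sum())
        series = 1.0 - 6.0 / np.pi**2 * sum(
            np.exp(-n**2 * np.pi**2 * d * t_half / r**2) / n**2
            for n in range(1, 300))
        assert uptake == pytest.approx(series, abs=0.01)


@pytest.fixture(scope="module")
def film_setup():
    scheme = default_scheme()
    props = PropertyModel()
    env = EnvironmentalState(20.0, 50.0, partial_pressures={"O2": 200.0},
                             total_pressure=1000.0, light=LightField.dark())
    material = props.material_properties(env, 0.05, scheme)
    return scheme, props, env, material


class TestSurfaceExchange:
    def make_grid(self, scheme, n=6):
        g = build_grid("planar-film", 1e-6, n, uniform=True,
                       species=[s.name for s in scheme.species])
        return g

    def test_equilibrium_means_zero_flux(self, film_setup):
        scheme, _, env, mat = film_setup
        g = self.make_grid(scheme)
        ceq = equilibrium_concentrations(scheme, env, mat)
        for name, v in ceq.items():
            g.concentrations[g.species.index(name), :] = v
        _, fluxes = surface_exchange(g, scheme, env, mat, 1.0)
        assert all(abs(f) < 1e-15 for f in fluxes.values())

    def test_supersaturated_outgasses(self, film_setup):
        scheme, _, env, mat = film_setup
        g = self.make_grid(scheme)
        ceq = equilibrium_concentrations(scheme, env, mat)
        g.concentrations[g.species.index("O2"), :] = 5 * ceq["O2"]
        _, fluxes = surface_exchange(g, scheme, env, mat, 1.0)
        assert fluxes["O2"] > 0  # positive = evaporation

    def test_fast_conductance_equals_clamped_boundary(self, film_setup):
        scheme, _, env, mat = film_setup
        g = self.make_grid(scheme)
        out, _ = surface_exchange(g, scheme, env, mat, dt=10.0,
                                  conductance=10.0)
        ceq = equilibrium_concentrations(scheme, env, mat)
        io2 = g.species.index("O2")
        assert out.concentrations[io2, -1] == pytest.approx(ceq["O2"], rel=0.01)

    def test_nonvolatiles_untouched(self, film_setup):
        scheme, _, env, mat = film_setup
        g = self.make_grid(scheme)
        g.concentrations[g.species.index("CA"), :] = 5000.0
        out, _ = surface_exchange(g, scheme, env, mat, 100.0)
        assert np.allclose(out.concentrations[g.species.index("CA")], 5000.0)


class TestAdvance:
    def test_closed_dark_state_is_constant(self, film_setup):
        scheme, props, env, mat = film_setup
        g = build_grid("sphere", 0.5e-6, 14, surface_refinement=4e-9,
                       species=[s.name for s in scheme.species])
        c0 = scheme.concentration_vector({"CA": 5000.0, "FeIIICit": 250.0})
        c0 = apply_equilibria(c0, scheme)
        g.concentrations[:] = c0[:, None]
        # seal the particle (no gas exchange) and switch the light off
        res = advance(g, scheme, env, mat, 600.0, segment_length=200.0,
                      conductance=0.0, move_boundary=False)
        assert np.allclose(res.concentrations[-1], res.concentrations[0],
                           rtol=1e-6, atol=1e-6)

    def test_well_mixed_limit_matches_zero_d_oracle(self, film_setup):
        """With very fast diffusion the layered model collapses to one box."""
        from scipy.integrate import solve_ivp
        scheme, props, env, _ = film_setup
        mat = props.material_properties(env, 0.05, scheme)
        mat.d_x = np.full(scheme.n_species, 1e-7)  # everything well mixed
        g = build_grid("sphere", 0.5e-6, 10, surface_refinement=2e-8,
                       species=[s.name for s in scheme.species])
        env_lit = EnvironmentalState(20.0, 50.0,
                                     partial_pressures={"O2": 200.0},
                                     total_pressure=1000.0,
                                     light=LightField.from_band("uv_365"))
        c0 = scheme.concentration_vector({"CA": 5000.0, "FeIIICit": 250.0})
        c0 = apply_equilibria(c0, scheme)
        g.concentrations[:] = c0[:, None]
        kc = 1e-4
        res = advance(g, scheme, env_lit, mat, 300.0, segment_length=300.0,
                      conductance=kc, move_boundary=False,
                      rtol=1e-8, atol=1e-11)
        v = res.volumes(-1)
        mean = res.concentrations[-1] @ (v / v.sum())

        ceq = equilibrium_concentrations(scheme, env_lit, mat)
        vol_idx = np.flatnonzero(scheme.volatile_mask)
        c_eq_vec = np.zeros(scheme.n_species)
        for i in vol_idx:
            c_eq_vec[i] = ceq[scheme.species[i].name]
        a_over_v = g.surface_area / g.volumes.sum()

        def f(t, y):
            yp = 0.5 * (y + np.sqrt(y * y + 1e-30))
            dy = rhs_layer(yp, scheme, env_lit.j, env_lit.rh, mat.d_x,
                           validate=False)
            dy[vol_idx] -= kc * a_over_v * (y[vol_idx] - c_eq_vec[vol_idx])
            return dy

        oracle = solve_ivp(f, (0, 300.0), c0, method="BDF",
                           rtol=1e-10, atol=1e-13).y[:, -1]
        scale = np.abs(oracle).max()
        assert np.max(np.abs(mean - oracle) / (np.abs(oracle) + 1e-6 * scale)) < 1e-3

    def test_iron_conserved_over_run(self, film_setup):
        scheme, props, _, _ = film_setup
        env = EnvironmentalState(20.0, 40.0, partial_pressures={"O2": 112.0},
                                 total_pressure=150.0,
                                 light=LightField.from_band("uv_365"))
        mat = props.material_properties(env, 1.0, scheme)
        g = build_grid("sphere", 0.3e-6, 12, surface_refinement=2e-9,
                       species=[s.name for s in scheme.species])
        c0 = scheme.concentration_vector({"CA": 4000.0, "FeIIICit": 2000.0})
        g.concentrations[:] = apply_equilibria(c0, scheme)[:, None]
        fe0 = scheme.fe_weights @ (g.concentrations @ g.volumes)
        res = advance(g, scheme, env, mat, 900.0, segment_length=300.0)
        fe1 = scheme.fe_weights @ (res.concentrations[-1] @ res.volumes(-1))
        assert fe1 == pytest.approx(fe0, rel=1e-6)


class TestUpdateGeometry:
    def grid(self):
        g = build_grid("sphere", 1e-6, 15, surface_refinement=5e-9, species=["X", "Y"])
        g.concentrations[0] = 100.0
        g.concentrations[1] = np.linspace(0, 50, 15)
        return g

    def test_zero_evaporation_is_identity(self):
        g = self.grid()
        out = update_geometry(g, 0.0)
        assert np.allclose(out.edges, g.edges)
        assert np.allclose(out.concentrations, g.concentrations)

    def test_third_of_mass_gives_twelve_percent_radius_loss(self):
        g = self.grid()
        out = update_geometry(g, 0.33 * g.volumes.sum())
        assert out.size / g.size == pytest.approx((1 - 0.33) ** (1 / 3), rel=1e-9)
        assert out.size / g.size == pytest.approx(0.875, abs=0.005)

    def test_remap_conserves_moles(self):
        g = self.grid()
        out = update_geometry(g, 0.2 * g.volumes.sum())
        assert np.allclose(out.total_moles(), g.total_moles(), rtol=1e-10)

    def test_overdraft_fails(self):
        g = self.grid()
        with pytest.raises(ValueError):
            update_geometry(g, 2 * g.volumes.sum())
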