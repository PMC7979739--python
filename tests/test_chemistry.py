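"""Rate laws, photolysis anchors, equilibria and conservation properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ferrad.chemistry import (Equilibrium, LightField, Reaction, ReactionScheme,
                              Species, apply_equilibria, default_scheme,
                              dump_mechanism, k_sr_of_rh, load_mechanism,
                              photolysis_rate, reaction_rates, rhs_layer)
from ferrad.constants import PER_MOLAR_TO_SI


class TestPhotolysisRate:
    @pytest.mark.parametrize("band,power,expected", [
        ("uv_365", 3.6, 2.2e-3),     # microscope UV LED at measured power
        ("vis_473", 40.0, 4.3e-3),   # levitation laser, full power
        ("vis_473", 20.0, 2.2e-3),   # half power halves j (linearity)
        ("cwft_lamp", None, 9.1e-3),
        ("full_sun", None, 5.23e-2),
    ])
    def test_band_anchors(self, band, power, expected):
        light = LightField.from_band(band, power)
        assert photolysis_rate(light) == pytest.approx(expected, rel=0.05)

    def test_dark_means_no_photolysis(self):
        assert photolysis_rate(LightField.from_band("uv_365", 0.0)) == 0.0

    def test_unknown_band_fails(self):
        with pytest.raises(KeyError):
            LightField.from_band("microwave")

    def test_linear_in_power(self):
        j1 = photolysis_rate(LightField.from_band("uv_365", 1.0))
        j5 = photolysis_rate(LightField.from_band("uv_365", 5.0))
        assert j5 == pytest.approx(5 * j1, rel=1e-12)


class TestKsr:
    def test_dilute_mode_is_rh_independent(self):
        for rh in (0.0, 37.0, 99.0):
            assert k_sr_of_rh(rh, mode="dilute") == 8.3e5

    def test_polynomial_at_rh50(self):
        # direct evaluation of the printed cubic: log10 k = 7.8173 at RH=50
        assert k_sr_of_rh(50.0) == pytest.approx(10 ** 7.8173, rel=1e-4)

    def test_polynomial_at_rh0(self):
        assert k_sr_of_rh(0.0) == pytest.approx(10 ** -0.05018, rel=1e-9)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            k_sr_of_rh(101.0)
        with pytest.raises(ValueError):
            k_sr_of_rh(-1.0)

    def test_continuous_and_finite(self):
        rh = np.linspace(0, 100, 2001)
        vals = np.array([k_sr_of_rh(r) for r in rh])
        assert np.all(np.isfinite(vals)) and np.all(vals > 0)
        # no jumps: neighbouring evaluations differ by < 5%
        assert np.max(np.abs(np.diff(np.log10(vals)))) < np.log10(1.05)


class TestReactionRates:
    def test_zero_state_zero_rates(self, scheme):
        c = np.zeros(scheme.n_species)
        rates = reaction_rates(c, scheme, j=1e-3, rh=50.0)
        assert np.all(rates == 0.0)

    def test_dark_equilibrated_state_is_stationary(self, scheme):
        # only the oxidized complex present, dark, no O2: nothing reacts
        c = scheme.concentration_vector({"CA": 5000.0, "FeIIICit": 250.0})
        c = apply_equilibria(c, scheme)
        dc = rhs_layer(c, scheme, j=0.0, rh=40.0)
        assert np.max(np.abs(dc)) < 1e-10 * 5000.0

    def test_negative_concentration_identified(self, scheme):
        c = np.zeros((scheme.n_species, 3))
        c[scheme.index["O2"], 1] = -1.0
        with pytest.raises(ValueError, match="O2.*layer 1"):
            reaction_rates(c, scheme, j=0.0, rh=50.0)

    def test_photolytic_rates_scale_with_j(self, scheme):
        c = scheme.concentration_vector({"FeIIICit": 100.0})
        r1 = reaction_rates(c, scheme, j=1e-3, rh=50.0)
        r2 = reaction_rates(c, scheme, j=2e-3, rh=50.0)
        photo = scheme._photo
        assert np.allclose(r2[photo], 2 * r1[photo])

    def test_diffusion_cap_reduces_bimolecular_rates(self, scheme):
        c = scheme.concentration_vector({"CCR": 100.0, "O2": 10.0})
        fast = reaction_rates(c, scheme, 0.0, 50.0, diffusivities=None)
        d_x = 1e-15 * scheme.f_dx  # highly viscous matrix
        slow = reaction_rates(c, scheme, 0.0, 50.0, diffusivities=d_x)
        i = [r.name for r in scheme._kinetic].index("R2_ccr_o2")
        assert slow[i] < fast[i]


class TestPhotostationaryState:
    def test_reduced_scheme_matches_closed_form(self, reduced_scheme):
        j, k = 4.3e-3, 2.0e-3
        c0 = reduced_scheme.concentration_vector({"AOX": 1.0})
        sol = solve_ivp(lambda t, y: rhs_layer(y, reduced_scheme, j, 50.0),
                        (0, 2e4), c0, method="LSODA", rtol=1e-10, atol=1e-14)
        frac = sol.y[0, -1] / sol.y[:, -1].sum()
        assert frac == pytest.approx(k / (j + k), abs=1e-6)


class TestConservation:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_iron_is_conserved_by_chemistry(self, seed):
        scheme = default_scheme()
        rng = np.random.default_rng(seed)
        c = rng.uniform(0, 100.0, scheme.n_species)
        dc = rhs_layer(c, scheme, j=5e-3, rh=rng.uniform(0, 100),
                       diffusivities=1e-12 * scheme.f_dx)
        fe_rate = scheme.fe_weights @ dc
        scale = np.abs(dc).max() + 1e-30
        assert abs(fe_rate) < 1e-12 * scale * scheme.n_species

    def test_carbon_ledger_in_closed_box(self, scheme):
        # condensed carbon is constant along a sealed 0-D trajectory because
        # volatile products stay in the box until surface exchange removes them
        c0 = scheme.concentration_vector(
            {"CA": 5000.0, "FeIIICit": 250.0, "O2": 10.0})
        c0 = apply_equilibria(c0, scheme)
        sol = solve_ivp(lambda t, y: rhs_layer(
            0.5 * (y + np.sqrt(y * y + 1e-24)), scheme, 2e-3, 50.0,
            validate=False),
            (0, 600.0), c0, method="LSODA", rtol=1e-8, atol=1e-12)
        carbon = scheme.c_weights @ sol.y
        assert np.max(np.abs(carbon - carbon[0])) < 1e-6 * carbon[0]


class TestApplyEquilibria:
    def test_strong_binding_with_excess_ligand(self):
        sp = [Species("M", 50.0, category="iron", n_fe=1),
              Species("L", 100.0, category="organic", n_c=6),
              Species("ML", 150.0, category="iron", n_fe=1, n_c=6)]
        scheme = ReactionScheme(sp, [], [Equilibrium("ML", "M", "L", 1e12)])
        c = scheme.concentration_vector({"M": 10.0, "L": 1000.0})
        out = apply_equilibria(c, scheme)
        assert out[scheme.index["M"]] < 1e-6 * 10.0
        assert out[scheme.index["ML"]] == pytest.approx(10.0, rel=1e-6)

    def test_no_metal_is_identity(self, scheme):
        c = scheme.concentration_vector({"CA": 1234.5, "O2": 7.0})
        out = apply_equilibria(c, scheme)
        assert np.allclose(out, c, rtol=1e-12)

    def test_equal_totals_match_scalar_root(self):
        sp = [Species("M", 50.0, category="iron", n_fe=1),
              Species("L", 100.0, category="organic", n_c=6),
              Species("ML", 150.0, category="iron", n_fe=1, n_c=6)]
        K = 1.0  # M^-1
        scheme = ReactionScheme(sp, [], [Equilibrium("ML", "M", "L", K)])
        total = 2000.0  # mol/m^3 each
        c = scheme.concentration_vector({"M": total, "L": total})
        out = apply_equilibria(c, scheme)
        k_si = K * PER_MOLAR_TO_SI
        # independent scalar solve of K = x/((total-x)^2)
        x = brentq(lambda x: k_si * (total - x) ** 2 - x, 0.0, total)
        assert out[scheme.index["ML"]] == pytest.approx(x, rel=1e-7)

    def test_totals_conserved_exactly(self, scheme):
        rng = np.random.default_rng(7)
        c = np.abs(rng.normal(100, 50, (scheme.n_species, 5)))
        out = apply_equilibria(c, scheme)
        for w in (scheme.fe_weights,):
            assert np.allclose(w @ out, w @ c, rtol=1e-12)
        ca_pool = [scheme.index[n] for n in ("CA", "FeIIICit", "FeIIHCit")]
        assert np.allclose(out[ca_pool].sum(axis=0), c[ca_pool].sum(axis=0),
                           rtol=1e-12)
        assert np.all(out >= 0)


class TestWellMixedOracle:
    def test_full_scheme_against_dense_mass_action_integrator(self, scheme):
        """The compiled RHS must agree with a brute-force evaluation built
        directly from the mechanism's reaction list."""
        env_dx = 1e-12 * scheme.f_dx
        j, rh = 2e-3, 50.0

        def brute_rhs(t, y):
            yp = 0.5 * (y + np.sqrt(y * y + 1e-24))
            dy = np.zeros_like(y)
            from ferrad.constants import AVOGADRO
            for r in scheme._kinetic:
                if r.law == "photolytic":
                    k = j
                elif r.law == "unimolecular":
                    k = r.rate_parameter
                else:
                    k_m = (k_sr_of_rh(rh) if r.ksr_mode == "rh_polynomial"
                           else r.rate_parameter)
                    k = k_m * PER_MOLAR_TO_SI
                    if r.diffusion_limited:
                        ia, ib = [scheme.index[n] for n, s in r.reactants.items()
                                  for _ in range(s)][:2], None
                        pair = [scheme.index[n] for n, s in r.reactants.items()
                                for _ in range(s)]
                        kd = 4 * np.pi * (env_dx[pair[0]] + env_dx[pair[1]]) \
                            * 5e-10 * AVOGADRO
                        k = 1.0 / (1.0 / k + 1.0 / kd)
                rate = k
                for name, s in r.reactants.items():
                    rate = rate * yp[scheme.index[name]] ** s
                for name, s in r.reactants.items():
                    dy[scheme.index[name]] -= s * rate
                for name, s in r.products.items():
                    dy[scheme.index[name]] += s * rate
            return dy

        c0 = scheme.concentration_vector(
            {"CA": 5000.0, "FeIIICit": 250.0, "O2": 10.0})
        c0 = apply_equilibria(c0, scheme)
        t_eval = [60.0, 300.0]
        fast = solve_ivp(lambda t, y: rhs_layer(
            0.5 * (y + np.sqrt(y * y + 1e-24)), scheme, j, rh, env_dx,
            validate=False), (0, 300), c0, method="LSODA",
            rtol=1e-9, atol=1e-13, t_eval=t_eval)
        slow = solve_ivp(brute_rhs, (0, 300), c0, method="Radau",
                         rtol=1e-9, atol=1e-13, t_eval=t_eval)
        scale = np.abs(fast.y).max(axis=1, keepdims=True) + 1e-12
        assert np.max(np.abs(fast.y - slow.y) / scale) < 1e-3


class TestMechanismIO:
    def test_round_trip(self, tmp_path, scheme):
        path = tmp_path / "mech.yaml"
        dump_mechanism(scheme, path)
        again = load_mechanism(path)
        assert [s.name for s in again.species] == [s.name for s in scheme.species]
        assert again.n_chemical == scheme.n_chemical
        assert again.switches == scheme.switches
        for a, b in zip(again._base_reactions(), scheme._base_reactions()):
            assert a.name == b.name and a.rate_parameter == b.rate_parameter
            assert a.reactants == b.reactants and a.products == b.products
        # and the compiled networks produce identical rates
        c = np.full(scheme.n_species, 10.0)
        r1 = reaction_rates(c, scheme, 1e-3, 40.0)
        r2 = reaction_rates(c, again, 1e-3, 40.0)
        assert np.allclose(r1, r2, rtol=1e-12)

    def test_default_switches_match_reported_configuration(self, scheme):
        assert scheme.switches["ccr_self_reaction"] is False
        assert scheme.switches["h2o2_first_order_loss"] == pytest.approx(1e-4)

    def test_element_balance_enforced(self):
        sp = [Species("A", 10.0, category="organic", n_c=2),
              Species("B", 10.0, category="organic", n_c=1)]
        with pytest.raises(ValueError, match="element balance"):
            ReactionScheme(sp, [Reaction({"A": 1}, {"B": 1}, "unimolecular",
                                         1.0, name="bad")])

    def test_henry_iff_volatile(self):
        with pytest.raises(ValueError, match="henry"):
            Species("X", 10.0, volatile=True)
        with pytest.raises(ValueError, match="henry"):
            Species("Y", 10.0, henry=1.0, volatile=False)
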