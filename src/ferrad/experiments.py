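"""Protocol drivers for the three laboratory pipelines and the ambient scan.

Each driver composes the transport integrator and the observables into a
scripted experiment:

* ``run_stxm`` — half-sphere particles on a substrate, 15 min UV photolysis
  followed by dark reoxidation under a fixed O2/H2O/He atmosphere; reports
  column-integrated beta ring profiles over time.
* ``run_edb`` — a single levitated 8 um droplet in pure O2, dark
  equilibration then multi-hour visible irradiation; reports r(t)/r0.
* ``run_cwft`` — a film coated inside a flow tube, broadband illumination
  with NO-titrated HO2 release; reports steady-state P_HO2.
* ``run_atmospheric_scan`` — quasi-steady radical burdens of a 0.5 um
  particle over (T, RH) or (Mr, j) grids.

All drivers are deterministic given their configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .chemistry import LightField, ReactionScheme, apply_equilibria, default_scheme
from .microphysics import EnvironmentalState, PropertyModel
from .observables import (BetaProfile, PhaseDiagram, beta_column_2d, p_ho2,
                          phase_scan, radical_burden, radius_trace)
from .transport import LayerGrid, SimulationResult, advance, build_grid

__all__ = ["ProtocolConfig", "Numerics", "run_stxm", "run_edb", "run_cwft",
           "run_atmospheric_scan", "initial_grid"]

# O2 partial pressure (mbar) used in the microscopy chamber at each RH
STXM_O2_MBAR = {40.0: 112.0, 50.0: 107.0, 60.0: 104.0}
# coated tube: 1.2 cm diameter, 50 cm length
CWFT_FILM_AREA = np.pi * 0.012 * 0.50  # m^2


@dataclass
class Numerics:
    """Grid and solver resolution for a protocol run."""

    n_layers: int = 24
    surface_refinement: float | None = None
    segment_length: float = 120.0
    rtol: float = 1e-5
    atol: float = 1e-8
    record_every: int = 1
    conductance: float = 1.0e-4

    def scaled(self, **kw) -> "Numerics":
        out = copy.copy(self)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class ProtocolConfig:
    """Declarative description of one laboratory run."""

    protocol: str
    mr: float = 0.05
    mr_uncertainty: float = 0.0
    temperature: float = 20.0
    rh: float = 50.0
    geometry: str = "sphere"
    size: float = 8.0e-6
    phases: list = field(default_factory=list)  # (duration_s, EnvironmentalState)
    numerics: Numerics = field(default_factory=Numerics)

    def __post_init__(self):
        if self.mr <= 0:
            raise ValueError("mole ratio must be positive")
        for duration, _ in self.phases:
            if duration <= 0:
                raise ValueError("phase durations must be positive")


def initial_grid(scheme: ReactionScheme, props: PropertyModel, geometry: str,
                 size: float, mr: float, env: EnvironmentalState,
                 numerics: Numerics, beta0: float = 1.0,
                 area: float = 1.0) -> LayerGrid:
    """Uniform initial state: citric acid plus iron citrate at mole ratio Mr.

    ``beta0`` sets the initial iron(III) fraction (1.0 = fully oxidized, the
    fresh-solution state); the remainder is placed in the iron(II) complex.
    """
    w = props.water_content(env.rh, mr, env.temperature)
    rho = props.density(env.rh, mr, env.temperature)  # g/cm^3
    dry_g_per_m3 = rho * 1e6 * (1.0 - w)
    m_fe3 = scheme.species[scheme.index["FeIIICit"]].molar_mass
    ca_total = dry_g_per_m3 / (192.12 + mr * m_fe3)  # mol/m^3 free citrate
    fe_total = mr * ca_total
    grid = build_grid(geometry, size, numerics.n_layers,
                      numerics.surface_refinement,
                      species=[s.name for s in scheme.species], area=area)
    c0 = scheme.concentration_vector({
        "CA": ca_total,
        "FeIIICit": fe_total * beta0,
        "FeIIHCit": fe_total * (1.0 - beta0),
    })
    grid.concentrations[:] = c0[:, None]
    grid.concentrations = apply_equilibria(grid.concentrations, scheme)
    return grid


def _run_phases(grid, scheme, props, mr, phases, numerics,
                henry_scaling=None) -> SimulationResult:
    result = None
    for duration, env in phases:
        material = props.material_properties(env, mr, scheme, henry_scaling)
        part = advance(grid, scheme, env, material, duration,
                       segment_length=numerics.segment_length,
                       conductance=numerics.conductance,
                       rtol=numerics.rtol, atol=numerics.atol,
                       record_every=numerics.record_every)
        grid.concentrations = part.concentrations[-1]
        grid.edges = part.edges[-1].copy()
        grid.time = part.times[-1]
        result = part if result is None else result.concat(part)
    return result


# -- STXM ---------------------------------------------------------------------


def run_stxm(rh: float = 40.0, mr: float = 1.0, radius: float = 0.5e-6,
             temperature: float = 20.0, light_duration: float = 900.0,
             reox_duration: float = 5400.0, beta0: float = 1.0,
             anoxic_wait: float = 0.0, no_light: bool = False,
             profile_times: int = 6, scheme: ReactionScheme | None = None,
             props: PropertyModel | None = None,
             numerics: Numerics | None = None,
             henry_scaling: float | None = None) -> dict:
    """Photoreduction / dark-reoxidation imaging protocol.

    Returns the initial ring profile (``beta0_profile``), ring profiles over
    the dark reoxidation (``profiles``), and the underlying result.  The
    ``anoxic_wait`` variant photolyzes in pure He and holds for the given
    time before O2 is admitted.
    """
    scheme = scheme or default_scheme()
    props = props or PropertyModel()
    numerics = numerics or Numerics(n_layers=20, segment_length=180.0)
    p_o2 = STXM_O2_MBAR.get(float(rh), 112.0)
    light = LightField.from_band("uv_365")
    if no_light:
        light = LightField.dark()
    gases_o2 = {"O2": p_o2}
    env_light = EnvironmentalState(temperature, rh, partial_pressures=(
        {} if anoxic_wait > 0 else gases_o2), total_pressure=150.0, light=light)
    env_dark = EnvironmentalState(temperature, rh, partial_pressures=gases_o2,
                                  total_pressure=150.0, light=LightField.dark())
    grid = initial_grid(scheme, props, "half-sphere", radius, mr,
                        env_dark, numerics, beta0=beta0)
    phases = [(600.0, env_dark), (light_duration, env_light)]
    if anoxic_wait > 0:
        env_hold = EnvironmentalState(temperature, rh, partial_pressures={},
                                      total_pressure=150.0, light=LightField.dark())
        phases.append((anoxic_wait, env_hold))
    phases.append((reox_duration, env_dark))
    result = _run_phases(grid, scheme, props, mr, phases, numerics,
                         henry_scaling=henry_scaling)

    t_light_off = 600.0 + light_duration + anoxic_wait
    beta0_profile = beta_column_2d(result, 0.0)
    times = np.linspace(t_light_off, result.times[-1], profile_times)
    profiles = [beta_column_2d(result, t) for t in times]
    return {"result": result, "beta0_profile": beta0_profile,
            "profiles": profiles, "profile_times": times,
            "light_off_time": t_light_off}


# -- EDB ----------------------------------------------------------------------


def run_edb(rh: float = 50.0, mr: float = 0.05, r0: float = 8.0e-6,
            temperature: float = 20.0, o2_mbar: float = 800.0,
            equilibration: float = 1800.0, light_duration: float = 19800.0,
            scheme: ReactionScheme | None = None,
            props: PropertyModel | None = None,
            numerics: Numerics | None = None,
            dark: bool = False, henry_scaling: float | None = None) -> dict:
    """Levitated-particle irradiation: dark equilibration, then visible light.

    The 473 nm laser runs at 40 mW mm^-2 (j = 4.3e-3 s^-1) except near
    RH = 47% where half power was used.
    """
    scheme = scheme or default_scheme()
    props = props or PropertyModel()
    numerics = numerics or Numerics(n_layers=24, segment_length=300.0)
    power = 20.0 if abs(rh - 47.0) < 1.0 else 40.0
    light = LightField.dark() if dark else LightField.from_band("vis_473", power)
    gases = {"O2": o2_mbar}
    env_dark = EnvironmentalState(temperature, rh, partial_pressures=gases,
                                  total_pressure=o2_mbar, light=LightField.dark())
    env_light = EnvironmentalState(temperature, rh, partial_pressures=gases,
                                   total_pressure=o2_mbar, light=light)
    grid = initial_grid(scheme, props, "sphere", r0, mr, env_dark, numerics)
    result = _run_phases(grid, scheme, props, mr,
                         [(equilibration, env_dark), (light_duration, env_light)],
                         numerics, henry_scaling=henry_scaling)
    trace = radius_trace(result)
    # normalize to the radius at light-on
    i_on = result.index_at(equilibration)
    r_on = result.radius[i_on]
    trace["r_over_r0"] = result.radius / r_on
    mass = result.total_dry_mass(scheme)
    return {"result": result, "trace": trace,
            "radius_loss_fraction": float(1.0 - result.radius[-1] / r_on),
            "mass_loss_fraction": float(1.0 - mass[-1] / mass[i_on]),
            "light_on_time": equilibration}


# -- CWFT ---------------------------------------------------------------------


def run_cwft(thickness: float = 1.1e-6, mr: float = 0.0784, rh: float = 38.5,
             temperature: float = 20.0, o2_fraction: float = 0.20,
             total_pressure: float = 1013.25, light_duration: float = 5400.0,
             equilibration: float = 300.0, cycles: int = 1,
             dark_interval: float = 1800.0,
             scheme: ReactionScheme | None = None,
             props: PropertyModel | None = None,
             numerics: Numerics | None = None,
             dark: bool = False, drift_tolerance: float = 0.05,
             henry_scaling: float | None = None) -> dict:
    """Coated-wall flow-tube HO2 release under broadband illumination.

    With ``cycles`` > 1 the lamp is toggled off/on and the release is
    reported per illuminated interval.
    """
    scheme = scheme or default_scheme()
    props = props or PropertyModel()
    numerics = numerics or Numerics(n_layers=20, segment_length=120.0)
    light = LightField.dark() if dark else LightField.from_band("cwft_lamp")
    gases = {"O2": o2_fraction * total_pressure}
    env_dark = EnvironmentalState(temperature, rh, partial_pressures=gases,
                                  total_pressure=total_pressure, light=LightField.dark())
    env_light = EnvironmentalState(temperature, rh, partial_pressures=gases,
                                   total_pressure=total_pressure, light=light)
    grid = initial_grid(scheme, props, "planar-film", thickness, mr, env_dark,
                        numerics, area=CWFT_FILM_AREA)
    phases = [(equilibration, env_dark)]
    for k in range(cycles):
        if k > 0:
            phases.append((dark_interval, env_dark))
        phases.append((light_duration, env_light))
    result = _run_phases(grid, scheme, props, mr, phases, numerics,
                         henry_scaling=henry_scaling)
    return {"result": result,
            "p_ho2": p_ho2(result, drift_tolerance=drift_tolerance)}


# -- ambient scan --------------------------------------------------------------


def run_atmospheric_scan(axes: dict, mr: float = 0.05, j: float = 5.23e-2,
                         temperature: float = 20.0, rh: float = 20.0,
                         radius: float = 0.5e-6, duration: float = 3600.0,
                         window: float = 1800.0, o2_fraction: float = 0.2095,
                         scheme: ReactionScheme | None = None,
                         props: PropertyModel | None = None,
                         numerics: Numerics | None = None) -> PhaseDiagram:
    """Quasi-steady [CCR]/[ROS] over a (temperature, rh) or (mr, j) grid.

    Each grid point is one ``duration`` simulation of a ``radius`` particle
    under continuous sunlight-scaled illumination; burdens are averaged over
    the trailing ``window``.
    """
    scheme = scheme or default_scheme()
    props = props or PropertyModel()
    numerics = numerics or Numerics(n_layers=20, segment_length=180.0)
    fixed = {"temperature": temperature, "rh": rh, "mr": mr, "j": j}

    def run_point(**coords):
        p = {**fixed, **coords}
        light = LightField.from_band("full_sun", p["j"] / 5.23e-2)
        env = EnvironmentalState(p["temperature"], p["rh"],
                                 partial_pressures={"O2": o2_fraction * 1013.25},
                                 total_pressure=1013.25, light=light)
        grid = initial_grid(scheme, props, "sphere", radius, p["mr"], env, numerics)
        material = props.material_properties(env, p["mr"], scheme)
        return advance(grid, scheme, env, material, duration,
                       segment_length=numerics.segment_length,
                       conductance=numerics.conductance,
                       rtol=numerics.rtol, atol=numerics.atol,
                       record_every=numerics.record_every)

    return phase_scan(run_point, axes, window=window)
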