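"""Environment-dependent material properties of the particle matrix.

Water content, water (and scaled species) diffusivities, density, effective
Henry's-law solubilities and the unit conversions between molarity and
molecules per microgram of particle mass.  All coefficients live in the
packaged ``properties.yaml`` and can be overridden per run.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .chemistry import LightField, ReactionScheme
from .constants import AVOGADRO, GAS_CONSTANT, celsius_to_kelvin

__all__ = [
    "EnvironmentalState",
    "MaterialProperties",
    "PropertyModel",
    "water_content",
    "dw",
    "henry_equilibrium",
    "burden_units",
    "burden_to_molarity",
    "load_properties",
]


def load_properties(path=None) -> dict:
    if path is None:
        text = (importlib.resources.files("ferrad.data") / "properties.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@dataclass
class EnvironmentalState:
    """Gas-phase and radiative environment around the particle or film."""

    temperature: float = 20.0  # degC
    rh: float = 40.0  # %
    rh_uncertainty: float = 2.0
    partial_pressures: dict = field(default_factory=dict)  # mbar per gas
    total_pressure: float = 1013.25  # mbar
    light: LightField = field(default_factory=LightField.dark)

    def __post_init__(self):
        if not 0.0 <= self.rh <= 100.0:
            raise ValueError(f"RH {self.rh}% outside [0, 100]")
        for gas, p in self.partial_pressures.items():
            if p < 0:
                raise ValueError(f"negative partial pressure for {gas}")
            if p > self.total_pressure + 1e-9:
                raise ValueError(f"partial pressure of {gas} exceeds total pressure")

    def partial_pressure_pa(self, gas: str) -> float:
        return self.partial_pressures.get(gas, 0.0) * 100.0

    @property
    def j(self) -> float:
        return self.light.j


class PropertyModel:
    """Evaluates the material-property parameterizations for one environment."""

    def __init__(self, config: dict | None = None):
        self.config = config or load_properties()

    # -- water content -------------------------------------------------------

    def water_content(self, rh: float, mr: float = 0.0, temperature: float = 20.0) -> float:
        """Equilibrium water mass fraction of the citric-acid matrix at RH (%).

        Monotone non-decreasing in RH and zero in the dry limit; the iron
        loading enters the transport only through the diffusivity correction,
        not the hygroscopicity.
        """
        if not 0.0 <= rh <= 100.0:
            raise ValueError(f"RH {rh}% outside [0, 100]")
        aw = rh / 100.0
        c1, c2, c3 = self.config["water_activity"]["coefficients"]
        w = aw * (c1 + c2 * aw + c3 * aw * aw)
        return float(min(max(w, 0.0), 0.999))

    # -- diffusivity ----------------------------------------------------------

    def dw(self, rh: float, mr: float = 0.0, temperature: float = 20.0) -> float:
        """Water diffusivity D_w (m^2 s^-1) in the matrix.

        Strictly increasing in RH; decreasing with iron loading above the
        reference mole ratio (a factor ``mr_factor`` between Mr = 0.05 and
        1.0, log-linear in log Mr); Arrhenius-type temperature scaling.
        """
        if not 0.0 <= rh <= 100.0:
            raise ValueError(f"RH {rh}% outside [0, 100]")
        if mr < 0:
            raise ValueError("mole ratio must be non-negative")
        cfg = self.config["water_diffusivity"]
        a0, a1, a2 = cfg["log10_coefficients"]
        aw = rh / 100.0
        log_d = a0 + a1 * aw + a2 * aw * aw
        d = 10.0 ** log_d
        lo, hi = cfg["mr_range"]
        if mr > lo:
            frac = (np.log(min(mr, hi)) - np.log(lo)) / (np.log(hi) - np.log(lo))
            d /= cfg["mr_factor"] ** frac
        t_ref = cfg["reference_temperature_k"]
        ea = cfg["activation_energy"]
        t_k = celsius_to_kelvin(temperature)
        d *= np.exp(-ea / GAS_CONSTANT * (1.0 / t_k - 1.0 / t_ref))
        return float(d)

    # -- density --------------------------------------------------------------

    def density(self, rh: float, mr: float = 0.0, temperature: float = 20.0) -> float:
        """Particle density (g cm^-3), volume-additive organic/water mixing."""
        w = self.water_content(rh, mr, temperature)
        rho_org = self.config["density"]["organic"]
        rho_w = self.config["density"]["water"]
        return float(1.0 / (w / rho_w + (1.0 - w) / rho_org))

    # -- assembled properties --------------------------------------------------

    def material_properties(self, env: EnvironmentalState, mr: float,
                            scheme: ReactionScheme,
                            henry_scaling: float | None = None) -> "MaterialProperties":
        d_w = self.dw(env.rh, mr, env.temperature)
        scaling = (self.config["henry"]["default_scaling"]
                   if henry_scaling is None else henry_scaling)
        d_x = d_w * scheme.f_dx
        henry_eff = {
            s.name: s.henry * scaling for s in scheme.species if s.volatile
        }
        return MaterialProperties(
            water_mass_fraction=self.water_content(env.rh, mr, env.temperature),
            density=self.density(env.rh, mr, env.temperature),
            d_w=d_w,
            d_x=d_x,
            henry_effective=henry_eff,
            henry_scaling=scaling,
        )


@dataclass
class MaterialProperties:
    water_mass_fraction: float
    density: float  # g/cm3
    d_w: float  # m2/s
    d_x: np.ndarray  # per species, m2/s
    henry_effective: dict  # mol m^-3 Pa^-1 per volatile species
    henry_scaling: float

    def __post_init__(self):
        if not 0.0 <= self.water_mass_fraction < 1.0:
            raise ValueError("water mass fraction outside [0, 1)")
        if self.d_w <= 0:
            raise ValueError("water diffusivity must be positive")


_DEFAULT_MODEL = None


def _model() -> PropertyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = PropertyModel()
    return _DEFAULT_MODEL


def water_content(rh: float, mr: float = 0.0, temperature: float = 20.0) -> float:
    return _model().water_content(rh, mr, temperature)


def dw(rh: float, mr: float = 0.0, temperature: float = 20.0) -> float:
    return _model().dw(rh, mr, temperature)


def henry_equilibrium(pressure_pa: float, species, scaling: float = 10.0) -> float:
    """Surface-layer concentration (mol m^-3) in Henry equilibrium with the gas.

    ``species`` is a :class:`~ferrad.chemistry.Species`; the effective
    solubility is the dilute constant times ``scaling``.
    """
    if pressure_pa < 0:
        raise ValueError("pressure must be non-negative")
    if species.henry is None:
        raise ValueError(f"species {species.name} has no Henry constant")
    return species.henry * scaling * pressure_pa


def burden_units(concentration_mm: float, density: float) -> float:
    """Convert a molarity (mM) to molecules per microgram of particle.

    molecules/ug = c[mol/L] * N_A [1/mol] / (rho [g/cm^3] * 1e3 [cm^3/L] * 1e6 [ug/g])
    """
    if concentration_mm < 0:
        raise ValueError("concentration must be non-negative")
    if density <= 0:
        raise ValueError("density must be positive")
    mol_per_l = concentration_mm * 1e-3
    return mol_per_l * AVOGADRO / (density * 1e3 * 1e6)


def burden_to_molarity(burden_per_ug: float, density: float) -> float:
    """Exact inverse of :func:`burden_units` (returns mM)."""
    if density <= 0:
        raise ValueError("density must be positive")
    return burden_per_ug * density * 1e3 * 1e6 / AVOGADRO * 1e3
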