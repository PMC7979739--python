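"""Species, reactions and rate laws of the iron-citrate photochemical cycle.

The condensed-phase mechanism couples ligand-to-metal charge-transfer (LMCT)
photolysis of the iron(III)-citrate complex to radical chemistry: photolysis
reduces the iron and leaves a decarboxylated carbon-centered radical (CCR),
O2 converts CCRs to peroxy radicals which eliminate HO2, and HO2/H2O2/O2
re-oxidize iron(II), closing the cycle.  Complexation of free iron with
citrate is treated as a fast equilibrium.

Concentrations are held in mol m^-3 throughout; rate constants are stored in
the conventional aqueous-kinetics units (M^-1 s^-1 for bimolecular steps) and
converted internally.  Bimolecular steps flagged ``diffusion_limited`` are
capped by the Smoluchowski encounter rate evaluated with the current
species diffusivities, which is what shuts radical chemistry down in a
viscous matrix.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .constants import AVOGADRO, PER_MOLAR_TO_SI

__all__ = [
    "Species",
    "Reaction",
    "Equilibrium",
    "ReactionScheme",
    "LightField",
    "photolysis_rate",
    "k_sr_of_rh",
    "reaction_rates",
    "apply_equilibria",
    "rhs_layer",
    "load_mechanism",
    "dump_mechanism",
    "default_scheme",
    "default_light_bands",
]

# forward rate used to realize fast complexation equilibria kinetically
EQUILIBRIUM_FORWARD_RATE = 1.0e4  # M^-1 s^-1

VALID_CATEGORIES = {"iron", "organic", "radical", "ros", "gas-derived", "product"}


@dataclass(frozen=True)
class Species:
    """A condensed-phase species.

    ``f_dx`` scales the species diffusivity relative to that of water,
    D_x = D_w * f_dx.  ``henry`` is the dilute-solution Henry's-law constant
    in mol m^-3 Pa^-1 and must be present exactly for volatile species.
    """

    name: str
    molar_mass: float  # g/mol
    f_dx: float = 1.0
    henry: float | None = None
    volatile: bool = False
    category: str = "product"
    n_fe: int = 0
    n_c: int = 0

    def __post_init__(self):
        if self.f_dx <= 0:
            raise ValueError(f"species {self.name}: f_dx must be positive")
        if self.volatile != (self.henry is not None):
            raise ValueError(
                f"species {self.name}: henry constant must be present iff volatile"
            )
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"species {self.name}: unknown category {self.category}")


@dataclass
class Reaction:
    """An elementary (or lumped) reaction with a mass-action rate law."""

    reactants: dict[str, int]
    products: dict[str, int]
    law: str  # photolytic | unimolecular | bimolecular
    rate_parameter: float = 0.0
    name: str = ""
    diffusion_limited: bool = False
    ksr_mode: str | None = None  # None | "rh_polynomial" | "dilute"
    calibratable: bool = False

    def __post_init__(self):
        if self.law not in {"photolytic", "unimolecular", "bimolecular"}:
            raise ValueError(f"reaction {self.name}: unknown law {self.law}")
        for stoich in list(self.reactants.values()) + list(self.products.values()):
            if not (isinstance(stoich, int) and stoich > 0):
                raise ValueError(f"reaction {self.name}: stoichiometry must be positive integers")
        order = sum(self.reactants.values())
        expected = {"photolytic": 1, "unimolecular": 1, "bimolecular": 2}[self.law]
        if order != expected:
            raise ValueError(
                f"reaction {self.name}: law {self.law} requires total reactant order {expected}"
            )


@dataclass
class Equilibrium:
    """Fast complexation equilibrium  metal + ligand <-> complex, K in M^-1."""

    complex: str
    metal: str
    ligand: str
    K: float

    def __post_init__(self):
        if not np.isfinite(self.K) or self.K <= 0:
            raise ValueError(f"equilibrium {self.complex}: K must be finite and positive")


@dataclass
class LightField:
    """Illumination state.

    The photolysis rate is j = power_density * quantum_yield * sigma_eff,
    where sigma_eff is a lumped actinic conversion constant for the band
    (mm^2 mW^-1 s^-1), fixed by the measured j of each lamp.
    """

    power_density: float  # mW mm^-2
    band: str
    quantum_yield: float
    effective_cross_section: float

    @classmethod
    def from_band(cls, band: str, power_density: float | None = None,
                  bands: Mapping[str, Mapping[str, float]] | None = None) -> "LightField":
        bands = bands if bands is not None else default_light_bands()
        if band not in bands:
            raise KeyError(f"no registered sigma-Phi constant for light band {band!r}")
        spec = bands[band]
        power = spec["reference_power"] if power_density is None else power_density
        return cls(power_density=power, band=band,
                   quantum_yield=spec["quantum_yield"],
                   effective_cross_section=spec["sigma_eff"])

    @property
    def j(self) -> float:
        return photolysis_rate(self)

    @classmethod
    def dark(cls) -> "LightField":
        return cls(power_density=0.0, band="uv_365", quantum_yield=1.0,
                   effective_cross_section=default_light_bands()["uv_365"]["sigma_eff"])


def photolysis_rate(light: LightField) -> float:
    """First-order photolysis rate j (s^-1) of the iron(III)-citrate complex."""
    if light.power_density < 0:
        raise ValueError("power density must be non-negative")
    return light.power_density * light.quantum_yield * light.effective_cross_section


class ReactionScheme:
    """A species set plus reaction network, compiled for fast rate evaluation.

    Switch handling: the first-order HO2 and H2O2 sinks and the optional CCR
    self-reaction are materialized as pseudo-reactions when the scheme is
    built, so the compiled network is self-contained.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction],
                 equilibria: Sequence[Equilibrium] = (),
                 switches: Mapping | None = None,
                 ksr_polynomial: Sequence[float] = (-2.854e-5, 0.0024, 0.1087, -0.05018),
                 ksr_dilute: float = 8.3e5,
                 source: dict | None = None):
        self.species = list(species)
        self.equilibria = list(equilibria)
        self.switches = dict(switches or {})
        self.ksr_polynomial = tuple(ksr_polynomial)
        self.ksr_dilute = float(ksr_dilute)
        self._source = source
        self._original_reactions = [copy.deepcopy(r) for r in reactions]

        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique within a scheme")
        self.index = {n: i for i, n in enumerate(names)}

        self.reactions = [copy.deepcopy(r) for r in reactions]
        self._apply_switches()
        self._validate()
        self._compile()

    # -- construction ------------------------------------------------------

    def _apply_switches(self):
        kept = []
        for r in self.reactions:
            switch = getattr(r, "_switch", None)
            if switch is not None and not self.switches.get(switch, False):
                continue
            kept.append(r)
        self.reactions = kept
        l_ho2 = float(self.switches.get("ho2_first_order_loss", 0.0))
        if l_ho2 > 0:
            self.reactions.append(Reaction({"HO2": 1}, {}, "unimolecular",
                                           l_ho2, name="L_ho2_loss"))
        l_h2o2 = float(self.switches.get("h2o2_first_order_loss", 0.0))
        if l_h2o2 > 0:
            self.reactions.append(Reaction({"H2O2": 1}, {}, "unimolecular",
                                           l_h2o2, name="L_h2o2_loss"))

    def _validate(self):
        for r in self.reactions:
            for name in list(r.reactants) + list(r.products):
                if name not in self.index:
                    raise ValueError(f"reaction {r.name} references undeclared species {name}")
            for attr in ("n_fe", "n_c"):
                lhs = sum(getattr(self.species[self.index[n]], attr) * s
                          for n, s in r.reactants.items())
                rhs = sum(getattr(self.species[self.index[n]], attr) * s
                          for n, s in r.products.items())
                if lhs != rhs:
                    raise ValueError(f"reaction {r.name}: element balance violated ({attr})")
        for eq in self.equilibria:
            for name in (eq.complex, eq.metal, eq.ligand):
                if name not in self.index:
                    raise ValueError(f"equilibrium references undeclared species {name}")

    def _compile(self):
        ns = len(self.species)
        # kinetic realization of the fast equilibria (forward + reverse)
        self._kinetic = list(self.reactions)
        for eq in self.equilibria:
            kf = EQUILIBRIUM_FORWARD_RATE
            self._kinetic.append(Reaction({eq.metal: 1, eq.ligand: 1}, {eq.complex: 1},
                                          "bimolecular", kf, name=f"E_{eq.complex}_f"))
            self._kinetic.append(Reaction({eq.complex: 1}, {eq.metal: 1, eq.ligand: 1},
                                          "unimolecular", kf / eq.K, name=f"E_{eq.complex}_r"))
        nr = len(self._kinetic)
        self.stoich = np.zeros((ns, nr))
        self._k_si = np.zeros(nr)
        self._photo = np.zeros(nr, bool)
        self._ksr = np.zeros(nr, bool)
        self._ridx = np.full((nr, 2), -1, int)  # up to two reactant slots
        self._dlim = np.zeros(nr, bool)
        for m, r in enumerate(self._kinetic):
            for n, s in r.reactants.items():
                self.stoich[self.index[n], m] -= s
            for n, s in r.products.items():
                self.stoich[self.index[n], m] += s
            slots = []
            for n, s in r.reactants.items():
                slots.extend([self.index[n]] * s)
            self._ridx[m, : len(slots)] = slots
            if r.law == "photolytic":
                self._photo[m] = True
            elif r.law == "bimolecular":
                if r.ksr_mode == "rh_polynomial":
                    self._ksr[m] = True
                self._k_si[m] = r.rate_parameter * PER_MOLAR_TO_SI
                self._dlim[m] = r.diffusion_limited
            else:
                self._k_si[m] = r.rate_parameter
        self._bimol = self._ridx[:, 1] >= 0
        self.n_species = ns
        self.n_reactions = nr
        # chemical reactions come first; kinetic equilibrium pairs follow
        self.n_chemical = len(self.reactions)
        self.molar_masses = np.array([s.molar_mass for s in self.species])
        self.fe_weights = np.array([s.n_fe for s in self.species], float)
        self.c_weights = np.array([s.n_c for s in self.species], float)
        self.volatile_mask = np.array([s.volatile for s in self.species])
        self.f_dx = np.array([s.f_dx for s in self.species])

    # -- convenience -------------------------------------------------------

    def species_index(self, name: str) -> int:
        return self.index[name]

    def concentration_vector(self, values: Mapping[str, float]) -> np.ndarray:
        c = np.zeros(self.n_species)
        for name, v in values.items():
            c[self.index[name]] = v
        return c

    def with_overrides(self, rate_overrides: Mapping[str, float] | None = None,
                       switch_overrides: Mapping | None = None) -> "ReactionScheme":
        """Return a copy with named rate parameters / switches replaced.

        Rate overrides are keyed by reaction name; switches by switch key.
        Used by the calibration stage.
        """
        reactions = [copy.deepcopy(r) for r in self._base_reactions()]
        for r in reactions:
            if rate_overrides and r.name in rate_overrides:
                r.rate_parameter = float(rate_overrides[r.name])
        switches = dict(self.switches)
        if switch_overrides:
            switches.update(switch_overrides)
        if rate_overrides:
            for key in ("ho2_first_order_loss", "h2o2_first_order_loss"):
                if key in rate_overrides:
                    switches[key] = float(rate_overrides[key])
        return ReactionScheme(self.species, reactions, self.equilibria, switches,
                              self.ksr_polynomial, self.ksr_dilute, source=self._source)

    def _base_reactions(self):
        return self._original_reactions

    # -- diffusion caps ----------------------------------------------------

    def encounter_rates(self, diffusivities: np.ndarray,
                        reaction_radius: float = 5.0e-10) -> np.ndarray:
        """Smoluchowski encounter rate constants (m^3 mol^-1 s^-1).

        ``diffusivities`` has shape (n_species,) or (n_species, L); the
        result matches the trailing layer dimension.
        """
        d = np.asarray(diffusivities)
        da = d[self._ridx[:, 0].clip(min=0)]
        db = d[self._ridx[:, 1].clip(min=0)]
        return 4.0 * np.pi * (da + db) * reaction_radius * AVOGADRO


# -- rate laws --------------------------------------------------------------


def k_sr_of_rh(rh: float, mode: str = "matrix",
               polynomial: Sequence[float] = (-2.854e-5, 0.0024, 0.1087, -0.05018),
               dilute: float = 8.3e5) -> float:
    """HO2 self-reaction rate coefficient (M^-1 s^-1).

    In ``matrix`` mode the RH-dependent parameterization
    log10 kSR = p3*RH^3 + p2*RH^2 + p1*RH + p0 is used; ``dilute`` mode
    returns the dilute aqueous-solution constant regardless of RH.
    """
    if not 0.0 <= rh <= 100.0:
        raise ValueError(f"relative humidity {rh} outside [0, 100]%")
    if mode == "dilute":
        return float(dilute)
    p3, p2, p1, p0 = polynomial
    return float(10.0 ** (p3 * rh**3 + p2 * rh**2 + p1 * rh + p0))


def reaction_rates(concentrations: np.ndarray, scheme: ReactionScheme, j: float,
                   rh: float, diffusivities: np.ndarray | None = None,
                   reaction_radius: float = 5.0e-10,
                   ksr_mode: str = "matrix", validate: bool = True) -> np.ndarray:
    """Mass-action rates (mol m^-3 s^-1) for every compiled reaction.

    ``concentrations`` has shape (n_species,) or (n_species, L) for L layers.
    Photolytic reactions scale with ``j``; the HO2 self-reaction uses
    :func:`k_sr_of_rh`; diffusion-limited steps are harmonically capped by
    the encounter rate when diffusivities are supplied.
    """
    c = np.atleast_2d(np.asarray(concentrations, float).T).T  # (ns, L)
    if validate and np.any(c < -1e-300):
        bad = np.argwhere(c < 0)
        s, layer = bad[0]
        raise ValueError(
            f"negative concentration of {scheme.species[s].name} in layer {layer}"
        )
    k = np.repeat(scheme._k_si[:, None], c.shape[1], axis=1)
    k[scheme._photo] = j
    if scheme._ksr.any():
        k[scheme._ksr] = k_sr_of_rh(rh, ksr_mode, scheme.ksr_polynomial,
                                    scheme.ksr_dilute) * PER_MOLAR_TO_SI
    if diffusivities is not None and scheme._dlim.any():
        kdiff = scheme.encounter_rates(diffusivities, reaction_radius)
        if kdiff.ndim == 1:
            kdiff = kdiff[:, None]
        m = scheme._dlim
        k[m] = 1.0 / (1.0 / k[m] + 1.0 / kdiff[m])
    rates = k * c[scheme._ridx[:, 0], :]
    rates[scheme._bimol] *= c[scheme._ridx[scheme._bimol, 1], :]
    if np.asarray(concentrations).ndim == 1:
        return rates[:, 0]
    return rates


def rhs_layer(concentrations: np.ndarray, scheme: ReactionScheme, j: float, rh: float,
              diffusivities: np.ndarray | None = None,
              reaction_radius: float = 5.0e-10,
              ksr_mode: str = "matrix", validate: bool = True) -> np.ndarray:
    """Chemical time derivative of every species in a well-mixed layer."""
    rates = reaction_rates(concentrations, scheme, j, rh, diffusivities,
                           reaction_radius, ksr_mode, validate)
    return scheme.stoich @ rates


# -- fast equilibria ---------------------------------------------------------


def apply_equilibria(concentrations: np.ndarray, scheme: ReactionScheme,
                     rtol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Project concentrations onto the complexation equilibria.

    Both iron-citrate equilibria share the citrate ligand, so the free-ligand
    concentration x solves the scalar conservation equation

        x + sum_i K_i * M_i,tot * x / (1 + K_i x) = L_tot,

    which is monotone in x and solved by bisection per layer.  Total iron and
    total citrate are conserved exactly by construction.
    """
    if not scheme.equilibria:
        return np.array(concentrations, float)
    c = np.atleast_2d(np.asarray(concentrations, float).T).T.copy()
    eqs = scheme.equilibria
    ligand = eqs[0].ligand
    if any(e.ligand != ligand for e in eqs):
        raise ValueError("shared-ligand solver requires a common ligand")
    il = scheme.index[ligand]
    ims = [scheme.index[e.metal] for e in eqs]
    ics = [scheme.index[e.complex] for e in eqs]
    ks = np.array([e.K * PER_MOLAR_TO_SI for e in eqs])  # m^3/mol
    m_tot = np.stack([c[im] + c[ic] for im, ic in zip(ims, ics)])  # (ne, L)
    l_tot = c[il] + sum(c[ic] for ic in ics)

    lo = np.zeros_like(l_tot)
    hi = l_tot.copy()

    def g(x):
        return x + np.sum(ks[:, None] * m_tot * x / (1.0 + ks[:, None] * x), axis=0) - l_tot

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        high = g(mid) > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
        if np.all((hi - lo) <= rtol * np.maximum(hi, 1e-300)):
            break
    else:
        width = np.max((hi - lo) / np.maximum(hi, 1e-300))
        layer = int(np.argmax((hi - lo) / np.maximum(hi, 1e-300)))
        raise RuntimeError(f"equilibrium solve did not converge in layer {layer} "
                           f"(relative width {width:.2e})")
    x = 0.5 * (lo + hi)
    # no bound metal anywhere in a layer -> the ligand stays exactly free
    x = np.where(m_tot.sum(axis=0) == 0, l_tot, x)
    c[il] = x
    for km, im, ic, mt in zip(ks, ims, ics, m_tot):
        bound = km * mt * x / (1.0 + km * x)
        c[ic] = bound
        c[im] = mt - bound
    if np.asarray(concentrations).ndim == 1:
        return c[:, 0]
    return c


# -- mechanism I/O -----------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("ferrad.data") / name


def load_mechanism(path=None) -> ReactionScheme:
    """Load a mechanism file (the packaged default when ``path`` is None)."""
    if path is None:
        text = _data_path("mechanism.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    species = [Species(**s) for s in doc["species"]]
    reactions = []
    for r in doc["reactions"]:
        rx = Reaction(
            reactants={k: int(v) for k, v in r["reactants"].items()},
            products={k: int(v) for k, v in r.get("products", {}).items()},
            law=r["law"],
            rate_parameter=float(r.get("rate_parameter", 0.0)),
            name=r.get("name", ""),
            diffusion_limited=bool(r.get("diffusion_limited", False)),
            ksr_mode=r.get("ksr_mode"),
            calibratable=bool(r.get("calibratable", False)),
        )
        if "switch" in r:
            rx._switch = r["switch"]
        reactions.append(rx)
    equilibria = [Equilibrium(**e) for e in doc.get("equilibria", [])]
    scheme = ReactionScheme(
        species, reactions, equilibria,
        switches=doc.get("switches", {}),
        ksr_polynomial=doc.get("ksr_rh_polynomial",
                               (-2.854e-5, 0.0024, 0.1087, -0.05018)),
        ksr_dilute=doc.get("ksr_dilute", 8.3e5),
        source=doc,
    )
    scheme.light_bands = doc.get("light_bands", {})
    return scheme


def dump_mechanism(scheme: ReactionScheme, path) -> None:
    """Write a mechanism back to YAML; load(dump(x)) reproduces x."""
    doc = {
        "species": [
            {k: v for k, v in vars(s).items() if v is not None and not
             (k in ("n_fe", "n_c") and v == 0)}
            for s in scheme.species
        ],
        "reactions": [],
        "equilibria": [vars(e).copy() for e in scheme.equilibria],
        "switches": dict(scheme.switches),
        "light_bands": getattr(scheme, "light_bands", default_light_bands()),
        "ksr_rh_polynomial": list(scheme.ksr_polynomial),
        "ksr_dilute": scheme.ksr_dilute,
    }
    for r in scheme._base_reactions():
        entry = {
            "name": r.name,
            "law": r.law,
            "reactants": dict(r.reactants),
            "products": dict(r.products),
            "rate_parameter": r.rate_parameter,
        }
        if r.diffusion_limited:
            entry["diffusion_limited"] = True
        if r.ksr_mode:
            entry["ksr_mode"] = r.ksr_mode
        if r.calibratable:
            entry["calibratable"] = True
        if getattr(r, "_switch", None):
            entry["switch"] = r._switch
        doc["reactions"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


_DEFAULT_CACHE: dict = {}


def default_scheme() -> ReactionScheme:
    """The packaged, calibrated default mechanism (fresh copy per call)."""
    return load_mechanism()


def default_light_bands() -> dict:
    if "bands" not in _DEFAULT_CACHE:
        doc = yaml.safe_load(_data_path("mechanism.yaml").read_text())
        _DEFAULT_CACHE["bands"] = doc["light_bands"]
    return _DEFAULT_CACHE["bands"]
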