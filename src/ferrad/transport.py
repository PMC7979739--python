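"""Layered geometry and time integration of the reaction-diffusion system.

The condensed phase is divided into concentric shells (or planar slabs for
films) with the finest layer at the surface, where the O2 reacto-diffusive
length can reach molecular scale.  Within :func:`advance`, chemistry,
inter-layer Fickian diffusion and surface gas exchange are integrated
together as one stiff ODE system (LSODA with a banded Jacobian); the fast
complexation equilibria are additionally projected exactly at every macro
step, and the outer boundary is moved at macro steps as volatile products
(CO2 and C2-5 carbonyls) escape.

Water is held at its equilibrium content for the ambient RH throughout and
enters only through density, layer volume and the diffusivity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import ode
from scipy.linalg import solve_banded

from .chemistry import ReactionScheme, apply_equilibria, reaction_rates
from .microphysics import EnvironmentalState, MaterialProperties

__all__ = ["LayerGrid", "SimulationResult", "build_grid", "diffusive_step",
           "surface_exchange", "advance", "update_geometry"]

GEOMETRIES = ("sphere", "half-sphere", "planar-film")


@dataclass
class LayerGrid:
    """Concentration state on a radially (or depth-) graded grid.

    ``edges`` ascend from the center (or substrate) to the outer surface;
    layer index 0 is innermost, the last layer touches the gas.  For films
    ``area`` is the film area and volumes are true m^3.
    """

    geometry: str
    edges: np.ndarray  # (L+1,), m
    concentrations: np.ndarray  # (n_species, L), mol m^-3
    species: list  # species names, aligned with the scheme
    time: float = 0.0
    area: float = 1.0  # film area, m^2 (ignored for particles)

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry}")
        self.edges = np.asarray(self.edges, float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("layer boundaries must be strictly increasing")
        self.concentrations = np.asarray(self.concentrations, float)
        if self.concentrations.shape[1] != len(self.edges) - 1:
            raise ValueError("concentration matrix does not match layer count")

    # -- geometry ------------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.edges) - 1

    @property
    def size(self) -> float:
        """Outer radius (particles) or film thickness (m)."""
        return float(self.edges[-1])

    @property
    def volumes(self) -> np.ndarray:
        return _shell_volumes(self.geometry, self.edges, self.area)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def interface_areas(self) -> np.ndarray:
        """Area of the L-1 interior interfaces."""
        r = self.edges[1:-1]
        if self.geometry == "sphere":
            return 4.0 * np.pi * r**2
        if self.geometry == "half-sphere":
            return 2.0 * np.pi * r**2
        return np.full(r.shape, self.area)

    @property
    def surface_area(self) -> np.ndarray:
        r = self.edges[-1]
        if self.geometry == "sphere":
            return 4.0 * np.pi * r**2
        if self.geometry == "half-sphere":
            return 2.0 * np.pi * r**2
        return self.area

    def copy(self) -> "LayerGrid":
        return LayerGrid(self.geometry, self.edges.copy(),
                         self.concentrations.copy(), list(self.species),
                         self.time, self.area)

    def total_moles(self) -> np.ndarray:
        return self.concentrations @ self.volumes


def _shell_volumes(geometry: str, edges: np.ndarray, area: float) -> np.ndarray:
    if geometry == "sphere":
        return 4.0 / 3.0 * np.pi * np.diff(edges**3)
    if geometry == "half-sphere":
        return 2.0 / 3.0 * np.pi * np.diff(edges**3)
    return np.diff(edges) * area


def _edges_from_volumes(geometry: str, volumes: np.ndarray, area: float) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(volumes)])
    if geometry == "sphere":
        return (cum * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    if geometry == "half-sphere":
        return (cum * 3.0 / (2.0 * np.pi)) ** (1.0 / 3.0)
    return cum / area


def build_grid(geometry: str, size: float, n_layers: int,
               surface_refinement: float | None = None,
               species: list | None = None,
               max_ratio: float = 1.6, uniform: bool = False,
               area: float = 1.0) -> LayerGrid:
    """Construct a geometrically graded grid, finest at the gas interface.

    ``surface_refinement`` is the outermost layer thickness; by default
    0.1 nm for sizes up to 1 um and 1 nm above, which resolves the
    sub-nanometer O2 penetration regime for submicron particles.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if uniform:
        edges = np.linspace(0.0, size, n_layers + 1)
    else:
        t_surf = surface_refinement
        if t_surf is None:
            t_surf = 0.1e-9 if size <= 1.0e-6 else 1.0e-9
        if t_surf * n_layers >= size:
            edges = np.linspace(0.0, size, n_layers + 1)
        else:
            ratio = _solve_grading(size / t_surf, n_layers)
            if ratio > max_ratio:
                raise ValueError(
                    f"surface refinement {t_surf:g} m infeasible with {n_layers} layers "
                    f"(needs adjacent-layer ratio {ratio:.2f} > {max_ratio})")
            thick = t_surf * ratio ** np.arange(n_layers)  # surface -> center
            thick = thick[::-1] * (size / thick.sum())
            edges = np.concatenate([[0.0], np.cumsum(thick)])
            edges[-1] = size
    n_species = 0 if species is None else len(species)
    conc = np.zeros((n_species, n_layers))
    return LayerGrid(geometry, edges, conc, species or [], area=area)


def _solve_grading(total_over_surf: float, n: int) -> float:
    """Solve (g^n - 1)/(g - 1) = total/t_surf for the grading ratio g > 1."""
    from scipy.optimize import brentq
    f = lambda g: (g**n - 1.0) / (g - 1.0) - total_over_surf
    if total_over_surf <= n:
        return 1.0
    return brentq(f, 1.0 + 1e-12, 10.0, xtol=1e-12)


# -- elementary steps ---------------------------------------------------------


def _diffusion_factors(grid: LayerGrid):
    """Per-interface conductance a/d and per-layer volumes."""
    v = grid.volumes
    a = grid.interface_areas
    d_centers = np.diff(grid.centers)
    return a / d_centers, v


def diffusive_step(grid: LayerGrid, diffusivities: np.ndarray, dt: float) -> LayerGrid:
    """One implicit (backward-Euler) Fickian diffusion step on a closed grid.

    Unconditionally stable; conserves each species' total moles to linear-
    solver precision because the operator is in flux form.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = grid.copy()
    cond, v = _diffusion_factors(grid)
    n = grid.n_layers
    for s in range(g.concentrations.shape[0]):
        d = diffusivities[s]
        if d <= 0:
            continue
        w = d * cond  # interface conductances, m^3/s
        ab = np.zeros((3, n))
        ab[1, :] = 1.0
        ab[1, :-1] += dt * w / v[:-1]
        ab[1, 1:] += dt * w / v[1:]
        ab[0, 1:] = -dt * w / v[:-1]
        ab[2, :-1] = -dt * w / v[1:]
        g.concentrations[s] = solve_banded((1, 1), ab, grid.concentrations[s])
    if np.any(g.concentrations < -1e-12 * max(1.0, g.concentrations.max())):
        raise RuntimeError("negative concentration after diffusive step (dt too large)")
    g.time = grid.time + dt
    return g


def equilibrium_concentrations(scheme: ReactionScheme, env: EnvironmentalState,
                               material: MaterialProperties) -> dict:
    """Henry-equilibrium concentration per volatile species for this gas phase."""
    out = {}
    for sp in scheme.species:
        if sp.volatile:
            p = env.partial_pressure_pa(sp.name)
            out[sp.name] = material.henry_effective[sp.name] * p
    return out


def surface_exchange(grid: LayerGrid, scheme: ReactionScheme, env: EnvironmentalState,
                     material: MaterialProperties, dt: float,
                     conductance: float = 1.0e-4):
    """Relax the outer layer toward Henry equilibrium over ``dt``.

    Returns ``(grid, fluxes)`` where fluxes maps volatile species to the net
    moles transferred to the gas (positive = evaporation).  The relaxation is
    integrated analytically, so arbitrarily large conductances are allowed
    (the clamped-boundary limit).
    """
    g = grid.copy()
    ceq = equilibrium_concentrations(scheme, env, material)
    v_out = grid.volumes[-1]
    a = grid.surface_area
    rate = conductance * a / v_out
    decay = np.exp(-rate * dt)
    fluxes = {}
    for name, ce in ceq.items():
        s = grid.species.index(name)
        c0 = grid.concentrations[s, -1]
        c1 = ce + (c0 - ce) * decay
        g.concentrations[s, -1] = c1
        fluxes[name] = (c0 - c1) * v_out
    g.time = grid.time + dt
    return g, fluxes


# -- results -----------------------------------------------------------------


@dataclass
class SimulationResult:
    """Time-resolved layer concentrations plus the evaporated-gas ledger."""

    times: np.ndarray  # (nt,), s
    concentrations: np.ndarray  # (nt, n_species, L)
    edges: np.ndarray  # (nt, L+1)
    evaporated: np.ndarray  # (nt, n_volatile), cumulative mol to gas
    species: list
    volatile_species: list
    geometry: str
    area: float = 1.0
    environment: EnvironmentalState | None = None
    material: MaterialProperties | None = None
    scheme: ReactionScheme | None = None

    @property
    def radius(self) -> np.ndarray:
        return self.edges[:, -1]

    def volumes(self, it: int) -> np.ndarray:
        return _shell_volumes(self.geometry, self.edges[it], self.area)

    def index_at(self, t: float) -> int:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"time {t} outside simulated range")
        return int(np.argmin(np.abs(self.times - t)))

    def concat(self, other: "SimulationResult") -> "SimulationResult":
        """Append a later result (continuation run) to this one."""
        return SimulationResult(
            times=np.concatenate([self.times, other.times]),
            concentrations=np.concatenate([self.concentrations, other.concentrations]),
            edges=np.concatenate([self.edges, other.edges]),
            evaporated=np.concatenate(
                [self.evaporated, other.evaporated + self.evaporated[-1]]),
            species=self.species, volatile_species=self.volatile_species,
            geometry=self.geometry, area=self.area,
            environment=other.environment, material=other.material,
            scheme=self.scheme,
        )

    def total_dry_mass(self, scheme: ReactionScheme) -> np.ndarray:
        """Condensed (water-free) mass history in kg."""
        mm = scheme.molar_masses * 1e-3  # kg/mol
        out = np.empty(len(self.times))
        for it in range(len(self.times)):
            out[it] = (self.concentrations[it].T @ mm) @ self.volumes(it)
        return out


# -- the integrator -----------------------------------------------------------


def _integrate_segment(rhs, y0, seg, ml, rtol, atol, t_now, n_conc,
                       depth: int = 0):
    """BDF (vode, banded Jacobian) over one macro segment, sub-stepping with
    clipped restarts if the stiff solver stalls on a sharp reaction front."""
    import warnings as _w
    solver = ode(rhs)
    solver.set_integrator("vode", method="bdf", lband=ml, uband=ml,
                          rtol=rtol, atol=atol, nsteps=200000)
    solver.set_initial_value(y0, 0.0)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        y = solver.integrate(seg)
    if solver.successful():
        return y
    if depth >= 3:
        raise RuntimeError(f"stiff solver failed near t={t_now:.1f}s")
    y = np.array(y0)
    for i in range(4):
        y[:n_conc] = np.maximum(y[:n_conc], 0.0)
        y = _integrate_segment(rhs, y, seg / 4.0, ml, rtol, atol * 10.0,
                               t_now + i * seg / 4.0, n_conc, depth + 1)
    return y


class _Rhs:
    """Assembled right-hand side: chemistry + diffusion + surface exchange."""

    def __init__(self, grid: LayerGrid, scheme: ReactionScheme,
                 env: EnvironmentalState, material: MaterialProperties,
                 conductance: float, reaction_radius: float):
        self.scheme = scheme
        self.env = env
        self.rh = env.rh
        self.j = env.j
        self.ns = scheme.n_species
        self.nl = grid.n_layers
        self.d_x = material.d_x
        self.reaction_radius = reaction_radius
        self.volatile_idx = np.flatnonzero(scheme.volatile_mask)
        ceq = equilibrium_concentrations(scheme, env, material)
        self.c_eq = np.array([ceq[scheme.species[i].name] for i in self.volatile_idx])
        self.update_geometry(grid)
        self.conductance = conductance

    def update_geometry(self, grid: LayerGrid):
        self.cond, self.vol = _diffusion_factors(grid)
        self.a_surf = grid.surface_area

    def __call__(self, t, y):
        ns, nl = self.ns, self.nl
        c = y[: ns * nl].reshape(nl, ns).T  # (ns, L)
        # smooth positive part for rate evaluation: mass action with negative
        # excursions is explosively unstable (negative x negative products),
        # while a hard clip destroys the smoothness the stiff solver needs;
        # the transition zone (|c| ~ 1e-15) sits far below the solver's
        # absolute tolerance so error control never has to resolve the kink
        c_pos = 0.5 * (c + np.sqrt(c * c + 1.0e-30))
        rates = reaction_rates(c_pos, self.scheme, self.j, self.rh, self.d_x,
                               self.reaction_radius, validate=False)
        dc = self.scheme.stoich @ rates
        # interior Fickian fluxes (flux > 0 flows inward, toward lower index)
        flux = self.d_x[:, None] * self.cond * (c[:, 1:] - c[:, :-1])
        dc[:, :-1] += flux / self.vol[:-1]
        dc[:, 1:] -= flux / self.vol[1:]
        # surface exchange for volatile species
        f_out = self.conductance * self.a_surf * (
            c[self.volatile_idx, -1] - self.c_eq)  # mol/s, positive = evaporation
        dc[self.volatile_idx, -1] -= f_out / self.vol[-1]
        return np.concatenate([dc.T.ravel(), f_out])


def advance(grid: LayerGrid, scheme: ReactionScheme, env: EnvironmentalState,
            material: MaterialProperties, t_end: float,
            n_segments: int | None = None, segment_length: float = 60.0,
            conductance: float = 1.0e-4, reaction_radius: float = 5.0e-10,
            rtol: float = 1e-5, atol: float = 1e-8,
            move_boundary: bool = True, min_volume_fraction: float = 1e-4,
            record_every: int = 1) -> SimulationResult:
    """Integrate the full reaction-diffusion system from ``grid.time``.

    Per macro segment: the complexation equilibria are imposed exactly, then
    chemistry, inter-layer diffusion and surface exchange are integrated
    together with a banded stiff solver, and finally layer volumes are
    recomputed from the evolved composition (constant density at the ambient
    RH), shrinking the outer boundary as volatiles escape.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if set(grid.species) != {s.name for s in scheme.species}:
        raise ValueError("grid and scheme species lists are inconsistent")
    nl, ns = grid.n_layers, scheme.n_species
    if n_segments is None:
        n_segments = max(1, int(np.ceil(t_end / segment_length)))
    seg = t_end / n_segments
    vol_idx = np.flatnonzero(scheme.volatile_mask)
    vol_names = [scheme.species[i].name for i in vol_idx]
    rhs = _Rhs(grid, scheme, env, material, conductance, reaction_radius)
    ml = ns + len(vol_idx)

    g = grid.copy()
    # species order in the grid must match the scheme
    order = [g.species.index(s.name) for s in scheme.species]
    g.concentrations = g.concentrations[order]
    g.species = [s.name for s in scheme.species]

    times = [g.time]
    conc_hist = [g.concentrations.copy()]
    edge_hist = [g.edges.copy()]
    evap = np.zeros(len(vol_idx))
    evap_hist = [evap.copy()]
    mm_kg = scheme.molar_masses * 1e-3
    rho_dry = material.density * 1e3 * (1.0 - material.water_mass_fraction)  # kg dry / m^3
    fe0 = float(scheme.fe_weights @ (g.concentrations @ g.volumes))
    w_surf0 = float(g.edges[-1] - g.edges[-2])

    for k in range(n_segments):
        g.concentrations = apply_equilibria(g.concentrations, scheme)
        y0 = np.concatenate([g.concentrations.T.ravel(), np.zeros(len(vol_idx))])
        y = _integrate_segment(rhs, y0, seg, ml, rtol, atol, g.time,
                               ns * nl)
        c = np.maximum(y[: ns * nl].reshape(nl, ns).T, 0.0)
        evap = evap + np.maximum(y[ns * nl:], -np.inf)
        g.concentrations = c
        g.time += seg

        if move_boundary:
            moles = c * rhs.vol
            dry_mass = mm_kg @ moles  # kg per layer
            v_new = np.maximum(dry_mass / rho_dry,
                               min_volume_fraction * rhs.vol)
            g.edges = _edges_from_volumes(g.geometry, v_new, g.area)
            g.concentrations = moles / v_new
            # regrid when surface layers collapse (mass loss is concentrated
            # there, so Lagrangian shrinking can degenerate the resolution)
            w_surf = g.edges[-1] - g.edges[-2]
            if w_surf < 0.3 * w_surf0 or w_surf > 3.0 * w_surf0:
                fresh = build_grid(g.geometry, g.size, nl,
                                   surface_refinement=min(w_surf0, g.size / (2 * nl)),
                                   species=list(g.species), area=g.area)
                fresh.concentrations = _conservative_remap(g, fresh)
                fresh.time = g.time
                g = fresh
            rhs.update_geometry(g)

        if fe0 > 0:
            fe_now = float(scheme.fe_weights @ (g.concentrations @ g.volumes))
            if abs(fe_now - fe0) > 1e-3 * fe0:
                raise RuntimeError(
                    f"iron conservation violated at t={g.time:.1f}s "
                    f"(relative drift {(fe_now - fe0) / fe0:+.2e}); "
                    "the stiff solve is untrustworthy here")

        if (k + 1) % record_every == 0 or k == n_segments - 1:
            times.append(g.time)
            conc_hist.append(g.concentrations.copy())
            edge_hist.append(g.edges.copy())
            evap_hist.append(evap.copy())

    return SimulationResult(
        times=np.array(times),
        concentrations=np.array(conc_hist),
        edges=np.array(edge_hist),
        evaporated=np.array(evap_hist),
        species=[s.name for s in scheme.species],
        volatile_species=vol_names,
        geometry=g.geometry, area=g.area,
        environment=env, material=material, scheme=scheme,
    )


def update_geometry(grid: LayerGrid, evaporated_volume: float,
                    n_layers: int | None = None,
                    surface_refinement: float | None = None) -> LayerGrid:
    """Shrink the outer boundary after losing ``evaporated_volume`` (m^3).

    The remaining condensed volume is redistributed on a fresh graded grid of
    the same style and the concentration field is remapped conservatively
    (total moles per species preserved).
    """
    v_tot = grid.volumes.sum()
    if evaporated_volume < 0 or evaporated_volume > v_tot:
        raise ValueError("evaporated volume outside [0, total condensed volume]")
    if evaporated_volume == 0:
        return grid.copy()
    v_new_tot = v_tot - evaporated_volume
    if grid.geometry == "sphere":
        new_size = (v_new_tot * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    elif grid.geometry == "half-sphere":
        new_size = (v_new_tot * 3.0 / (2.0 * np.pi)) ** (1.0 / 3.0)
    else:
        new_size = v_new_tot / grid.area
    if surface_refinement is None:
        # keep the relative surface resolution of the incoming grid
        surface_refinement = float(np.diff(grid.edges)[-1]) * new_size / grid.size
    new = build_grid(grid.geometry, new_size, n_layers or grid.n_layers,
                     surface_refinement, species=list(grid.species),
                     area=grid.area)
    new.concentrations = _conservative_remap(grid, new)
    new.time = grid.time
    return new


def _conservative_remap(old: LayerGrid, new: LayerGrid) -> np.ndarray:
    """Project concentrations onto a new grid preserving per-species moles.

    Works in normalized cumulative-volume coordinates, so total moles per
    species are preserved exactly while concentrations pick up the volume
    compression factor.
    """
    v_old = old.volumes
    v_new = new.volumes
    x_old = np.concatenate([[0.0], np.cumsum(v_old)]) / v_old.sum()
    x_new = np.concatenate([[0.0], np.cumsum(v_new)]) / v_new.sum()
    out = np.empty((old.concentrations.shape[0], new.n_layers))
    for s in range(old.concentrations.shape[0]):
        cum = np.concatenate([[0.0], np.cumsum(old.concentrations[s] * v_old)])
        cum_new = np.interp(x_new, x_old, cum)
        out[s] = np.diff(cum_new) / v_new
    return out
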