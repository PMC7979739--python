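"""Maps simulation state to the measured quantities.

Covers the iron(III) fraction beta (radial and 2-D column-integrated ring
profiles as seen by a transmission X-ray microscope), single-particle radius
traces, steady-state areal HO2 release from films, volume-averaged radical
burdens ([CCR], [ROS]) in both mM and molecules per microgram, the O2
penetration depth beneath the surface, and (T, RH) / (Mr, j) phase diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AVOGADRO, MOLM3_TO_MOLAR
from .microphysics import burden_units
from .transport import SimulationResult

__all__ = ["BetaProfile", "PhaseDiagram", "beta_radial", "beta_column_2d",
           "radius_trace", "p_ho2", "radical_burden", "o2_penetration_depth",
           "phase_scan"]

FE3_SPECIES = ("FeIIICit", "Fe3")
FE_CATEGORY_NAMES = ("FeIIICit", "Fe3", "Fe2", "FeIIHCit")
CCR_SPECIES = ("CCR",)
ROS_SPECIES = ("HO2", "H2O2", "OH", "RO2")


@dataclass
class BetaProfile:
    """Iron(III) fraction against depth, as shells or perimeter rings."""

    time: float
    position: np.ndarray  # shell center depth (m) or ring index (1 = perimeter)
    beta: np.ndarray
    uncertainty: float = 0.07
    kind: str = "radial"  # or "ring"

    def __post_init__(self):
        finite = np.isfinite(self.beta)
        if np.any((self.beta[finite] < -1e-9) | (self.beta[finite] > 1 + 1e-9)):
            raise ValueError("beta outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "position": self.position,
                             "beta": self.beta, "uncertainty": self.uncertainty})


@dataclass
class PhaseDiagram:
    """Quasi-steady radical burdens on a 2-D environmental grid."""

    axis_names: tuple
    axis_values: tuple  # (array, array)
    ccr_mm: np.ndarray  # (n1, n2)
    ros_mm: np.ndarray
    ccr_per_ug: np.ndarray
    ros_per_ug: np.ndarray
    window: float = 1800.0

    def to_frame(self) -> pd.DataFrame:
        n1, n2 = np.meshgrid(self.axis_values[0], self.axis_values[1], indexing="ij")
        return pd.DataFrame({
            self.axis_names[0]: n1.ravel(), self.axis_names[1]: n2.ravel(),
            "ccr_mM": self.ccr_mm.ravel(), "ros_mM": self.ros_mm.ravel(),
            "ccr_per_ug": self.ccr_per_ug.ravel(), "ros_per_ug": self.ros_per_ug.ravel(),
        })


def _species_idx(result: SimulationResult, names) -> list:
    return [result.species.index(n) for n in names if n in result.species]


def beta_radial(result: SimulationResult, t: float) -> BetaProfile:
    """Per-shell iron(III) fraction at time ``t``.

    Shells with no iron are reported as NaN (missing).
    """
    it = result.index_at(t)
    c = result.concentrations[it]
    fe3 = c[_species_idx(result, FE3_SPECIES)].sum(axis=0)
    fe_tot = c[_species_idx(result, FE_CATEGORY_NAMES)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(fe_tot > 0, fe3 / np.maximum(fe_tot, 1e-300), np.nan)
    edges = result.edges[it]
    depth = edges[-1] - 0.5 * (edges[:-1] + edges[1:])
    return BetaProfile(time=result.times[it], position=depth, beta=beta, kind="radial")


def beta_column_2d(result: SimulationResult, t: float, pixel: float = 35e-9,
                   n_z: int = 400, n_sub: int = 3) -> BetaProfile:
    """Column-integrated beta ring profile of a half-sphere particle.

    Every pixel column through the hemisphere integrates Fe(III) and total Fe
    along the beam; pixels are then averaged in rings indexed by their
    distance from the particle perimeter (ring 1 = perimeter pixels), which
    is how 2-D microscope images are reduced to profiles.
    """
    if result.geometry != "half-sphere":
        raise ValueError("column-integrated beta requires half-sphere geometry")
    it = result.index_at(t)
    edges = result.edges[it]
    radius = edges[-1]
    if pixel >= radius:
        raise ValueError("pixel size exceeds particle radius")
    c = result.concentrations[it]
    fe3 = c[_species_idx(result, FE3_SPECIES)].sum(axis=0)
    fe_tot = c[_species_idx(result, FE_CATEGORY_NAMES)].sum(axis=0)

    # pixel grid covering the projected disk, supersampled within each pixel
    # so ring averages converge to the continuum column integrals
    half = int(np.ceil(radius / pixel)) + 1
    fine = pixel / n_sub
    xy = (np.arange(-half * n_sub, half * n_sub + 1) + 0.5) * fine
    gx, gy = np.meshgrid(xy, xy, indexing="ij")
    s = np.hypot(gx, gy).ravel()
    mask = s < radius
    s_in = s[mask]

    # z-integration through the hemisphere per sub-pixel ray
    zmax = np.sqrt(radius**2 - s_in**2)
    zq = (np.arange(n_z) + 0.5) / n_z  # mid-point quadrature
    r_pts = np.sqrt(s_in[:, None] ** 2 + (zq[None, :] * zmax[:, None]) ** 2)
    shell = np.clip(np.searchsorted(edges, r_pts) - 1, 0, len(edges) - 2)
    col_fe3 = fe3[shell].mean(axis=1) * zmax
    col_fe = fe_tot[shell].mean(axis=1) * zmax

    ring = np.floor((radius - s_in) / pixel).astype(int) + 1
    n_rings = ring.max()
    beta_ring = np.full(n_rings, np.nan)
    for k in range(1, n_rings + 1):
        m = ring == k
        tot = col_fe[m].sum()
        if tot > 0:
            beta_ring[k - 1] = col_fe3[m].sum() / tot
    return BetaProfile(time=result.times[it], position=np.arange(1, n_rings + 1),
                       beta=beta_ring, kind="ring")


def radius_trace(result: SimulationResult) -> pd.DataFrame:
    """Normalized radius history r(t)/r0 (dimensionless, starts at 1)."""
    if result.geometry == "planar-film":
        raise ValueError("radius trace requires particle geometry")
    r = result.radius
    return pd.DataFrame({"time_s": result.times, "r_over_r0": r / r[0]})


def p_ho2(result: SimulationResult, area: float | None = None,
          steady_fraction: float = 0.1, drift_tolerance: float = 0.05) -> float:
    """Steady-state HO2 release (molecules cm^-2 s^-1) from a film.

    The areal flux is the time derivative of the cumulative HO2 gas ledger
    over the final ``steady_fraction`` of the run; a relative drift of the
    flux larger than ``drift_tolerance`` across that window raises an error
    reporting the drift.
    """
    if result.geometry != "planar-film":
        raise ValueError("HO2 release is defined for films")
    area = result.area if area is None else area
    iv = result.volatile_species.index("HO2")
    t = result.times
    e = result.evaporated[:, iv]
    t0 = t[-1] - steady_fraction * (t[-1] - t[0])
    win = t >= t0
    if win.sum() < 3:
        win = np.zeros_like(t, bool)
        win[-3:] = True
    tw, ew = t[win], e[win]
    flux = np.gradient(ew, tw)
    mean = flux.mean()
    if mean <= 0:
        return 0.0
    drift = (flux[-1] - flux[0]) / mean
    if abs(drift) > drift_tolerance:
        raise RuntimeError(
            f"no steady state: HO2 flux drift {drift:+.1%} over the last "
            f"{steady_fraction:.0%} of the run")
    return float(mean / area * AVOGADRO / 1e4)  # molecules cm^-2 s^-1


def radical_burden(result: SimulationResult, window: float = 1800.0,
                   density: float | None = None) -> dict:
    """Volume-weighted, time-averaged [CCR] and [ROS] over the last ``window`` s.

    Returns mM and molecules per microgram (using the run's density model).
    """
    t = result.times
    if window > t[-1] - t[0] + 1e-9:
        window = t[-1] - t[0]
    sel = np.flatnonzero(t >= t[-1] - window - 1e-9)
    if len(sel) == 0:
        sel = np.array([len(t) - 1])
    idx_ccr = _species_idx(result, CCR_SPECIES)
    idx_ros = _species_idx(result, ROS_SPECIES)
    ccr_vals, ros_vals = [], []
    for it in sel:
        v = result.volumes(it)
        w = v / v.sum()
        c = result.concentrations[it]
        ccr_vals.append(float(c[idx_ccr].sum(axis=0) @ w))
        ros_vals.append(float(c[idx_ros].sum(axis=0) @ w))
    ccr_mm = np.mean(ccr_vals) * MOLM3_TO_MOLAR * 1e3  # mol/m^3 -> mM
    ros_mm = np.mean(ros_vals) * MOLM3_TO_MOLAR * 1e3
    rho = density if density is not None else (
        result.material.density if result.material else 1.0)
    return {
        "ccr_mM": ccr_mm, "ros_mM": ros_mm,
        "ccr_per_ug": burden_units(ccr_mm, rho),
        "ros_per_ug": burden_units(ros_mm, rho),
    }


def o2_penetration_depth(result: SimulationResult, t: float,
                         threshold: float = np.exp(-1.0)) -> float:
    """Depth below the surface where [O2] first falls under threshold x surface value.

    Monotone linear interpolation between layer centers; if O2 never falls
    below the threshold the particle size is returned (>= size flag).
    """
    it = result.index_at(t)
    c = result.concentrations[it][result.species.index("O2")]
    edges = result.edges[it]
    size = edges[-1]
    depth = size - 0.5 * (edges[:-1] + edges[1:])  # per layer, surface last
    c_surf = c[-1]
    if c_surf <= 0:
        return size
    target = threshold * c_surf
    # walk inward from the surface
    d_in = depth[::-1]  # increasing depth
    c_in = c[::-1]
    below = np.flatnonzero(c_in < target)
    if len(below) == 0:
        return size
    k = below[0]
    if k == 0:
        return float(d_in[0])
    # interpolate between the last point above and the first below
    d0, d1 = d_in[k - 1], d_in[k]
    c0, c1 = c_in[k - 1], c_in[k]
    return float(d0 + (c0 - target) / max(c0 - c1, 1e-300) * (d1 - d0))


def phase_scan(run_point, axes: dict, window: float = 1800.0) -> PhaseDiagram:
    """Run one simulation per grid point and collect quasi-steady burdens.

    ``run_point(**coords)`` must run a 1 h (by default) simulation at the
    given coordinates and return its :class:`SimulationResult`;
    ``axes`` maps two axis names to value arrays, e.g.
    ``{"temperature": [...], "rh": [...]}`` or ``{"mr": [...], "j": [...]}``.
    """
    (name1, vals1), (name2, vals2) = axes.items()
    vals1 = np.asarray(vals1, float)
    vals2 = np.asarray(vals2, float)
    shape = (len(vals1), len(vals2))
    ccr_mm = np.zeros(shape)
    ros_mm = np.zeros(shape)
    ccr_ug = np.zeros(shape)
    ros_ug = np.zeros(shape)
    for i, v1 in enumerate(vals1):
        for k, v2 in enumerate(vals2):
            result = run_point(**{name1: v1, name2: v2})
            b = radical_burden(result, window=window)
            ccr_mm[i, k] = b["ccr_mM"]
            ros_mm[i, k] = b["ros_mM"]
            ccr_ug[i, k] = b["ccr_per_ug"]
            ros_ug[i, k] = b["ros_per_ug"]
    return PhaseDiagram((name1, name2), (vals1, vals2), ccr_mm, ros_mm,
                        ccr_ug, ros_ug, window=window)
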