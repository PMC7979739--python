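"""Seeded pseudo-observation generators with the instruments' noise structure.

These emulate what the three instruments would record for a known model
state, so the full pipeline (including calibration) can be exercised without
any archived beamline or balance data:

* two-energy optical-density image pairs of half-sphere particles at the
  iron(II)/iron(III) resonances, with photon-counting noise calibrated to a
  ring-profile uncertainty of about +-0.07,
* particle radius traces with a slowly varying refractive-index error
  envelope,
* flow-tube NO-depletion traces, where HO2 released from the film titrates
  NO 1:1 and run-to-run reproducibility is about 10%.

Every generator takes a seed and is bit-reproducible; every
generator/inverter pair is exact in the noiseless limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AVOGADRO, GAS_CONSTANT

__all__ = ["StxmImagePair", "gen_stxm_images", "invert_beta", "gen_edb_trace",
           "gen_cwft_no_trace", "no_drop_to_pho2", "hemisphere_thickness"]

# resonant X-ray energies (eV) and mass-absorption pairs (m^2 mol^-1 of Fe)
ENERGY_FE2 = 707.8
ENERGY_FE3 = 709.5
# rows: energy (707.8, 709.5); cols: (Fe(II), Fe(III)) molar absorptivity
ABSORPTIVITY = np.array([[350.0, 80.0],
                         [90.0, 360.0]])
ORGANIC_BACKGROUND = 2.0e5  # OD per m of matrix thickness
DEFAULT_I0 = 8000.0  # photons per pixel


@dataclass
class StxmImagePair:
    """Optical-density rasters at the two iron resonances.

    OD = -ln(I/I0) per pixel; the sidecar fields carry everything needed to
    invert the pair back to an iron(III)-fraction map.
    """

    od_fe2: np.ndarray  # raster at 707.8 eV
    od_fe3: np.ndarray  # raster at 709.5 eV
    pixel: float  # m
    mask: np.ndarray  # bool, particle footprint
    radius: float  # m, projected particle radius
    thickness: np.ndarray  # m, column thickness per pixel
    i0: float = DEFAULT_I0
    energies: tuple = (ENERGY_FE2, ENERGY_FE3)
    seed: int | None = None

    def __post_init__(self):
        if np.any(self.od_fe2[self.mask] < -1e-9) or np.any(self.od_fe3[self.mask] < -1e-9):
            raise ValueError("optical density must be non-negative inside the mask")

    def sidecar(self) -> str:
        return json.dumps({"pixel_nm": self.pixel * 1e9, "radius_nm": self.radius * 1e9,
                           "energies_ev": list(self.energies), "i0": self.i0,
                           "seed": self.seed})


def hemisphere_thickness(radius: float, pixel: float):
    """Pixel grid, mask and column thickness of a half-sphere on a substrate."""
    half = int(np.ceil(radius / pixel)) + 1
    xy = (np.arange(-half, half + 1) + 0.5) * pixel
    gx, gy = np.meshgrid(xy, xy, indexing="ij")
    s = np.hypot(gx, gy)
    mask = s < radius
    h = np.where(mask, np.sqrt(np.maximum(radius**2 - s**2, 0.0)), 0.0)
    return s, mask, h


def gen_stxm_images(beta_shells: np.ndarray, edges: np.ndarray,
                    fe_concentration: float, pixel: float = 35e-9,
                    i0: float = DEFAULT_I0, seed: int = 0,
                    noiseless: bool = False, n_z: int = 200) -> StxmImagePair:
    """Synthesize a two-energy image pair of a half-sphere particle.

    ``beta_shells`` gives the iron(III) fraction per radial shell bounded by
    ``edges`` (m); ``fe_concentration`` is the (uniform) total iron in
    mol m^-3.  Per-pixel transmitted intensities receive Poisson photon noise
    unless ``noiseless``.
    """
    beta_shells = np.asarray(beta_shells, float)
    if np.any((beta_shells < 0) | (beta_shells > 1)):
        raise ValueError("beta must lie in [0, 1]")
    radius = float(edges[-1])
    if pixel >= radius:
        raise ValueError("pixel size exceeds particle radius")
    s, mask, h = hemisphere_thickness(radius, pixel)
    s_in = s[mask]
    zmax = h[mask]
    zq = (np.arange(n_z) + 0.5) / n_z
    r_pts = np.sqrt(s_in[:, None] ** 2 + (zq[None, :] * zmax[:, None]) ** 2)
    shell = np.clip(np.searchsorted(edges, r_pts) - 1, 0, len(edges) - 2)
    col_fe = fe_concentration * zmax  # mol/m^2
    col_fe3 = fe_concentration * beta_shells[shell].mean(axis=1) * zmax
    col_fe2 = col_fe - col_fe3

    od = np.zeros((2,) + s.shape)
    for e in range(2):
        od_in = (ABSORPTIVITY[e, 0] * col_fe2 + ABSORPTIVITY[e, 1] * col_fe3
                 + ORGANIC_BACKGROUND * zmax)
        od[e][mask] = od_in
    if not noiseless:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(i0 * np.exp(-od))
        od = -np.log(np.maximum(counts, 1.0) / i0)
        od[:, ~mask] = 0.0
        od = np.maximum(od, 0.0)
    return StxmImagePair(od_fe2=od[0], od_fe3=od[1], pixel=pixel, mask=mask,
                         radius=radius, thickness=h, i0=i0,
                         seed=None if noiseless else seed)


def invert_beta(pair: StxmImagePair):
    """Unmix the two-energy pair into an iron(III)-fraction map and ring profile.

    Per pixel, the organic background is subtracted and the 2x2 absorptivity
    matrix inverted to give Fe(II) and Fe(III) column densities; the ring
    profile averages beta-weighted columns by distance from the perimeter.
    Returns ``(beta_map, ring_profile_dataframe)``.
    """
    a = ABSORPTIVITY
    if abs(np.linalg.det(a)) < 1e-9 * np.abs(a).max() ** 2:
        raise ValueError("singular unmixing: absorptivity vectors are collinear")
    if not pair.mask.any():
        raise ValueError("empty particle mask")
    ainv = np.linalg.inv(a)
    od = np.stack([pair.od_fe2[pair.mask], pair.od_fe3[pair.mask]])
    od = od - ORGANIC_BACKGROUND * pair.thickness[pair.mask]
    cols = ainv @ od  # (2, n_pixels): Fe(II), Fe(III) columns
    tot = cols.sum(axis=0)
    beta_pix = np.clip(np.divide(cols[1], np.maximum(tot, 1e-300)), 0.0, 1.0)

    beta_map = np.full(pair.mask.shape, np.nan)
    beta_map[pair.mask] = beta_pix

    half = pair.mask.shape[0] // 2
    xy = (np.arange(-half, half + 1) + 0.5) * pair.pixel
    gx, gy = np.meshgrid(xy, xy, indexing="ij")
    s_in = np.hypot(gx, gy)[pair.mask]
    ring = np.floor((pair.radius - s_in) / pair.pixel).astype(int) + 1
    rows = []
    for k in range(1, ring.max() + 1):
        m = ring == k
        w = np.maximum(tot[m], 0.0)
        if w.sum() > 0:
            b = float(np.average(beta_pix[m], weights=w))
        else:
            b = float("nan")
        rows.append({"ring": k, "beta": b, "n_pixels": int(m.sum())})
    return beta_map, pd.DataFrame(rows)


def gen_edb_trace(trace: pd.DataFrame, envelope_fraction: float = 0.005,
                  white_noise: float = 2.0e-4, seed: int = 0) -> pd.DataFrame:
    """Overlay the refractive-index error envelope on a model radius trace.

    A smooth multiplicative drift bounded by ``envelope_fraction`` (the
    refractive-index uncertainty in the sizing) plus small white noise.
    """
    rng = np.random.default_rng(seed)
    t = trace["time_s"].to_numpy()
    r = trace["r_over_r0"].to_numpy()
    n = len(r)
    if envelope_fraction > 0 and n > 2:
        walk = np.cumsum(rng.standard_normal(n))
        k = max(3, n // 10)
        kernel = np.ones(k) / k
        walk = np.convolve(walk, kernel, mode="same")
        walk -= walk.mean()
        peak = np.abs(walk).max()
        env = envelope_fraction * walk / peak if peak > 0 else np.zeros(n)
    else:
        env = np.zeros(n)
    noise = white_noise * rng.standard_normal(n) if white_noise > 0 else 0.0
    out = trace.copy()
    out["r_over_r0"] = r * (1.0 + env) + noise
    out["envelope"] = env
    return out


def gen_cwft_no_trace(p_ho2_values, film_area: float, flow_lpm: float = 1.0,
                      baseline_no_ppb: float = 500.0, cycle_noise: float = 0.10,
                      temperature: float = 20.0, pressure_pa: float = 101325.0,
                      points_per_cycle: int = 20, seed: int = 0) -> pd.DataFrame:
    """NO concentration time series for light on/off cycles.

    During each illuminated cycle the released HO2 (``p_ho2_values``, one
    steady value per cycle, molecules cm^-2 s^-1) scavenges NO 1:1, so the NO
    mixing ratio drops by P_HO2 * A / (molar gas flow); a multiplicative
    run-scale error of ``cycle_noise`` is applied per cycle.
    """
    if flow_lpm <= 0:
        raise ValueError("flow must be positive")
    rng = np.random.default_rng(seed)
    t_k = temperature + 273.15
    n_dot = pressure_pa * (flow_lpm * 1e-3 / 60.0) / (GAS_CONSTANT * t_k)  # mol/s
    rows = []
    t = 0.0
    dt = 60.0
    for icyc, p in enumerate(np.atleast_1d(p_ho2_values)):
        for _ in range(points_per_cycle):  # dark interval
            rows.append({"time_s": t, "no_ppb": baseline_no_ppb, "light": 0,
                         "cycle": icyc})
            t += dt
        release_mol_s = p * film_area * 1e4 / AVOGADRO  # molecules/cm^2/s -> mol/s
        drop_ppb = release_mol_s / n_dot * 1e9
        if drop_ppb > 0.5 * baseline_no_ppb:
            raise ValueError("NO depletion exceeds 50% of baseline: "
                             "excess-NO assumption violated")
        factor = 1.0 + cycle_noise * rng.standard_normal() if cycle_noise > 0 else 1.0
        for _ in range(points_per_cycle):  # lit interval
            rows.append({"time_s": t, "no_ppb": baseline_no_ppb - drop_ppb * factor,
                         "light": 1, "cycle": icyc})
            t += dt
    return pd.DataFrame(rows)


def no_drop_to_pho2(trace: pd.DataFrame, film_area: float, flow_lpm: float = 1.0,
                    temperature: float = 20.0,
                    pressure_pa: float = 101325.0) -> np.ndarray:
    """Recover P_HO2 (molecules cm^-2 s^-1) per cycle from an NO trace."""
    t_k = temperature + 273.15
    n_dot = pressure_pa * (flow_lpm * 1e-3 / 60.0) / (GAS_CONSTANT * t_k)
    out = []
    for _, cyc in trace.groupby("cycle"):
        base = cyc.loc[cyc["light"] == 0, "no_ppb"].mean()
        lit = cyc.loc[cyc["light"] == 1, "no_ppb"].mean()
        drop_mol_s = (base - lit) * 1e-9 * n_dot
        out.append(drop_mol_s * AVOGADRO / (film_area * 1e4))
    return np.asarray(out)
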