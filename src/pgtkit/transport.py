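"""Proton transport through layered targets in the continuous-slowing-down
approximation.

The energy-loss model is a Bragg-Kleeman range-energy power law referenced to
water, ``R_water(E) = bk_alpha * E**bk_p`` (R in mm, E in MeV).  Each material
scales the water stopping power by its mass density and a dimensionless
water-equivalence factor, so the linear stopping power of material *m* is::

    (dE/dz)_m = -rho_m * water_equiv_m * S_water(E)

With this model the quantity ``E**bk_p`` decreases linearly with depth inside
a homogeneous slice, which gives closed-form slice propagation; transit times
are obtained by adaptive quadrature over energy.  A per-material measured
stopping-power table (two columns, E in MeV and S in MeV cm^2/g) may override
the analytic law, in which case propagation falls back to an ODE solver.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp

from .constants import CONSTANTS

__all__ = [
    "Material",
    "Slice",
    "LayeredPhantom",
    "MATERIALS",
    "velocity",
    "stopping_power",
    "energy_at_depth",
    "csda_range",
    "transit_time",
    "depth_at_time",
    "E_FLOOR",
    "BK_P_WATER",
    "BK_ALPHA_WATER",
]

#: Termination energy (MeV) for range/time integrals.  Below this the power-law
#: stopping power and 1/v both blow up; truncating here biases the range by
#: well under 0.1 mm.
E_FLOOR = 1.0

#: Bragg-Kleeman exponent for water.
BK_P_WATER = 1.77
#: Bragg-Kleeman coefficient for water (mm / MeV**p), calibrated so that a
#: 230 MeV proton has a 330 mm range in water.
BK_ALPHA_WATER = 330.0 / 230.0**BK_P_WATER

_E_MAX = 300.0  # model validity ceiling, MeV


@dataclass(frozen=True)
class Material:
    """A target material for CSDA transport.

    Parameters
    ----------
    name : str
        Registry identifier.
    rho : float
        Mass density, g/cm^3.  Gases use their true (small) density.
    bk_alpha, bk_p : float
        Water-referenced Bragg-Kleeman constants (mm/MeV^p, dimensionless).
    water_equiv : float
        Ratio of the material's mass stopping power to water's, so that
        ``rho * water_equiv`` is the linear stopping power relative to water.
    yield_factor : float
        Relative prompt-gamma emission per unit mass path (1.0 = water-like).
    stopping_table : tuple of (tuple, tuple), optional
        Optional measured override ``(energies_MeV, S_MeV_cm2_per_g)``;
        log-log interpolated.
    """

    name: str
    rho: float
    bk_alpha: float = BK_ALPHA_WATER
    bk_p: float = BK_P_WATER
    water_equiv: float = 1.0
    yield_factor: float = 1.0
    stopping_table: tuple | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"material {self.name!r}: rho must be > 0")
        if not 1.0 < self.bk_p < 2.2:
            raise ValueError(f"material {self.name!r}: bk_p outside (1, 2.2)")
        if self.yield_factor < 0:
            raise ValueError(f"material {self.name!r}: yield_factor must be >= 0")
        if self.water_equiv <= 0:
            raise ValueError(f"material {self.name!r}: water_equiv must be > 0")

    @property
    def k_lin(self) -> float:
        """Linear stopping-power scale relative to water (dimensionless)."""
        return self.rho * self.water_equiv


# Built-in registry.  PMMA and cortical bone carry water-equivalence factors
# chosen so their *linear* relative stopping powers are 1.16 and 1.57.
MATERIALS: dict[str, Material] = {
    "water": Material("water", rho=1.0),
    "pmma": Material("pmma", rho=1.19, water_equiv=1.16 / 1.19),
    "air": Material("air", rho=1.204e-3),
    "bone": Material("bone", rho=1.85, water_equiv=1.57 / 1.85),
}


@dataclass(frozen=True)
class Slice:
    """One homogeneous layer of a phantom."""

    material: Material
    thickness: float  # mm

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slice thickness must be > 0")


class LayeredPhantom:
    """An ordered stack of homogeneous slices along the beam axis.

    The beam enters at z = 0 (front face) and z grows along the beam axis.
    Slice boundaries are half-open: slice *i* occupies ``[z_i, z_{i+1})``.
    """

    def __init__(self, slices: Sequence[Slice]):
        self.slices = tuple(slices)
        self._edges = np.concatenate([[0.0], np.cumsum([s.thickness for s in self.slices])])

    @property
    def length(self) -> float:
        """Total phantom length (mm); exactly the sum of slice thicknesses."""
        return float(self._edges[-1])

    @property
    def boundaries(self) -> np.ndarray:
        """Slice boundary positions including 0 and the total length."""
        return self._edges.copy()

    def material_at(self, z: float) -> Material:
        """Material of the slice containing depth ``z`` in [0, length)."""
        if not 0 <= z < self.length:
            raise ValueError(f"z={z} outside [0, {self.length})")
        i = bisect.bisect_right(self._edges, z) - 1
        return self.slices[min(i, len(self.slices) - 1)].material

    def rho_at(self, z: np.ndarray) -> np.ndarray:
        """Vectorized mass density profile (g/cm^3); 0 outside the phantom."""
        z = np.asarray(z, dtype=float)
        idx = np.clip(np.searchsorted(self._edges, z, side="right") - 1, 0, len(self.slices) - 1)
        rho = np.array([s.material.rho for s in self.slices])[idx]
        return np.where((z >= 0) & (z < self.length), rho, 0.0)

    def k_lin_at(self, z: np.ndarray) -> np.ndarray:
        """Vectorized linear stopping-power scale relative to water."""
        z = np.asarray(z, dtype=float)
        idx = np.clip(np.searchsorted(self._edges, z, side="right") - 1, 0, len(self.slices) - 1)
        k = np.array([s.material.k_lin for s in self.slices])[idx]
        return np.where((z >= 0) & (z < self.length), k, 0.0)

    def yield_at(self, z: np.ndarray) -> np.ndarray:
        """Vectorized yield factor profile; 0 outside the phantom."""
        z = np.asarray(z, dtype=float)
        idx = np.clip(np.searchsorted(self._edges, z, side="right") - 1, 0, len(self.slices) - 1)
        yf = np.array([s.material.yield_factor for s in self.slices])[idx]
        return np.where((z >= 0) & (z < self.length), yf, 0.0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(f"{s.material.name}:{s.thickness:g}mm" for s in self.slices)
        return f"LayeredPhantom({parts})"


def homogeneous(material: Material | str, length: float) -> LayeredPhantom:
    """Convenience constructor for a single-slice phantom."""
    if isinstance(material, str):
        material = MATERIALS[material]
    return LayeredPhantom([Slice(material, length)])


# ---------------------------------------------------------------------------
# kinematics and stopping power


def velocity(E, constants=CONSTANTS):
    """Relativistic proton speed (mm/ns) at kinetic energy ``E`` (MeV).

    Accepts scalars or arrays; raises for negative energies.
    """
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < 0):
        raise ValueError("kinetic energy must be >= 0")
    gamma = 1.0 + E_arr / constants.m_p_c2
    v = constants.c * np.sqrt(1.0 - gamma**-2)
    return float(v) if np.isscalar(E) or E_arr.ndim == 0 else v


def stopping_power(material: Material, E: float) -> float:
    """Mass stopping power S(E) in MeV cm^2/g.

    From the Bragg-Kleeman law the linear stopping power in water (MeV/mm)
    is ``1 / (bk_alpha * bk_p * E**(bk_p-1))``; converting per-cm and per-
    density (rho_water = 1 g/cm^3) and applying the material's water-
    equivalence factor gives the mass stopping power.  A measured table on
    the material, if present, overrides the analytic law.
    """
    if E <= 0:
        raise ValueError("stopping power undefined at E <= 0; use E >= E_FLOOR")
    E = max(E, E_FLOOR)
    if material.stopping_table is not None:
        e_grid, s_grid = (np.asarray(a, dtype=float) for a in material.stopping_table)
        return float(np.exp(np.interp(np.log(E), np.log(e_grid), np.log(s_grid))))
    s_lin_water = 1.0 / (material.bk_alpha * material.bk_p * E ** (material.bk_p - 1.0))
    return 10.0 * material.water_equiv * s_lin_water


def _dEdz(material: Material, E: float) -> float:
    """Linear energy loss dE/dz in MeV/mm (positive number)."""
    return material.rho * stopping_power(material, E) / 10.0


def _has_tables(phantom: LayeredPhantom) -> bool:
    return any(s.material.stopping_table is not None for s in phantom.slices)


def _slice_exit_energy(material: Material, E_in: float, thickness: float) -> float:
    """Energy after crossing ``thickness`` mm of a homogeneous material.

    Returns a value <= E_FLOOR if the proton stops inside the slice.
    Closed form for the analytic model: E**p falls linearly with depth at
    rate k_lin / bk_alpha.
    """
    if E_in <= E_FLOOR:
        return E_FLOOR
    if material.stopping_table is None:
        p, a = material.bk_p, material.bk_alpha
        val = E_in**p - material.k_lin * thickness / a
        return val ** (1.0 / p) if val > E_FLOOR**p else E_FLOOR
    sol = solve_ivp(
        lambda z, y: [-_dEdz(material, max(y[0], E_FLOOR))],
        (0.0, thickness),
        [E_in],
        rtol=1e-10,
        atol=1e-10,
        dense_output=False,
        events=lambda z, y: y[0] - E_FLOOR,
    )
    return float(sol.y[0, -1]) if sol.t[-1] == thickness else E_FLOOR


def _slice_stop_depth(material: Material, E_in: float) -> float:
    """Residual range (mm) of a proton of energy ``E_in`` in a material."""
    if E_in <= E_FLOOR:
        return 0.0
    if material.stopping_table is None:
        p, a = material.bk_p, material.bk_alpha
        return a * (E_in**p - E_FLOOR**p) / material.k_lin
    val, _ = quad(lambda e: 1.0 / _dEdz(material, e), E_FLOOR, E_in, limit=200)
    return val


def energy_at_depth(phantom: LayeredPhantom, E0: float, z: float) -> float:
    """Proton kinetic energy (MeV) after penetrating to depth ``z`` (mm).

    Returns 0.0 once the proton has stopped (z at or beyond the CSDA range).
    """
    if E0 <= 0:
        raise ValueError("E0 must be > 0")
    if z < 0:
        raise ValueError("z must be >= 0")
    E = E0
    z_done = 0.0
    for s in phantom.slices:
        if z <= z_done:
            break
        step = min(s.thickness, z - z_done)
        E = _slice_exit_energy(s.material, E, step)
        if E <= E_FLOOR:
            return 0.0
        z_done += step
    if z > z_done:  # beyond the physical phantom: vacuum, no loss
        pass
    return float(E) if E > E_FLOOR else 0.0


def csda_range(phantom: LayeredPhantom, E0: float) -> float:
    """Depth (mm) at which the proton stops, or ``inf`` if it exits the
    phantom still above the energy floor (shoot-through)."""
    if E0 <= 0:
        raise ValueError("E0 must be > 0")
    if E0 > _E_MAX:
        raise ValueError(f"E0={E0} MeV beyond model validity ({_E_MAX} MeV)")
    E = E0
    z_done = 0.0
    for s in phantom.slices:
        stop = _slice_stop_depth(s.material, E)
        if stop <= s.thickness:
            return z_done + stop
        E = _slice_exit_energy(s.material, E, s.thickness)
        z_done += s.thickness
    return float("inf")


def _slice_time(material: Material, E_in: float, E_out: float, constants=CONSTANTS) -> float:
    """Transit time (ns) across the part of a slice where the proton slows
    from ``E_in`` to ``E_out``, by adaptive quadrature over energy."""
    if E_in <= E_out:
        return 0.0

    def integrand(E):
        return 1.0 / (velocity(E, constants) * _dEdz(material, E))

    val, _ = quad(integrand, max(E_out, E_FLOOR), E_in, epsabs=1e-16, epsrel=1e-12, limit=500)
    return val


def transit_time(phantom: LayeredPhantom, E0: float, z: float, constants=CONSTANTS) -> float:
    """Proton transit time (ns) from the front face to depth ``z`` (mm)."""
    if z < 0:
        raise ValueError("z must be >= 0")
    rng = csda_range(phantom, E0)
    if z > rng + 1e-9:
        raise ValueError(f"z={z} mm beyond the CSDA range ({rng:.3f} mm)")
    t = 0.0
    E = E0
    z_done = 0.0
    for s in phantom.slices:
        if z <= z_done + 1e-15:
            break
        step = min(s.thickness, z - z_done)
        E_next = _slice_exit_energy(s.material, E, step)
        if E_next <= E_FLOOR:
            t += _slice_time(s.material, E, E_FLOOR, constants)
            return t
        t += _slice_time(s.material, E, E_next, constants)
        E = E_next
        z_done += step
    return t


def depth_at_time(phantom: LayeredPhantom, E0: float, t: float, constants=CONSTANTS) -> float:
    """Invert :func:`transit_time` by bisection; ``t`` in ns, result in mm."""
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = csda_range(phantom, E0)
    if not np.isfinite(rng):
        rng = phantom.length
    t_max = transit_time(phantom, E0, rng, constants)
    if t > t_max + 1e-12:
        raise ValueError(f"t={t} ns beyond the total transit time ({t_max:.6f} ns)")
    if t == 0.0:
        return 0.0
    lo, hi = 0.0, rng
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if transit_time(phantom, E0, mid, constants) < t:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
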