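"""Detector characterization and Compton-camera primitives.

Covers the empirical scintillator resolution fits, the background-
suppression figure of merit of timing measurements at a pulsed accelerator,
photon attenuation from bundled mass-attenuation tables, Compton scattering
kinematics, cone-of-response construction and backprojection, and the
Anger-logic block-detector position estimate with a simple flood-map
simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .constants import CONSTANTS

__all__ = [
    "ResolutionFit",
    "RESOLUTION_PRESETS",
    "AttenuationTable",
    "load_attenuation_table",
    "ComptonEvent",
    "Cone",
    "energy_resolution",
    "time_resolution",
    "fom_bsr",
    "mean_free_path",
    "attenuation_fraction",
    "compton_cos_theta",
    "compton_scattered_energy",
    "cone_from_event",
    "backproject",
    "anger_position",
    "simulate_flood_map",
]


@dataclass(frozen=True)
class ResolutionFit:
    """Empirical energy/timing resolution fit of a block detector.

    Energy resolution (% FWHM): a_E / sqrt(E/MeV) + b_E.
    Time resolution (ps FWHM):  a_t / sqrt(E/MeV) + b_t.
    """

    a_E: float
    b_E: float
    a_t: float
    b_t: float
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.a_E, self.b_E, self.a_t, self.b_t) < 0:
            raise ValueError("resolution fit coefficients must be >= 0")


RESOLUTION_PRESETS: dict[str, ResolutionFit] = {
    "LSO2": ResolutionFit(3.8, 5.6, 460.0, 80.0, "LSO2"),
    "BGO1": ResolutionFit(9.2, 3.7, 4900.0, 10.0, "BGO1"),
}


def energy_resolution(fit: ResolutionFit, E: float) -> float:
    """Relative energy resolution (FWHM, percent) at energy ``E`` (MeV)."""
    if E <= 0:
        raise ValueError("E must be > 0")
    return fit.a_E / math.sqrt(E) + fit.b_E


def time_resolution(fit: ResolutionFit, E: float) -> float:
    """Time resolution (FWHM, ps) at energy ``E`` (MeV)."""
    if E <= 0:
        raise ValueError("E must be > 0")
    return fit.a_t / math.sqrt(E) + fit.b_t


def fom_bsr(sigma_det: float, sigma_bunch: float, t_bunch: float) -> float:
    """Background-suppression figure of merit of a timing measurement.

    1 minus the quadrature sum of detector and bunch FWHM widths over the
    bunch period, clipped at zero.  All arguments in the same time unit.
    """
    if t_bunch <= 0:
        raise ValueError("t_bunch must be > 0")
    if sigma_det < 0 or sigma_bunch < 0:
        raise ValueError("sigma arguments must be >= 0")
    return max(0.0, 1.0 - math.hypot(sigma_det, sigma_bunch) / t_bunch)


# ---------------------------------------------------------------------------
# photon attenuation


@dataclass(frozen=True)
class AttenuationTable:
    """Photon total mass-attenuation grid for one material.

    ``energies`` (MeV, strictly increasing) and ``mu_over_rho`` (cm^2/g)
    define a log-log interpolated curve; ``rho`` is the density in g/cm^3.
    """

    material: str
    energies: tuple
    mu_over_rho: tuple
    rho: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies)
        m = np.asarray(self.mu_over_rho)
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("attenuation coefficients must be > 0")
        if self.rho <= 0:
            raise ValueError("density must be > 0")

    def mu_rho_at(self, E: float) -> float:
        """Log-log interpolated mass attenuation coefficient (cm^2/g)."""
        e = np.asarray(self.energies)
        if not e[0] <= E <= e[-1]:
            raise ValueError(f"E={E} MeV outside table range [{e[0]}, {e[-1]}]")
        return float(np.exp(np.interp(math.log(E), np.log(e),
                                      np.log(np.asarray(self.mu_over_rho)))))


def load_attenuation_table(material: str) -> AttenuationTable:
    """Load a bundled attenuation preset: 'pb', 'csi' or 'water'."""
    name = material.lower()
    ref = resources.files("pgtkit.data") / f"attenuation_{name}.tsv"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(f"no bundled attenuation table for {material!r}") from None
    rho = None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#"):
            if "density_g_cm3" in line:
                rho = float(line.split("=")[1])
            continue
        if line:
            e, m = line.split()
            rows.append((float(e), float(m)))
    return AttenuationTable(name, tuple(r[0] for r in rows), tuple(r[1] for r in rows), rho)


def mean_free_path(table: AttenuationTable, E: float) -> float:
    """Photon mean free path (cm) at energy ``E`` (MeV): the reciprocal of
    the linear attenuation coefficient."""
    return 1.0 / (table.mu_rho_at(E) * table.rho)


def attenuation_fraction(table: AttenuationTable, thickness: float, E: float) -> float:
    """Percentage of photons attenuated by a slab of given thickness (cm)."""
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    return 100.0 * (1.0 - math.exp(-thickness / mean_free_path(table, E)))


# ---------------------------------------------------------------------------
# Compton kinematics and cones


@dataclass(frozen=True)
class ComptonEvent:
    """Two-plane coincidence: scatter then absorption.

    Positions in mm; ``L_s`` and ``L_a`` are the energy deposits (MeV) in
    the scatterer and absorber.
    """

    r_s: tuple
    r_a: tuple
    L_s: float
    L_a: float

    def __post_init__(self) -> None:
        if self.L_s <= 0 or self.L_a <= 0:
            raise ValueError("energy deposits must be > 0")
        if np.allclose(self.r_s, self.r_a):
            raise ValueError("scatter and absorber positions must differ")


@dataclass(frozen=True)
class Cone:
    """Cone of possible photon incidence directions."""

    vertex: tuple
    axis: tuple  # unit vector, pointing from absorber through scatterer
    half_angle: float  # rad

    def __post_init__(self) -> None:
        if not math.isclose(float(np.linalg.norm(self.axis)), 1.0, rel_tol=1e-9):
            raise ValueError("axis must be a unit vector")
        if not 0 < self.half_angle < math.pi:
            raise ValueError("half angle must be in (0, pi)")


def compton_cos_theta(L_s: float, L_a: float, constants=CONSTANTS) -> tuple[float, bool]:
    """Cosine of the Compton scattering angle from the two energy deposits.

    With total energy E = L_s + L_a and scattered energy E' = L_a,
    cos(theta) = 1 - m_e c^2 (1/E' - 1/E).  Returns ``(cos_theta, valid)``
    where ``valid`` is False if the value falls outside [-1, 1]
    (kinematically forbidden deposit split).
    """
    if L_s <= 0 or L_a <= 0:
        raise ValueError("energy deposits must be > 0")
    e_tot = L_s + L_a
    cos_t = 1.0 - constants.m_e_c2 * (1.0 / L_a - 1.0 / e_tot)
    return cos_t, -1.0 <= cos_t <= 1.0


def compton_scattered_energy(E_gamma: float, theta: float, constants=CONSTANTS) -> float:
    """Scattered photon energy (MeV) for incident ``E_gamma`` at angle
    ``theta`` (rad); the forward Compton relation used as test oracle and in
    event generation."""
    return E_gamma / (1.0 + (E_gamma / constants.m_e_c2) * (1.0 - math.cos(theta)))


def cone_from_event(event: ComptonEvent, constants=CONSTANTS) -> Cone:
    """Cone of response of a two-plane event: vertex at the scatter point,
    axis from the absorber hit through the scatter hit (against the
    scattered photon's travel), opening angle from the Compton relation."""
    cos_t, valid = compton_cos_theta(event.L_s, event.L_a, constants)
    if not valid:
        raise ValueError("kinematically forbidden event: |cos theta| > 1")
    axis = np.asarray(event.r_s, dtype=float) - np.asarray(event.r_a, dtype=float)
    norm = np.linalg.norm(axis)
    axis = axis / norm
    return Cone(tuple(np.asarray(event.r_s, dtype=float)), tuple(axis), math.acos(cos_t))


def backproject(cones: list[Cone], grid_points: np.ndarray,
                angular_tolerance: float = 0.02) -> np.ndarray:
    """Count, for every grid point, the cones whose surface passes within
    ``angular_tolerance`` (rad) of the point.

    ``grid_points`` is an (N, 3) array; the result is a length-N intensity
    array.  Use :func:`plane_grid` to build planar lattices.
    """
    if len(cones) == 0:
        raise ValueError("need at least one cone")
    pts = np.asarray(grid_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("grid_points must be a non-empty (N, 3) array")
    intensity = np.zeros(pts.shape[0])
    for cone in cones:
        d = pts - np.asarray(cone.vertex)
        norm = np.linalg.norm(d, axis=1)
        ok = norm > 0
        cosang = np.zeros(len(pts))
        cosang[ok] = d[ok] @ np.asarray(cone.axis) / norm[ok]
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        intensity += np.abs(ang - cone.half_angle) <= angular_tolerance
    return intensity


def plane_grid(x: np.ndarray, y: np.ndarray, z: float) -> np.ndarray:
    """(len(x)*len(y), 3) lattice on the plane at height ``z``; points are
    ordered row-major so ``intensity.reshape(len(x), len(y))`` recovers the
    image with x as the first axis."""
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])


# ---------------------------------------------------------------------------
# Anger logic


#: PMT corner positions in block coordinates under the documented layout:
#: PMT1 lower-left, PMT2 lower-right, PMT3 upper-left, PMT4 upper-right.
_PMT_LAYOUT = ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0))


def anger_position(p1: float, p2: float, p3: float, p4: float) -> tuple[float, float]:
    """Block-coordinate position estimate from the four PMT light shares:
    X = (p2 + p4) / sum, Y = (p3 + p4) / sum, both in [0, 1]."""
    shares = (p1, p2, p3, p4)
    if any(p < 0 for p in shares):
        raise ValueError("light shares must be >= 0")
    total = sum(shares)
    if total <= 0:
        raise ValueError("zero total light")
    return (p2 + p4) / total, (p3 + p4) / total


def simulate_flood_map(n_pixels_per_side: int, E: float, fit: ResolutionFit,
                       n_events: int, seed: int, n_hist_bins: int = 128,
                       noise_scale: float = 1.0) -> np.ndarray:
    """Simulated block-detector flood map.

    Events land uniformly on an ``n x n`` grid of pixel centers; light
    shares follow a bilinear sharing model and carry multiplicative noise
    with relative sigma proportional to the statistical part of the energy
    resolution at ``E`` (the 1/sqrt(N_photons) scaling).  Returns the 2D
    histogram of the reconstructed Anger positions.
    """
    if n_pixels_per_side < 2:
        raise ValueError("need at least 2 pixels per side")
    rng = np.random.default_rng(seed)
    n = n_pixels_per_side
    centers = (np.arange(n) + 0.5) / n
    ix = rng.integers(0, n, size=n_events)
    iy = rng.integers(0, n, size=n_events)
    x, y = centers[ix], centers[iy]
    shares = np.stack([(1 - x) * (1 - y), x * (1 - y), (1 - x) * y, x * y], axis=1)
    # statistical light-share fluctuation: FWHM% -> relative sigma
    rel_sigma = noise_scale * (fit.a_E / math.sqrt(E)) / 100.0 / (2 * math.sqrt(2 * math.log(2)))
    if rel_sigma > 0:
        shares = np.clip(shares * (1 + rng.normal(0, rel_sigma, shares.shape)), 0, None)
    total = shares.sum(axis=1)
    ok = total > 0
    X = (shares[ok, 1] + shares[ok, 3]) / total[ok]
    Y = (shares[ok, 2] + shares[ok, 3]) / total[ok]
    hist, _, _ = np.histogram2d(X, Y, bins=n_hist_bins, range=[[0, 1], [0, 1]])
    return hist
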