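"""Forward model of prompt-gamma-timing (PGT) spectra.

A detection time is the proton transit time to the emission depth plus the
photon time of flight to the detector, smeared by the system time resolution
(detector plus bunch spread, added in quadrature as FWHM) and folded modulo
the accelerator bunch period.  The emission density along the track follows
the box approximation generalized to heterogeneous targets: proportional to
local mass density times a per-material yield factor, constant otherwise,
and zero beyond the proton range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from . import transport
from .constants import CONSTANTS
from .transport import LayeredPhantom, csda_range, velocity

__all__ = [
    "BeamSpec",
    "DetectorSpec",
    "PGTSpectrum",
    "DriftModel",
    "EventList",
    "bunch_sigma_at",
    "arrival_time",
    "emission_density",
    "sensitivity",
    "expected_spectrum",
    "sample_events",
    "apply_drift",
    "TransportProfile",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: (proton energy MeV, bunch FWHM ns) anchors for the C230-like machine:
#: 2 ns at 100 MeV shrinking to 350 ps at 230 MeV; linear in between.
BUNCH_SIGMA_ANCHORS = ((100.0, 2.0), (230.0, 0.35))


def bunch_sigma_at(E0: float) -> float:
    """Bunch time spread FWHM (ns) interpolated linearly in beam energy,
    clamped at the anchor values outside [100, 230] MeV."""
    (e1, s1), (e2, s2) = BUNCH_SIGMA_ANCHORS
    if E0 <= e1:
        return s1
    if E0 >= e2:
        return s2
    return s1 + (s2 - s1) * (E0 - e1) / (e2 - e1)


@dataclass(frozen=True)
class BeamSpec:
    """Beam configuration.

    ``sigma_bunch`` is the bunch time spread FWHM in ns; if None it is
    interpolated from the built-in energy anchors.  ``gamma_yield`` is the
    mean number of prompt gammas (above threshold) per proton.
    """

    E0: float
    f_bunch: float = 106.0  # MHz
    sigma_bunch: float | None = None
    n_protons: float = 1e8
    gamma_yield: float = 0.16

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError("E0 must be > 0")
        if self.f_bunch <= 0:
            raise ValueError("f_bunch must be > 0")
        if self.sigma_bunch is not None and self.sigma_bunch < 0:
            raise ValueError("sigma_bunch must be >= 0")
        if self.gamma_yield < 0:
            raise ValueError("gamma_yield must be >= 0")

    @property
    def t_bunch(self) -> float:
        """Bunch period in ns."""
        return 1000.0 / self.f_bunch

    @property
    def sigma_bunch_fwhm(self) -> float:
        return self.sigma_bunch if self.sigma_bunch is not None else bunch_sigma_at(self.E0)


@dataclass(frozen=True)
class DetectorSpec:
    """Single monolithic timing detector on a ring around the beam axis.

    ``alpha`` is the ring angle w.r.t. the beam axis in degrees, ``d`` the
    distance (mm) from the ring centre, ``z_ref`` the axial position of the
    ring centre (None = phantom mid-length, resolved by the model functions).
    ``sigma_det`` is the detector time resolution FWHM in ns.
    """

    alpha: float = 90.0
    d: float = 300.0
    radius: float = 25.4
    eff: float = 1.0
    sigma_det: float = 0.3
    z_ref: float | None = None

    def __post_init__(self) -> None:
        if self.d <= self.radius:
            raise ValueError("detector distance must exceed its radius")
        if not 0 < self.eff <= 1:
            raise ValueError("eff must be in (0, 1]")
        if self.sigma_det < 0:
            raise ValueError("sigma_det must be >= 0")

    def position(self, z_ref: float) -> np.ndarray:
        a = math.radians(self.alpha)
        return np.array([self.d * math.sin(a), 0.0, z_ref + self.d * math.cos(a)])


@dataclass
class PGTSpectrum:
    """Binned detection-time histogram (phase within one bunch period)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have len(bin_edges) - 1 entries")
        if np.any(self.counts < -1e-9):
            raise ValueError("counts must be >= 0")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bins must be uniform")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class DriftModel:
    """Piecewise-linear bunch-phase drift versus wall time.

    ``breakpoints`` is a sequence of (wall time s, phase offset ns) pairs
    with strictly increasing wall times.
    """

    breakpoints: tuple

    def __post_init__(self) -> None:
        times = [b[0] for b in self.breakpoints]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("drift breakpoint wall-times must be strictly increasing")

    def offset(self, wall_time: np.ndarray) -> np.ndarray:
        wall_time = np.asarray(wall_time, dtype=float)
        times = np.array([b[0] for b in self.breakpoints])
        offs = np.array([b[1] for b in self.breakpoints])
        if np.any(wall_time < times[0]) or np.any(wall_time > times[-1]):
            warnings.warn("wall time outside drift domain; extrapolating with end values")
        return np.interp(wall_time, times, offs)


@dataclass
class EventList:
    """Sampled detection events: bunch phase (ns) and wall time (s)."""

    phase: np.ndarray
    wall_time: np.ndarray
    t_bunch: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.wall_time = np.asarray(self.wall_time, dtype=float)
        if self.phase.shape != self.wall_time.shape:
            raise ValueError("phase and wall_time must have matching shapes")


# ---------------------------------------------------------------------------


def _resolve_z_ref(detector: DetectorSpec, phantom: LayeredPhantom) -> float:
    return detector.z_ref if detector.z_ref is not None else 0.5 * phantom.length


class TransportProfile:
    """Dense, cached depth profile of one phantom/beam/detector configuration.

    Precomputes proton energy, transit time, photon flight distance, arrival
    time, emission density and solid-angle sensitivity on a fine z grid so
    spectrum construction and sampling are vectorized.
    """

    def __init__(self, phantom: LayeredPhantom, beam: BeamSpec, detector: DetectorSpec,
                 dz: float = 0.01, constants=CONSTANTS):
        self.phantom, self.beam, self.detector = phantom, beam, detector
        self.constants = constants
        rng = csda_range(phantom, beam.E0)
        self.range = min(rng, phantom.length) if np.isfinite(rng) else phantom.length
        self.z_ref = _resolve_z_ref(detector, phantom)
        n = max(int(self.range / dz), 200)
        self.z = np.linspace(0.0, self.range, n + 1)
        # closed-form per-slice energies, vectorized
        self.E = self._energy_grid()
        v = velocity(np.maximum(self.E, transport.E_FLOOR), constants)
        inv_v = np.where(self.E > 0, 1.0 / v, 1.0 / velocity(transport.E_FLOOR, constants))
        from scipy.integrate import cumulative_trapezoid

        self.t_p = np.concatenate([[0.0], cumulative_trapezoid(inv_v, self.z)])
        det_pos = detector.position(self.z_ref)
        dx, dy = det_pos[0], det_pos[1]
        self.dist = np.sqrt(dx**2 + dy**2 + (det_pos[2] - self.z) ** 2)
        if np.any(self.dist <= detector.radius):
            raise ValueError("emission point inside the detector radius")
        self.tof = self.dist / constants.c
        self.t_arr = self.t_p + self.tof
        self.eps = phantom.rho_at(self.z) * phantom.yield_at(self.z)
        self.w = detector.radius**2 / (4.0 * self.dist**2)
        if np.any(np.diff(self.t_arr) <= 0):
            raise ValueError("arrival time is not strictly monotone for this geometry")

    def _energy_grid(self) -> np.ndarray:
        E = np.empty_like(self.z)
        e_in = self.beam.E0
        edges = self.phantom.boundaries
        floor_p = None
        E[:] = 0.0
        for i, s in enumerate(self.phantom.slices):
            lo, hi = edges[i], edges[i + 1]
            mask = (self.z >= lo) & (self.z <= hi)
            if not mask.any():
                continue
            m = s.material
            if m.stopping_table is None:
                p, a = m.bk_p, m.bk_alpha
                val = e_in**p - m.k_lin * (self.z[mask] - lo) / a
                E[mask] = np.where(val > 0, np.abs(val) ** (1.0 / p), 0.0)
            else:  # rare path: per-point numeric propagation
                E[mask] = [transport.energy_at_depth(self.phantom, self.beam.E0, z)
                           for z in self.z[mask]]
            e_in = transport._slice_exit_energy(m, e_in, s.thickness)
            if e_in <= transport.E_FLOOR:
                break
        return np.maximum(E, 0.0)

    # -- derived quantities -------------------------------------------------

    @property
    def sigma_sys_fwhm(self) -> float:
        return math.hypot(self.detector.sigma_det, self.beam.sigma_bunch_fwhm)

    def mean_signal_counts(self) -> float:
        """Poisson mean of detected signal events.

        ``gamma_yield`` counts gammas per fully stopped proton; for shoot-
        through targets the emission scales with the fraction of the water-
        equivalent range covered inside the target, so stacking more target
        material grows the spectrum area until the beam stops.
        """
        num = np.trapezoid(self.eps * self.w, self.z)
        den = np.trapezoid(self.eps, self.z)
        if den == 0:
            return 0.0
        wepl = np.trapezoid(self.phantom.k_lin_at(self.z), self.z)
        r_water = transport.BK_ALPHA_WATER * self.beam.E0**transport.BK_P_WATER
        frac = min(wepl / r_water, 1.0)
        return (self.beam.n_protons * self.beam.gamma_yield * self.detector.eff
                * frac * num / den)

    def arrival_of_depth(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self.z, self.t_arr)

    def depth_of_arrival(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.t_arr, self.z)

    def darrival_dz(self, z: float) -> float:
        """Local derivative of arrival time w.r.t. depth (ns/mm)."""
        E = float(np.interp(z, self.z, self.E))
        inv_v = 1.0 / velocity(max(E, transport.E_FLOOR), self.constants)
        det_pos = self.detector.position(self.z_ref)
        dist = float(np.interp(z, self.z, self.dist))
        dtof = (z - det_pos[2]) / (dist * self.constants.c)
        return inv_v + dtof


def arrival_time(phantom: LayeredPhantom, beam: BeamSpec, detector: DetectorSpec,
                 z: float, constants=CONSTANTS) -> float:
    """Detection time (ns) of a prompt gamma emitted at depth ``z``:
    proton transit time plus straight-line photon time of flight."""
    z_ref = _resolve_z_ref(detector, phantom)
    t_p = transport.transit_time(phantom, beam.E0, z, constants)
    det_pos = detector.position(z_ref)
    dist = float(np.linalg.norm(det_pos - np.array([0.0, 0.0, z])))
    return t_p + dist / constants.c


def emission_density(phantom: LayeredPhantom, E0: float, z) -> np.ndarray | float:
    """Relative prompt-gamma emission density (per mm): local mass density
    times yield factor inside [0, range), zero beyond."""
    rng = csda_range(phantom, E0)
    z_arr = np.asarray(z, dtype=float)
    out = phantom.rho_at(z_arr) * phantom.yield_at(z_arr)
    out = np.where(z_arr < rng, out, 0.0)
    return float(out) if np.isscalar(z) or z_arr.ndim == 0 else out


def sensitivity(detector: DetectorSpec, z, z_ref: float = 0.0) -> np.ndarray | float:
    """Far-field solid-angle fraction of the detector face as seen from an
    emission point on the axis at depth ``z``."""
    z_arr = np.asarray(z, dtype=float)
    det_pos = detector.position(z_ref)
    dist = np.sqrt(det_pos[0] ** 2 + det_pos[1] ** 2 + (det_pos[2] - z_arr) ** 2)
    if np.any(dist <= detector.radius):
        raise ValueError("emission point inside the detector radius")
    w = detector.radius**2 / (4.0 * dist**2)
    return float(w) if np.isscalar(z) or z_arr.ndim == 0 else w


def _fold_gaussian_into_bins(times: np.ndarray, weights: np.ndarray, sigma: float,
                             edges: np.ndarray, t_bunch: float, wrap: bool) -> np.ndarray:
    """Deposit Gaussian kernels (std ``sigma``) of given weights into bins,
    folding modulo the bunch period when ``wrap``."""
    counts = np.zeros(len(edges) - 1)
    if wrap:
        pad = 8.0 * sigma
        k_lo = math.floor((edges[0] - pad - times.max()) / t_bunch)
        k_hi = math.ceil((edges[-1] + pad - times.min()) / t_bunch)
        reps = range(k_lo, k_hi + 1)
    else:
        reps = (0,)
    if sigma == 0:
        for k in reps:
            t = times + k * t_bunch
            idx = np.searchsorted(edges, t, side="right") - 1
            ok = (idx >= 0) & (idx < len(counts))
            np.add.at(counts, idx[ok], weights[ok])
        return counts
    for k in reps:
        t = times + k * t_bunch
        # ndtr CDF differences across bin edges, vectorized over (bins, times)
        z = (edges[:, None] - t[None, :]) / sigma
        cdf = ndtr(z)
        counts += ((cdf[1:] - cdf[:-1]) * weights[None, :]).sum(axis=1)
    return counts


def default_bins(beam: BeamSpec, n_bins: int = 100) -> np.ndarray:
    return np.linspace(0.0, beam.t_bunch, n_bins + 1)


def expected_spectrum(phantom: LayeredPhantom, beam: BeamSpec, detector: DetectorSpec,
                      bins: np.ndarray | int = 100, background: float = 0.05,
                      wrap: bool = True, profile: TransportProfile | None = None) -> PGTSpectrum:
    """Analytic expected PGT spectrum (box emission model).

    The expectation is the depth integral of emission density times
    sensitivity, transported to arrival time, convolved with a Gaussian of
    FWHM sqrt(sigma_det^2 + sigma_bunch^2) and folded modulo the bunch
    period.  ``background`` is the flat-pedestal fraction of total counts.
    The integral of the signal part equals the Poisson mean used by
    :func:`sample_events`.
    """
    if profile is None:
        profile = TransportProfile(phantom, beam, detector)
    edges = default_bins(beam, bins) if isinstance(bins, int) else np.asarray(bins, dtype=float)
    if not 0 <= background < 1:
        raise ValueError("background fraction must be in [0, 1)")
    mu_sig = profile.mean_signal_counts()
    counts = np.zeros(len(edges) - 1)
    if mu_sig > 0:
        # midpoint weights on the dense grid
        zc = 0.5 * (profile.z[:-1] + profile.z[1:])
        dz = np.diff(profile.z)
        ew = np.interp(zc, profile.z, profile.eps * profile.w) * dz
        if ew.sum() > 0:
            weights = ew / ew.sum() * mu_sig
            tc = np.interp(zc, profile.z, profile.t_arr)
            sigma = profile.sigma_sys_fwhm * FWHM_TO_SIGMA
            tc_w = np.mod(tc, beam.t_bunch) if wrap else tc
            counts = _fold_gaussian_into_bins(tc_w, weights, sigma, edges, beam.t_bunch, wrap)
    mu_bkg = mu_sig * background / (1.0 - background)
    counts = counts + mu_bkg / (len(edges) - 1)
    meta = {"n_protons": beam.n_protons, "seed": None, "wrap": wrap,
            "t_bunch_ns": beam.t_bunch, "expected": True}
    return PGTSpectrum(edges, counts, meta)


def sample_events(phantom: LayeredPhantom, beam: BeamSpec, detector: DetectorSpec,
                  seed: int, bins: np.ndarray | int = 100, background: float = 0.05,
                  wrap: bool = True, duration: float = 1.0,
                  profile: TransportProfile | None = None) -> tuple[EventList, PGTSpectrum]:
    """Monte Carlo twin of :func:`expected_spectrum`.

    Draws a Poisson number of signal events, samples emission depths by
    inverse CDF of the sensitivity-weighted emission density, adds Gaussian
    timing jitter and a flat background admixture, and wraps phases into
    [0, t_bunch).  Fully reproducible for a fixed seed.
    """
    if profile is None:
        profile = TransportProfile(phantom, beam, detector)
    rng = np.random.default_rng(seed)
    edges = default_bins(beam, bins) if isinstance(bins, int) else np.asarray(bins, dtype=float)
    mu_sig = profile.mean_signal_counts()
    n_sig = rng.poisson(mu_sig)
    # inverse-CDF depth sampling
    pdf = profile.eps * profile.w
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(profile.z))])
    if cdf[-1] > 0:
        z_smp = np.interp(rng.random(n_sig) * cdf[-1], cdf, profile.z)
    else:
        z_smp = np.empty(0)
        n_sig = 0
    t = profile.arrival_of_depth(z_smp)
    sigma = profile.sigma_sys_fwhm * FWHM_TO_SIGMA
    if sigma > 0 and n_sig:
        t = t + rng.normal(0.0, sigma, size=n_sig)
    mu_bkg = mu_sig * background / (1.0 - background)
    n_bkg = rng.poisson(mu_bkg)
    t_bkg = rng.random(n_bkg) * beam.t_bunch
    phases = np.concatenate([t, t_bkg])
    if wrap:
        phases = np.mod(phases, beam.t_bunch)
    wall = rng.random(phases.size) * duration
    events = EventList(phases, wall, beam.t_bunch)
    counts, _ = np.histogram(phases, bins=edges)
    meta = {"n_protons": beam.n_protons, "seed": seed, "wrap": wrap,
            "t_bunch_ns": beam.t_bunch, "expected": False}
    return events, PGTSpectrum(edges, counts.astype(float), meta)


def apply_drift(events: EventList, drift: DriftModel) -> EventList:
    """Shift each event's phase by the drift offset at its wall time and
    re-wrap modulo the bunch period."""
    off = drift.offset(events.wall_time)
    phase = np.mod(events.phase + off, events.t_bunch)
    return EventList(phase, events.wall_time.copy(), events.t_bunch)


def histogram_events(events: EventList, bins: np.ndarray | int = 100,
                     meta: dict | None = None) -> PGTSpectrum:
    """Bin an event list into a PGT spectrum."""
    edges = (np.linspace(0.0, events.t_bunch, bins + 1)
             if isinstance(bins, int) else np.asarray(bins, dtype=float))
    counts, _ = np.histogram(events.phase, bins=edges)
    return PGTSpectrum(edges, counts.astype(float), meta or {"t_bunch_ns": events.t_bunch})
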