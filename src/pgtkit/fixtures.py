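"""Canned experiment geometries.

Presets reproduce the cylindrical-target irradiations at a 106-MHz
cyclotron: a full (400-mm) PMMA target at 230 MeV, the same target with a
5-mm air cavity or a 20-mm cortical-bone insert with front face at
f = 169 mm, and a stacked-target series of partial PMMA thicknesses.
"""

from __future__ import annotations

from .model import BeamSpec, DetectorSpec, PGTSpectrum, sample_events
from .transport import MATERIALS, LayeredPhantom, Slice

__all__ = ["FIXTURES", "make_fixture", "insert_phantom", "stacked_phantom"]

_FULL_LENGTH = 400.0  # mm of PMMA, stops 230 MeV protons
_F_INSERT = 169.0  # mm, insert front face


def insert_phantom(f: float, h: float, insert_material: str,
                   total: float = _FULL_LENGTH, bulk: str = "pmma") -> LayeredPhantom:
    """Bulk target of ``total`` mm with an insert of thickness ``h`` whose
    front face sits at depth ``f``."""
    if not 0 < f < f + h < total:
        raise ValueError("insert must lie strictly inside the target")
    m_bulk, m_ins = MATERIALS[bulk], MATERIALS[insert_material]
    return LayeredPhantom([Slice(m_bulk, f), Slice(m_ins, h), Slice(m_bulk, total - f - h)])


def stacked_phantom(thickness: float) -> LayeredPhantom:
    """Homogeneous PMMA target of the given thickness (stacked-target run)."""
    return LayeredPhantom([Slice(MATERIALS["pmma"], thickness)])


def _beam_230() -> BeamSpec:
    return BeamSpec(E0=230.0, f_bunch=106.0, n_protons=1e8, gamma_yield=0.16)


def _detector_ring() -> DetectorSpec:
    return DetectorSpec(alpha=90.0, d=300.0, radius=25.4, eff=0.5, sigma_det=0.3)


FIXTURES = {
    "wpe_homogeneous_230": lambda: (stacked_phantom(_FULL_LENGTH), _beam_230(), _detector_ring()),
    "wpe_cavity_5mm": lambda: (insert_phantom(_F_INSERT, 5.0, "air"), _beam_230(), _detector_ring()),
    "wpe_bone_20mm": lambda: (insert_phantom(_F_INSERT, 20.0, "bone"), _beam_230(), _detector_ring()),
}


def make_fixture(name: str, seed: int | None = None
                 ) -> tuple[LayeredPhantom, BeamSpec, DetectorSpec, PGTSpectrum | None]:
    """Return (phantom, beam, detector[, sampled spectrum]) for a preset.

    With a seed, a Monte Carlo spectrum is sampled deterministically.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    phantom, beam, detector = FIXTURES[name]()
    spectrum = None
    if seed is not None:
        _, spectrum = sample_events(phantom, beam, detector, seed)
    return phantom, beam, detector, spectrum
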