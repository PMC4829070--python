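"""Physical constants used throughout the package."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants in the units used internally (mm, ns, MeV).

    Attributes
    ----------
    c : float
        Speed of light in vacuum, mm/ns.
    m_p_c2 : float
        Proton rest energy, MeV.
    m_e_c2 : float
        Electron rest energy, MeV.
    """

    c: float = 299.792458
    m_p_c2: float = 938.272
    m_e_c2: float = 0.511

    def __post_init__(self) -> None:
        if self.c <= 0 or self.m_p_c2 <= 0 or self.m_e_c2 <= 0:
            raise ValueError("all physical constants must be positive")


#: Module-level default constant set.
CONSTANTS = PhysicalConstants()
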