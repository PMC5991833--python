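"""Physical constants used throughout the package.

Everything internal is strict SI: volts, coulombs, farads, metres, seconds,
mol·m⁻³ for electrolyte concentrations.  Millivolts, picoamps and
femtofarads appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: vacuum permittivity (F·m⁻¹)
EPS0 = 8.8541878128e-12

#: elementary charge (C)
E_CHARGE = 1.602176634e-19


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic and electrostatic constants of the bathing solutions.

    Parameters
    ----------
    R : float
        Ideal gas constant (J·mol⁻¹·K⁻¹).
    F : float
        Faraday constant (C·mol⁻¹).
    T : float
        Absolute temperature (K).  Default 295 K, i.e. room temperature.
    eps_sol : float
        Absolute permittivity of the bulk aqueous solution (F·m⁻¹).
        Default 78.5 × vacuum permittivity.
    """

    R: float = 8.314462618
    F: float = 96485.33212
    T: float = 295.0
    eps_sol: float = field(default=78.5 * EPS0)

    def __post_init__(self) -> None:
        for name in ("R", "F", "T", "eps_sol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 250.0 <= self.T <= 330.0:
            raise ValueError(f"temperature {self.T} K outside the supported range [250, 330] K")

    @property
    def RT(self) -> float:
        """Thermal energy per mole, R·T (J·mol⁻¹)."""
        return self.R * self.T

    @property
    def thermal_voltage(self) -> float:
        """RT/F (V), ~25.4 mV at 295 K."""
        return self.R * self.T / self.F


DEFAULT_CONSTANTS = PhysicalConstants()
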