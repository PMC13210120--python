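"""Physical constants for homonuclear proton dipolar couplings.

CODATA 2018 values.  The only derived quantity used by the analysis is the
dipolar prefactor ``K_HH = -mu0 * hbar * gammaH**2 / (8 * pi**2)`` in Hz m^3;
a proton pair at 200 pm then has a coupling of about -1.50e4 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

MU0 = 1.25663706212e-6  # vacuum permeability [N A^-2]
HBAR = 1.054571817e-34  # reduced Planck constant [J s]
GAMMA_H = 2.6752218744e8  # 1H magnetogyric ratio [rad s^-1 T^-1]

PM_PER_M = 1.0e12


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of constants entering the dipolar coupling prefactor."""

    mu0: float = MU0
    hbar: float = HBAR
    gammaH: float = GAMMA_H
    k_hh: float = field(init=False)

    def __post_init__(self) -> None:
        k = -self.mu0 * self.hbar * self.gammaH**2 / (8.0 * math.pi**2)
        object.__setattr__(self, "k_hh", k)

    @property
    def k_hh_pm(self) -> float:
        """Prefactor in Hz pm^3 (for distances expressed in pm)."""
        return self.k_hh * PM_PER_M**3


CONSTANTS = PhysicalConstants()
K_HH = CONSTANTS.k_hh  # Hz m^3, negative
K_HH_PM = CONSTANTS.k_hh_pm  # Hz pm^3, negative
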