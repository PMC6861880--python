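"""Physical constants of the three transported gases.

All partial pressures in this package are in mmHg, gas amounts are volumes
at STPD (0 degC, 760 mmHg) in mL, blood contents in mL_gas per mL_blood.
"""

from __future__ import annotations

from dataclasses import dataclass

#: universal gas constant, J mol-1 K-1
R_UNIVERSAL = 8.314462618

#: molar volume of an ideal gas at STPD, mL mol-1
STPD_MOLAR_VOLUME = 22_413.96

#: saturated water vapour pressure at body temperature (37 degC), mmHg
WATER_VAPOUR_MMHG = 47.0

MMHG_PER_ATM = 760.0


@dataclass(frozen=True)
class GasSpecies:
    """One transported gas and its physical constants.

    Parameters
    ----------
    name : str
        One of ``"O2"``, ``"CO2"``, ``"CO"``.
    molar_mass : float
        g mol-1.
    cp : float
        Specific heat at constant pressure, kJ kg-1 K-1.
    alpha : float
        Physical solubility in blood, mL_gas mL_blood-1 mmHg-1.
    """

    name: str
    molar_mass: float
    cp: float
    alpha: float

    def __post_init__(self) -> None:
        if self.name not in ("O2", "CO2", "CO"):
            raise ValueError(f"unknown gas {self.name!r}")
        if min(self.molar_mass, self.cp, self.alpha) <= 0:
            raise ValueError("gas constants must be positive")

    @property
    def R(self) -> float:
        """Specific (mass-basis) gas constant, kJ kg-1 K-1."""
        return R_UNIVERSAL / self.molar_mass  # J/(g K) == kJ/(kg K)

    @property
    def stpd_density(self) -> float:
        """Ideal-gas density at STPD, g mL-1."""
        return self.molar_mass / STPD_MOLAR_VOLUME


O2 = GasSpecies("O2", molar_mass=31.998, cp=0.918, alpha=3.0e-5)
CO2 = GasSpecies("CO2", molar_mass=44.009, cp=0.844, alpha=6.7e-4)
CO = GasSpecies("CO", molar_mass=28.010, cp=1.040, alpha=2.4e-5)

GASES: dict[str, GasSpecies] = {g.name: g for g in (O2, CO2, CO)}


def ppm_to_mmhg(ppm: float, barometric_mmhg: float = MMHG_PER_ATM,
                wet: bool = True) -> float:
    """Convert an ambient trace-gas mole fraction in ppm to a partial pressure.

    With ``wet=True`` the fraction applies to the water-vapour-corrected
    (tracheal) pressure ``barometric - 47 mmHg``, which is the pressure the
    alveolar gas actually sees.
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    base = barometric_mmhg - WATER_VAPOUR_MMHG if wet else barometric_mmhg
    return ppm * 1e-6 * base


def volume_stpd_to_mass_rate(v_ml_min: float, gas: GasSpecies) -> float:
    """STPD volumetric rate (mL min-1) -> mass rate (kg s-1)."""
    return v_ml_min * gas.stpd_density * 1e-3 / 60.0
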