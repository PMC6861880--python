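"""Hemoglobin binding and blood gas contents.

The oxygen dissociation curve is a Hill curve extended to competitive CO
binding through the first-order Haldane relation

    S_CO / S_O2 = M * P_CO / P_O2

with the normalisation S_O2 + S_CO + S_free = 1.  Writing the combined
ligand pressure P_eff = P_O2 + M * P_CO, total heme occupancy follows the
Hill curve in P_eff and is partitioned between the two ligands in
proportion to P_O2 : M * P_CO.  This reproduces the two facts the model
rests on -- sigmoidal cooperative O2 binding and a CO affinity a couple of
hundred times that of O2 -- with the fewest free parameters.

Total blood content of a heme-bound gas is

    C = alpha * P + N * [Hb] * S

(dissolved plus bound).  CO2 is carried mostly as bicarbonate and never
competes for heme sites here; its content curve is the empirical power law
``co2_content``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .gases import CO2 as _CO2
from .gases import GASES, GasSpecies

__all__ = [
    "HemoglobinVariant",
    "BloodState",
    "ADULT",
    "FETAL",
    "o2_co_saturations",
    "gas_content",
    "co2_content",
    "invert_co2_content",
    "invert_saturation",
    "pressures_from_contents",
]

#: molar mass of the hemoglobin tetramer, g mol-1
HB_MOLAR_MASS = 64_458.0

#: CO2 content power law C = a * P**b (mL CO2 per mL blood, P in mmHg);
#: fit to standard whole-blood CO2 dissociation data (0.44 mL/mL at 40 mmHg)
CO2_CURVE_A = 0.0821
CO2_CURVE_B = 0.455


@dataclass(frozen=True)
class HemoglobinVariant:
    """Binding parameters of one hemoglobin variant.

    Parameters
    ----------
    kind : str
        ``"adult"`` or ``"fetal"``.
    hb_conc : float
        Hemoglobin concentration, g dL-1.
    n_capacity : float
        Carrying capacity, mL gas (STPD) per g Hb (Hufner-type constant).
    p50_o2 : float
        O2 pressure at half saturation (no CO), mmHg.
    hill_n : float
        Hill cooperativity exponent.
    m_haldane : float
        CO/O2 relative affinity (Haldane constant).
    """

    kind: str
    hb_conc: float
    n_capacity: float = 1.34
    p50_o2: float = 26.6
    hill_n: float = 2.7
    m_haldane: float = 218.0

    def __post_init__(self) -> None:
        if self.kind not in ("adult", "fetal"):
            raise ValueError(f"kind must be 'adult' or 'fetal', got {self.kind!r}")
        if min(self.hb_conc, self.n_capacity, self.p50_o2, self.hill_n) <= 0:
            raise ValueError("hemoglobin parameters must be positive")
        if not 100.0 <= self.m_haldane <= 300.0:
            raise ValueError("m_haldane outside the physiological 100-300 band")

    @property
    def hb_conc_g_ml(self) -> float:
        """[Hb] in g per mL of blood."""
        return self.hb_conc / 100.0

    @property
    def capacity(self) -> float:
        """Maximal bound-gas content N*[Hb], mL gas per mL blood."""
        return self.n_capacity * self.hb_conc_g_ml


#: maternal (pregnant adult) hemoglobin
ADULT = HemoglobinVariant(kind="adult", hb_conc=12.1, p50_o2=26.6)
#: fetal hemoglobin (higher O2 affinity)
FETAL = HemoglobinVariant(kind="fetal", hb_conc=14.5, p50_o2=19.0)


@dataclass
class BloodState:
    """Partial pressures, saturations, contents and flow of one blood stream.

    ``P`` and ``C`` are keyed by gas name ("O2", "CO2", "CO"); ``S`` by the
    heme-bindable gases ("O2", "CO").  Contents in mL gas (STPD) per mL
    blood, flow in mL min-1, temperature in K.
    """

    P: dict[str, float]
    S: dict[str, float]
    C: dict[str, float]
    flow: float
    T: float = 310.15

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.P.values()):
            raise ValueError("partial pressures must be non-negative")
        s_o2, s_co = self.S.get("O2", 0.0), self.S.get("CO", 0.0)
        if s_o2 < 0 or s_co < 0 or s_o2 + s_co > 1 + 1e-12:
            raise ValueError("saturations must be in [0,1] with S_O2+S_CO<=1")
        for name, c in self.C.items():
            if c + 1e-15 < GASES[name].alpha * self.P[name] * (name != "CO2"):
                raise ValueError(f"{name} content below its dissolved fraction")


def o2_co_saturations(p_o2: float, p_co: float,
                      hb: HemoglobinVariant) -> tuple[float, float]:
    """Equilibrium (S_O2, S_CO) under competitive binding.

    Satisfies the Haldane relation S_CO/S_O2 = M*P_CO/P_O2 identically and
    reduces to the Hill curve when ``p_co == 0``.
    """
    if p_o2 < 0 or p_co < 0:
        raise ValueError("partial pressures must be non-negative")
    p_eff = p_o2 + hb.m_haldane * p_co
    if p_eff == 0.0:
        return 0.0, 0.0
    z = (p_eff / hb.p50_o2) ** hb.hill_n
    s_tot = z / (1.0 + z)
    s_o2 = s_tot * p_o2 / p_eff
    s_co = s_tot * hb.m_haldane * p_co / p_eff
    return s_o2, s_co


def gas_content(p: float, s: float, gas: GasSpecies,
                hb: HemoglobinVariant) -> float:
    """Total content alpha*P + N*[Hb]*S for a heme-bound gas; CO2 delegates
    to :func:`co2_content` (S is ignored for CO2)."""
    if p < 0:
        raise ValueError("pressure must be non-negative")
    if gas.name == "CO2":
        return co2_content(p)
    if not 0.0 <= s <= 1.0:
        raise ValueError("saturation must be in [0, 1]")
    return gas.alpha * p + hb.capacity * s


def co2_content(p_co2: float, a: float = CO2_CURVE_A,
                b: float = CO2_CURVE_B) -> float:
    """Whole-blood CO2 content (mL/mL) at a given partial pressure.

    Monotone, concave power law through the origin; coefficients are a fit
    to standard whole-blood CO2 dissociation data and can be swapped via
    the ``a``/``b`` hooks (or the config file).
    """
    if p_co2 < 0:
        raise ValueError("pressure must be non-negative")
    return a * p_co2 ** b


def invert_co2_content(c: float, a: float = CO2_CURVE_A,
                       b: float = CO2_CURVE_B) -> float:
    """Inverse of :func:`co2_content`."""
    if c < 0:
        raise ValueError("content must be non-negative")
    return (c / a) ** (1.0 / b)


def blood_contents(p_o2: float, p_co2: float, p_co: float,
                   hb: HemoglobinVariant) -> tuple[dict, dict]:
    """Saturations and contents of all three gases at given pressures."""
    s_o2, s_co = o2_co_saturations(p_o2, p_co, hb)
    c = {
        "O2": gas_content(p_o2, s_o2, GASES["O2"], hb),
        "CO": gas_content(p_co, s_co, GASES["CO"], hb),
        "CO2": co2_content(p_co2),
    }
    return {"O2": s_o2, "CO": s_co}, c


def make_blood_state(p_o2: float, p_co2: float, p_co: float,
                     hb: HemoglobinVariant, flow: float,
                     temperature: float = 310.15) -> BloodState:
    s, c = blood_contents(p_o2, p_co2, p_co, hb)
    return BloodState(P={"O2": p_o2, "CO2": p_co2, "CO": p_co},
                      S=s, C=c, flow=flow, T=temperature)


def invert_saturation(s_target: float, p_co: float, hb: HemoglobinVariant,
                      p_max: float = 5000.0) -> float:
    """O2 pressure at which S_O2 equals ``s_target`` for a fixed CO pressure.

    Raises ``ValueError`` when the target is unreachable (CO occupancy caps
    the attainable S_O2 below the target).
    """
    if not 0.0 < s_target < 1.0:
        raise ValueError("target saturation must be in (0, 1)")
    s_hi = o2_co_saturations(p_max, p_co, hb)[0]
    if s_target >= s_hi:
        raise ValueError(
            f"S_O2={s_target} unreachable below {p_max} mmHg at P_CO={p_co}")
    return brentq(lambda p: o2_co_saturations(p, p_co, hb)[0] - s_target,
                  0.0, p_max, xtol=1e-12, rtol=1e-15)


def pressures_from_contents(c_o2: float, c_co: float, hb: HemoglobinVariant,
                            p_o2_max: float = 5000.0,
                            p_co_max: float = 50.0) -> tuple[float, float]:
    """Invert total O2 and CO contents to the (P_O2, P_CO) pair.

    Nested bracketed root finds: for each trial P_O2 the CO content is
    monotone in P_CO, and with that inner match the O2 content is monotone
    in P_O2.
    """
    o2, co = GASES["O2"], GASES["CO"]
    if c_o2 < 0 or c_co < 0:
        raise ValueError("contents must be non-negative")
    if c_o2 == 0 and c_co == 0:
        return 0.0, 0.0

    def p_co_for(p_o2: float) -> float:
        if c_co == 0.0:
            return 0.0
        f = lambda p_co: gas_content(
            p_co, o2_co_saturations(p_o2, p_co, hb)[1], co, hb) - c_co
        hi = p_co_max
        while f(hi) < 0:
            hi *= 4.0
            if hi > 1e6:
                raise ValueError("CO content exceeds blood capacity")
        return brentq(f, 0.0, hi, xtol=1e-13, rtol=1e-15)

    def res_o2(p_o2: float) -> float:
        p_co = p_co_for(p_o2)
        s_o2 = o2_co_saturations(p_o2, p_co, hb)[0]
        return gas_content(p_o2, s_o2, o2, hb) - c_o2

    if res_o2(p_o2_max) < 0:
        raise ValueError("O2 content exceeds blood capacity")
    p_o2 = brentq(res_o2, 0.0, p_o2_max, xtol=1e-11, rtol=1e-15)
    return p_o2, p_co_for(p_o2)


def co_pressure_for_hbco(hbco: float, p_o2: float,
                         hb: HemoglobinVariant) -> float:
    """CO pressure at which S_CO equals ``hbco`` for a given O2 pressure."""
    if not 0.0 <= hbco < 1.0:
        raise ValueError("HbCO fraction must be in [0, 1)")
    if hbco == 0.0:
        return 0.0
    f = lambda p_co: o2_co_saturations(p_o2, p_co, hb)[1] - hbco
    hi = 1.0
    while f(hi) < 0:
        hi *= 4.0
        if hi > 1e6:
            raise ValueError(f"HbCO={hbco} unreachable")
    return brentq(f, 0.0, hi, xtol=1e-13, rtol=1e-15)
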