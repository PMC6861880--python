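"""Steady-state maternal respiratory gas exchange.

A minimal steady-state surrogate of the maternal respiratory system:

* one alveolar compartment -- ideal-gas species balances over the alveolar
  ventilation with water-vapour-corrected inspired pressures,
* a pulmonary-capillary equilibration step -- end-capillary blood leaves at
  alveolar O2/CO2 pressures; CO equilibrates with the alveolar gas with an
  endogenous carboxyhemoglobin floor,
* a venous-admixture (shunt) mixing step that forms arterial blood from
  end-capillary and mixed-venous blood, and
* one tissue compartment with fixed O2 consumption ``vo2`` and CO2
  production ``rq * vo2`` closed by venous return at the cardiac output.

The shunt fraction is the one reconstructed parameter: it is calibrated
once (``calibrate_shunt``) so that baseline (0 ppm CO, room air) arterial
PO2 is 90 mmHg with the default pregnancy parameters; the packaged default
is that calibrated value.  The mixed-venous PO2 then lands at ~40 mmHg by
the Table-of-pregnancy mass balance alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .gases import WATER_VAPOUR_MMHG, ppm_to_mmhg
from .hemoglobin import (ADULT, BloodState, HemoglobinVariant,
                         blood_contents, invert_co2_content,
                         make_blood_state, pressures_from_contents)

__all__ = [
    "PregnancyParams",
    "Environment",
    "LungResult",
    "ConvergenceError",
    "solve_maternal_steady_state",
    "co_uptake_rate",
    "calibrate_shunt",
]

#: venous-admixture fraction giving arterial PO2 = 90.0 mmHg at baseline
#: (output of ``calibrate_shunt()`` with Table-default pregnancy parameters)
DEFAULT_SHUNT = 0.1491879


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class PregnancyParams:
    """Physiological parameters of the pregnant woman.

    Defaults are the published pregnancy values consumed by the model:
    cardiac output 7.2 L/min, blood volume 6.53 L, O2 consumption
    249 mL/min, ventilation 8.51 L/min, [Hb] 12.1 g/dL, RQ 0.83.
    """

    cardiac_output: float = 7.2      # L min-1
    blood_volume: float = 6.53       # L
    vo2: float = 249.0               # mL STPD min-1
    ventilation: float = 8.51        # L BTPS min-1 (effective alveolar)
    hb_conc: float = 12.1            # g dL-1
    rq: float = 0.83                 # dimensionless
    shunt: float = DEFAULT_SHUNT     # venous-admixture fraction
    hbco_floor: float = 0.01         # endogenous baseline HbCO fraction
    dl_co_lung: float = 30.0         # lung CO diffusing capacity, mL min-1 mmHg-1

    def __post_init__(self) -> None:
        if min(self.cardiac_output, self.blood_volume, self.vo2,
               self.ventilation, self.hb_conc, self.rq) <= 0:
            raise ValueError("pregnancy parameters must be positive")
        if not 0.0 <= self.shunt < 1.0:
            raise ValueError("shunt fraction must be in [0, 1)")
        if not 0.0 <= self.hbco_floor < 1.0:
            raise ValueError("hbco_floor must be in [0, 1)")

    @property
    def vco2(self) -> float:
        """CO2 production, mL STPD min-1."""
        return self.rq * self.vo2


@dataclass(frozen=True)
class Environment:
    """Ambient gas composition and conditions."""

    co_ppm: float = 0.0
    fio2: float = 0.2094
    fico2: float = 0.0004
    barometric_pressure: float = 760.0   # mmHg
    body_temperature: float = 310.15     # K
    ambient_temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.co_ppm < 0:
            raise ValueError("co_ppm must be non-negative")
        fco = self.co_ppm * 1e-6
        if not (0.0 <= self.fio2 <= 1.0 and 0.0 <= self.fico2 <= 1.0
                and self.fio2 + self.fico2 + fco <= 1.0):
            raise ValueError("inspired fractions must lie in [0,1] and sum <= 1")
        if self.barometric_pressure <= WATER_VAPOUR_MMHG:
            raise ValueError("barometric pressure below water vapour pressure")

    @property
    def p_insp(self) -> dict[str, float]:
        """Water-vapour-corrected inspired partial pressures, mmHg."""
        dry = self.barometric_pressure - WATER_VAPOUR_MMHG
        return {"O2": self.fio2 * dry, "CO2": self.fico2 * dry,
                "CO": ppm_to_mmhg(self.co_ppm, self.barometric_pressure)}


@dataclass
class LungResult:
    """Solved maternal steady state."""

    arterial: BloodState
    venous: BloodState
    alveolar_pressures: dict[str, float]
    #: alveolar ventilation converted to STPD, mL min-1
    ventilation_stpd: float
    #: inspired partial pressures, mmHg
    inspired_pressures: dict[str, float]
    #: net gas uptake into blood, mL STPD min-1, positive into blood
    uptake: dict[str, float]
    #: water-vapour-corrected total pressure backing the gas fractions, mmHg
    dry_pressure: float = 760.0 - WATER_VAPOUR_MMHG
    iterations: int = 0


def co_uptake_rate(alveolar_p_co: float, arterial_p_co: float,
                   dl_co_lung: float) -> float:
    """Linear alveolar-to-blood CO transfer, mL min-1 (positive into blood)."""
    if alveolar_p_co < 0 or arterial_p_co < 0:
        raise ValueError("pressures must be non-negative")
    return dl_co_lung * (alveolar_p_co - arterial_p_co)


def _alveolar_pressures(env: Environment, params: PregnancyParams,
                        v_stpd: float) -> dict[str, float]:
    """Alveolar partial pressures from per-gas ventilation balances."""
    dry = env.barometric_pressure - WATER_VAPOUR_MMHG
    p = env.p_insp
    # volumetric species balances on STPD volumes; the small inspired/expired
    # volume difference (RQ != 1) is neglected in this surrogate
    p_o2 = p["O2"] - params.vo2 / v_stpd * dry
    p_co2 = p["CO2"] + params.vco2 / v_stpd * dry
    p_co = p["CO"]  # net CO exchange ~ 0 at chronic steady state
    if p_o2 <= 0:
        raise ValueError("ventilation too low: alveolar PO2 <= 0")
    return {"O2": p_o2, "CO2": p_co2, "CO": p_co}


def solve_maternal_steady_state(
        env: Environment, params: PregnancyParams,
        hb: HemoglobinVariant = ADULT,
        tol: float = 1e-10, max_iter: int = 10_000,
        damping: float = 0.5) -> LungResult:
    """Solve the maternal lung/tissue steady state.

    Damped fixed-point iteration on the venous contents; converges when the
    relative change of all arterial/venous pressures falls below ``tol``.
    """
    q = params.cardiac_output * 1000.0  # mL min-1
    v_stpd = (params.ventilation * 1000.0
              * (273.15 / env.body_temperature)
              * ((env.barometric_pressure - WATER_VAPOUR_MMHG) / 760.0))
    alv = _alveolar_pressures(env, params, v_stpd)

    # end-capillary blood equilibrated with alveolar gas
    s_ec, c_ec = blood_contents(alv["O2"], alv["CO2"], alv["CO"], hb)

    dc = {"O2": -params.vo2 / q, "CO2": params.vco2 / q, "CO": 0.0}
    c_ve = {k: max(v + dc[k], 0.0) for k, v in c_ec.items()}
    s = params.shunt
    prev_p: dict[str, float] | None = None
    residual = float("inf")

    # endogenous CO production enters as a constant arterial content source
    # equivalent to `hbco_floor` of bound CO; smooth in the ambient CO level
    # (an exposure-independent heme-turnover source), it puts the 0-ppm
    # maternal HbCO at ~1.1x the configured offset
    c_endo_co = hb.capacity * params.hbco_floor

    for it in range(1, max_iter + 1):
        c_ar = {k: (1 - s) * c_ec[k] + s * c_ve[k] for k in c_ec}
        c_ar["CO"] += c_endo_co
        p_o2_ar, p_co_ar = pressures_from_contents(c_ar["O2"], c_ar["CO"], hb)
        p_co2_ar = invert_co2_content(c_ar["CO2"])

        c_ve_new = {k: c_ar[k] + dc[k] for k in c_ar}
        p_o2_ve, p_co_ve = pressures_from_contents(c_ve_new["O2"],
                                                   c_ve_new["CO"], hb)
        p_co2_ve = invert_co2_content(c_ve_new["CO2"])

        cur_p = {"O2a": p_o2_ar, "CO2a": p_co2_ar, "COa": p_co_ar,
                 "O2v": p_o2_ve, "CO2v": p_co2_ve, "COv": p_co_ve}
        if prev_p is not None:
            residual = max(abs(cur_p[k] - prev_p[k]) / max(abs(cur_p[k]), 1e-12)
                           for k in cur_p)
            if residual < tol:
                arterial = make_blood_state(p_o2_ar, p_co2_ar, p_co_ar, hb, q,
                                            env.body_temperature)
                # arterial contents may carry the HbCO floor override
                arterial.C = c_ar
                venous = make_blood_state(p_o2_ve, p_co2_ve, p_co_ve, hb, q,
                                          env.body_temperature)
                uptake = {"O2": q * (c_ar["O2"] - c_ve_new["O2"]),
                          "CO2": q * (c_ar["CO2"] - c_ve_new["CO2"]),
                          "CO": q * (c_ar["CO"] - c_ve_new["CO"])}
                return LungResult(
                    arterial=arterial, venous=venous,
                    alveolar_pressures=alv, ventilation_stpd=v_stpd,
                    inspired_pressures=env.p_insp, uptake=uptake,
                    dry_pressure=env.barometric_pressure - WATER_VAPOUR_MMHG,
                    iterations=it)
        prev_p = cur_p
        c_ve = {k: (1 - damping) * c_ve[k] + damping * c_ve_new[k]
                for k in c_ve}

    raise ConvergenceError("maternal lung fixed point did not converge",
                           residual)


def calibrate_shunt(target_arterial_po2: float = 90.0,
                    env: Environment | None = None,
                    params: PregnancyParams | None = None,
                    hb: HemoglobinVariant = ADULT) -> float:
    """Venous-admixture fraction reproducing the baseline arterial PO2.

    One-time calibration of the only reconstructed lung parameter; run at
    0 ppm CO with the pregnancy defaults it returns ~0.1211.
    """
    env = env or Environment()
    params = params or PregnancyParams()

    def err(shunt: float) -> float:
        res = solve_maternal_steady_state(env, replace(params, shunt=shunt), hb)
        return res.arterial.P["O2"] - target_arterial_po2

    return brentq(err, 0.0, 0.45, xtol=1e-9)
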