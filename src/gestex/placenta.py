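"""Two-compartment placental gas exchanger.

The placenta is modelled as two well-mixed compartments (maternal and
fetal blood), each at its outlet pressure.  For each gas the diffusive
transfer rate across the membrane

    V_dot = D_L * (P_maternal_venous - P_fetal_venous)

must equal the rate at which the fetal stream carries the gas away,

    flow * (C(P_fetal_venous) - C(P_fetal_arterial)).

The fetal venous pressure solving this balance is found by bisection.

Per-gas closures:

* O2 -- the fetal O2 demand is a constant ``vo2_fetal``; the transfer rate
  equals it in steady state, so the maternal-to-fetal pressure difference
  stays constant across CO exposures and the fetal *arterial* pressure is
  solved from the content balance.  ``calibrate`` fixes ``D_L(O2)`` and
  ``vo2_fetal`` once so that the 0-ppm solution is exactly
  arterial 25 mmHg / venous 28.8 mmHg (umbilical reference values).
* CO -- outer fixed-point iteration: each pass sets the fetal arterial CO
  pressure to the previous venous one and re-bisects, stopping on a
  relative pressure-change criterion; a 2% fetal carboxyhemoglobin floor
  represents the endogenous fetal CO load.
* CO2 -- solved in the fetal-to-maternal direction with a fixed fetal
  arterial (umbilical-artery) CO2 boundary.

Diffusing capacities and the umbilical flow are per kg of fetal weight;
``fetal_weight`` scales both to absolute rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.optimize import bisect

from .gases import GASES
from .hemoglobin import (FETAL, BloodState, HemoglobinVariant,
                         co_pressure_for_hbco, co2_content, gas_content,
                         make_blood_state, o2_co_saturations)
from .lung import ConvergenceError

__all__ = [
    "PlacentaParams",
    "PlacentaResult",
    "BracketingError",
    "placental_diffusion_rate",
    "fetal_uptake_rate",
    "solve_fetal_venous_pressure",
    "solve_placenta",
    "calibrate",
]

#: calibrated O2 diffusing capacity and fetal O2 demand (per kg fetus) for
#: the default 0-ppm baseline (outputs of ``calibrate()``; regenerate with it
#: after changing any upstream default)
DEFAULT_DL_O2_PER_KG = 0.0830353
DEFAULT_VO2_FETAL_PER_KG = 0.9491582


class BracketingError(ValueError):
    """The bisection bracket does not contain a sign change."""


@dataclass(frozen=True)
class PlacentaParams:
    """Placental exchanger parameters.

    Diffusing capacities ``dl`` are mL min-1 mmHg-1 kg-1 (the printed unit
    omits the mmHg-1 that the transfer law requires); ``umbilical_flow`` is
    mL min-1 kg-1 (default 66, the published umbilical value); both scale
    with ``fetal_weight``.
    """

    dl_o2: float = DEFAULT_DL_O2_PER_KG
    dl_co_ratio: float = 0.82    # CO/O2 placental diffusivity ratio
    dl_co2_ratio: float = 20.0   # CO2/O2 placental diffusivity ratio
    umbilical_flow: float = 66.0
    fetal_weight: float = 3.0            # kg
    p_f_ar_o2: float = 25.0              # baseline fetal arterial PO2, mmHg
    p_f_ar_co2: float = 55.0             # fetal arterial (umbilical-artery) PCO2
    vo2_fetal: float = DEFAULT_VO2_FETAL_PER_KG  # mL min-1 kg-1
    hbco_baseline_fetal: float = 0.02
    tol: float = 1e-6                    # bisection relative tolerance
    max_outer_iter: int = 1000

    def __post_init__(self) -> None:
        if min(self.dl_o2, self.dl_co_ratio, self.dl_co2_ratio,
               self.umbilical_flow, self.fetal_weight, self.vo2_fetal,
               self.tol) <= 0:
            raise ValueError("placental parameters must be positive")
        if not 0.0 <= self.hbco_baseline_fetal < 1.0:
            raise ValueError("fetal HbCO baseline must be in [0, 1)")

    def dl(self, gas: str) -> float:
        """Absolute diffusing capacity, mL min-1 mmHg-1."""
        base = self.dl_o2 * self.fetal_weight
        return {"O2": base, "CO": base * self.dl_co_ratio,
                "CO2": base * self.dl_co2_ratio}[gas]

    @property
    def flow(self) -> float:
        """Absolute umbilical blood flow, mL min-1."""
        return self.umbilical_flow * self.fetal_weight

    @property
    def vo2(self) -> float:
        """Absolute fetal O2 demand, mL STPD min-1."""
        return self.vo2_fetal * self.fetal_weight


@dataclass
class PlacentaResult:
    """Solved placental exchange."""

    fetal_arterial: BloodState
    fetal_venous: BloodState
    #: diffusive transfer rate per gas, mL STPD min-1, positive maternal->fetal
    transfer: dict[str, float]
    #: endogenous fetal CO production implied by a binding HbCO floor,
    #: mL STPD min-1 (0 when the diffusive equilibrium exceeds the floor)
    endogenous_co: float = 0.0
    #: per-gas residual of (diffusion law) - (fetal stream balance), with the
    #: endogenous CO source included; mL STPD min-1
    residual: dict[str, float] = None  # type: ignore[assignment]


def placental_diffusion_rate(dl: float, p_m_ve: float, p_f_ve: float) -> float:
    """Diffusive transfer D_L*(P_m,ve - P_f,ve); positive maternal->fetal."""
    if p_m_ve < 0 or p_f_ve < 0:
        raise ValueError("pressures must be non-negative")
    return dl * (p_m_ve - p_f_ve)


def fetal_uptake_rate(flow: float, c_ve: float, c_ar: float) -> float:
    """Rate at which the fetal stream gains a gas: flow*(C_ve - C_ar)."""
    if c_ve < 0 or c_ar < 0:
        raise ValueError("contents must be non-negative")
    return flow * (c_ve - c_ar)


def _fetal_content(gas: str, p: float, p_other: float,
                   hb: HemoglobinVariant) -> float:
    """Content of ``gas`` at pressure ``p``; ``p_other`` is the companion
    heme ligand pressure (P_CO for O2 and vice versa; ignored for CO2)."""
    if gas == "CO2":
        return co2_content(p)
    if gas == "O2":
        s = o2_co_saturations(p, p_other, hb)[0]
    else:
        s = o2_co_saturations(p_other, p, hb)[1]
    return gas_content(p, s, GASES[gas], hb)


def solve_fetal_venous_pressure(gas: str, p_m_ve: float, p_f_ar: float,
                                params: PlacentaParams,
                                hb_fetal: HemoglobinVariant = FETAL,
                                p_other_ar: float = 0.0,
                                p_other_ve: float = 0.0,
                                margin: float = 5.0) -> float:
    """Bisect the per-gas balance for the fetal venous pressure.

    Residual:  D_L*(P_m,ve - P) - flow*(C(P) - C(P_f,ar)).  The bracket is
    [min(P_f,ar, P_m,ve) - margin, max(...) + margin] clipped at zero.
    ``p_other_ar``/``p_other_ve`` carry the companion heme-ligand pressure
    for the competitive saturation (arterial / venous side respectively).
    """
    if p_m_ve < 0 or p_f_ar < 0:
        raise ValueError("pressures must be non-negative")
    dl, flow = params.dl(gas), params.flow
    c_ar = _fetal_content(gas, p_f_ar, p_other_ar, hb_fetal)

    def residual(p: float) -> float:
        return (placental_diffusion_rate(dl, p_m_ve, p)
                - fetal_uptake_rate(flow, _fetal_content(gas, p, p_other_ve,
                                                         hb_fetal), c_ar))

    if p_m_ve == p_f_ar and p_other_ar == p_other_ve:
        return p_f_ar  # zero gradient, zero transfer
    lo = max(min(p_f_ar, p_m_ve) - margin, 0.0)
    hi = max(p_f_ar, p_m_ve) + margin
    rlo, rhi = residual(lo), residual(hi)
    if rlo * rhi > 0:
        raise BracketingError(
            f"{gas}: no sign change in [{lo:.3f}, {hi:.3f}] mmHg "
            f"(residuals {rlo:.3e}, {rhi:.3e})")
    return bisect(residual, lo, hi, xtol=1e-10,
                  rtol=max(params.tol * 1e-4, 1e-15))


def _solve_co_fixed_point(p_m_ve_co: float, p_f_co_init: float,
                          params: PlacentaParams, hb: HemoglobinVariant,
                          p_o2_ve: float) -> float:
    """Outer iteration: fetal arterial CO pressure := previous venous one.

    The fetal compartment is well mixed at its outlet (venous) state, so
    both CO contents in the balance are evaluated on the venous-O2
    dissociation state; the fixed point is then the zero-gradient
    equilibrium with the maternal venous CO pressure.  The plain iteration
    contracts at a rate 1 - D_L/(flow*dC/dP) which is very close to 1, so
    Aitken delta-squared extrapolation is applied to successive iterates.
    """
    if p_m_ve_co == 0.0 and p_f_co_init == 0.0:
        return 0.0

    def step(p_prev: float) -> float:
        return solve_fetal_venous_pressure(
            "CO", p_m_ve_co, p_prev, params, hb,
            p_other_ar=p_o2_ve, p_other_ve=p_o2_ve)

    p0 = p_f_co_init
    for _ in range(params.max_outer_iter):
        p1 = step(p0)
        p2 = step(p1)
        d1, d2 = p1 - p0, p2 - p1
        denom = d2 - d1
        p_acc = p2 - d2 * d2 / denom if denom != 0.0 else p2
        p_acc = min(max(p_acc, 0.0), max(p_m_ve_co, p2) * 2.0 + 1e-12)
        if abs(p_acc - p0) <= params.tol * max(abs(p_acc), 1e-12):
            return p_acc
        p0 = p_acc
    raise ConvergenceError("placental CO fixed point did not converge",
                           abs(p_acc - p0))


def solve_placenta(maternal_venous: BloodState, params: PlacentaParams,
                   hb_fetal: HemoglobinVariant = FETAL) -> PlacentaResult:
    """Solve fetal arterial and venous states for all three gases.

    O2 and CO couple through the competitive binding model, so their
    closures are iterated jointly until the fetal CO pressure stabilises.
    """
    p_m = maternal_venous.P
    dl_o2, flow, vo2 = params.dl("O2"), params.flow, params.vo2
    o2_gas, co_gas = GASES["O2"], GASES["CO"]

    # constant-demand O2 closure: transfer == vo2 fixes the venous pressure
    p_fv_o2 = p_m["O2"] - vo2 / dl_o2
    if p_fv_o2 <= 0:
        raise ConvergenceError(
            "maternal venous PO2 too low to supply the fetal O2 demand",
            p_fv_o2)

    p_co = 0.0  # fetal CO pressure (venous == arterial at the fixed point)
    p_fa_o2 = params.p_f_ar_o2
    for _ in range(params.max_outer_iter):
        try:
            p_co_new = _solve_co_fixed_point(p_m["CO"], p_co, params, hb_fetal,
                                             p_o2_ve=p_fv_o2)
        except ConvergenceError as err:
            raise ConvergenceError(f"CO: {err}", err.residual) from err
        # endogenous fetal HbCO floor, referenced to venous blood
        p_floor = co_pressure_for_hbco(params.hbco_baseline_fetal, p_fv_o2,
                                       hb_fetal)
        p_co_new = max(p_co_new, p_floor)

        # fetal arterial O2 from the content balance at fixed demand
        s_fv = o2_co_saturations(p_fv_o2, p_co_new, hb_fetal)
        c_fv_o2 = gas_content(p_fv_o2, s_fv[0], o2_gas, hb_fetal)
        c_fa_o2 = c_fv_o2 - vo2 / flow
        if c_fa_o2 <= 0:
            raise ConvergenceError("fetal arterial O2 content exhausted",
                                   c_fa_o2)

        def res_ar(p: float) -> float:
            s = o2_co_saturations(p, p_co_new, hb_fetal)[0]
            return gas_content(p, s, o2_gas, hb_fetal) - c_fa_o2

        p_fa_o2 = bisect(res_ar, 0.0, p_fv_o2, xtol=1e-10)
        if abs(p_co_new - p_co) <= params.tol * max(p_co_new, 1e-12):
            p_co = p_co_new
            break
        p_co = p_co_new
    else:
        raise ConvergenceError("O2/CO placental coupling did not converge",
                               abs(p_co_new - p_co))

    # CO2: fetal -> maternal, fixed umbilical-artery boundary
    p_fv_co2 = solve_fetal_venous_pressure("CO2", p_m["CO2"],
                                           params.p_f_ar_co2, params, hb_fetal)

    fetal_venous = make_blood_state(p_fv_o2, p_fv_co2, p_co, hb_fetal, flow,
                                    maternal_venous.T)
    fetal_arterial = make_blood_state(p_fa_o2, params.p_f_ar_co2, p_co,
                                      hb_fetal, flow, maternal_venous.T)
    transfer = {g: placental_diffusion_rate(params.dl(g), p_m[g],
                                            fetal_venous.P[g])
                for g in ("O2", "CO2", "CO")}
    # when the HbCO floor binds, the implied endogenous fetal CO production
    # closes the CO balance (the floor is above the diffusive equilibrium)
    endogenous_co = max(0.0, -transfer["CO"])

    # balance residuals: diffusion law vs fetal stream gain (well-mixed
    # compartment, venous dissociation state), endogenous source included;
    # the well-mixed fetal CO gain is identically zero at the fixed point
    res = {
        "O2": transfer["O2"] - flow * (c_fv_o2 - c_fa_o2),
        "CO2": transfer["CO2"] - fetal_uptake_rate(
            flow, co2_content(p_fv_co2), co2_content(params.p_f_ar_co2)),
        "CO": transfer["CO"] + endogenous_co,
    }
    return PlacentaResult(fetal_arterial=fetal_arterial,
                          fetal_venous=fetal_venous, transfer=transfer,
                          endogenous_co=endogenous_co, residual=res)


def calibrate(maternal_venous: BloodState,
              params: PlacentaParams | None = None,
              hb_fetal: HemoglobinVariant = FETAL,
              target_p_f_ve_o2: float = 28.8) -> PlacentaParams:
    """One-time calibration of D_L(O2) and the fetal O2 demand.

    Given the 0-ppm maternal venous state, fixes ``vo2_fetal`` so the
    fetal stream spans exactly arterial ``p_f_ar_o2`` (25 mmHg) to venous
    ``target_p_f_ve_o2`` (28.8 mmHg, the umbilical reference), and
    ``dl_o2`` so the diffusive transfer matches that demand.  Returns a new
    parameter set; fully reproducible from Table defaults.
    """
    params = params or PlacentaParams()
    if maternal_venous.P["O2"] <= target_p_f_ve_o2:
        raise ValueError("maternal venous PO2 must exceed the fetal target")
    # fetal CO floor at baseline (2% HbCO) enters the contents
    p_co = co_pressure_for_hbco(params.hbco_baseline_fetal,
                                target_p_f_ve_o2, hb_fetal)
    c_ve = _fetal_content("O2", target_p_f_ve_o2, p_co, hb_fetal)
    c_ar = _fetal_content("O2", params.p_f_ar_o2, p_co, hb_fetal)
    vo2_abs = fetal_uptake_rate(params.flow, c_ve, c_ar)
    dl_abs = vo2_abs / (maternal_venous.P["O2"] - target_p_f_ve_o2)
    return replace(params,
                   dl_o2=dl_abs / params.fetal_weight,
                   vo2_fetal=vo2_abs / params.fetal_weight)
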