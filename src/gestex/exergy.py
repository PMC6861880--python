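"""Exergy and entropy-generation analyses of the lung and the placenta.

Three analyses are applied to each organ:

* **Model 1** -- every gas (in air or dissolved in blood) is treated as an
  ideal gas at its partial pressure; stream exergies follow
  ``b = cp (T - T0 - T0 ln(T/T0)) + R T0 ln(P/P0)`` and the organ balance
  yields a destroyed exergy rate and (only here, where every stream has an
  absolute exergy) an exergy efficiency.
* **Model 2** -- O2 and CO are also carried bound to hemoglobin; the blood
  terms are replaced by the reaction exergy of the binding steps,
  ``dB_Hb = -dG_Hb`` per mole bound, with cumulative four-step Gibbs
  energies (fetal values from equilibrium constants of fetal Hb; the adult
  table is a documented synthetic stand-in).  A bicarbonate term covers
  CO2.
* **Model 3** -- only the entropy generated by spontaneous diffusion down
  the partial-pressure gradients, sigma = sum_i m_dot_i R_i ln(P_hi/P_lo),
  converted by Gouy-Stodola: B_d = T0 * sigma.  Each per-gas term is
  oriented along the actual flux, so sigma >= 0 by construction (the
  printed per-gas forms carry an overall sign typo absorbed here).

Absolute Model 1/2 values depend on metabolic auxiliaries (B_M, W_resp,
Q_M, organ temperatures) that are not fixed by the transport model; they
are configurable with documented literature-magnitude defaults, so trends
across CO exposure are meaningful while absolute values are
configuration-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .gases import GASES, MMHG_PER_ATM, GasSpecies, volume_stpd_to_mass_rate
from .hemoglobin import HB_MOLAR_MASS, BloodState, HemoglobinVariant
from .lung import LungResult
from .placenta import PlacentaResult

__all__ = [
    "ReferenceState",
    "OrganAuxiliaries",
    "GibbsTable",
    "ExergyReport",
    "GIBBS_FETAL",
    "GIBBS_ADULT",
    "LUNG_AUX",
    "PLACENTA_AUX",
    "stream_exergy",
    "blood_stream_exergy",
    "hb_reaction_exergy",
    "lung_model1",
    "lung_model2",
    "lung_model3",
    "placenta_model1",
    "placenta_model2",
    "placenta_model3",
]


@dataclass(frozen=True)
class ReferenceState:
    """Dead-state environment: T0 = 25 degC, P0 = 1 atm."""

    T0: float = 298.15
    P0: float = MMHG_PER_ATM

    def __post_init__(self) -> None:
        if self.T0 <= 0 or self.P0 <= 0:
            raise ValueError("reference state must be positive")


@dataclass(frozen=True)
class OrganAuxiliaries:
    """Metabolic auxiliaries of one organ (all in W, temperatures in K)."""

    B_M: float       # metabolic exergy rate
    Q_M: float       # heat transfer to the surroundings
    T_organ: float
    W_resp: float = 0.0  # respiratory-muscle power (lung only)

    def __post_init__(self) -> None:
        for v in (self.B_M, self.Q_M, self.T_organ, self.W_resp):
            if not math.isfinite(v):
                raise ValueError("auxiliary rates must be finite")
        if self.T_organ <= 0:
            raise ValueError("organ temperature must be positive")

    def heat_exergy(self, ref: ReferenceState) -> float:
        """Carnot exergy of the heat loss, W."""
        return self.Q_M * (1.0 - ref.T0 / self.T_organ)


#: lung auxiliaries: lung-tissue metabolism ~2 W (VO2 of the lung itself),
#: near-equal heat rejection, quiet-breathing respiratory power ~0.7 W
LUNG_AUX = OrganAuxiliaries(B_M=1.92, Q_M=1.84, T_organ=310.15, W_resp=0.72)
#: placental auxiliaries: high organ metabolism (~10 mL O2/min => ~3.6 W)
PLACENTA_AUX = OrganAuxiliaries(B_M=3.6, Q_M=3.4, T_organ=310.15)


@dataclass(frozen=True)
class GibbsTable:
    """Cumulative standard Gibbs energies of the four Hb binding steps.

    ``co`` and ``o2`` each hold the cumulative values (kJ per mol Hb) for
    1..4 bound ligands; cooperativity makes each column strictly
    decreasing.
    """

    co: tuple[float, float, float, float]
    o2: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for col in (self.co, self.o2):
            if len(col) != 4 or any(b >= a for a, b in zip(col, col[1:])):
                raise ValueError("Gibbs columns must be strictly decreasing "
                                 "4-step sequences")

    def dg4(self, gas: str) -> float:
        """Cumulative Gibbs energy of full (4-site) loading, kJ/mol Hb."""
        return {"CO": self.co[3], "O2": self.o2[3]}[gas]

    def cumulative(self, gas: str, sites: float) -> float:
        """Cumulative Gibbs energy at a fractional site occupancy, kJ/mol Hb.

        Piecewise-linear through (0, 0) and the four tabulated steps, so a
        partial loading is charged with the per-step energies it traverses.
        Each ligand is evaluated on its own binding curve (mixed O2/CO
        occupancy is not cross-coupled here).
        """
        if not 0.0 <= sites <= 4.0 + 1e-12:
            raise ValueError("site occupancy must be in [0, 4]")
        col = (0.0,) + {"CO": self.co, "O2": self.o2}[gas]
        sites = min(sites, 4.0)
        k = min(int(sites), 3)
        return col[k] + (sites - k) * (col[k + 1] - col[k])


#: fetal hemoglobin, from equilibrium constants at biological conditions
GIBBS_FETAL = GibbsTable(co=(-150.09, -301.04, -464.96, -634.09),
                         o2=(-18.34, -37.41, -59.86, -95.89))

# Synthetic stand-in for the (unpublished here) adult table: each fetal
# step is shifted by RT ln(P50_adult/P50_fetal) per bound site at 310.15 K
# (+0.868 kJ/mol/site), expressing the lower O2 affinity of adult Hb.
_SHIFT = 8.314462618e-3 * 310.15 * math.log(26.6 / 19.0)
GIBBS_ADULT = GibbsTable(
    co=tuple(g + (i + 1) * _SHIFT for i, g in enumerate(GIBBS_FETAL.co)),
    o2=tuple(g + (i + 1) * _SHIFT for i, g in enumerate(GIBBS_FETAL.o2)),
)

#: effective Gibbs energy of the CO2/bicarbonate partition at physiological
#: pH (RT ln of the HCO3-/CO2 ratio ~ 20), kJ per mol CO2; configurable
DELTA_G_CO2 = -7.7


@dataclass
class ExergyReport:
    """Result of one exergy analysis of one organ."""

    model: int
    organ: str
    B_d: float                       # destroyed exergy rate, W
    eta: float | None = None         # exergy efficiency (Model 1 only)
    sigma: float | None = None       # entropy generation, W/K (Model 3)
    per_gas: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def stream_exergy(gas: GasSpecies, t: float, p_i: float,
                  ref: ReferenceState) -> float:
    """Specific flow exergy of an ideal-gas stream, kJ/kg.

    ``b = cp (T - T0 - T0 ln(T/T0)) + R T0 ln(P_i/P0)``.  Zero pressure is
    a domain error (the logarithm diverges).
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    if p_i <= 0:
        raise ValueError(
            f"{gas.name}: stream exergy undefined at zero partial pressure")
    thermal = gas.cp * (t - ref.T0 - ref.T0 * math.log(t / ref.T0))
    chemical = gas.R * ref.T0 * math.log(p_i / ref.P0)
    return thermal + chemical


def blood_stream_exergy(state: BloodState, ref: ReferenceState) -> float:
    """Exergy rate carried by the gases of one blood stream, W.

    Each gas is treated as an ideal gas at its blood partial pressure
    (Model 1 convention); mass rate from the STPD content times flow.
    """
    total = 0.0
    for name, gas in GASES.items():
        p = state.P[name]
        c = state.C[name]
        if c <= 0 or p <= 0:
            continue
        m_dot = volume_stpd_to_mass_rate(state.flow * c, gas)
        total += m_dot * stream_exergy(gas, state.T, p, ref) * 1e3
    return total


def _air_stream_exergy(volumes_stpd: dict[str, float],
                       pressures: dict[str, float], t: float,
                       ref: ReferenceState) -> float:
    """Exergy rate of the tracked gases in an air stream, W."""
    total = 0.0
    for name, gas in GASES.items():
        v, p = volumes_stpd[name], pressures[name]
        if v <= 0 or p <= 0:
            continue
        total += (volume_stpd_to_mass_rate(v, gas)
                  * stream_exergy(gas, t, p, ref) * 1e3)
    return total


def hb_reaction_exergy(hb_mol_per_min: float, s_from: float, s_to: float,
                       gibbs: GibbsTable, gas: str) -> float:
    """Reaction exergy rate of a saturation change ``s_from -> s_to``, W.

    ``dB_Hb = -dG_Hb``: the Hb stream moving from occupancy ``4*s_from``
    to ``4*s_to`` traverses the cumulative binding curve, gaining
    ``-(G(4 s_to) - G(4 s_from))`` per mole of Hb.  Additive over
    consecutive changes and antisymmetric under swapping the two states.
    """
    dg = gibbs.cumulative(gas, 4.0 * s_to) - gibbs.cumulative(gas, 4.0 * s_from)
    return -dg * hb_mol_per_min * 1e3 / 60.0


def _hb_flow_mol_min(state: BloodState, hb: HemoglobinVariant) -> float:
    return state.flow * hb.hb_conc_g_ml / HB_MOLAR_MASS


def _co2_reaction_exergy(mol_co2_per_min: float,
                         delta_g_co2: float = DELTA_G_CO2) -> float:
    """Bicarbonate-reaction exergy of a CO2 molar exchange rate, W."""
    return -delta_g_co2 * mol_co2_per_min * 1e3 / 60.0


def _lung_air_terms(lung: LungResult, env_temperature: float,
                    ref: ReferenceState) -> tuple[float, float]:
    """(inspired, expired) air exergy rates of the tracked gases, W."""
    v, dry = lung.ventilation_stpd, lung.dry_pressure
    p_ins = lung.inspired_pressures
    p_alv = lung.alveolar_pressures
    vol_ins = {g: v * p_ins[g] / dry for g in GASES}
    vol_exp = {g: v * p_alv[g] / dry for g in GASES}
    b_ins = _air_stream_exergy(vol_ins, p_ins, env_temperature, ref)
    b_exp = _air_stream_exergy(vol_exp, p_alv, lung.arterial.T, ref)
    return b_ins, b_exp


def lung_model1(lung: LungResult, aux: OrganAuxiliaries = LUNG_AUX,
                ref: ReferenceState = ReferenceState(),
                env_temperature: float | None = None) -> ExergyReport:
    """Destroyed exergy rate and efficiency with all gases dissolved."""
    t_env = ref.T0 if env_temperature is None else env_temperature
    b_ins, b_exp = _lung_air_terms(lung, t_env, ref)
    b_ar = blood_stream_exergy(lung.arterial, ref)
    b_ve = blood_stream_exergy(lung.venous, ref)
    q_x = aux.heat_exergy(ref)

    b_d = aux.B_M + b_ve + b_ins + aux.W_resp - b_ar - b_exp - q_x
    num = b_ar + b_exp + q_x
    den = aux.B_M + aux.W_resp + b_ve + b_ins
    report = ExergyReport(model=1, organ="lung", B_d=b_d,
                          per_gas={"B_ins": b_ins, "B_exp": b_exp,
                                   "B_ar": b_ar, "B_ve": b_ve})
    if num == 0.0 and den == 0.0:
        report.eta = None
        report.warnings.append("efficiency undefined (0/0) at reference state")
    else:
        report.eta = num / den
        if not 0.0 < report.eta < 1.0:
            report.warnings.append(
                f"efficiency {report.eta:.4f} outside (0,1): single-pressure "
                "reference makes stream exergies negative")
    return report


def lung_model2(lung: LungResult, hb: HemoglobinVariant,
                aux: OrganAuxiliaries = LUNG_AUX,
                gibbs: GibbsTable = GIBBS_ADULT,
                ref: ReferenceState = ReferenceState(),
                delta_g_co2: float = DELTA_G_CO2,
                env_temperature: float | None = None) -> ExergyReport:
    """Destroyed exergy with O2/CO carried bound to hemoglobin."""
    if gibbs is None:
        raise ValueError("lung_model2 requires a Gibbs table")
    t_env = ref.T0 if env_temperature is None else env_temperature
    b_ins, b_exp = _lung_air_terms(lung, t_env, ref)
    q_x = aux.heat_exergy(ref)

    n_hb = _hb_flow_mol_min(lung.arterial, hb)
    db_o2 = hb_reaction_exergy(n_hb, lung.venous.S["O2"],
                               lung.arterial.S["O2"], gibbs, "O2")
    db_co = hb_reaction_exergy(n_hb, lung.venous.S["CO"],
                               lung.arterial.S["CO"], gibbs, "CO")
    # molar CO2 change along the flow (outlet arterial minus inlet venous;
    # negative: the blood unloads CO2 in the lung)
    mol_co2 = (lung.arterial.flow
               * (lung.arterial.C["CO2"] - lung.venous.C["CO2"])
               / 22_413.96)
    db_co2 = _co2_reaction_exergy(mol_co2, delta_g_co2)
    delta_b_reaction = db_co2 + db_co + db_o2

    b_d = (aux.B_M + b_ins + aux.W_resp - b_exp - q_x - delta_b_reaction)
    return ExergyReport(model=2, organ="lung", B_d=b_d,
                        per_gas={"dB_Hb_O2": db_o2, "dB_Hb_CO": db_co,
                                 "dB_CO2": db_co2,
                                 "dB_reaction": delta_b_reaction})


def _diffusion_entropy_term(flux_stpd_ml_min: float, gas: GasSpecies,
                            p_from: float, p_to: float) -> float:
    """Entropy generated by one gas diffusing down its gradient, W/K.

    ``m_dot R ln(P_from/P_to)`` with the flux signed along from->to, so the
    product is non-negative whenever the flux runs down the gradient.
    """
    if flux_stpd_ml_min == 0.0:
        return 0.0
    if p_from <= 0 or p_to <= 0:
        raise ValueError(f"{gas.name}: zero pressure in entropy term")
    m_dot = volume_stpd_to_mass_rate(flux_stpd_ml_min, gas)
    return m_dot * gas.R * math.log(p_from / p_to) * 1e3


def lung_model3(lung: LungResult,
                ref: ReferenceState = ReferenceState()) -> ExergyReport:
    """Entropy generation of alveolar-blood diffusion; B_d = T0 * sigma."""
    per_gas = {}
    for name, gas in GASES.items():
        flux = lung.uptake[name]  # positive into blood (alveolus -> blood)
        per_gas[name] = _diffusion_entropy_term(
            flux, gas, lung.alveolar_pressures[name], lung.arterial.P[name])
    sigma = sum(per_gas.values())
    return ExergyReport(model=3, organ="lung", B_d=ref.T0 * sigma,
                        sigma=sigma, per_gas=per_gas)


def placenta_model1(maternal_arterial: BloodState,
                    maternal_venous: BloodState,
                    placenta: PlacentaResult,
                    aux: OrganAuxiliaries = PLACENTA_AUX,
                    ref: ReferenceState = ReferenceState()) -> ExergyReport:
    """Placental destroyed exergy and efficiency, all gases dissolved."""
    b_ar_m = blood_stream_exergy(maternal_arterial, ref)
    b_ve_m = blood_stream_exergy(maternal_venous, ref)
    b_ar_f = blood_stream_exergy(placenta.fetal_arterial, ref)
    b_ve_f = blood_stream_exergy(placenta.fetal_venous, ref)
    q_x = aux.heat_exergy(ref)

    b_d = b_ar_m + b_ar_f + aux.B_M - b_ve_m - b_ve_f - q_x
    num = b_ve_m + b_ve_f + q_x
    den = aux.B_M + b_ar_m + b_ar_f
    report = ExergyReport(model=1, organ="placenta", B_d=b_d,
                          per_gas={"B_ar_m": b_ar_m, "B_ve_m": b_ve_m,
                                   "B_ar_f": b_ar_f, "B_ve_f": b_ve_f})
    if num == 0.0 and den == 0.0:
        report.eta = None
        report.warnings.append("efficiency undefined (0/0) at reference state")
    else:
        report.eta = num / den
        if not 0.0 < report.eta < 1.0:
            report.warnings.append(
                f"efficiency {report.eta:.4f} outside (0,1): single-pressure "
                "reference makes stream exergies negative")
    return report


def placenta_model2(maternal_arterial: BloodState,
                    maternal_venous: BloodState,
                    placenta: PlacentaResult,
                    hb_maternal: HemoglobinVariant,
                    hb_fetal: HemoglobinVariant,
                    aux: OrganAuxiliaries = PLACENTA_AUX,
                    gibbs_fetal: GibbsTable = GIBBS_FETAL,
                    gibbs_adult: GibbsTable = GIBBS_ADULT,
                    ref: ReferenceState = ReferenceState()) -> ExergyReport:
    """Placental destroyed exergy with Hb-bound O2 and CO reaction terms."""
    if gibbs_fetal is None or gibbs_adult is None:
        raise ValueError("placenta_model2 requires both Gibbs tables")
    base = placenta_model1(maternal_arterial, maternal_venous, placenta,
                           aux, ref)
    n_hb_m = _hb_flow_mol_min(maternal_arterial, hb_maternal)
    n_hb_f = _hb_flow_mol_min(placenta.fetal_venous, hb_fetal)
    # per-stream saturation change along the flow (outlet - inlet)
    terms = {
        "dB_O2_maternal": hb_reaction_exergy(
            n_hb_m, maternal_arterial.S["O2"], maternal_venous.S["O2"],
            gibbs_adult, "O2"),
        "dB_O2_fetal": hb_reaction_exergy(
            n_hb_f, placenta.fetal_arterial.S["O2"],
            placenta.fetal_venous.S["O2"], gibbs_fetal, "O2"),
        "dB_CO_maternal": hb_reaction_exergy(
            n_hb_m, maternal_arterial.S["CO"], maternal_venous.S["CO"],
            gibbs_adult, "CO"),
        "dB_CO_fetal": hb_reaction_exergy(
            n_hb_f, placenta.fetal_arterial.S["CO"],
            placenta.fetal_venous.S["CO"], gibbs_fetal, "CO"),
    }
    delta_b = sum(terms.values())
    b_d = base.B_d + delta_b
    terms["dB_reaction"] = delta_b
    return ExergyReport(model=2, organ="placenta", B_d=b_d, per_gas=terms)


def placenta_model3(maternal_venous: BloodState, placenta: PlacentaResult,
                    ref: ReferenceState = ReferenceState()) -> ExergyReport:
    """Entropy generation of trans-placental diffusion; B_d = T0 * sigma.

    Per-gas terms use the maternal-venous vs fetal-venous pressure ratio
    and the transferred mass rate, oriented maternal -> fetal; because the
    diffusive flux carries the sign of the same gradient, every term is
    non-negative.
    """
    per_gas = {}
    for name, gas in GASES.items():
        flux = placenta.transfer[name]  # positive maternal -> fetal
        p_m, p_f = maternal_venous.P[name], placenta.fetal_venous.P[name]
        if flux != 0.0 and p_m == p_f:
            per_gas[name] = 0.0
            continue
        per_gas[name] = _diffusion_entropy_term(flux, gas, p_m, p_f)
    sigma = sum(per_gas.values())
    return ExergyReport(model=3, organ="placenta", B_d=ref.T0 * sigma,
                        sigma=sigma, per_gas=per_gas)
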