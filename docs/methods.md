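# Methods

## Scope and structure

`gestex` couples three steady-state submodels — maternal lung, placental
exchanger, exergy analyses — into a deterministic chain driven by one
exposure variable, the ambient CO mole fraction in ppm. No transient
(washin/washout) kinetics are modelled: every result is the chronic
steady state for a constant exposure.

## Blood gas layer (`gestex.hemoglobin`)

Competitive O2/CO binding uses a Hill curve in the effective ligand
pressure `P_eff = P_O2 + M·P_CO`, partitioned between the ligands in
proportion `P_O2 : M·P_CO`. This satisfies the Haldane relation
`S_CO/S_O2 = M·P_CO/P_O2` identically (it is the defining constraint of
the model) and reduces to the plain Hill curve without CO.

| parameter | default | unit | why |
|---|---|---|---|
| adult P50 | 26.6 | mmHg | standard adult oxyhemoglobin half-saturation |
| fetal P50 | 19.0 | mmHg | fetal Hb's higher O2 affinity |
| Hill n | 2.7 | – | standard cooperativity for both variants |
| M (Haldane) | 218 | – | CO/O2 affinity ratio, inside the 200–300 band |
| N | 1.34 | mL/g | Hüfner-type carrying capacity |
| [Hb] maternal / fetal | 12.1 / 14.5 | g/dL | pregnancy / umbilical values |
| α (O2, CO2, CO) | 3.0e-5, 6.7e-4, 2.4e-5 | mL·mL⁻¹·mmHg⁻¹ | physical solubilities |

Pregnancy-induced 2,3-DPG right-shift of the curve and Bohr
(temperature/pH) corrections to P50 are deliberately out of scope.

CO2 content uses the power law `C = 0.0821·P^0.455` mL/mL — a monotone,
concave single-expression fit to standard whole-blood CO2 dissociation
data (0.44 mL/mL at 40 mmHg). Both coefficients are exposed; swapping in
another curve requires no other change. CO2 never competes for heme sites
here (carbamino transport is folded into the empirical curve).

## Maternal lung (`gestex.lung`)

A minimal steady-state surrogate with one reconstructed parameter:

1. **Alveolar balances** (STPD volumes, water-vapour-corrected inspired
   pressures, 47 mmHg at 37 °C): `P_A,O2 = P_I,O2 − V̇O2·(P_dry)/V̇_A`,
   `P_A,CO2 = P_I,CO2 + RQ·V̇O2·(P_dry)/V̇_A`, `P_A,CO = P_I,CO` (net CO
   exchange is ~0 at the chronic steady state). The printed ventilation
   (8.51 L/min BTPS) is treated as effective alveolar ventilation; the
   small inspired/expired volume difference (RQ ≠ 1) is neglected. This
   yields the low alveolar PCO2 (~21 mmHg) characteristic of pregnancy
   hyperventilation.
2. **End-capillary equilibration** with alveolar gas.
3. **Venous admixture**: arterial content = (1−s)·end-capillary +
   s·mixed-venous, per gas. The shunt fraction s is the one free
   parameter; `calibrate_shunt()` fixes it once so baseline arterial PO2
   is 90 mmHg (packaged default s = 0.1492). Alveolar-pressure
   equilibration alone would put arterial PO2 at ~124 mmHg, inconsistent
   with the 90/40 mmHg boundary pair the rest of the chain is built on.
4. **Tissue compartment** with fixed VO2 = 249 mL/min and
   V̇CO2 = RQ·VO2, closed by venous return at 7.2 L/min. Mixed venous PO2
   (~40 mmHg) is then a result, not an input.
5. **Endogenous CO** enters as a constant arterial content source
   equivalent to 1% HbCO (`hbco_floor`). A heme-turnover source is
   exposure-independent, so the additive form keeps every output smooth
   in ppm; a hard `max()` floor would kink each curve at the
   floor/exposure crossover. Baseline maternal HbCO settles at ~1.18%
   (the venous-admixture recycle slightly amplifies the source), and
   baseline arterial S_O2 at 95.3% — the pure-O2 curve value of 96.4% at
   90 mmHg minus the heme occupied by CO.

The solver is a damped fixed-point iteration on venous contents
(damping 0.5, relative pressure tolerance 1e-10, cap 10 000); arterial
and venous pressures are obtained by bracketed inversion of the content
laws, so the returned state satisfies the per-gas mass balances to
numerical precision.

## Placenta (`gestex.placenta`)

Two well-mixed compartments, each at its outlet pressure. Per-gas balance

    D_L · (P_m,ve − P_f,ve) = Q_umb · (C(P_f,ve) − C(P_f,ar))

solved by bisection (scipy, xtol 1e-10). Diffusing capacities and the
umbilical flow (66 mL·min⁻¹·kg⁻¹) are per kg of fetus (default 3 kg);
`D_L` carries the mmHg⁻¹ the transfer law requires.

**O2 closure.** The fetal O2 demand is a constant, so the transfer rate —
hence the maternal-to-fetal venous pressure difference — is the same at
every exposure, and the fetal *arterial* pressure adapts: the arterial
content is the venous content minus demand/flow. `calibrate()` fixes both
`vo2_fetal` (0.949 mL·min⁻¹·kg⁻¹) and `D_L(O2)`
(0.0830 mL·min⁻¹·mmHg⁻¹·kg⁻¹) once from the 0-ppm umbilical pair
(arterial 25 / venous 28.8 mmHg) and the lung model's venous PO2. Under
exposure the fetal arterial saturation falls steeply — the price of
holding the O2 supply constant.

**CO closure.** The outer fixed point (arterial CO pressure := previous
venous) is run with both contents evaluated on the outlet (venous)
dissociation state, consistent with the well-mixed compartment; its fixed
point is the zero-gradient equilibrium with maternal venous CO. Evaluated
literally on the arterial dissociation state the iteration instead runs
away to ~90% fetal HbCO, because the arterial/venous S_CO asymmetry at
equal P_CO behaves as a perpetual source — a degenerate reading, not a
physical regime. The contraction rate of the plain iteration is
`1 − D_L/(Q·dC/dP) ≈ 1 − 10⁻³`, so Aitken Δ² extrapolation is applied;
convergence uses the relative pressure-change criterion (ε = 1e-6). A 2%
fetal HbCO floor represents the endogenous fetal CO load; when it binds
(at ambient CO below ~10 ppm) the implied endogenous production closes
the CO balance and is reported as `endogenous_co`.

**CO2.** Solved fetus → mother against a fixed umbilical-artery boundary
of 55 mmHg (a literature umbilical-arterial value; the transport model
needs only a boundary, and no value is printed in the source tables),
with `D_L(CO2) = 20·D_L(O2)` and `D_L(CO) = 0.82·D_L(O2)` (standard
membrane-diffusivity ratios, both configurable).

## Exergy analyses (`gestex.exergy`)

Reference state T0 = 298.15 K, P0 = 760 mmHg for every gas. Stream
exergy per unit mass of gas *i*:
`b_i = cp_i(T − T0 − T0 ln T/T0) + R_i T0 ln(P_i/P0)`; blood gases are
carried at their partial pressures with mass rates from STPD contents ×
flow; air streams use the inspired/alveolar compositions (inspired air at
ambient = reference temperature, expired at body temperature; water
vapour and N2 are not tracked).

*Model 1* evaluates the full organ balance (metabolic exergy, breathing
work, heat exergy, four streams) and the efficiency as the ratio of
output to input stream exergies. Because every physiological partial
pressure lies far below P0, all stream exergies are **negative**, the
efficiency leaves (0, 1), and its CO-trend inverts relative to the
published direction; the report flags this as a model-inconsistency
warning rather than hiding it. Recovering positive stream exergies would
require per-gas atmospheric reference pressures, which the single-P0
reference deliberately excludes.

*Model 2* replaces the blood-stream terms by reaction exergies
`ΔB = −ΔG`. Binding Gibbs energies are cumulative four-step tables
(kJ/mol Hb); a partial saturation change is charged along the
piecewise-linear cumulative curve, so a single-step binding uses the
per-step energy. Each ligand is evaluated on its own curve (no
cross-coupled mixed-occupancy surface). The fetal table is built from
fetal-Hb equilibrium constants; the **adult table is a synthetic
stand-in** derived by shifting each fetal step by
`RT·ln(P50_adult/P50_fetal)` per bound site (+0.87 kJ/mol/site at
310 K) — the principled minimal correction for the affinity difference —
and is fully configurable. CO2 carries a per-mole bicarbonate-partition
term (−7.7 kJ/mol, ≈ RT·ln 20 for the HCO3⁻/CO2 ratio at physiological
pH). With the default auxiliaries the absolute Model-2 destruction rates
are negative; only their trends are interpretable (see limitations).

*Model 3* sums `ṁ_i R_i ln(P_source/P_sink)` over the three gases with
the flux signed along source → sink (alveolar vs arterial pressures for
the lung, maternal-venous vs fetal-venous for the placenta), so
`σ̇ ≥ 0` term by term, and `B_d = +T0 σ̇` (Gouy–Stodola; the printed
per-gas forms carry a sign typo that this orientation absorbs).

Auxiliaries (all configurable; magnitudes chosen once from organ
physiology): lung B_M = 1.92 W, Q_M = 1.84 W (lung-tissue VO2 ≈
5–6 mL/min), W_resp = 0.72 W (quiet-breathing work at the elevated
pregnancy ventilation), placenta B_M = 3.6 W, Q = 3.4 W (placental VO2
≈ 10 mL/min), organ temperatures 310.15 K. Absolute Model-1/2 values
scale with these; trend directions across the CO sweep do not.

## What a green test does and does not establish

The parameter draws of `generate_fixture_scenarios` perturb the placental
defaults by ±20% — physiological variability, not measurement noise; the
model itself is deterministic. Green trend tests establish the *sign* of
each exergy response to CO at the packaged auxiliaries, not absolute
wattages (unprinted in the source). The fetal venous saturations the
model computes (~75% at 0 ppm, ~60% at 100 ppm) follow from any standard
dissociation curve at the stated pressures; the published ~30%/~10%
levels would require an effective P50 near 39 mmHg and are not
reproducible from the stated parameters — the acceptance suite keeps
those checks red rather than bending the curve. Likewise, with a 2%
fetal floor against a ~1% maternal baseline, and a high-affinity fetal
curve at low fetal PO2, steady-state fetal HbCO exceeds maternal at
every exposure (consistent with independent fetal-physiology literature,
opposite to the published claim).

## Numerical choices

- Bracketed scalar solvers throughout (scipy `bisect`/`brentq`); content
  inversions nest two bracketed solves (CO inner, O2 outer).
- Degenerate inputs: zero pressures are valid for saturations/contents
  (S = C = 0) but domain errors for stream exergy (log divergence) —
  reported with the gas named.
- Ties/edge cases: equal boundary pressures short-circuit to
  zero-transfer fixed points; the Aitken step is clipped to the physical
  bracket.
- Tolerances: bisection xtol 1e-10 mmHg (balance residuals < 1e-6 of the
  flux scale), lung fixed point 1e-10 relative, CO outer loop ε = 1e-6.

## Known limitations

- Chronic steady state only; no Coburn–Forster–Kane washin dynamics.
- No facilitated CO diffusion; simple diffusion for all three gases.
- Maternal-side placental stream exergies use the systemic
  arterial/venous states at cardiac output (the two-compartment reading
  of "enters at 90, leaves at 40 mmHg"), not a separate uterine flow.
- Single-P0 reference makes Model-1 efficiencies leave (0, 1) and
  Model-2 absolute levels negative; both are surfaced, not corrected.
- The adult Gibbs table is synthetic (see above); absolute Model-2
  placental splits between maternal and fetal terms inherit that.
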