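# gestex

Steady-state simulation of O2, CO2 and carbon monoxide exchange in a
pregnant woman's respiratory system and across the placenta, with three
exergy / entropy-generation analyses of both organs.

Ambient CO — from traffic tunnels, faulty heaters or passive smoking (a
smoke-filled room reaches ~100 ppm) — binds hemoglobin with roughly 200–300
times the affinity of O2. In pregnancy this is doubly harmful: maternal
carboxyhemoglobin (HbCO) lowers the O2 content of the blood perfusing the
placenta, and the fetus, which already lives at low O2 pressures, is pushed
toward hypoxia. `gestex` lets physiologists and biomedical-thermodynamics
researchers sweep ambient CO from 0 to 100 ppm and quantify both the
fetal gas state and the irreversibility (destroyed exergy) of the lung and
the placenta.

## Model

**Blood gas binding.** Hemoglobin saturation follows a Hill curve extended
to competitive CO binding by the Haldane relation,

    S_CO / S_O2 = M · P_CO / P_O2,        M = 218

with total occupancy `S_tot = z/(1+z)`, `z = ((P_O2 + M·P_CO)/P50)^n`
partitioned between the two ligands (adult P50 = 26.6 mmHg, fetal
P50 = 19.0 mmHg, n = 2.7). Total content of a heme-bound gas is
`C = α·P + N·[Hb]·S`; CO2 content uses an empirical power-law dissociation
curve.

**Maternal lung.** One alveolar compartment (per-gas ventilation balances
with water-vapour-corrected inspired pressures), alveolar–capillary
equilibration, a venous-admixture (shunt) step calibrated once so the
baseline arterial PO2 is 90 mmHg, and a tissue compartment with fixed VO2
(249 mL/min) and RQ 0.83, closed at the pregnant cardiac output
(7.2 L/min). Mixed venous PO2 then lands at ~40 mmHg from the mass balance
alone.

**Placenta.** Two well-mixed compartments at their outlet pressures. For
each gas the membrane flux `V̇ = D_L (P_m,ve − P_f,ve)` must equal the
fetal stream's uptake `Q_umb (C(P_f,ve) − C(P_f,ar))`; the venous pressure
solving this balance is found by bisection. The fetal O2 demand is a
constant calibrated from the umbilical reference pair (arterial 25 mmHg /
venous 28.8 mmHg at 0 ppm), so the maternal–fetal venous O2 gap stays
constant across exposures. Fetal CO equilibrates with maternal venous CO
(with a 2% fetal HbCO floor); CO2 flows fetus → mother against a fixed
umbilical-artery boundary.

**Exergy analyses** (per organ):

1. *Dissolved ideal gases* — stream exergy
   `b = cp(T − T0 − T0 ln T/T0) + R T0 ln(P_i/P0)` with T0 = 25 °C,
   P0 = 1 atm; destroyed exergy from the organ balance, plus an exergy
   efficiency.
2. *Hemoglobin reactions* — O2/CO carried bound to Hb; reaction exergy
   `ΔB_Hb = −ΔG_Hb` from cumulative four-step binding Gibbs energies
   (fetal table from fetal-Hb equilibrium constants), plus a bicarbonate
   term for CO2.
3. *Diffusion only* — entropy generated by transport down the
   partial-pressure gradients, `σ̇ = Σ ṁ_i R_i ln(P_hi/P_lo) ≥ 0`, and
   Gouy–Stodola `B_d = T0 σ̇`.

## Worked example

```bash
gestex simulate --co-ppm 100
```

prints (abridged) the coupled state for chronic 100 ppm exposure:

```
maternal arterial : PO2 84.70 mmHg, S_O2 84.9 %, HbCO 12.2 %
fetal venous      : PO2 23.30 mmHg, S_O2 60.3 %, HbCO 17.0 %
destroyed exergy  : lung model 1 = 2.691 W, placenta model 3 = 0.0090 W
```

Reading: the mother's HbCO has climbed into the chronic-poisoning band
(5–25%), her arterial O2 saturation has fallen from 95% to 85%, and the
fetal venous PO2 has dropped from the healthy 28.8 mmHg umbilical value
into the hypoxic 20–25 mmHg window — while the maternal-to-fetal venous
PO2 gap stays fixed, because the placenta must still deliver the same
fetal O2 demand down a gradient that now sits lower on both sides.

A full sweep with every pressure, saturation, transfer rate and all six
exergy outputs:

```bash
gestex sweep --grid 0:100:5 --out sweep.csv
gestex calibrate-dl --target-po2 28.8   # re-derive D_L(O2) from scratch
```

`write_sweep_csv` / the CLI prepend a provenance block with every resolved
parameter, and repeated runs are bit-identical.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at the packaged table defaults (after running
both documented calibrations at run time): the baseline maternal arterial
PO2 and S_O2, the calibrated baseline umbilical venous PO2, and the fetal
venous PO2 and S_O2 at 0 and 100 ppm, writing one JSON object keyed by
target id.

See `docs/methods.md` for assumptions, parameter provenance, numerical
choices and known limitations.
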