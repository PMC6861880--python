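"""Sweep orchestration: run the lung -> placenta -> exergy chain across
ambient CO levels and tabulate every plotted quantity as CSV.

The model contains no randomness, so a sweep is fully determined by its
configuration; the CSV writer prepends a provenance block (all resolved
parameters) as ``#`` comment lines.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exergy import (GIBBS_ADULT, GIBBS_FETAL, LUNG_AUX, PLACENTA_AUX,
                     ExergyReport, OrganAuxiliaries, ReferenceState,
                     lung_model1, lung_model2, lung_model3, placenta_model1,
                     placenta_model2, placenta_model3)
from .hemoglobin import ADULT, FETAL, HemoglobinVariant
from .lung import (ConvergenceError, Environment, LungResult,
                   PregnancyParams, solve_maternal_steady_state)
from .placenta import PlacentaParams, PlacentaResult, solve_placenta

__all__ = [
    "SweepSpec",
    "ModelConfig",
    "ScenarioResult",
    "SCENARIO_PRESETS",
    "run_scenario",
    "run_sweep",
    "sweep_dataframe",
    "write_sweep_csv",
    "generate_fixture_scenarios",
    "load_config",
]

#: named ambient-CO scenario presets, ppm (passive smoking: a smoke-filled
#: room reaches ~100 ppm)
SCENARIO_PRESETS = {"urban_baseline": 0.0, "tunnel": 50.0,
                    "passive_smoking": 100.0}


@dataclass(frozen=True)
class SweepSpec:
    """Grid of ambient CO levels to sweep."""

    co_ppm_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 101, 5))
    output_path: str | None = None

    def __post_init__(self) -> None:
        g = self.co_ppm_grid
        if len(g) == 0 or any(x < 0 for x in g) or list(g) != sorted(g):
            raise ValueError("co_ppm_grid must be non-empty, non-negative "
                             "and sorted")

    @classmethod
    def from_preset(cls, name: str) -> "SweepSpec":
        return cls(co_ppm_grid=(SCENARIO_PRESETS[name],))


@dataclass
class ModelConfig:
    """Every tunable of the coupled model, with paper/table defaults."""

    environment: Environment = field(default_factory=Environment)
    pregnancy: PregnancyParams = field(default_factory=PregnancyParams)
    placenta: PlacentaParams = field(default_factory=PlacentaParams)
    hb_maternal: HemoglobinVariant = ADULT
    hb_fetal: HemoglobinVariant = FETAL
    lung_aux: OrganAuxiliaries = LUNG_AUX
    placenta_aux: OrganAuxiliaries = PLACENTA_AUX
    reference: ReferenceState = field(default_factory=ReferenceState)
    #: pin the maternal venous PO2 entering the placenta at 40 mmHg instead
    #: of the lung model's computed value
    pin_maternal_venous_po2: float | None = None


@dataclass
class ScenarioResult:
    co_ppm: float
    lung: LungResult
    placenta: PlacentaResult
    reports: dict[str, ExergyReport]


def run_scenario(co_ppm: float, config: ModelConfig | None = None
                 ) -> ScenarioResult:
    """Run the full chain for one ambient CO level."""
    cfg = config or ModelConfig()
    env = replace(cfg.environment, co_ppm=co_ppm)
    lung = solve_maternal_steady_state(env, cfg.pregnancy, cfg.hb_maternal)
    maternal_venous = lung.venous
    if cfg.pin_maternal_venous_po2 is not None:
        p = dict(maternal_venous.P)
        p["O2"] = cfg.pin_maternal_venous_po2
        from .hemoglobin import make_blood_state
        maternal_venous = make_blood_state(
            p["O2"], p["CO2"], p["CO"], cfg.hb_maternal,
            maternal_venous.flow, maternal_venous.T)
    plac = solve_placenta(maternal_venous, cfg.placenta, cfg.hb_fetal)
    ref = cfg.reference
    reports = {
        "lung_m1": lung_model1(lung, cfg.lung_aux, ref,
                               env.ambient_temperature),
        "lung_m2": lung_model2(lung, cfg.hb_maternal, cfg.lung_aux,
                               GIBBS_ADULT, ref,
                               env_temperature=env.ambient_temperature),
        "lung_m3": lung_model3(lung, ref),
        "plac_m1": placenta_model1(lung.arterial, maternal_venous, plac,
                                   cfg.placenta_aux, ref),
        "plac_m2": placenta_model2(lung.arterial, maternal_venous, plac,
                                   cfg.hb_maternal, cfg.hb_fetal,
                                   cfg.placenta_aux, GIBBS_FETAL,
                                   GIBBS_ADULT, ref),
        "plac_m3": placenta_model3(maternal_venous, plac, ref),
    }
    return ScenarioResult(co_ppm=co_ppm, lung=lung, placenta=plac,
                          reports=reports)


def _row(res: ScenarioResult) -> dict[str, float]:
    lung, plac, rep = res.lung, res.placenta, res.reports
    row: dict[str, float] = {"co_ppm": res.co_ppm}
    for g in ("O2", "CO2", "CO"):
        row[f"P_alv_{g}_mmHg"] = lung.alveolar_pressures[g]
        row[f"P_mat_ar_{g}_mmHg"] = lung.arterial.P[g]
        row[f"P_mat_ve_{g}_mmHg"] = lung.venous.P[g]
        row[f"P_fet_ar_{g}_mmHg"] = plac.fetal_arterial.P[g]
        row[f"P_fet_ve_{g}_mmHg"] = plac.fetal_venous.P[g]
        row[f"transfer_{g}_ml_min"] = plac.transfer[g]
    for g in ("O2", "CO"):
        row[f"S_mat_ar_{g}"] = lung.arterial.S[g]
        row[f"S_mat_ve_{g}"] = lung.venous.S[g]
        row[f"S_fet_ar_{g}"] = plac.fetal_arterial.S[g]
        row[f"S_fet_ve_{g}"] = plac.fetal_venous.S[g]
    row["Bd_lung_m1_W"] = rep["lung_m1"].B_d
    row["Bd_lung_m2_W"] = rep["lung_m2"].B_d
    row["Bd_lung_m3_W"] = rep["lung_m3"].B_d
    row["eta_lung_m1"] = rep["lung_m1"].eta
    row["sigma_lung_W_K"] = rep["lung_m3"].sigma
    row["Bd_plac_m1_W"] = rep["plac_m1"].B_d
    row["Bd_plac_m2_W"] = rep["plac_m2"].B_d
    row["Bd_plac_m3_W"] = rep["plac_m3"].B_d
    row["eta_plac_m1"] = rep["plac_m1"].eta
    row["sigma_plac_W_K"] = rep["plac_m3"].sigma
    return row


def run_sweep(spec: SweepSpec, config: ModelConfig | None = None
              ) -> tuple[pd.DataFrame, list[str]]:
    """Run every grid point; failures are recorded and the sweep continues.

    Returns the results table and a list of per-level error messages.
    """
    cfg = config or ModelConfig()
    rows, errors = [], []
    for ppm in spec.co_ppm_grid:
        try:
            rows.append(_row(run_scenario(ppm, cfg)))
        except (ConvergenceError, ValueError) as err:
            errors.append(f"co_ppm={ppm}: {err}")
    return pd.DataFrame(rows), errors


def sweep_dataframe(spec: SweepSpec | None = None,
                    config: ModelConfig | None = None) -> pd.DataFrame:
    """Convenience wrapper raising on any per-level failure."""
    df, errors = run_sweep(spec or SweepSpec(), config)
    if errors:
        raise RuntimeError("; ".join(errors))
    return df


def _provenance(cfg: ModelConfig) -> list[str]:
    lines = ["# gestex sweep -- resolved parameters"]
    for name in ("environment", "pregnancy", "placenta", "hb_maternal",
                 "hb_fetal", "lung_aux", "placenta_aux", "reference"):
        lines.append(f"# {name}: {asdict(getattr(cfg, name))}")
    lines.append(f"# pin_maternal_venous_po2: {cfg.pin_maternal_venous_po2}")
    lines.append("# units: pressures mmHg, saturations fraction, transfer "
                 "mL(STPD)/min, B_d W, sigma W/K")
    return lines


def write_sweep_csv(path: str | Path, spec: SweepSpec | None = None,
                    config: ModelConfig | None = None) -> pd.DataFrame:
    """Run a sweep and write a provenance-headed CSV; returns the table."""
    cfg = config or ModelConfig()
    df, errors = run_sweep(spec or SweepSpec(), cfg)
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for line in _provenance(cfg):
            fh.write(line + "\n")
        for err in errors:
            fh.write(f"# ERROR {err}\n")
        df.to_csv(fh, index=False, lineterminator="\n",
                  float_format="%.10g")
    return df


def generate_fixture_scenarios(seed: int, n: int = 50,
                               spread: float = 0.2) -> list[dict[str, float]]:
    """Reproducible random-but-physiological placental parameter draws.

    Each draw perturbs the table defaults by up to +/-``spread`` (20%);
    used by the bisection-vs-grid oracle property tests.
    """
    rng = np.random.default_rng(seed)
    base = {
        "dl_o2": 0.0824648,
        "umbilical_flow": 66.0,
        "hb_conc_fetal": 14.5,
        "p50_fetal": 19.0,
        "p_m_ve_o2": 40.0,
        "p_f_ar_o2": 25.0,
    }
    draws = []
    for _ in range(n):
        factors = rng.uniform(1.0 - spread, 1.0 + spread, size=len(base))
        draws.append({k: v * f for (k, v), f in zip(base.items(), factors)})
    return draws


def load_config(path: str | Path) -> ModelConfig:
    """Build a :class:`ModelConfig` from a flat YAML file.

    Top-level keys mirror the ModelConfig sections; unknown keys raise.
    Example::

        environment: {co_ppm: 50}
        pregnancy: {vo2: 260}
        placenta: {fetal_weight: 3.2}
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    cfg = ModelConfig()
    builders = {
        "environment": (Environment, "environment"),
        "pregnancy": (PregnancyParams, "pregnancy"),
        "placenta": (PlacentaParams, "placenta"),
        "hb_maternal": (HemoglobinVariant, "hb_maternal"),
        "hb_fetal": (HemoglobinVariant, "hb_fetal"),
        "lung_aux": (OrganAuxiliaries, "lung_aux"),
        "placenta_aux": (OrganAuxiliaries, "placenta_aux"),
        "reference": (ReferenceState, "reference"),
    }
    for key, val in raw.items():
        if key == "pin_maternal_venous_po2":
            cfg.pin_maternal_venous_po2 = val
            continue
        if key not in builders:
            raise ValueError(f"unknown config section {key!r}")
        cls, attr = builders[key]
        if not isinstance(val, dict):
            raise ValueError(f"config section {key!r} must be a mapping")
        setattr(cfg, attr, replace(getattr(cfg, attr), **val))
    return cfg
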