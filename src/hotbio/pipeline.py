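"""Stage orchestration: schema validation, table-level stage functions and
the end-to-end run.

All tables are header-named, UTF-8, '.'-decimal CSV; units are encoded in
column names.  Each stage is a pure DataFrame -> DataFrame function wrapping
the corresponding calculation module, and ``run_all`` chains
simulate -> rates -> budget -> energetics -> cells and writes a
machine-readable JSON report of the headline quantities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import population, radiotracer, simulate, sulfate, thermo

logger = logging.getLogger("hotbio")

__all__ = [
    "SCHEMAS",
    "validate",
    "compute_rates",
    "budget_table",
    "budget_summary",
    "energetics_table",
    "cells_table",
    "RunConfig",
    "run_all",
]

# ---------------------------------------------------------------------------
# schemas
# ---------------------------------------------------------------------------

#: column -> rule; rules: "num" any numeric, ">0", ">=0", "frac" in [0,1],
#: "text", or a tuple of allowed values
SCHEMAS: dict[str, dict[str, object]] = {
    "vials": {
        "sample_id": "text",
        "assay": ("SR", "MG", "AOM"),
        "depth_mbsf": ">=0",
        "activity_product_bq": ">=0",
        "activity_substrate_bq": ">=0",
        "medium_conc_mM": ">=0",
        "medium_vol_ml": ">0",
        "porewater_conc_mM": ">=0",
        "sediment_vol_ml": ">=0",
        "porosity": "frac",
        "alpha": ">0",
        "bulk_density_g_cm3": ">0",
        "time_d": ">0",
        "mass_g": ">0",
        "temp_C": "num",
    },
    "controls": {
        "control_type": tuple(t.value for t in radiotracer.ControlType),
        "assay": ("SR", "MG", "AOM"),
        "value": ">=0",
        "unit": "text",
    },
    "rates": {
        "sample_id": "text",
        "depth_mbsf": ">=0",
        "assay": ("SR", "MG", "AOM"),
        "rate_pmol_cm3_d": ">=0",
        "turnover_fraction": "frac",
        "censored": "num",
        "mbql": ">=0",
    },
    "profile": {
        "depth_mbsf": ">=0",
        "temp_C": "num",
        "sulfate_mM": ">=0",
        "acetate_mM": ">=0",
        "dic_mM": ">=0",
        "hs_mM": ">=0",
        "cells_per_cm3": ">=0",
        "porosity": "frac",
        "formation_factor": ">0",
        "bulk_density_g_cm3": ">0",
    },
    "species": {
        "depth_mbsf": ">=0",
        "SO4--": ">=0",
        "CH3COO-": ">=0",
        "HCO3-": ">=0",
        "HS-": ">=0",
        "CH4": ">=0",
        "H2": ">=0",
        "ph": "num",
    },
}


def validate(table: pd.DataFrame, schema_name: str) -> list[dict[str, object]]:
    """Check a table against a registered schema.

    Returns a list of violations, each naming the row (or None for a missing
    column), the column and the rule broken; empty on success.  Column order
    is irrelevant; extra columns are allowed.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(
            f"unknown schema {schema_name!r}; registered: {sorted(SCHEMAS)}"
        )
    schema = SCHEMAS[schema_name]
    diagnostics: list[dict[str, object]] = []
    for col, rule in schema.items():
        if col not in table.columns:
            diagnostics.append({"row": None, "column": col, "rule": "missing column"})
            continue
        series = table[col]
        if rule == "text":
            bad = series.isna()
            rule_name = "non-null text"
        elif isinstance(rule, tuple):
            bad = ~series.astype(str).isin(rule)
            rule_name = f"one of {rule}"
        else:
            values = pd.to_numeric(series, errors="coerce")
            if rule == "num":
                bad = values.isna()
                rule_name = "numeric"
            elif rule == ">0":
                bad = ~(values > 0)
                rule_name = "> 0"
            elif rule == ">=0":
                bad = ~(values >= 0)
                rule_name = ">= 0"
            elif rule == "frac":
                bad = ~((values >= 0) & (values <= 1))
                rule_name = "in [0, 1]"
            else:  # pragma: no cover - schema definition error
                raise ValueError(f"unknown rule {rule!r}")
        for idx in series.index[bad]:
            diagnostics.append({"row": int(idx), "column": col, "rule": rule_name})
    return diagnostics


def _require_valid(table: pd.DataFrame, schema_name: str) -> None:
    problems = validate(table, schema_name)
    if problems:
        head = "; ".join(
            f"row {p['row']}, column {p['column']!r}: {p['rule']}"
            for p in problems[:5]
        )
        raise ValueError(f"{schema_name} table failed validation: {head}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def compute_rates(
    vials: pd.DataFrame,
    controls: pd.DataFrame,
    sd_convention: Literal["sample", "population"] = "sample",
) -> pd.DataFrame:
    """Vial and control tables -> per-vial rates with MBQL censoring."""
    _require_valid(vials, "vials")
    _require_valid(controls, "controls")

    limits: dict[str, radiotracer.DetectionLimit] = {}
    for assay, group in controls.groupby("assay"):
        killed = group[group["control_type"] == "killed"]["value"]
        if len(killed) >= 2:
            limits[str(assay)] = radiotracer.mbql(
                radiotracer.ControlSeries(
                    control_type=radiotracer.ControlType.killed,
                    assay=radiotracer.Assay(str(assay)),
                    values=tuple(killed),
                ),
                sd_convention,
            )

    rows = []
    for _, row in vials.iterrows():
        pool = radiotracer.total_pool_moles(
            medium_conc=row["medium_conc_mM"] * 1e-3,
            medium_volume=row["medium_vol_ml"],
            porewater_conc=row["porewater_conc_mM"] * 1e-3,
            sediment_volume=row["sediment_vol_ml"],
            porosity=row["porosity"],
        )
        vial = radiotracer.IncubationVial(
            sample_id=str(row["sample_id"]),
            assay=radiotracer.Assay(str(row["assay"])),
            depth=float(row["depth_mbsf"]),
            activity_product=float(row["activity_product_bq"]),
            activity_substrate=float(row["activity_substrate_bq"]),
            pool_total=pool,
            bulk_density=float(row["bulk_density_g_cm3"]),
            incubation_time=float(row["time_d"]),
            sediment_mass=float(row["mass_g"]),
            fractionation_factor=float(row["alpha"]),
        )
        result = radiotracer.turnover_rate(vial)
        limit = limits.get(str(row["assay"]))
        if limit is not None:
            radiotracer.censor([result], limit)
        rows.append(
            {
                "sample_id": result.sample_id,
                "depth_mbsf": result.depth,
                "assay": result.assay.value,
                "rate_pmol_cm3_d": result.rate,
                "turnover_fraction": result.turnover_fraction,
                "censored": result.censored,
                "mbql": result.limit_used,
            }
        )
    return pd.DataFrame(rows)


def budget_table(
    profile: pd.DataFrame,
    column: sulfate.SedimentColumn,
    scenario: sulfate.DepletionScenario,
    form: sulfate.DiffusionForm = "standard",
) -> pd.DataFrame:
    """Per-depth diffusion fractions plus the scalar budget quantities."""
    _require_valid(profile, "profile")
    depths = profile["depth_mbsf"].to_numpy(dtype=float)
    frac = np.ones_like(depths)
    below = depths > column.boundary_depth
    frac[below] = sulfate.relative_concentration(
        depths[below] - column.boundary_depth, scenario.duration, column, form
    )
    tau = sulfate.depletion_time(
        scenario.initial_sulfate, column.porosity, scenario.srr
    )
    avg = sulfate.average_rate(
        scenario.observed_depletion, column.porosity, scenario.duration
    )
    corg = sulfate.corg_equivalent(
        scenario.observed_depletion,
        column.porosity,
        column.bulk_density,
        scenario.stoichiometry,
        scenario.carbon_molar_mass,
    )
    return pd.DataFrame(
        {
            "depth_mbsf": depths,
            "frac_remaining": frac,
            "pct_lowered": 100.0 * (1.0 - frac),
            "tau_days": tau,
            "avg_srr": avg,
            "corg_wt_pct": corg,
        }
    )


def budget_summary(
    column: sulfate.SedimentColumn,
    scenario: sulfate.DepletionScenario,
    depletion_low: float | None = None,
    form: sulfate.DiffusionForm = "standard",
) -> dict[str, float]:
    """The headline budget numbers as a flat dict."""
    low = scenario.observed_depletion if depletion_low is None else depletion_low
    out = {
        "tau_days": sulfate.depletion_time(
            scenario.initial_sulfate, column.porosity, scenario.srr
        ),
        "avg_srr_high": sulfate.average_rate(
            scenario.observed_depletion, column.porosity, scenario.duration
        ),
        "avg_srr_low": sulfate.average_rate(low, column.porosity, scenario.duration),
        "corg_wt_pct_high": sulfate.corg_equivalent(
            scenario.observed_depletion, column.porosity, column.bulk_density,
            scenario.stoichiometry, scenario.carbon_molar_mass,
        ),
        "corg_wt_pct_low": sulfate.corg_equivalent(
            low, column.porosity, column.bulk_density,
            scenario.stoichiometry, scenario.carbon_molar_mass,
        ),
        "tortuosity2": column.tortuosity2,
    }
    for z in (150.0, 200.0, 250.0):
        out[f"pct_lowered_{int(column.boundary_depth + z)}mbsf"] = float(
            sulfate.percent_lowering(z, scenario.duration, column, form)
        )
    return out


def energetics_table(
    species: pd.DataFrame,
    reactions: dict[str, thermo.ReactionSpec] | None = None,
    dh_params: thermo.DebyeHuckelParams | None = None,
    gradient: float = 100.0,
    surface_temp: float = 2.0,
    ionic_strength: float = 0.64,
    pressure: float = 55.8,
) -> pd.DataFrame:
    """Per-depth, per-reaction in-situ Gibbs energies from a species table.

    Concentrations of exactly zero are treated as below detection and take
    the species' detection floor (0.1 umol L-1).
    """
    _require_valid(species, "species")
    if reactions is None:
        reactions = thermo.load_reactions()
    if dh_params is None:
        dh_params = thermo.load_dh_params()
    species_params = thermo.load_species_params()

    rows = []
    conc_cols = [c for c in species.columns if c not in ("depth_mbsf", "ph")]
    for _, row in species.iterrows():
        depth = float(row["depth_mbsf"])
        temp_c = thermo.insitu_temperature(depth, gradient, surface_temp)
        state = thermo.ThermoState(
            temperature=temp_c + 273.15,
            pressure=pressure,
            ionic_strength=ionic_strength,
        )
        conc = {c: float(row[c]) for c in conc_cols}
        below = {c: conc[c] <= 0.0 for c in conc_cols}
        sp = thermo.build_species(conc, below, species_params)
        act = thermo.activities(sp, state, dh_params, ph=float(row["ph"]))
        for name, rxn in reactions.items():
            q = thermo.activity_quotient(rxn, act)
            rows.append(
                {
                    "depth_mbsf": depth,
                    "temp_C": temp_c,
                    "reaction": name,
                    "Q": q,
                    "dG_kj_mol": thermo.gibbs_energy(rxn, state, q),
                }
            )
    return pd.DataFrame(rows)


#: which packaged reaction supplies dG_R for each assay's per-cell energetics
ASSAY_REACTION = {"SR": "SR_acetate", "MG": "MG_acetate", "AOM": "AOM"}


def cells_table(
    rates: pd.DataFrame,
    profile: pd.DataFrame,
    energetics: pd.DataFrame,
    functional_fraction: float = 1.0,
    growth_yield: float = 0.01,
    recovery_correction: bool = True,
    repair_model: population.RepairCostModel | None = None,
) -> pd.DataFrame:
    """Join rates, cell counts and reaction energies into per-cell quantities.

    Each rate row is matched to the nearest profile depth for its cell count
    and to the nearest energetics depth of its assay's reaction for dG_R.
    Depths whose cell count sits below the quantification limit are flagged
    (per-cell values there are bounds, not estimates).
    """
    _require_valid(rates, "rates")
    _require_valid(profile, "profile")
    if repair_model is None:
        repair_model = population.RepairCostModel.calibrated()
    params = population.BiomassParams(growth_yield=growth_yield)
    prof = profile.sort_values("depth_mbsf").reset_index(drop=True)

    rows = []
    for _, row in rates.iterrows():
        depth = float(row["depth_mbsf"])
        idx = (prof["depth_mbsf"] - depth).abs().idxmin()
        cells = float(prof.loc[idx, "cells_per_cm3"])
        temp_c = float(prof.loc[idx, "temp_C"])
        pop = population.CellPopulation(
            abundance=cells, functional_fraction=functional_fraction
        )
        rxn_name = ASSAY_REACTION[str(row["assay"])]
        sub = energetics[energetics["reaction"] == rxn_name]
        if sub.empty:
            raise ValueError(f"no energetics rows for reaction {rxn_name!r}")
        eidx = (sub["depth_mbsf"] - depth).abs().idxmin()
        dg = float(sub.loc[eidx, "dG_kj_mol"])

        rate_pmol = float(row["rate_pmol_cm3_d"])
        rate_mol = rate_pmol * 1e-12
        cost = repair_model.cost(temp_c)
        rows.append(
            {
                "sample_id": row["sample_id"],
                "depth_mbsf": depth,
                "assay": row["assay"],
                "cells_per_cm3": cells,
                "cells_censored": pop.censored,
                "dG_kj_mol": dg,
                "cell_rate_fmol": population.cell_specific_rate(rate_pmol, pop),
                "energy_kj_cell_d": population.energy_turnover(
                    dg, rate_mol, pop.abundance
                ),
                "repair_cost_kj_cell_d": cost,
                "repair_threshold_fmol": population.threshold_cell_rate(cost, dg),
                "maintenance_rate_pmol_cm3_d": population.maintenance_rate(
                    cost, pop.abundance, dg
                )
                * 1e12,
                "t_b_days": population.biomass_turnover_time(
                    pop, rate_mol, params, recovery_correction
                )
                if rate_mol > 0
                else float("inf"),
                "specific_turnover": (
                    population.specific_turnover(
                        population.biomass_turnover_time(
                            pop, rate_mol, params, recovery_correction
                        )
                    )
                    if rate_mol > 0
                    else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of the end-to-end run (defaults = study conditions)."""

    outdir: Path = Path("hotbio_out")
    seed: int = 0
    sd_convention: Literal["sample", "population"] = "sample"
    diffusion_form: sulfate.DiffusionForm = "standard"
    functional_fraction: float = 1.0
    growth_yield: float = 0.01
    recovery_correction: bool = True
    # budget scenario (study constants)
    initial_sulfate_mm: float = 28.0
    depletion_low_mm: float = 22.0
    depletion_high_mm: float = 28.0
    measured_srr: float = 0.3  # pmol cm-3 d-1 below the activity collapse
    burial_age_yr: float = 4.0e5
    simulation: simulate.SimulationConfig | None = None

    def sim_config(self) -> simulate.SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return simulate.SimulationConfig(seed=self.seed)


def run_all(config: RunConfig | None = None) -> dict:
    """simulate -> rates -> budget -> energetics -> cells; JSON report.

    Writes every stage table plus ``report.json`` under ``config.outdir``
    and returns the report dict.
    """
    if config is None:
        config = RunConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()

    logger.info("simulating incubations and profile (seed=%d)", sim.seed)
    vials, controls = simulate.simulate_incubation(sim)
    profile, species = simulate.simulate_profile(sim)

    logger.info("computing rates for %d vials", len(vials))
    rates = compute_rates(vials, controls, config.sd_convention)

    column = sulfate.SedimentColumn(
        porosity=sim.porosity,
        bulk_density=sim.bulk_density,
        boundary_depth=sim.sulfate_boundary,
        geothermal_gradient=sim.geothermal_gradient,
        surface_temperature=sim.surface_temperature,
    )
    scenario = sulfate.DepletionScenario(
        initial_sulfate=config.initial_sulfate_mm * 1e-3,
        observed_depletion=config.depletion_high_mm * 1e-3,
        duration=config.burial_age_yr,
        srr=config.measured_srr,
    )
    budget = budget_table(profile, column, scenario, config.diffusion_form)
    summary = budget_summary(
        column, scenario, config.depletion_low_mm * 1e-3, config.diffusion_form
    )

    logger.info("computing energetics and per-cell quantities")
    energetics = energetics_table(
        species,
        gradient=sim.geothermal_gradient,
        surface_temp=sim.surface_temperature,
    )
    percell = cells_table(
        rates,
        profile,
        energetics,
        functional_fraction=config.functional_fraction,
        growth_yield=config.growth_yield,
        recovery_correction=config.recovery_correction,
    )

    for name, tab in [
        ("vials", vials),
        ("controls", controls),
        ("profile", profile),
        ("species", species),
        ("rates", rates),
        ("budget", budget),
        ("dG", energetics),
        ("percell", percell),
    ]:
        tab.to_csv(outdir / f"{name}.csv", index=False)

    mbql_by_assay = {
        a: float(g["mbql"].iloc[0])
        for a, g in rates.groupby("assay")
        if g["mbql"].notna().all()
    }
    deep = percell[percell["depth_mbsf"] > 360.0]
    report = {
        "seed": sim.seed,
        "budget": summary,
        "mbql_pmol_cm3_d": mbql_by_assay,
        "n_vials": int(len(rates)),
        "n_censored": int(rates["censored"].sum()),
        "deep_median_cell_rate_fmol": float(deep["cell_rate_fmol"].median()),
        "deep_median_repair_threshold_fmol": float(
            deep["repair_threshold_fmol"].median()
        ),
        "deep_median_t_b_days": float(deep["t_b_days"].median()),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("report written to %s", outdir / "report.json")
    return report
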