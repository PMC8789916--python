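"""In-situ Gibbs energies of the catabolic reactions.

The energy of a reaction at in-situ (non-standard) conditions is

    dG_R = dG0_insitu + R * T * ln Q

where dG0_insitu is the standard-state Gibbs energy at in-situ temperature
and pressure (consumed as input data: computing dG0(T, P) from an
equation-of-state database is deliberately outside this package) and Q the
activity quotient of products over reactants.  Activities are measured
concentrations times activity coefficients from the extended (B-dot)
Debye-Hueckel equation

    log10 gamma = -A(T) z^2 sqrt(I) / (1 + B(T) a0 sqrt(I)) + bdot * I

with ionic strength I, charge z, ion-size parameter a0 (Angstrom) and the
B-dot term; neutral species use gamma = 10^(bdot * I).  A(T) and B(T) are
interpolated from a packaged 0-150 degC table of standard literature values.

Five catabolic reactions are packaged: sulfate-dependent anaerobic methane
oxidation, sulfate reduction from acetate and from hydrogen, and
methanogenesis from acetate and from hydrogen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .units import R_KJ, celsius_to_kelvin

__all__ = [
    "Species",
    "ReactionSpec",
    "ThermoState",
    "DebyeHuckelParams",
    "insitu_temperature",
    "activity_coefficient",
    "activity_quotient",
    "gibbs_energy",
    "load_dh_params",
    "load_reactions",
    "reaction_balance",
    "SPECIES_COMPOSITION",
]

#: element composition and charge of every species used by the packaged
#: reactions (needed only for the balance check, not the energetics)
SPECIES_COMPOSITION: dict[str, dict[str, int]] = {
    "CH4": {"C": 1, "H": 4, "charge": 0},
    "SO4--": {"S": 1, "O": 4, "charge": -2},
    "HCO3-": {"H": 1, "C": 1, "O": 3, "charge": -1},
    "HS-": {"H": 1, "S": 1, "charge": -1},
    "H2O": {"H": 2, "O": 1, "charge": 0},
    "CH3COO-": {"C": 2, "H": 3, "O": 2, "charge": -1},
    "H2": {"H": 2, "charge": 0},
    "H+": {"H": 1, "charge": 1},
}


@dataclass(frozen=True)
class Species:
    """A dissolved species with its Debye-Hueckel parameters.

    ``below_detection`` marks a concentration reported below the analytical
    limit; the ``below_detection_floor`` (default 0.1 umol L-1, the
    convention used for sulfide) then replaces it.
    """

    name: str
    charge: int
    concentration: float  # mol L-1
    ion_size_parameter: float = 4.0  # Angstrom
    bdot: float | None = None  # None -> global bdot(T) for ions, 0.1 neutrals
    below_detection: bool = False
    below_detection_floor: float = 1e-7  # mol L-1

    def effective_concentration(self) -> float:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.below_detection:
            return self.below_detection_floor
        return self.concentration


@dataclass(frozen=True)
class ThermoState:
    temperature: float  # K
    pressure: float = 55.8  # MPa, median in-situ value
    ionic_strength: float = 0.64  # mol L-1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")


@dataclass(frozen=True)
class ReactionSpec:
    """Catabolic reaction: signed stoichiometry (products +, reactants -)
    and the standard-state Gibbs energy at in-situ T, P (kJ mol-1)."""

    name: str
    stoichiometry: Mapping[str, float]
    dG0_insitu: float  # kJ mol-1 at the state it was tabulated for

    def reversed(self) -> "ReactionSpec":
        return ReactionSpec(
            name=f"{self.name}_reversed",
            stoichiometry={k: -v for k, v in self.stoichiometry.items()},
            dG0_insitu=-self.dG0_insitu,
        )


# ---------------------------------------------------------------------------
# temperature model
# ---------------------------------------------------------------------------

def insitu_temperature(
    depth: float, gradient: float = 100.0, surface_temp: float = 2.0
) -> float:
    """Linear geothermal temperature (degC) at a depth (mbsf).

    Default gradient 100 degC km-1 and seafloor temperature 2 degC.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return surface_temp + gradient * depth / 1000.0


# ---------------------------------------------------------------------------
# Debye-Hueckel activity coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DebyeHuckelParams:
    """Temperature tables of the Debye-Hueckel A, B and B-dot coefficients.

    A in (kg/mol)^0.5, B in (kg/mol)^0.5 per Angstrom, bdot dimensionless;
    linearly interpolated in temperature (degC).
    """

    temperatures: tuple[float, ...]
    A: tuple[float, ...]
    B: tuple[float, ...]
    bdot: tuple[float, ...]

    def at(self, temperature_c: float) -> tuple[float, float, float]:
        t = float(temperature_c)
        lo, hi = self.temperatures[0], self.temperatures[-1]
        if not lo <= t <= hi:
            raise ValueError(
                f"temperature {t} degC outside the parameter table [{lo}, {hi}]"
            )
        a = float(np.interp(t, self.temperatures, self.A))
        b = float(np.interp(t, self.temperatures, self.B))
        bd = float(np.interp(t, self.temperatures, self.bdot))
        return a, b, bd


def load_dh_params(path=None) -> DebyeHuckelParams:
    """Load the A(T), B(T), bdot(T) table (packaged default if no path)."""
    if path is None:
        text = resources.files("hotbio.data").joinpath("dh_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    tab = raw["debye_huckel"]
    return DebyeHuckelParams(
        temperatures=tuple(tab["temperature_C"]),
        A=tuple(tab["A"]),
        B=tuple(tab["B"]),
        bdot=tuple(tab["bdot"]),
    )


#: fallback bdot for neutral species when none is supplied (salting-out term)
NEUTRAL_BDOT = 0.1


def activity_coefficient(
    species: Species,
    state: ThermoState,
    dh_params: DebyeHuckelParams | None = None,
) -> float:
    """Extended Debye-Hueckel (B-dot) activity coefficient.

    Charged species: log10 gamma = -A z^2 sqrt(I)/(1 + B a0 sqrt(I)) + bdot*I.
    Neutral species: gamma = 10^(bdot * I).  At I = 0 every gamma is 1.
    """
    if dh_params is None:
        dh_params = load_dh_params()
    temperature_c = state.temperature - 273.15
    A, B, global_bdot = dh_params.at(temperature_c)
    I = state.ionic_strength
    if species.charge == 0:
        bdot = NEUTRAL_BDOT if species.bdot is None else species.bdot
        return 10.0 ** (bdot * I)
    bdot = global_bdot if species.bdot is None else species.bdot
    sqrt_i = math.sqrt(I)
    log_gamma = (
        -A * species.charge**2 * sqrt_i / (1.0 + B * species.ion_size_parameter * sqrt_i)
        + bdot * I
    )
    return 10.0**log_gamma


def activities(
    species: Mapping[str, Species],
    state: ThermoState,
    dh_params: DebyeHuckelParams | None = None,
    ph: float | None = None,
) -> dict[str, float]:
    """Activities (gamma * concentration) for a set of species.

    Water activity is 1 by convention; if ``ph`` is given, a(H+) = 10**-pH
    directly (a pH measurement is already an activity).
    """
    if dh_params is None:
        dh_params = load_dh_params()
    out: dict[str, float] = {"H2O": 1.0}
    if ph is not None:
        out["H+"] = 10.0**-ph
    for name, sp in species.items():
        if name in out:
            continue
        gamma = activity_coefficient(sp, state, dh_params)
        out[name] = gamma * sp.effective_concentration()
    return out


# ---------------------------------------------------------------------------
# activity quotient and Gibbs energy
# ---------------------------------------------------------------------------

def activity_quotient(
    reaction: ReactionSpec, activity_map: Mapping[str, float]
) -> float:
    """Q = product of activities to their signed stoichiometric coefficients.

    Water takes activity 1 whether or not it is supplied.  A zero activity on
    the product side sends Q to 0; a zero reactant activity is undefined.
    """
    q = 1.0
    for name, nu in reaction.stoichiometry.items():
        if name == "H2O":
            continue
        if name not in activity_map:
            raise KeyError(f"no activity supplied for species {name!r}")
        a = activity_map[name]
        if a < 0:
            raise ValueError(f"negative activity for {name!r}")
        if a == 0.0:
            if nu > 0:
                return 0.0
            raise ZeroDivisionError(
                f"zero activity for reactant {name!r} makes Q undefined"
            )
        q *= a**nu
    return q


def gibbs_energy(reaction: ReactionSpec, state: ThermoState, Q: float) -> float:
    """dG_R = dG0_insitu + R T ln Q (kJ per mole of reaction turnover).

    Negative values are exergonic.
    """
    if Q <= 0:
        raise ValueError("Q must be positive")
    return reaction.dG0_insitu + R_KJ * state.temperature * math.log(Q)


# ---------------------------------------------------------------------------
# packaged reactions
# ---------------------------------------------------------------------------

def load_reactions(path=None) -> dict[str, ReactionSpec]:
    """Load reaction stoichiometries and dG0_insitu values (packaged default).

    The packaged table carries one dG0 per reaction, tabulated for the
    920 mbsf / 100 degC / 55.8 MPa reference state; edit or supply your own
    YAML for other states.
    """
    if path is None:
        text = resources.files("hotbio.data").joinpath("reactions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, ReactionSpec] = {}
    for name, spec in raw["reactions"].items():
        out[name] = ReactionSpec(
            name=name,
            stoichiometry={k: float(v) for k, v in spec["stoichiometry"].items()},
            dG0_insitu=float(spec["dG0_insitu_kj_mol"]),
        )
    return out


def load_species_params(path=None) -> dict[str, dict[str, float]]:
    """Per-species charge, ion-size and bdot parameters from the DH table."""
    if path is None:
        text = resources.files("hotbio.data").joinpath("dh_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: dict(p) for name, p in raw["species"].items()}


def build_species(
    concentrations: Mapping[str, float],
    below_detection: Mapping[str, bool] | None = None,
    species_params: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, Species]:
    """Assemble :class:`Species` objects from concentrations (mol L-1)."""
    if species_params is None:
        species_params = load_species_params()
    below_detection = below_detection or {}
    out: dict[str, Species] = {}
    for name, conc in concentrations.items():
        p = species_params.get(name)
        if p is None:
            raise KeyError(f"no Debye-Hueckel parameters for species {name!r}")
        out[name] = Species(
            name=name,
            charge=int(p["charge"]),
            concentration=float(conc),
            ion_size_parameter=float(p.get("ion_size_A", 4.0)),
            bdot=p.get("bdot"),
            below_detection=bool(below_detection.get(name, False)),
        )
    return out


def load_reference_state(path=None) -> dict:
    """The packaged deep-sediment reference state the dG0 table is anchored to.

    Returns a dict with keys ``depth_mbsf``, ``temperature_C``,
    ``pressure_MPa``, ``ionic_strength``, ``ph`` and ``concentrations_mol_l``
    (with a ``below_detection`` marker list).
    """
    if path is None:
        text = resources.files("hotbio.data").joinpath("reactions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return raw["reference_state"]


def reaction_balance(reaction: ReactionSpec) -> dict[str, float]:
    """Net element and charge balance of a reaction (all zeros if balanced)."""
    totals: dict[str, float] = {}
    for name, nu in reaction.stoichiometry.items():
        comp = SPECIES_COMPOSITION.get(name)
        if comp is None:
            raise KeyError(f"no composition registered for species {name!r}")
        for elem, count in comp.items():
            totals[elem] = totals.get(elem, 0.0) + nu * count
    return {k: v for k, v in totals.items() if abs(v) > 1e-9}
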