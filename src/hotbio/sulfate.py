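"""Diffusion plausibility model and budget arithmetic for porewater sulfate.

After rapid burial emplaces a sulfate-depleted section on top of a
sulfate-rich one, downward diffusive loss toward the depleted zone sets the
maximum abiotic lowering of sulfate below the boundary.  The half-space
solution with a zero-concentration boundary at depth ``z = 0`` (600 mbsf in
the study column) and effective diffusivity D_eff = D / theta^2 is

    C(z, t) / C0 = erf( z / (2 * sqrt(D_eff * t)) )

Tortuosity is derived from porosity and formation factor, theta^2 = phi * F.
The budget arithmetic links an assumed initial porewater sulfate
concentration c0, porosity phi and a volumetric sulfate reduction rate:
depletion time tau = c0 * phi / SRR, its rearrangement gives the mean rate
over a period, and a 2:1 organic-carbon:sulfate stoichiometry converts a
depletion to the equivalent organic carbon oxidized (wt% of dry sediment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import erf

from .units import CM3_PER_L, DAYS_PER_YEAR, PMOL_PER_MOL

__all__ = [
    "SedimentColumn",
    "DepletionScenario",
    "tortuosity",
    "relative_concentration",
    "depletion_time",
    "average_rate",
    "corg_equivalent",
]


def tortuosity(porosity: float, formation_factor: float) -> float:
    """Tortuosity-squared from porosity and formation factor: theta^2 = phi*F."""
    if not 0.0 < porosity < 1.0:
        raise ValueError("porosity must lie in (0, 1)")
    if formation_factor < 1.0:
        raise ValueError("formation factor must be >= 1")
    return porosity * formation_factor


@dataclass(frozen=True)
class SedimentColumn:
    """Physical parameters of the sediment column.

    ``diffusion_coefficient`` is the free-solution value D (m2 yr-1); the
    porewater-effective diffusivity is D / tortuosity2.  ``boundary_depth``
    is the zero-concentration boundary (mbsf) and ``bottom_depth`` the
    impermeable base used by numerical models (the closed form treats the
    column as a half space).
    """

    diffusion_coefficient: float = 0.054  # m2 yr-1
    porosity: float = 0.35
    formation_factor: float = 14.0
    bulk_density: float = 2.2  # g cm-3
    boundary_depth: float = 600.0  # mbsf
    bottom_depth: float = 1200.0  # mbsf
    geothermal_gradient: float = 100.0  # degC km-1
    surface_temperature: float = 2.0  # degC

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")
        if self.formation_factor < 1.0:
            raise ValueError("formation factor must be >= 1")
        if self.bottom_depth <= self.boundary_depth:
            raise ValueError("bottom_depth must exceed boundary_depth")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be positive")

    @property
    def tortuosity2(self) -> float:
        return tortuosity(self.porosity, self.formation_factor)

    @property
    def effective_diffusivity(self) -> float:
        """D / theta^2, m2 yr-1."""
        return self.diffusion_coefficient / self.tortuosity2


DiffusionForm = Literal["standard", "as_printed"]


def relative_concentration(
    z_below_boundary,
    t: float,
    column: SedimentColumn | None = None,
    form: DiffusionForm = "standard",
):
    """Fraction of the initial concentration remaining, C(z,t)/C0 in [0, 1].

    ``z_below_boundary`` is metres below the zero-concentration boundary
    (positive downward), ``t`` years since burial onset.  ``form="standard"``
    is the textbook half-space solution erf(z / (2*sqrt(D_eff*t))); the
    ``"as_printed"`` dialect erf(z / sqrt(2*D*t/theta^2)) is retained for
    comparison but does not reproduce the study's stated percentages.
    Accepts scalars or arrays in ``z``.
    """
    if t <= 0:
        raise ValueError("time must be positive")
    z = np.asarray(z_below_boundary, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth below boundary must be non-negative")
    if column is None:
        column = SedimentColumn()
    d_eff = column.effective_diffusivity
    if form == "standard":
        arg = z / (2.0 * np.sqrt(d_eff * t))
    elif form == "as_printed":
        arg = z / np.sqrt(2.0 * column.diffusion_coefficient * t / column.tortuosity2)
    else:
        raise ValueError(f"unknown form {form!r}")
    out = erf(arg)
    return float(out) if np.isscalar(z_below_boundary) else out


def percent_lowering(
    z_below_boundary,
    t: float,
    column: SedimentColumn | None = None,
    form: DiffusionForm = "standard",
):
    """Percent reduction of the initial concentration, 100*(1 - C/C0)."""
    rel = relative_concentration(z_below_boundary, t, column, form)
    return 100.0 * (1.0 - np.asarray(rel)) if not np.isscalar(rel) else 100.0 * (1.0 - rel)


@dataclass(frozen=True)
class DepletionScenario:
    """A sulfate depletion budget over a stated period.

    ``initial_sulfate`` and ``observed_depletion`` are porewater
    concentrations (mol L-1); ``duration`` in years; ``srr`` the volumetric
    sulfate reduction rate in pmol cm-3 d-1 of bulk sediment.
    """

    initial_sulfate: float  # mol L-1 porewater
    observed_depletion: float  # mol L-1 porewater
    duration: float  # yr
    srr: float  # pmol cm-3 d-1
    stoichiometry: float = 2.0  # mol C_org per mol SO4
    carbon_molar_mass: float = 12.0  # g mol-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.observed_depletion <= self.initial_sulfate:
            raise ValueError("observed_depletion must lie in [0, initial_sulfate]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _porewater_to_bulk_pmol_cm3(conc_mol_per_l: float, porosity: float) -> float:
    # mol L-1 porewater -> pmol per cm3 of bulk sediment
    return conc_mol_per_l / CM3_PER_L * porosity * PMOL_PER_MOL


def depletion_time(
    initial_sulfate: float, porosity: float, srr: float
) -> float:
    """Time tau (days) to deplete the porewater sulfate inventory at rate SRR.

    tau = c0 * phi / SRR with c0 in mol L-1 porewater, SRR in pmol cm-3 d-1
    of bulk sediment; the factor phi converts the porewater concentration to
    the bulk-volume inventory the rate draws on.
    """
    if srr <= 0:
        raise ValueError("srr must be positive")
    if initial_sulfate < 0:
        raise ValueError("initial sulfate must be non-negative")
    if not 0.0 < porosity <= 1.0:
        raise ValueError("porosity must lie in (0, 1]")
    return _porewater_to_bulk_pmol_cm3(initial_sulfate, porosity) / srr


def average_rate(depletion: float, porosity: float, duration_yr: float) -> float:
    """Mean volumetric rate (pmol cm-3 d-1) implied by a depletion over a period.

    The rearranged depletion-time relation: SRR = c_depleted * phi / tau.
    """
    if duration_yr <= 0:
        raise ValueError("duration must be positive")
    if depletion < 0:
        raise ValueError("depletion must be non-negative")
    if not 0.0 < porosity <= 1.0:
        raise ValueError("porosity must lie in (0, 1]")
    tau_days = duration_yr * DAYS_PER_YEAR
    return _porewater_to_bulk_pmol_cm3(depletion, porosity) / tau_days


def corg_equivalent(
    depletion: float,
    porosity: float,
    bulk_density: float,
    stoichiometry: float = 2.0,
    molar_mass: float = 12.0,
) -> float:
    """Organic carbon oxidized (wt% of bulk sediment) for a sulfate depletion.

    With oxidation-state-zero organic matter, 2 CH2O + SO4(2-) ->
    2 HCO3(-) + HS(-) + H(+): each mol of sulfate reduced oxidizes
    ``stoichiometry`` mol of organic carbon.  The depletion (mol L-1
    porewater) times porosity gives mol per cm3 bulk; times stoichiometry and
    the carbon molar mass, divided by the bulk density, gives the mass
    fraction, reported as a percent.
    """
    if depletion < 0:
        raise ValueError("depletion must be non-negative")
    if bulk_density <= 0:
        raise ValueError("bulk_density must be positive")
    if not 0.0 < porosity <= 1.0:
        raise ValueError("porosity must lie in (0, 1]")
    grams_c_per_cm3 = depletion / CM3_PER_L * porosity * stoichiometry * molar_mass
    return grams_c_per_cm3 / bulk_density * 100.0
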