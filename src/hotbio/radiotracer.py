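"""Volumetric turnover rates from radiotracer slurry incubations.

Sulfate reduction is measured with 35S-sulfate (product pool: total reduced
inorganic sulfur, TRIS), methanogenesis with 14C-DIC (product pool: 14CH4),
and AOM layouts reuse the same arithmetic with product/substrate swapped.
The volumetric rate follows the standard tracer turnover equation

    rate = A_prod / (A_prod + A_sub) * pool * alpha * rho / (t * m)

with ``pool`` the total substrate inventory of the vial (mol), ``alpha`` the
isotopic fractionation correction (1.06 for 35S sulfate reduction, 1.08 for
14C methanogenesis), ``rho`` the bulk sediment density (g cm-3), ``t`` the
incubation time (d) and ``m`` the sediment mass (g).  The result is per cm3
of wet sediment (sediment volume = m / rho) and is reported in
pmol cm-3 d-1.

Detection limits follow the killed-control convention: the minimum
biological quantification limit (MBQL) is the mean of gamma-irradiated
(killed) control rates plus three standard deviations.  Rates below the
MBQL are flagged as censored, never deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Sequence

import numpy as np

from .units import PMOL_PER_MOL

__all__ = [
    "Assay",
    "ControlType",
    "IncubationVial",
    "ControlSeries",
    "RateResult",
    "DetectionLimit",
    "DEFAULT_ALPHA",
    "turnover_rate",
    "total_pool_moles",
    "counts_to_becquerel",
    "mbql",
    "censor",
    "control_consistency",
]


class Assay(str, Enum):
    SR = "SR"
    MG = "MG"
    AOM = "AOM"


class ControlType(str, Enum):
    counter_blank = "counter_blank"
    distillation_blank = "distillation_blank"
    medium = "medium"
    drill_fluid = "drill_fluid"
    sediment = "sediment"
    killed = "killed"


#: isotopic fractionation correction factors by assay
DEFAULT_ALPHA = {Assay.SR: 1.06, Assay.MG: 1.08, Assay.AOM: 1.06}


@dataclass(frozen=True)
class IncubationVial:
    """One radiotracer slurry incubation.

    Activities are in Bq (pre-converted from counts; see
    :func:`counts_to_becquerel`), pool_total in mol, density in g cm-3,
    time in d, mass in g.
    """

    sample_id: str
    assay: Assay
    depth: float  # mbsf
    activity_product: float  # Bq (A_TRIS for SR, 14CH4-derived for MG)
    activity_substrate: float  # Bq (A_SO4 for SR, A_DIC for MG)
    pool_total: float  # mol substrate in the vial
    bulk_density: float  # g cm-3
    incubation_time: float  # d
    sediment_mass: float  # g
    fractionation_factor: float | None = None  # alpha; assay default if None
    incubation_temperature: float = float("nan")  # degC, carried through

    def __post_init__(self) -> None:
        if self.activity_product < 0 or self.activity_substrate < 0:
            raise ValueError("activities must be non-negative")
        if self.activity_product + self.activity_substrate <= 0:
            raise ValueError(
                "activity_product + activity_substrate must be positive "
                "(turnover fraction undefined)"
            )
        for name in ("pool_total", "bulk_density", "incubation_time", "sediment_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def alpha(self) -> float:
        if self.fractionation_factor is not None:
            return self.fractionation_factor
        return DEFAULT_ALPHA[Assay(self.assay)]


@dataclass(frozen=True)
class ControlSeries:
    """A labelled series of blank/control measurements for one assay.

    Values are rate-equivalents (pmol cm-3 d-1) or raw Bq, as long as one
    convention is used consistently within an assay.
    """

    control_type: ControlType
    assay: Assay
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if any(v < 0 for v in self.values):
            raise ValueError("control values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self, convention: Literal["sample", "population"] = "sample") -> float:
        ddof = 1 if convention == "sample" else 0
        return float(np.std(self.values, ddof=ddof))


@dataclass
class RateResult:
    sample_id: str
    assay: Assay
    depth: float
    rate: float  # pmol cm-3 d-1
    turnover_fraction: float
    censored: bool = False
    limit_used: float = float("nan")  # pmol cm-3 d-1

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not 0.0 <= self.turnover_fraction <= 1.0:
            raise ValueError("turnover_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DetectionLimit:
    """Minimum biological quantification limit for an assay."""

    assay: Assay
    mbql: float  # pmol cm-3 d-1 (or Bq-equivalent, matching the inputs)
    mean_killed: float
    sd_killed: float

    def __post_init__(self) -> None:
        if self.mbql < self.mean_killed:
            raise ValueError("mbql cannot be below the killed-control mean")


# ---------------------------------------------------------------------------
# rate calculation
# ---------------------------------------------------------------------------

def turnover_rate(vial: IncubationVial) -> RateResult:
    """Volumetric turnover rate (pmol cm-3 d-1 wet sediment) for one vial.

    Implements the tracer turnover equation; the fraction of label found in
    the product pool, scaled by the substrate inventory, the isotope
    fractionation correction and the sediment volume in the vial.
    """
    frac = vial.activity_product / (vial.activity_product + vial.activity_substrate)
    rate_mol = (
        frac
        * vial.pool_total
        * vial.alpha
        * vial.bulk_density
        / (vial.incubation_time * vial.sediment_mass)
    )
    return RateResult(
        sample_id=vial.sample_id,
        assay=Assay(vial.assay),
        depth=vial.depth,
        rate=rate_mol * PMOL_PER_MOL,
        turnover_fraction=frac,
    )


def total_pool_moles(
    medium_conc: float,
    medium_volume: float,
    porewater_conc: float = 0.0,
    sediment_volume: float = 0.0,
    porosity: float = 0.0,
) -> float:
    """Total substrate inventory of a vial (mol).

    The slurry combines artificial seawater medium (``medium_conc`` mol L-1 in
    ``medium_volume`` mL) with wet sediment whose porewater contributes
    ``porewater_conc`` mol L-1 over the pore volume
    ``porosity * sediment_volume`` (mL).  Tracer additions are excluded; they
    do not change the pool detectably.
    """
    if medium_conc < 0 or porewater_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if medium_volume <= 0:
        raise ValueError("medium_volume must be positive")
    if sediment_volume < 0:
        raise ValueError("sediment_volume must be non-negative")
    if not 0.0 <= porosity <= 1.0:
        raise ValueError("porosity must lie in [0, 1]")
    return (
        medium_conc * medium_volume / 1e3
        + porewater_conc * porosity * sediment_volume / 1e3
    )


def counts_to_becquerel(
    counts_per_minute: float, counting_efficiency: float = 1.0
) -> float:
    """Scintillation counts per minute -> Bq, given a counting efficiency.

    Defaults to pass-through of cpm/60 at efficiency 1; activities in this
    package are normally supplied pre-converted.
    """
    if not 0 < counting_efficiency <= 1:
        raise ValueError("counting_efficiency must lie in (0, 1]")
    if counts_per_minute < 0:
        raise ValueError("counts must be non-negative")
    return counts_per_minute / 60.0 / counting_efficiency


# ---------------------------------------------------------------------------
# detection limits and censoring
# ---------------------------------------------------------------------------

def mbql(
    killed: ControlSeries,
    sd_convention: Literal["sample", "population"] = "sample",
) -> DetectionLimit:
    """Minimum biological quantification limit: killed mean + 3 SD.

    The killed (gamma-irradiated) controls quantify abiotic tracer turnover;
    their mean plus three standard deviations bounds what biology must exceed
    to be quantifiable.  SD convention defaults to the sample (n-1) estimator.
    """
    if ControlType(killed.control_type) is not ControlType.killed:
        raise ValueError("mbql requires a killed control series")
    if killed.n < 2:
        raise ValueError("mbql needs at least two killed-control values")
    mean = killed.mean()
    sd = killed.sd(sd_convention)
    return DetectionLimit(
        assay=Assay(killed.assay), mbql=mean + 3.0 * sd, mean_killed=mean, sd_killed=sd
    )


def censor(results: Iterable[RateResult], limit: DetectionLimit) -> list[RateResult]:
    """Flag rates strictly below the MBQL as censored (values preserved)."""
    out: list[RateResult] = []
    for r in results:
        if Assay(r.assay) is not Assay(limit.assay):
            raise ValueError(
                f"assay mismatch: result {r.assay} vs limit {limit.assay}"
            )
        r.censored = r.rate < limit.mbql
        r.limit_used = limit.mbql
        out.append(r)
    return out


def control_consistency(
    series: Sequence[ControlSeries],
) -> dict[tuple[str, str], dict[str, float | bool]]:
    """Check each non-medium control against its assay's medium control.

    A series passes if its mean lies within one standard deviation of the
    medium-control mean (the medium control's own SD).  Returns a mapping
    keyed by (assay, control_type) with the means, the tolerance and a
    pass/fail flag.
    """
    medium = {
        Assay(s.assay): s
        for s in series
        if ControlType(s.control_type) is ControlType.medium
    }
    assays_present = {Assay(s.assay) for s in series}
    missing = assays_present - set(medium)
    if missing:
        raise ValueError(
            "missing medium control series for assay(s): "
            + ", ".join(sorted(a.value for a in missing))
        )
    report: dict[tuple[str, str], dict[str, float | bool]] = {}
    for s in series:
        if ControlType(s.control_type) is ControlType.medium:
            continue
        med = medium[Assay(s.assay)]
        tol = med.sd()
        delta = abs(s.mean() - med.mean())
        report[(Assay(s.assay).value, ControlType(s.control_type).value)] = {
            "mean": s.mean(),
            "medium_mean": med.mean(),
            "medium_sd": tol,
            "within_one_sd": bool(delta <= tol),
        }
    return report
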