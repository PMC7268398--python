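"""Annuitized capital costs for sequencing instruments.

A sequencer bought outright for ``K`` dollars is converted to an
*equivalent annual cost* (EAC) by dividing the acquisition price by the
annuity factor

.. math::

    a(r, n) = \\frac{1 - (1 + r)^{-n}}{r},

where ``n`` is the useful life in years and ``r`` the annual interest
rate; at ``r = 0`` the factor equals ``n`` (straight-line).  The EAC is
then spread over the number of patients the instrument serves per year,
and annual maintenance is charged as a fixed fraction of the machine's
per-patient cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "EquipmentSpec",
    "DirectCapital",
    "CapitalResult",
    "annuity_factor",
    "per_patient_capital",
    "direct_capital",
]


def annuity_factor(r: float, n: int) -> float:
    """Annuity factor ``(1 - (1+r)^-n) / r``.

    Parameters
    ----------
    r : float
        Annual interest (discount) rate as a fraction, ``r >= 0``.
    n : int
        Useful life in whole years, ``n >= 1``.

    Returns
    -------
    float
        Dimensionless factor; the zero-interest limit is ``n``.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"useful life must be a whole number of years >= 1, got {n!r}")
    if not math.isfinite(r) or r < 0:
        raise ValueError(f"interest rate must be a finite fraction >= 0, got {r!r}")
    if r == 0:
        return float(n)
    # -expm1(-n*log1p(r)) is 1-(1+r)^-n computed stably for tiny r
    return -math.expm1(-n * math.log1p(r)) / r


class EquipmentSpec(BaseModel):
    """Capital inputs for one instrument.

    ``maintenance_ratio`` expresses annual maintenance as a fraction of
    the machine's equivalent annual cost (default one half, matching the
    convention that maintenance is charged at 50% of the annuitized
    machine cost).
    """

    model_config = ConfigDict(extra="forbid")

    acquisition_price: float = Field(gt=0)
    useful_life_years: int = Field(default=5, ge=1)
    interest_rate: float = Field(default=0.03, ge=0)
    annual_patients: float = Field(gt=0)
    maintenance_ratio: float = Field(default=0.5, ge=0)


class DirectCapital(BaseModel):
    """Per-patient machine and maintenance costs given directly.

    Used when the acquisition price and throughput behind the published
    per-patient figures are not available.
    """

    model_config = ConfigDict(extra="forbid")

    machine_per_patient: float = Field(ge=0)
    maintenance_per_patient: float = Field(ge=0)


@dataclass(frozen=True)
class CapitalResult:
    """Per-patient capital allocation.

    ``annuity_factor`` and ``equivalent_annual_cost`` are ``None`` when
    the per-patient figures were supplied directly rather than derived
    from an acquisition price.
    """

    machine_per_patient: float
    maintenance_per_patient: float
    annuity_factor: Optional[float] = None
    equivalent_annual_cost: Optional[float] = None

    @property
    def capital_per_patient(self) -> float:
        return self.machine_per_patient + self.maintenance_per_patient


def per_patient_capital(
    spec: EquipmentSpec,
    method: Literal["annuity", "straight_line"] = "annuity",
) -> CapitalResult:
    """Allocate an instrument's capital cost to one patient.

    The acquisition price is annuitized over its useful life (or divided
    evenly when ``method="straight_line"``), divided by annual patient
    throughput, and maintenance is added at ``maintenance_ratio`` times
    the machine's per-patient cost.
    """
    if method == "annuity":
        factor = annuity_factor(spec.interest_rate, spec.useful_life_years)
    elif method == "straight_line":
        factor = float(spec.useful_life_years)
    else:
        raise ValueError(f"unknown amortisation method {method!r}")
    eac = spec.acquisition_price / factor
    machine = eac / spec.annual_patients
    maintenance = spec.maintenance_ratio * machine
    return CapitalResult(
        machine_per_patient=machine,
        maintenance_per_patient=maintenance,
        annuity_factor=factor,
        equivalent_annual_cost=eac,
    )


def direct_capital(direct: DirectCapital) -> CapitalResult:
    """Wrap directly-specified per-patient machine/maintenance costs."""
    return CapitalResult(
        machine_per_patient=direct.machine_per_patient,
        maintenance_per_patient=direct.maintenance_per_patient,
    )
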