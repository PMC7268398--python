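"""Seeded generator of synthetic sequencing projects.

Emulates the *cost structure* of real cancer sequencing applications —
not reads, protocols or bioinformatic outputs.  Each synthetic project
draws positive per-patient component costs from lognormal distributions
(one per workflow component), scaled by:

* a technology tier (panel / exome / genome) that multiplies library
  preparation and sequencing costs and widens the storage footprint,
* a sample design: tumour/germline pairs add a second sampling
  component and double the per-sample laboratory work,
* a rework rate: the fraction of samples that fail quality control and
  must be re-extracted, inflating extraction consumables and QC by
  ``(1 + rework_rate)`` (a 30% tumour-sample failure rate is a realistic
  upper end for fresh tumour biopsies),
* cloud storage priced per GB-month from the drawn footprint.

Generation is deterministic per ``(seed, index)`` with one named
generator per project; there is no global random state.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .capital import EquipmentSpec
from .model import Project, ResourceItem
from .pricing import DEFAULT_USD_PER_AUD, STORAGE_TIERS, StorageSpec, storage_cost_per_patient

__all__ = [
    "LognormalParams",
    "SyntheticParams",
    "generate_project",
    "generate_cohort",
    "expected_total_excl_capital",
]

TECHNOLOGIES = ("panel", "exome", "genome")


class LognormalParams(BaseModel):
    """Lognormal cost component: ``median`` AUD and log-scale ``sigma``."""

    model_config = ConfigDict(extra="forbid")

    median: float = Field(gt=0)
    sigma: float = Field(gt=0)

    @property
    def mean(self) -> float:
        return self.median * math.exp(self.sigma**2 / 2.0)


def _default_components() -> dict[str, LognormalParams]:
    # Medians chosen at the targeted-panel scale; library preparation and
    # sequencing are multiplied up for exome/genome tiers.
    return {
        "sampling": LognormalParams(median=25.0, sigma=0.2),
        "extraction_consumables": LognormalParams(median=35.0, sigma=0.4),
        "extraction_qc": LognormalParams(median=30.0, sigma=0.8),
        "extraction_labour": LognormalParams(median=10.0, sigma=1.0),
        "library_prep": LognormalParams(median=150.0, sigma=0.5),
        "library_prep_labour": LognormalParams(median=15.0, sigma=0.8),
        "sequencing": LognormalParams(median=300.0, sigma=0.5),
        "analysis_labour": LognormalParams(median=60.0, sigma=0.8),
        "software": LognormalParams(median=2.0, sigma=0.5),
        "reporting": LognormalParams(median=30.0, sigma=0.8),
    }


class SyntheticParams(BaseModel):
    """Conditions under which a synthetic cohort is generated."""

    model_config = ConfigDict(extra="forbid")

    n_projects: int = Field(default=100, ge=1)
    technology_mix: dict[str, float] = Field(
        default_factory=lambda: {"panel": 1 / 3, "exome": 1 / 3, "genome": 1 / 3}
    )
    pair_probability: float = Field(default=0.5, ge=0, le=1)
    components: dict[str, LognormalParams] = Field(default_factory=_default_components)
    tech_multiplier: dict[str, float] = Field(
        default_factory=lambda: {"panel": 1.0, "exome": 4.0, "genome": 7.0}
    )
    analysis_multiplier: dict[str, float] = Field(
        default_factory=lambda: {"panel": 1.0, "exome": 1.2, "genome": 2.0}
    )
    storage_gb_range: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "panel": (1.0, 3.0),
            "exome": (8.0, 25.0),
            "genome": (70.0, 160.0),
        }
    )
    storage_tier: str = "nearline"
    storage_months: int = Field(default=60, ge=0)
    usd_per_aud: float = Field(default=DEFAULT_USD_PER_AUD, gt=0)
    rework_rate: float = Field(default=0.0, ge=0, le=0.5)
    reporting_probability: float = Field(default=0.5, ge=0, le=1)
    n_patients_range: tuple[int, int] = (3, 800)
    equipment_acquisition: LognormalParams = Field(
        default_factory=lambda: LognormalParams(median=400_000.0, sigma=0.5)
    )
    equipment_annual_patients: LognormalParams = Field(
        default_factory=lambda: LognormalParams(median=800.0, sigma=0.7)
    )
    maintenance_ratio: float = Field(default=0.5, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticParams":
        total = sum(self.technology_mix.get(t, 0.0) for t in TECHNOLOGIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"technology_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.technology_mix.values()):
            raise ValueError("technology_mix probabilities must be non-negative")
        if self.storage_tier not in STORAGE_TIERS:
            raise ValueError(
                f"unknown storage tier {self.storage_tier!r}; "
                f"valid: {', '.join(sorted(STORAGE_TIERS))}"
            )
        for tech in TECHNOLOGIES:
            lo, hi = self.storage_gb_range[tech]
            if not (0 <= lo <= hi):
                raise ValueError(f"storage_gb_range[{tech!r}] must satisfy 0 <= lo <= hi")
        lo, hi = self.n_patients_range
        if not (1 <= lo <= hi):
            raise ValueError("n_patients_range must satisfy 1 <= lo <= hi")
        return self


def _rng_for(params: SyntheticParams, index: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, index])


def generate_project(params: SyntheticParams, index: int) -> Project:
    """Generate one synthetic project, deterministic per ``(seed, index)``."""
    if index < 0:
        raise ValueError(f"project index must be non-negative, got {index}")
    rng = _rng_for(params, index)
    comp = params.components

    def draw(name: str) -> float:
        p = comp[name]
        return float(rng.lognormal(mean=math.log(p.median), sigma=p.sigma))

    tech = TECHNOLOGIES[
        rng.choice(len(TECHNOLOGIES), p=[params.technology_mix.get(t, 0.0) for t in TECHNOLOGIES])
    ]
    paired = bool(rng.random() < params.pair_probability)
    n_patients = int(rng.integers(params.n_patients_range[0], params.n_patients_range[1] + 1))

    pair = 2.0 if paired else 1.0
    rework = 1.0 + params.rework_rate
    tech_mult = params.tech_multiplier[tech]

    items = [
        ResourceItem(
            label="germline sample collection",
            step="sampling",
            cost_type="other",
            per_patient_cost=draw("sampling"),
        )
    ]
    if paired:
        items.append(
            ResourceItem(
                label="tumour sample handling",
                step="sampling",
                cost_type="other",
                per_patient_cost=draw("sampling"),
            )
        )
    items += [
        ResourceItem(
            label="extraction consumables",
            step="dna_extraction",
            cost_type="consumables",
            per_patient_cost=draw("extraction_consumables") * rework * pair,
        ),
        ResourceItem(
            label="validation / quality control",
            step="dna_extraction",
            cost_type="testing",
            per_patient_cost=draw("extraction_qc") * rework * pair,
        ),
        ResourceItem(
            label="extraction labour",
            step="dna_extraction",
            cost_type="labour",
            per_patient_cost=draw("extraction_labour") * pair,
        ),
        ResourceItem(
            label="library preparation consumables",
            step="library_preparation",
            cost_type="consumables",
            per_patient_cost=draw("library_prep") * tech_mult * pair,
        ),
        ResourceItem(
            label="library preparation labour",
            step="library_preparation",
            cost_type="labour",
            per_patient_cost=draw("library_prep_labour") * pair,
        ),
        ResourceItem(
            label="sequencing testing",
            step="sequencing",
            cost_type="testing",
            per_patient_cost=draw("sequencing") * tech_mult * pair,
        ),
        ResourceItem(
            label="analysis labour",
            step="analysis",
            cost_type="labour",
            per_patient_cost=draw("analysis_labour") * params.analysis_multiplier[tech],
        ),
        ResourceItem(
            label="computing software",
            step="analysis",
            cost_type="equipment",
            per_patient_cost=draw("software"),
        ),
    ]
    has_reporting = bool(rng.random() < params.reporting_probability)
    if has_reporting:
        items.append(
            ResourceItem(
                label="multidisciplinary team meeting",
                step="clinician_reporting",
                cost_type="labour",
                per_patient_cost=draw("reporting"),
            )
        )

    lo, hi = params.storage_gb_range[tech]
    gb = float(rng.uniform(lo, hi)) * pair
    storage = StorageSpec(
        gb_per_patient=gb,
        usd_per_gb_month=STORAGE_TIERS[params.storage_tier],
        months=params.storage_months,
        usd_per_aud=params.usd_per_aud,
    )
    items.append(
        ResourceItem(
            label="data storage (cloud)",
            step="data_storage",
            cost_type="other",
            per_patient_cost=storage_cost_per_patient(storage),
        )
    )

    equipment = EquipmentSpec(
        acquisition_price=float(
            rng.lognormal(
                mean=math.log(params.equipment_acquisition.median),
                sigma=params.equipment_acquisition.sigma,
            )
        ),
        useful_life_years=5,
        interest_rate=0.03,
        annual_patients=float(
            rng.lognormal(
                mean=math.log(params.equipment_annual_patients.median),
                sigma=params.equipment_annual_patients.sigma,
            )
        ),
        maintenance_ratio=params.maintenance_ratio,
    )

    return Project(
        name=f"synthetic_{params.seed}_{index:04d}",
        n_patients=n_patients,
        technology=tech,
        sample_design="tumour_germline_pair" if paired else "germline_only",
        items=items,
        equipment=equipment,
        storage=storage,
        metadata={
            "synthetic": True,
            "seed": params.seed,
            "index": index,
            "rework_rate": params.rework_rate,
            "has_reporting": has_reporting,
        },
    )


def generate_cohort(params: SyntheticParams) -> list[Project]:
    """Generate ``params.n_projects`` projects, indices ``0..n-1``."""
    return [generate_project(params, i) for i in range(params.n_projects)]


def expected_total_excl_capital(params: SyntheticParams) -> float:
    """Analytic expectation of a project's capital-exclusive total.

    Marginalises over the technology mix, pairing and reporting
    probabilities using the lognormal mean ``median * exp(sigma^2/2)``
    per component; used to cross-check the generator by Monte Carlo.
    """
    comp = params.components
    mean = {name: p.mean for name, p in comp.items()}
    p_pair = params.pair_probability
    e_pair = 1.0 + p_pair  # E[2 if paired else 1]
    rework = 1.0 + params.rework_rate

    e_tech_mult = sum(
        params.technology_mix.get(t, 0.0) * params.tech_multiplier[t] for t in TECHNOLOGIES
    )
    e_analysis_mult = sum(
        params.technology_mix.get(t, 0.0) * params.analysis_multiplier[t]
        for t in TECHNOLOGIES
    )
    e_gb = sum(
        params.technology_mix.get(t, 0.0)
        * (params.storage_gb_range[t][0] + params.storage_gb_range[t][1])
        / 2.0
        for t in TECHNOLOGIES
    )
    storage_price = (
        STORAGE_TIERS[params.storage_tier] * params.storage_months / params.usd_per_aud
    )

    total = mean["sampling"] * (1.0 + p_pair)
    total += (mean["extraction_consumables"] + mean["extraction_qc"]) * rework * e_pair
    total += mean["extraction_labour"] * e_pair
    total += mean["library_prep"] * e_tech_mult * e_pair
    total += mean["library_prep_labour"] * e_pair
    total += mean["sequencing"] * e_tech_mult * e_pair
    total += mean["analysis_labour"] * e_analysis_mult
    total += mean["software"]
    total += mean["reporting"] * params.reporting_probability
    total += e_gb * e_pair * storage_price
    return total
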