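"""One-way deterministic sensitivity analysis.

Inputs to a cost model are perturbed one at a time — a selected group of
line items (by step, cost type or label pattern) or the capital block —
between a low and a high value, the per-patient total is recomputed, and
parameters are ranked by the *swing* (absolute difference between the
high and low totals) for tornado-style reporting.

Relative changes are expressed against the capital-inclusive total, the
denominator under which a 10% price cut on combined library preparation
and sequencing moves a portfolio of six projects by an average of about
7% per 10% cut.

Resource use here is deterministic (point estimates per project), so
there is no probabilistic/bootstrap analysis; all variation is explicit
scenario variation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .capital import DirectCapital, EquipmentSpec
from .categories import ActivityStep, CostType
from .model import CostBreakdown, Project, component_cost, per_patient_breakdown

__all__ = [
    "SelectorError",
    "ItemSelector",
    "ScenarioSpec",
    "TornadoRow",
    "apply_scenario",
    "relative_total_change",
    "cross_project_sensitivity",
    "SensitivitySummary",
    "tornado",
    "tornado_frame",
    "default_scenarios",
]


class SelectorError(ValueError):
    """Raised when a scenario selector matches nothing in a project."""


class ItemSelector(BaseModel):
    """Selects line items (and/or the capital block) of a project.

    Criteria combine conjunctively: an item matches when it lies in one
    of ``steps`` (if given), has ``cost_type`` (if given) and its label
    matches ``label_pattern`` (if given, a case-insensitive regular
    expression).  ``capital=True`` additionally selects the machine +
    maintenance block.
    """

    model_config = ConfigDict(extra="forbid")

    steps: Optional[tuple[ActivityStep, ...]] = None
    cost_type: Optional[CostType] = None
    label_pattern: Optional[str] = None
    capital: bool = False

    @field_validator("steps", mode="before")
    @classmethod
    def _parse_steps(cls, v):
        if v is None:
            return None
        return tuple(ActivityStep.parse(s) for s in v)

    @field_validator("cost_type", mode="before")
    @classmethod
    def _parse_type(cls, v):
        return None if v is None else CostType.parse(v)

    @model_validator(mode="after")
    def _check_any(self) -> "ItemSelector":
        if self.steps is None and self.cost_type is None and self.label_pattern is None and not self.capital:
            raise ValueError("selector must constrain steps, cost_type, label_pattern or capital")
        return self

    def selects_items(self) -> bool:
        return self.steps is not None or self.cost_type is not None or self.label_pattern is not None

    def matches(self, item) -> bool:
        if not self.selects_items():
            return False
        if self.steps is not None and item.step not in self.steps:
            return False
        if self.cost_type is not None and item.cost_type != self.cost_type:
            return False
        if self.label_pattern is not None and not re.search(
            self.label_pattern, item.label, flags=re.IGNORECASE
        ):
            return False
        return True

    def describe(self) -> str:
        parts = []
        if self.steps is not None:
            parts.append("steps=" + "+".join(s.value for s in self.steps))
        if self.cost_type is not None:
            parts.append(f"cost_type={self.cost_type.value}")
        if self.label_pattern is not None:
            parts.append(f"label~{self.label_pattern!r}")
        if self.capital:
            parts.append("capital")
        return ", ".join(parts) or "<empty>"


class ScenarioSpec(BaseModel):
    """One named perturbation for one-way sensitivity analysis.

    Either a single multiplicative ``factor`` (or absolute ``set_to``
    replacement), or a ``low``/``high`` factor pair for two-sided
    tornado analysis.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    selector: ItemSelector
    factor: Optional[float] = Field(default=None, gt=0)
    low: Optional[float] = Field(default=None, gt=0)
    high: Optional[float] = Field(default=None, gt=0)
    set_to: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_perturbation(self) -> "ScenarioSpec":
        has_pair = self.low is not None or self.high is not None
        if self.factor is None and self.set_to is None and not has_pair:
            raise ValueError(f"scenario {self.name!r}: give factor, set_to, or low/high")
        if self.factor is not None and has_pair:
            raise ValueError(f"scenario {self.name!r}: factor and low/high are exclusive")
        if self.set_to is not None and (self.factor is not None or has_pair):
            raise ValueError(f"scenario {self.name!r}: set_to excludes factors")
        return self


def _scale_equipment(equipment, factor: float):
    if isinstance(equipment, DirectCapital):
        return DirectCapital(
            machine_per_patient=equipment.machine_per_patient * factor,
            maintenance_per_patient=equipment.maintenance_per_patient * factor,
        )
    if isinstance(equipment, EquipmentSpec):
        return equipment.model_copy(
            update={"acquisition_price": equipment.acquisition_price * factor}
        )
    return equipment


def apply_scenario(
    project: Project,
    scenario: ScenarioSpec,
    factor: Optional[float] = None,
) -> Project:
    """Return a modified copy of ``project`` with the scenario applied.

    ``factor`` overrides the scenario's own single factor (used by
    :func:`tornado` to evaluate the low and high sides).  The input
    project is never mutated.  Raises :class:`SelectorError`, naming the
    selector, when nothing matches.
    """
    selector = scenario.selector
    if factor is None:
        factor = scenario.factor
    if factor is None and scenario.set_to is None:
        raise ValueError(
            f"scenario {scenario.name!r} has no single factor; pass one explicitly"
        )

    modified = project.model_copy(deep=True)
    n_matched = 0
    if selector.selects_items():
        new_items = []
        for item in modified.items:
            if selector.matches(item):
                n_matched += 1
                if scenario.set_to is not None:
                    item = item.model_copy(
                        update={
                            "per_patient_cost": scenario.set_to,
                            "quantity": None,
                            "unit_price": None,
                        }
                    )
                elif item.per_patient_cost is not None:
                    item = item.model_copy(
                        update={"per_patient_cost": item.per_patient_cost * factor}
                    )
                else:
                    item = item.model_copy(
                        update={"unit_price": item.unit_price * factor}
                    )
            new_items.append(item)
        modified = modified.model_copy(update={"items": new_items})

    if selector.capital:
        if modified.equipment is None:
            raise SelectorError(
                f"scenario {scenario.name!r} selects capital but project "
                f"{project.name!r} has no equipment input"
            )
        n_matched += 1
        modified = modified.model_copy(
            update={"equipment": _scale_equipment(modified.equipment, factor or 1.0)}
        )

    if n_matched == 0:
        raise SelectorError(
            f"scenario {scenario.name!r} matched no items in project "
            f"{project.name!r} (selector: {selector.describe()})"
        )
    return modified


def relative_total_change(
    project: Project,
    scenario: ScenarioSpec,
    factor: Optional[float] = None,
) -> float:
    """Percent change of the capital-inclusive total under one scenario."""
    baseline = per_patient_breakdown(project)
    if baseline.total_incl_capital <= 0:
        raise ValueError(
            f"project {project.name!r} has a non-positive baseline total"
        )
    perturbed = per_patient_breakdown(apply_scenario(project, scenario, factor=factor))
    return (
        100.0
        * (perturbed.total_incl_capital - baseline.total_incl_capital)
        / baseline.total_incl_capital
    )


@dataclass(frozen=True)
class SensitivitySummary:
    """Mean and range of per-project relative changes for one scenario."""

    scenario: str
    mean: float
    min: float
    max: float
    per_project: dict[str, float]


def cross_project_sensitivity(
    projects: Sequence[Project],
    scenario: ScenarioSpec,
    factor: Optional[float] = None,
) -> SensitivitySummary:
    """Unweighted mean and min-max of relative changes across projects."""
    if len(projects) == 0:
        raise ValueError("cross_project_sensitivity requires at least one project")
    changes = {
        p.name: relative_total_change(p, scenario, factor=factor) for p in projects
    }
    values = list(changes.values())
    return SensitivitySummary(
        scenario=scenario.name,
        mean=float(sum(values) / len(values)),
        min=float(min(values)),
        max=float(max(values)),
        per_project=changes,
    )


@dataclass(frozen=True)
class TornadoRow:
    """Low/high totals and swing for one parameter of a tornado diagram."""

    parameter: str
    baseline_total: float
    total_low: float
    total_high: float
    relative_change_low: float
    relative_change_high: float

    @property
    def swing(self) -> float:
        return abs(self.total_high - self.total_low)


def _total_under(project: Project, scenario: ScenarioSpec, factor: Optional[float],
                 baseline: CostBreakdown) -> float:
    if factor is None and scenario.set_to is None:
        return baseline.total_incl_capital
    return per_patient_breakdown(
        apply_scenario(project, scenario, factor=factor)
    ).total_incl_capital


def tornado(project: Project, scenarios: Sequence[ScenarioSpec]) -> list[TornadoRow]:
    """Evaluate scenarios one at a time and rank them by swing.

    For a scenario with only a single factor (or ``set_to``), the other
    end of the bar is the baseline total.  Rows sort by swing
    descending, ties broken by parameter name ascending, so the output
    is deterministic.
    """
    if len(scenarios) == 0:
        raise ValueError("tornado requires at least one scenario")
    baseline = per_patient_breakdown(project)
    base_total = baseline.total_incl_capital
    rows = []
    for scenario in scenarios:
        if scenario.low is not None or scenario.high is not None:
            low_total = _total_under(project, scenario, scenario.low, baseline)
            high_total = _total_under(project, scenario, scenario.high, baseline)
        else:
            # single-sided scenario: one end is the baseline
            low_total = base_total
            high_total = _total_under(project, scenario, scenario.factor, baseline)
        rel = lambda t: 100.0 * (t - base_total) / base_total if base_total > 0 else 0.0
        rows.append(
            TornadoRow(
                parameter=scenario.name,
                baseline_total=base_total,
                total_low=low_total,
                total_high=high_total,
                relative_change_low=rel(low_total),
                relative_change_high=rel(high_total),
            )
        )
    rows.sort(key=lambda row: (-row.swing, row.parameter))
    return rows


def tornado_frame(rows: Sequence[TornadoRow]):
    """Tornado rows as a DataFrame (one row per parameter, sorted)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "baseline_total": r.baseline_total,
                "total_low": r.total_low,
                "total_high": r.total_high,
                "swing": r.swing,
                "relative_change_low_pct": r.relative_change_low,
                "relative_change_high_pct": r.relative_change_high,
            }
            for r in rows
        ]
    )


def plot_tornado(rows: Sequence[TornadoRow], ax=None, title: str = ""):
    """Render a tornado diagram with matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.6 * max(len(rows), 2) + 1))
    ordered = list(rows)[::-1]  # largest swing on top
    for i, row in enumerate(ordered):
        left = min(row.total_low, row.total_high)
        width = row.swing
        ax.barh(i, width, left=left, color="#4878a8")
        ax.axvline(row.baseline_total, color="black", lw=1)
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([r.parameter for r in ordered])
    ax.set_xlabel("Total per-patient cost (AUD, incl. capital)")
    if title:
        ax.set_title(title)
    return ax


def default_scenarios() -> list[ScenarioSpec]:
    """The standard one-way scenario set.

    Library preparation + sequencing prices +/-10%, all labour +/-20%,
    storage moved from the nearline tier to coldline (x0.7) or regional
    (x2.5), and the capital block +/-20%.
    """
    return [
        ScenarioSpec(
            name="library_prep_and_sequencing_price",
            selector=ItemSelector(steps=("library_preparation", "sequencing")),
            low=0.9,
            high=1.1,
        ),
        ScenarioSpec(
            name="labour_rates",
            selector=ItemSelector(cost_type="labour"),
            low=0.8,
            high=1.2,
        ),
        ScenarioSpec(
            name="storage_tier",
            selector=ItemSelector(steps=("data_storage",)),
            low=0.7,
            high=2.5,
        ),
        ScenarioSpec(
            name="capital_equipment",
            selector=ItemSelector(capital=True),
            low=0.8,
            high=1.2,
        ),
    ]
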