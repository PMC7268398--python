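"""Per-patient micro-costing of genomic sequencing workflows.

The accounting unit is the *patient*, not the sample: where a workflow
sequences matched tumour and germline samples, every line item already
carries the cost of both samples for one patient.  A
:class:`ResourceItem` values one resource either as a per-patient cost
directly or as ``quantity x unit_price``; a :class:`Project` bundles the
inventory with instrument and storage inputs.

:class:`MicroCostingModel` is the entry point: build it from a
:class:`Project` (or a config file, fixture name or DataFrame) and call
:meth:`~MicroCostingModel.fit` to obtain a :class:`CostResults` holding
the per-step and per-type breakdowns, capital add-on and totals, with
``summary()`` producing the familiar two-axis cost table.

Conventions
-----------
* Step shares are percentages of the total **excluding** capital.
* The cost-type table folds annuitized machine + maintenance into the
  ``equipment`` row, so type totals sum to the capital-inclusive total.
* All arithmetic is at full floating precision; rounding happens only
  at rendering (2 dp AUD, whole USD, 1 dp percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Literal, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .capital import (
    CapitalResult,
    DirectCapital,
    EquipmentSpec,
    direct_capital,
    per_patient_capital,
)
from .categories import MERGED_LIB_SEQ, ActivityStep, CostType, step_order
from .pricing import DEFAULT_USD_PER_AUD, StorageSpec, convert_aud_to_usd, storage_cost_per_patient

__all__ = [
    "ITEM_TOLERANCE",
    "TABLE_TOLERANCE",
    "ResourceItem",
    "Project",
    "CostBreakdown",
    "UndefinedShareError",
    "component_cost",
    "per_patient_breakdown",
    "step_shares",
    "type_breakdown",
    "cross_project_summary",
    "CrossProjectSummary",
    "CheckResult",
    "validate_project",
    "MicroCostingModel",
    "CostResults",
]

#: Tolerance for item-level money comparisons (half a cent).
ITEM_TOLERANCE = 0.005
#: Tolerance for table-level totals.
TABLE_TOLERANCE = 0.05

Technology = Literal["panel", "exome", "genome"]
SampleDesign = Literal["germline_only", "tumour_only", "tumour_germline_pair"]


class UndefinedShareError(ValueError):
    """Raised when shares are requested for a zero-cost breakdown."""


class ResourceItem(BaseModel):
    """One costed line item of a sequencing workflow.

    Exactly one costing form must be populated: either
    ``per_patient_cost``, or ``quantity`` together with ``unit_price``.
    If both are given they must agree within half a cent.
    """

    model_config = ConfigDict(extra="forbid")

    label: str
    step: ActivityStep
    cost_type: CostType
    per_patient_cost: Optional[float] = None
    quantity: Optional[float] = None
    unit_price: Optional[float] = None
    merged: bool = False
    note: str = ""

    @field_validator("step", mode="before")
    @classmethod
    def _parse_step(cls, v: Any) -> ActivityStep:
        return ActivityStep.parse(v)

    @field_validator("cost_type", mode="before")
    @classmethod
    def _parse_type(cls, v: Any) -> CostType:
        return CostType.parse(v)

    @model_validator(mode="after")
    def _check_costing(self) -> "ResourceItem":
        has_direct = self.per_patient_cost is not None
        has_qty = self.quantity is not None or self.unit_price is not None
        if has_qty and (self.quantity is None or self.unit_price is None):
            raise ValueError(
                f"item {self.label!r}: quantity and unit_price must be given together"
            )
        if not has_direct and not has_qty:
            raise ValueError(
                f"item {self.label!r}: give per_patient_cost or quantity + unit_price"
            )
        for name in ("per_patient_cost", "quantity", "unit_price"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValueError(
                    f"item {self.label!r}: {name} must be finite and non-negative, got {value!r}"
                )
        if has_direct and has_qty:
            implied = self.quantity * self.unit_price
            if abs(implied - self.per_patient_cost) > ITEM_TOLERANCE:
                raise ValueError(
                    f"item {self.label!r}: per_patient_cost {self.per_patient_cost} "
                    f"disagrees with quantity x unit_price = {implied:.4f}"
                )
        if self.merged and self.step not in (
            ActivityStep.LIBRARY_PREPARATION,
            ActivityStep.SEQUENCING,
        ):
            raise ValueError(
                f"item {self.label!r}: only library preparation and sequencing "
                f"items may be merged, not {self.step.value}"
            )
        return self


def component_cost(item: ResourceItem) -> float:
    """Per-patient AUD cost of one item (direct, or quantity x price)."""
    if item.per_patient_cost is not None:
        return float(item.per_patient_cost)
    return float(item.quantity) * float(item.unit_price)


class Project(BaseModel):
    """A sequencing application: inventory plus capital and storage inputs.

    ``equipment`` is either a full :class:`~seqcost.capital.EquipmentSpec`
    (acquisition price, life, rate, throughput, maintenance ratio) or a
    :class:`~seqcost.capital.DirectCapital` with the per-patient machine
    and maintenance costs stated directly.  ``storage`` may carry a
    :class:`~seqcost.pricing.StorageSpec`; it contributes to the
    breakdown only when no explicit data-storage item exists.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    n_patients: int = Field(gt=0)
    technology: Technology = "panel"
    sample_design: SampleDesign = "germline_only"
    items: list[ResourceItem] = Field(default_factory=list)
    equipment: Optional[Union[DirectCapital, EquipmentSpec]] = None
    storage: Optional[StorageSpec] = None
    display_name: str = ""
    metadata: dict[str, Any] = Field(default_factory=dict)

    @property
    def merged_lib_seq(self) -> bool:
        """True when any item covers library preparation and sequencing jointly."""
        return any(item.merged for item in self.items)

    def capital_result(self) -> Optional[CapitalResult]:
        if self.equipment is None:
            return None
        if isinstance(self.equipment, EquipmentSpec):
            return per_patient_capital(self.equipment)
        return direct_capital(self.equipment)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient costs of one project along both axes.

    ``per_step`` is keyed by step label in workflow order; when any item
    merges library preparation with sequencing, those two steps are
    reported under the single combined key
    ``"library_prep_and_sequencing"``.  ``per_type`` includes annuitized
    capital under ``equipment`` so its values sum to
    ``total_incl_capital``.  ``step_shares`` are percentages of
    ``total_excl_capital`` (zero-filled for an all-zero project);
    ``present_steps`` records which step keys actually carry items, so
    renderers can distinguish an absent step ("n/a") from a costed
    zero.
    """

    per_step: dict[str, float]
    per_type: dict[str, float]
    total_excl_capital: float
    capital_per_patient: float
    total_incl_capital: float
    step_shares: dict[str, float]
    capital_addon_percent: float
    present_steps: frozenset[str]
    merged: bool
    capital: Optional[CapitalResult] = None


def _step_key(step: ActivityStep, merged: bool) -> str:
    if merged and step in (ActivityStep.LIBRARY_PREPARATION, ActivityStep.SEQUENCING):
        return MERGED_LIB_SEQ
    return step.value


def per_patient_breakdown(
    project: Project,
    amortisation: Literal["annuity", "straight_line"] = "annuity",
) -> CostBreakdown:
    """Aggregate a project's inventory into a per-patient cost breakdown.

    Capital (machine + maintenance) is computed from the project's
    equipment input and kept outside ``total_excl_capital``; a storage
    spec is priced and included only when the inventory has no explicit
    data-storage item.
    """
    merged = project.merged_lib_seq
    keys = step_order(merged)
    per_step = {k: 0.0 for k in keys}
    per_type = {t.value: 0.0 for t in CostType}
    present: set[str] = set()

    for item in project.items:
        cost = component_cost(item)
        key = _step_key(item.step, merged)
        per_step[key] += cost
        per_type[item.cost_type.value] += cost
        present.add(key)

    storage_key = ActivityStep.DATA_STORAGE.value
    if project.storage is not None and storage_key not in present:
        cost = storage_cost_per_patient(project.storage)
        per_step[storage_key] += cost
        per_type[CostType.OTHER.value] += cost
        present.add(storage_key)

    if isinstance(project.equipment, EquipmentSpec):
        cap = per_patient_capital(project.equipment, method=amortisation)
    elif isinstance(project.equipment, DirectCapital):
        cap = direct_capital(project.equipment)
    else:
        cap = None
    capital_pp = cap.capital_per_patient if cap is not None else 0.0
    per_type[CostType.EQUIPMENT.value] += capital_pp

    total_excl = sum(per_step.values())
    total_incl = total_excl + capital_pp
    if total_excl > 0:
        shares = {k: 100.0 * v / total_excl for k, v in per_step.items()}
        addon = 100.0 * capital_pp / total_excl
    else:
        shares = {k: 0.0 for k in per_step}
        addon = 0.0

    return CostBreakdown(
        per_step=per_step,
        per_type=per_type,
        total_excl_capital=total_excl,
        capital_per_patient=capital_pp,
        total_incl_capital=total_incl,
        step_shares=shares,
        capital_addon_percent=addon,
        present_steps=frozenset(present),
        merged=merged,
        capital=cap,
    )


def step_shares(breakdown: CostBreakdown) -> dict[str, float]:
    """Step shares as percentages of the capital-exclusive total.

    Raises :class:`UndefinedShareError` when the total is not positive.
    """
    if breakdown.total_excl_capital <= 0:
        raise UndefinedShareError(
            "step shares are undefined for a project with zero total cost"
        )
    return {
        k: 100.0 * v / breakdown.total_excl_capital
        for k, v in breakdown.per_step.items()
    }


def type_breakdown(project: Project) -> dict[str, float]:
    """Per-patient AUD by cost type, with capital folded into equipment."""
    return per_patient_breakdown(project).per_type


@dataclass(frozen=True)
class CrossProjectSummary:
    """Mean and range of step shares and capital add-on across projects.

    Step shares always combine library preparation with sequencing, so
    projects that outsource the two as one service remain comparable
    with projects that split them.
    """

    shares: pd.DataFrame
    capital_addon_mean: float
    capital_addon_min: float
    capital_addon_max: float
    n_projects: int

    def to_frame(self) -> pd.DataFrame:
        frame = self.shares.copy()
        frame.loc["capital_addon"] = [
            self.capital_addon_mean,
            self.capital_addon_min,
            self.capital_addon_max,
        ]
        return frame


def _combined_shares(breakdown: CostBreakdown) -> dict[str, float]:
    """Step shares with library prep + sequencing always combined."""
    if breakdown.total_excl_capital <= 0:
        raise UndefinedShareError(
            "step shares are undefined for a project with zero total cost"
        )
    combined: dict[str, float] = {k: 0.0 for k in step_order(merged=True)}
    for key, value in breakdown.per_step.items():
        if key in (
            ActivityStep.LIBRARY_PREPARATION.value,
            ActivityStep.SEQUENCING.value,
        ):
            key = MERGED_LIB_SEQ
        combined[key] += value
    total = breakdown.total_excl_capital
    return {k: 100.0 * v / total for k, v in combined.items()}


def cross_project_summary(projects: Sequence[Project]) -> CrossProjectSummary:
    """Mean and min-max of unrounded step shares across projects.

    The capital add-on (capital as % of the capital-exclusive total) is
    summarised the same way.  Requires at least one project.
    """
    if len(projects) == 0:
        raise ValueError("cross_project_summary requires at least one project")
    breakdowns = [per_patient_breakdown(p) for p in projects]
    share_rows = [_combined_shares(b) for b in breakdowns]
    frame = pd.DataFrame(share_rows, index=[p.name for p in projects])
    shares = pd.DataFrame(
        {"mean": frame.mean(), "min": frame.min(), "max": frame.max()}
    )
    shares.index.name = "step"
    addons = [b.capital_addon_percent for b in breakdowns]
    return CrossProjectSummary(
        shares=shares,
        capital_addon_mean=float(sum(addons) / len(addons)),
        capital_addon_min=float(min(addons)),
        capital_addon_max=float(max(addons)),
        n_projects=len(projects),
    )


@dataclass(frozen=True)
class CheckResult:
    """Outcome of one validation check on a project."""

    check: str
    ok: bool
    message: str


def validate_project(project: Project) -> list[CheckResult]:
    """Run the accounting invariants on one project.

    Checks that step costs sum to the capital-exclusive total, type
    costs to the capital-inclusive total, that both match a brute-force
    re-sum of the raw inventory, that shares normalise to 100%, and —
    when the project metadata declares ``expected_total_excl_capital``
    or ``expected_total_incl_capital`` — that the computed totals agree
    with the declared ones to within a cent.  Content problems are
    reported, never raised.
    """
    breakdown = per_patient_breakdown(project)
    checks: list[CheckResult] = []

    step_sum = sum(breakdown.per_step.values())
    checks.append(
        CheckResult(
            "step_sum_conservation",
            abs(step_sum - breakdown.total_excl_capital) <= TABLE_TOLERANCE,
            f"sum(per_step)={step_sum:.4f} vs total_excl={breakdown.total_excl_capital:.4f}",
        )
    )
    type_sum = sum(breakdown.per_type.values())
    checks.append(
        CheckResult(
            "type_sum_conservation",
            abs(type_sum - breakdown.total_incl_capital) <= TABLE_TOLERANCE,
            f"sum(per_type)={type_sum:.4f} vs total_incl={breakdown.total_incl_capital:.4f}",
        )
    )
    brute = sum(component_cost(item) for item in project.items)
    if project.storage is not None and not any(
        item.step == ActivityStep.DATA_STORAGE for item in project.items
    ):
        brute += storage_cost_per_patient(project.storage)
    checks.append(
        CheckResult(
            "brute_force_item_sum",
            abs(brute - breakdown.total_excl_capital) <= TABLE_TOLERANCE,
            f"brute-force item sum {brute:.4f} vs total_excl={breakdown.total_excl_capital:.4f}",
        )
    )
    if breakdown.total_excl_capital > 0:
        share_sum = sum(breakdown.step_shares.values())
        checks.append(
            CheckResult(
                "share_normalisation",
                abs(share_sum - 100.0) <= 0.2,
                f"sum(step_shares)={share_sum:.4f}%",
            )
        )
    for key, computed in (
        ("expected_total_excl_capital", breakdown.total_excl_capital),
        ("expected_total_incl_capital", breakdown.total_incl_capital),
    ):
        declared = project.metadata.get(key)
        if declared is not None:
            checks.append(
                CheckResult(
                    key,
                    abs(float(declared) - computed) <= 0.01,
                    f"declared {float(declared):.2f} vs computed {computed:.2f}",
                )
            )
    return checks


class MicroCostingModel:
    """Bottom-up per-patient cost model of one sequencing project.

    Parameters
    ----------
    project : Project
        The resource inventory with capital and storage inputs.
    usd_per_aud : float, optional
        Exchange rate used when reporting USD equivalents.
    amortisation : {"annuity", "straight_line"}, optional
        How the instrument's acquisition price is spread over its
        useful life.  The annuity method divides by
        ``(1 - (1+r)^-n) / r``; straight-line divides by ``n``.

    Examples
    --------
    >>> from seqcost import MicroCostingModel
    >>> res = MicroCostingModel.from_fixture("melanoma_exome").fit()
    >>> round(res.total_excl_capital, 2)
    870.63
    """

    def __init__(
        self,
        project: Project,
        *,
        usd_per_aud: float = DEFAULT_USD_PER_AUD,
        amortisation: Literal["annuity", "straight_line"] = "annuity",
    ) -> None:
        if not usd_per_aud > 0:
            raise ValueError(f"exchange rate must be positive, got {usd_per_aud!r}")
        self.project = project
        self.usd_per_aud = usd_per_aud
        self.amortisation = amortisation

    @classmethod
    def from_fixture(cls, name: str, **kwargs: Any) -> "MicroCostingModel":
        """Build the model from one of the packaged example projects."""
        from .fixtures import load_fixture

        return cls(load_fixture(name), **kwargs)

    @classmethod
    def from_config(cls, path: Any, **kwargs: Any) -> "MicroCostingModel":
        """Build the model from a YAML project config file."""
        from .io import read_project_config

        return cls(read_project_config(path), **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        *,
        name: str = "project",
        n_patients: int = 1,
        technology: Technology = "panel",
        sample_design: SampleDesign = "germline_only",
        equipment: Optional[Union[DirectCapital, EquipmentSpec]] = None,
        storage: Optional[StorageSpec] = None,
        **kwargs: Any,
    ) -> "MicroCostingModel":
        """Build the model from an inventory DataFrame.

        Expected columns: ``label``, ``step``, ``cost_type`` and either
        ``per_patient_cost`` or ``quantity`` + ``unit_price`` (optional
        ``merged``, ``note``).
        """
        from .io import items_from_frame

        project = Project(
            name=name,
            n_patients=n_patients,
            technology=technology,
            sample_design=sample_design,
            items=items_from_frame(frame),
            equipment=equipment,
            storage=storage,
        )
        return cls(project, **kwargs)

    def fit(self) -> "CostResults":
        """Aggregate the inventory and return the fitted results."""
        breakdown = per_patient_breakdown(self.project, amortisation=self.amortisation)
        return CostResults(self, breakdown)


class CostResults:
    """Fitted per-patient cost breakdown with reporting helpers.

    Exposes the per-step and per-type tables, capital block and totals,
    plus one-way sensitivity analysis via :meth:`relative_change` and
    :meth:`tornado`.
    """

    def __init__(self, model: MicroCostingModel, breakdown: CostBreakdown) -> None:
        self.model = model
        self.project = model.project
        self.breakdown = breakdown

    # -- scalar results -------------------------------------------------
    @property
    def per_step(self) -> dict[str, float]:
        return dict(self.breakdown.per_step)

    @property
    def per_type(self) -> dict[str, float]:
        return dict(self.breakdown.per_type)

    @property
    def total_excl_capital(self) -> float:
        return self.breakdown.total_excl_capital

    @property
    def capital_per_patient(self) -> float:
        return self.breakdown.capital_per_patient

    @property
    def total_incl_capital(self) -> float:
        return self.breakdown.total_incl_capital

    @property
    def step_shares(self) -> dict[str, float]:
        return dict(self.breakdown.step_shares)

    @property
    def capital_addon_percent(self) -> float:
        return self.breakdown.capital_addon_percent

    def total_usd(self, include_capital: bool = False) -> float:
        """Total per-patient cost converted to USD at the model's rate."""
        total = self.total_incl_capital if include_capital else self.total_excl_capital
        return convert_aud_to_usd(total, self.model.usd_per_aud)

    # -- tables ---------------------------------------------------------
    def step_table(self) -> pd.DataFrame:
        """One row per item: step key, label, cost type, AUD per patient."""
        merged = self.breakdown.merged
        rows = [
            {
                "step": _step_key(item.step, merged),
                "label": item.label,
                "cost_type": item.cost_type.value,
                "aud_per_patient": component_cost(item),
            }
            for item in self.project.items
        ]
        return pd.DataFrame(
            rows, columns=["step", "label", "cost_type", "aud_per_patient"]
        )

    def step_summary(self) -> pd.DataFrame:
        """Per-step totals and shares; share is NaN for absent steps."""
        rows = []
        for key in step_order(self.breakdown.merged):
            present = key in self.breakdown.present_steps
            rows.append(
                {
                    "step": key,
                    "aud_per_patient": self.breakdown.per_step[key],
                    "share_pct": self.breakdown.step_shares[key] if present else float("nan"),
                    "present": present,
                }
            )
        return pd.DataFrame(rows)

    def type_table(self) -> pd.DataFrame:
        """Per-type totals; shares are % of the capital-inclusive total."""
        total = self.total_incl_capital
        rows = []
        for cost_type in CostType:
            value = self.breakdown.per_type[cost_type.value]
            rows.append(
                {
                    "cost_type": cost_type.value,
                    "aud_per_patient": value,
                    "share_pct": 100.0 * value / total if total > 0 else 0.0,
                }
            )
        return pd.DataFrame(rows)

    # -- sensitivity ----------------------------------------------------
    def relative_change(self, scenario: Any) -> float:
        """Percent change of the capital-inclusive total under a scenario."""
        from .sensitivity import relative_total_change

        return relative_total_change(self.project, scenario)

    def tornado(self, scenarios: Sequence[Any]) -> list:
        """One-way sensitivity rows sorted by swing, largest first."""
        from .sensitivity import tornado

        return tornado(self.project, scenarios)

    # -- serialisation / display ----------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "project": self.project.name,
            "n_patients": self.project.n_patients,
            "technology": self.project.technology,
            "sample_design": self.project.sample_design,
            "usd_per_aud": self.model.usd_per_aud,
            "per_step": self.per_step,
            "per_type": self.per_type,
            "step_shares": self.step_shares,
            "total_excl_capital": self.total_excl_capital,
            "capital_per_patient": self.capital_per_patient,
            "capital_addon_percent": self.capital_addon_percent,
            "total_incl_capital": self.total_incl_capital,
            "total_usd_excl_capital": self.total_usd(),
            "total_usd_incl_capital": self.total_usd(include_capital=True),
        }

    def summary(self) -> str:
        """Human-readable report mirroring the two-axis cost table."""
        from .render import render_results_summary

        return render_results_summary(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CostResults {self.project.name}: "
            f"AU${self.total_excl_capital:.2f}/patient excl. capital>"
        )
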