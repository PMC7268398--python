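"""Reading and writing inventories, project configs and reports.

Inventories travel as UTF-8 CSV with a header row (columns ``label``,
``step``, ``cost_type`` and either ``per_patient_cost`` or ``quantity``
+ ``unit_price``; optional ``merged`` and ``note``).  A full project —
metadata, inventory, equipment and storage blocks — travels as a YAML
config document validated by the pydantic domain types.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Sequence, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .capital import DirectCapital, EquipmentSpec
from .model import CostResults, Project, ResourceItem
from .pricing import StorageSpec
from .render import format_aud, format_pct, frame_to_markdown
from .sensitivity import ItemSelector, ScenarioSpec

__all__ = [
    "items_from_frame",
    "read_inventory_csv",
    "write_inventory_csv",
    "read_project_config",
    "write_project_config",
    "read_scenarios",
    "write_results",
]

PathLike = Union[str, Path]

_ITEM_COLUMNS = [
    "label",
    "step",
    "cost_type",
    "per_patient_cost",
    "quantity",
    "unit_price",
    "merged",
    "note",
]


def _clean(value: Any) -> Any:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def items_from_frame(frame: pd.DataFrame) -> list[ResourceItem]:
    """Build validated items from an inventory DataFrame."""
    required = {"label", "step", "cost_type"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(
            f"inventory is missing required columns: {', '.join(sorted(missing))}"
        )
    items = []
    for _, row in frame.iterrows():
        record: dict[str, Any] = {
            "label": row["label"],
            "step": row["step"],
            "cost_type": row["cost_type"],
        }
        for col in ("per_patient_cost", "quantity", "unit_price"):
            if col in frame.columns:
                value = _clean(row[col])
                if value is not None:
                    record[col] = float(value)
        if "merged" in frame.columns:
            value = _clean(row["merged"])
            if value is not None:
                record["merged"] = str(value).strip().lower() in ("1", "true", "yes")
        if "note" in frame.columns:
            value = _clean(row["note"])
            if value is not None:
                record["note"] = str(value)
        items.append(ResourceItem(**record))
    return items


def read_inventory_csv(path: PathLike) -> list[ResourceItem]:
    """Read a resource inventory from CSV."""
    frame = pd.read_csv(
        path,
        dtype={"label": str, "step": str, "cost_type": str},
        float_precision="round_trip",
    )
    if frame.empty:
        raise ValueError(f"inventory {path} contains no items")
    return items_from_frame(frame)


def write_inventory_csv(items: Sequence[ResourceItem], path: PathLike) -> None:
    """Write items as an inventory CSV (round-trips losslessly)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=_ITEM_COLUMNS)
        writer.writeheader()
        for item in items:
            writer.writerow(
                {
                    "label": item.label,
                    "step": item.step.value,
                    "cost_type": item.cost_type.value,
                    "per_patient_cost": (
                        "" if item.per_patient_cost is None else repr(item.per_patient_cost)
                    ),
                    "quantity": "" if item.quantity is None else repr(item.quantity),
                    "unit_price": "" if item.unit_price is None else repr(item.unit_price),
                    "merged": "true" if item.merged else "",
                    "note": item.note,
                }
            )


def _project_from_mapping(doc: dict[str, Any], source: str) -> Project:
    if not isinstance(doc, dict):
        raise ValueError(f"{source}: project config must be a mapping")
    data = dict(doc)
    equipment = data.pop("equipment", None)
    if equipment is not None:
        if "acquisition_price" in equipment:
            equipment = EquipmentSpec(**equipment)
        else:
            equipment = DirectCapital(**equipment)
    storage = data.pop("storage", None)
    if storage is not None:
        storage = StorageSpec(**storage)
    items = data.pop("items", [])
    try:
        return Project(
            items=[ResourceItem(**item) for item in items],
            equipment=equipment,
            storage=storage,
            **data,
        )
    except ValidationError as exc:
        raise ValueError(f"{source}: invalid project config: {exc}") from exc


def read_project_config(path: PathLike) -> Project:
    """Read and validate a YAML project config."""
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    return _project_from_mapping(doc, source=str(path))


def write_project_config(project: Project, path: PathLike) -> None:
    """Write a project as a YAML config document."""
    doc = project.model_dump(mode="json", exclude_none=True, exclude_defaults=False)
    # drop empty cosmetic fields
    for key in ("display_name", "metadata"):
        if not doc.get(key):
            doc.pop(key, None)
    for item in doc.get("items", []):
        if not item.get("note"):
            item.pop("note", None)
        if not item.get("merged"):
            item.pop("merged", None)
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False, allow_unicode=True)


def read_scenarios(path: PathLike) -> list[ScenarioSpec]:
    """Read a YAML scenario file (top-level key ``scenarios``)."""
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ValueError(f"{path}: scenario file needs a top-level 'scenarios' list")
    scenarios = []
    for entry in doc["scenarios"]:
        try:
            selector = ItemSelector(**entry.pop("selector", {}))
            scenarios.append(ScenarioSpec(selector=selector, **entry))
        except (ValidationError, TypeError) as exc:
            raise ValueError(f"{path}: invalid scenario {entry!r}: {exc}") from exc
    if not scenarios:
        raise ValueError(f"{path}: scenario file lists no scenarios")
    return scenarios


# -- report writing -----------------------------------------------------


def _step_report_frame(results: CostResults) -> pd.DataFrame:
    """Step-axis report: item rows plus per-step share and totals."""
    breakdown = results.breakdown
    rows: list[dict[str, Any]] = []
    items = results.step_table()
    from .categories import step_order
    from .render import step_title

    for key in step_order(breakdown.merged):
        present = key in breakdown.present_steps
        for _, item in items[items["step"] == key].iterrows():
            rows.append(
                {
                    "section": step_title(key),
                    "row": item["label"],
                    "aud_per_patient": round(item["aud_per_patient"], 2),
                    "share_pct": "",
                }
            )
        rows.append(
            {
                "section": step_title(key),
                "row": "% of total",
                "aud_per_patient": "",
                "share_pct": format_pct(breakdown.step_shares[key]) if present else "n/a",
            }
        )
    rows.append(
        {
            "section": "TOTAL per person",
            "row": "excluding capital",
            "aud_per_patient": round(breakdown.total_excl_capital, 2),
            "share_pct": "",
        }
    )
    cap = breakdown.capital
    if cap is not None:
        rows.append(
            {
                "section": "Capital costs",
                "row": "sequencing machine",
                "aud_per_patient": round(cap.machine_per_patient, 2),
                "share_pct": "",
            }
        )
        rows.append(
            {
                "section": "Capital costs",
                "row": "maintenance",
                "aud_per_patient": round(cap.maintenance_per_patient, 2),
                "share_pct": "",
            }
        )
        rows.append(
            {
                "section": "Capital costs",
                "row": "% extra from total per person",
                "aud_per_patient": "",
                "share_pct": format_pct(breakdown.capital_addon_percent),
            }
        )
    rows.append(
        {
            "section": "TOTAL per person",
            "row": "including capital",
            "aud_per_patient": round(breakdown.total_incl_capital, 2),
            "share_pct": "",
        }
    )
    return pd.DataFrame(rows, columns=["section", "row", "aud_per_patient", "share_pct"])


def write_results(
    results: CostResults,
    outdir: PathLike,
    formats: Sequence[str] = ("csv", "markdown"),
) -> list[Path]:
    """Write step/type report tables for one fitted project.

    Emits ``<name>_steps.*`` and ``<name>_types.*`` in each requested
    format (``csv``, ``markdown``, ``json``) and returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = results.project.name
    step_frame = _step_report_frame(results)
    type_frame = results.type_table().round({"aud_per_patient": 2, "share_pct": 1})
    written: list[Path] = []
    for fmt in formats:
        if fmt == "csv":
            for suffix, frame in (("steps", step_frame), ("types", type_frame)):
                path = outdir / f"{name}_{suffix}.csv"
                frame.to_csv(path, index=False)
                written.append(path)
        elif fmt == "markdown":
            for suffix, frame, fmts in (
                ("steps", step_frame, {}),
                (
                    "types",
                    type_frame,
                    {"aud_per_patient": format_aud, "share_pct": format_pct},
                ),
            ):
                path = outdir / f"{name}_{suffix}.md"
                path.write_text(frame_to_markdown(frame, fmts) + "\n", encoding="utf-8")
                written.append(path)
        elif fmt == "json":
            path = outdir / f"{name}.json"
            path.write_text(
                json.dumps(results.to_dict(), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            written.append(path)
        else:
            raise ValueError(f"unknown output format {fmt!r}")
    return written
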