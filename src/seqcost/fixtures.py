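"""Packaged example projects.

Six worked examples of cancer sequencing applications costed per
patient, spanning the three technology tiers: two targeted panels
(lung/melanoma, breast), two exomes (melanoma from saliva, lung from
tumour/blood pairs) and two whole genomes (oesophageal cancer,
mesothelioma).  Each fixture carries the per-patient component costs of
the published breakdown, the directly-specified per-patient capital
block, and workflow metadata.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .io import _project_from_mapping
from .model import Project
from .sensitivity import ScenarioSpec

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_projects", "default_scenario_file"]

#: Names of the packaged fixture projects, in the canonical column order
#: (panels, then exomes, then genomes).
FIXTURE_NAMES: tuple[str, ...] = (
    "lung_melanoma_panel",
    "breast_panel",
    "melanoma_exome",
    "lung_exome",
    "oesophageal_genome",
    "mesothelioma_genome",
)


def load_fixture(name: str) -> Project:
    """Load one packaged example project by name.

    Raises ``KeyError`` listing the valid names when ``name`` is
    unknown.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    path = resources.files("seqcost").joinpath(f"data/fixtures/{name}.yaml")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    return _project_from_mapping(doc, source=f"fixture {name}")


def fixture_projects() -> list[Project]:
    """All six packaged projects in canonical order."""
    return [load_fixture(name) for name in FIXTURE_NAMES]


def default_scenario_file() -> str:
    """Contents of the packaged default sensitivity scenario file."""
    path = resources.files("seqcost").joinpath("data/default_scenarios.yaml")
    return path.read_text(encoding="utf-8")


def default_scenarios() -> list[ScenarioSpec]:
    """Parsed default scenario set (same content as the packaged file)."""
    from .sensitivity import default_scenarios as _builtin

    return _builtin()
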