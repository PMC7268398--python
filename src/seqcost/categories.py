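"""Workflow taxonomies: seven activity steps and five cost types.

A clinical sequencing workflow is costed along two orthogonal axes.  The
*activity step* axis follows the logical flow of the work — obtaining the
sample, extracting DNA, preparing sequencing libraries, sequencing,
bioinformatic analysis, storing the data and reporting results to
clinicians.  The *cost type* axis classifies the same line items by the
kind of resource consumed: labour, consumables, outsourced/validation
testing, equipment and a residual "other" bucket.

Where library preparation and sequencing are outsourced as a single
commercial service the two steps cannot be split; such items are flagged
``merged`` and reported under the combined key
:data:`MERGED_LIB_SEQ`.
"""

from __future__ import annotations

import enum

__all__ = [
    "ActivityStep",
    "CostType",
    "MERGED_LIB_SEQ",
    "STEP_ORDER",
    "step_order",
]

#: Report key used when library preparation and sequencing are merged.
MERGED_LIB_SEQ = "library_prep_and_sequencing"


class ActivityStep(str, enum.Enum):
    """One of the seven canonical stages of a sequencing workflow."""

    SAMPLING = "sampling"
    DNA_EXTRACTION = "dna_extraction"
    LIBRARY_PREPARATION = "library_preparation"
    SEQUENCING = "sequencing"
    ANALYSIS = "analysis"
    DATA_STORAGE = "data_storage"
    CLINICIAN_REPORTING = "clinician_reporting"

    @property
    def ordinal(self) -> int:
        """Position of the step in the workflow, 1-based."""
        return _STEP_ORDINALS[self]

    @classmethod
    def parse(cls, value: "ActivityStep | str | int") -> "ActivityStep":
        """Parse a step from its label (case-insensitive), alias or ordinal."""
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            for step, ordinal in _STEP_ORDINALS.items():
                if ordinal == value:
                    return step
            raise ValueError(
                f"unknown step ordinal {value!r}; expected 1-7"
            )
        key = str(value).strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return _STEP_ALIASES[key]
        except KeyError:
            valid = ", ".join(s.value for s in cls)
            raise ValueError(
                f"unknown activity step {value!r}; expected one of: {valid}"
            ) from None


_STEP_ORDINALS: dict[ActivityStep, int] = {
    ActivityStep.SAMPLING: 1,
    ActivityStep.DNA_EXTRACTION: 2,
    ActivityStep.LIBRARY_PREPARATION: 3,
    ActivityStep.SEQUENCING: 4,
    ActivityStep.ANALYSIS: 5,
    ActivityStep.DATA_STORAGE: 6,
    ActivityStep.CLINICIAN_REPORTING: 7,
}

_STEP_ALIASES: dict[str, ActivityStep] = {
    **{s.value: s for s in ActivityStep},
    "sample": ActivityStep.SAMPLING,
    "extraction": ActivityStep.DNA_EXTRACTION,
    "dna_extraction": ActivityStep.DNA_EXTRACTION,
    "library_prep": ActivityStep.LIBRARY_PREPARATION,
    "library_preparation_&_capture": ActivityStep.LIBRARY_PREPARATION,
    "storage": ActivityStep.DATA_STORAGE,
    "reporting": ActivityStep.CLINICIAN_REPORTING,
    "reporting_to_clinicians": ActivityStep.CLINICIAN_REPORTING,
}

#: Canonical step labels in workflow order.
STEP_ORDER: tuple[str, ...] = tuple(s.value for s in ActivityStep)


def step_order(merged: bool) -> tuple[str, ...]:
    """Report-row keys in workflow order.

    When ``merged`` is true, library preparation and sequencing collapse
    into the single combined key at position 3.
    """
    if not merged:
        return STEP_ORDER
    return (
        ActivityStep.SAMPLING.value,
        ActivityStep.DNA_EXTRACTION.value,
        MERGED_LIB_SEQ,
        ActivityStep.ANALYSIS.value,
        ActivityStep.DATA_STORAGE.value,
        ActivityStep.CLINICIAN_REPORTING.value,
    )


class CostType(str, enum.Enum):
    """Resource classification: the closed five-member set."""

    LABOUR = "labour"
    CONSUMABLES = "consumables"
    TESTING = "testing"
    EQUIPMENT = "equipment"
    OTHER = "other"

    @classmethod
    def parse(cls, value: "CostType | str") -> "CostType":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace(" ", "_").replace("-", "_")
        if key == "labor":
            key = "labour"
        try:
            return cls(key)
        except ValueError:
            valid = ", ".join(t.value for t in cls)
            raise ValueError(
                f"unknown cost type {value!r}; expected one of: {valid}"
            ) from None
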