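"""Cloud-storage pricing and currency conversion.

Sequencing output is held in commercial cloud storage priced per
gigabyte per month in USD.  Three access tiers are carried as presets:
coldline (very infrequent access, USD 0.007/GB-month), nearline
(infrequent, USD 0.01) and regional (frequent, USD 0.025).  Short-term
retention is conventionally five years (60 months).

Costs are kept in Australian dollars; the exchange rate is always an
explicit input expressed as USD per AUD (e.g. 0.6929 for 2018).
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "STORAGE_TIERS",
    "DEFAULT_USD_PER_AUD",
    "StorageSpec",
    "storage_cost_per_patient",
    "convert_aud_to_usd",
]

#: USD per GB per month by cloud access tier.
STORAGE_TIERS: dict[str, float] = {
    "coldline": 0.007,
    "nearline": 0.01,
    "regional": 0.025,
}

#: 2018 USD per AUD used for reporting; always overridable.
DEFAULT_USD_PER_AUD = 0.6929


class StorageSpec(BaseModel):
    """Per-patient cloud storage footprint and pricing."""

    model_config = ConfigDict(extra="forbid")

    gb_per_patient: float = Field(ge=0)
    usd_per_gb_month: float = Field(default=STORAGE_TIERS["nearline"], gt=0)
    months: int = Field(default=60, ge=0)
    usd_per_aud: float = Field(default=DEFAULT_USD_PER_AUD, gt=0)

    @classmethod
    def from_tier(
        cls,
        tier: str,
        gb_per_patient: float,
        months: int = 60,
        usd_per_aud: float = DEFAULT_USD_PER_AUD,
    ) -> "StorageSpec":
        """Build a spec from a named access tier."""
        try:
            price = STORAGE_TIERS[tier]
        except KeyError:
            valid = ", ".join(sorted(STORAGE_TIERS))
            raise ValueError(
                f"unknown storage tier {tier!r}; expected one of: {valid}"
            ) from None
        return cls(
            gb_per_patient=gb_per_patient,
            usd_per_gb_month=price,
            months=months,
            usd_per_aud=usd_per_aud,
        )


def storage_cost_per_patient(spec: StorageSpec) -> float:
    """AUD cost of holding one patient's data for the retention period.

    USD charges accumulate as GB x price x months and are converted to
    AUD at the spec's exchange rate.
    """
    usd = spec.gb_per_patient * spec.usd_per_gb_month * spec.months
    return usd / spec.usd_per_aud


def convert_aud_to_usd(amount_aud: float, usd_per_aud: float = DEFAULT_USD_PER_AUD) -> float:
    """Convert an AUD amount to USD at ``usd_per_aud``."""
    if not usd_per_aud > 0:
        raise ValueError(f"exchange rate must be positive, got {usd_per_aud!r}")
    return amount_aud * usd_per_aud
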