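"""Final disposition codes and contact-outcome rates.

Contact outcomes are classified into AAPOR-style final disposition codes in
four blocks — registered, eligible non-respondents, unknown eligibility, not
eligible — and summarized as recruitment, consent and completion rates, each
reported with its numerator and denominator disclosed and rounded half-up to
one decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import pandas as pd

from .errors import ValidationError

__all__ = [
    "CODE_BLOCKS",
    "DispositionTable",
    "RateReport",
    "tabulate_dispositions",
    "recruitment_rate",
    "consent_rate",
    "completion_rate",
    "eligible_invitees",
    "round_half_up",
]

#: disposition code -> block: 1 registered, 2 eligible non-respondent,
#: 3 unknown eligibility, 4 not eligible
CODE_BLOCKS: dict[str, int] = {
    "registered": 1,
    "refusal": 2,
    "restricted_access": 2,
    "nothing_returned": 3,
    "unclear_address": 3,
    "deceased": 4,
    "moved_abroad": 4,
    "other_sample": 4,
}


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DispositionTable:
    """Counts per final disposition code at one stage."""

    counts: dict[str, int]
    stage: str = "registration"

    def __post_init__(self) -> None:
        for code, n in self.counts.items():
            if code not in CODE_BLOCKS:
                raise ValidationError(f"unknown disposition code {code!r}")
            if n < 0 or int(n) != n:
                raise ValidationError(f"count for {code!r} must be a non-negative integer")
        self.counts = {code: int(self.counts.get(code, 0)) for code in CODE_BLOCKS}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def block_total(self, block: int) -> int:
        return sum(n for code, n in self.counts.items() if CODE_BLOCKS[code] == block)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"code": code, "block": CODE_BLOCKS[code], "count": n}
            for code, n in self.counts.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class RateReport:
    """A single outcome rate with its arithmetic disclosed."""

    name: str
    numerator: int
    denominator: int
    variant: str = "simple"
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValidationError(f"{self.name}: undefined rate, denominator is {self.denominator}")
        if not 0 <= self.numerator <= self.denominator:
            raise ValidationError(
                f"{self.name}: numerator {self.numerator} outside [0, {self.denominator}]"
            )
        self.rate = round_half_up(100.0 * self.numerator / self.denominator, 1)


def tabulate_dispositions(records: pd.DataFrame, stage: str = "registration") -> DispositionTable:
    """Count records per final disposition code.

    Every record must carry a recognized code; an unknown value raises a
    validation error naming the offending row.
    """
    counts: dict[str, int] = {code: 0 for code in CODE_BLOCKS}
    col = records["disposition"] if "disposition" in records.columns else records.iloc[:, 0]
    for idx, code in col.items():
        if pd.isna(code):
            raise ValidationError(f"row {idx!r} has no disposition code")
        if code not in CODE_BLOCKS:
            raise ValidationError(f"row {idx!r} has unknown disposition code {code!r}")
        counts[code] += 1
    return DispositionTable(counts, stage=stage)


def recruitment_rate(table: DispositionTable, variant: str = "simple") -> RateReport:
    """Registrants over invitees.

    ``simple``: registered / total of the table.  ``aapor_e1``: registered /
    (registered + eligible non-respondents + unknown eligibility), dropping
    the confirmed-not-eligible block from the denominator.
    """
    registered = table.block_total(1)
    if variant == "simple":
        denom = table.total
    elif variant == "aapor_e1":
        denom = table.block_total(1) + table.block_total(2) + table.block_total(3)
    else:
        raise ValidationError(f"unknown recruitment-rate variant {variant!r}")
    return RateReport("recruitment_rate", registered, denom, variant=variant)


def consent_rate(n_consented: int, n_identified: int) -> RateReport:
    return RateReport("consent_rate", n_consented, n_identified)


def completion_rate(
    n_completed: int | Mapping[str, tuple[int, int]], n_registered: int | None = None
) -> RateReport | dict[str, RateReport]:
    """Completed interviews over registrants; accepts per-stratum input.

    Pass two integers for an overall rate, or a mapping
    ``{stratum: (completed, registered)}`` for one report per stratum.
    """
    if isinstance(n_completed, Mapping):
        return {
            stratum: RateReport(f"completion_rate[{stratum}]", num, den)
            for stratum, (num, den) in n_completed.items()
        }
    if n_registered is None:
        raise ValidationError("n_registered required for an overall completion rate")
    return RateReport("completion_rate", n_completed, n_registered)


def eligible_invitees(n_consented: int, preparation_exclusions: Mapping[str, int]) -> int:
    """Consented minus itemized preparation-stage exclusions."""
    excluded = sum(preparation_exclusions.values())
    remaining = n_consented - excluded
    if remaining < 0:
        raise ValidationError(
            f"exclusions ({excluded}) exceed consented cases ({n_consented})"
        )
    return remaining
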