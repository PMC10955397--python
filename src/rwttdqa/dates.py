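"""Calendar dates with declared precision.

EHR-derived oncology tables routinely truncate dates: a death date may be
released only as a year, an administration date only as a month.  Treating
those as missing throws information away; treating them as full dates invents
it.  :class:`PartialDate` keeps the populated components and exposes a
precision so downstream code can decide, per computation, whether a value is
usable (day arithmetic requires day precision) and so quality checks can count
the exclusions they cause.

Comparison between two partial dates is defined only at their shared
precision: ``2017`` compares equal to ``2017-03-05`` because nothing finer
than the year is shared.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Tuple

DAY = "day"
MONTH = "month"
YEAR = "year"

_RANK = {YEAR: 0, MONTH: 1, DAY: 2}


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known down to day, month, or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.year <= 9999:
            raise ValueError(f"year out of range: {self.year}")
        if self.day is not None and self.month is None:
            raise ValueError("a day component requires a month component")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # delegates day-in-month validation (incl. leap years)
            dt.date(self.year, self.month, self.day)

    # -- construction ------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse an ISO-8601 date, truncation allowed.

        Accepts ``"2017"``, ``"2017-03"``, ``"2017-03-05"``.  Raises
        :class:`ValueError` on anything else.
        """
        parts = str(text).strip().split("-")
        if not 1 <= len(parts) <= 3 or any(not p.isdigit() for p in parts):
            raise ValueError(f"unparseable date: {text!r}")
        nums = [int(p) for p in parts]
        return cls(*nums)

    @classmethod
    def parse_lenient(cls, text: str) -> Tuple[Optional["PartialDate"], bool]:
        """Parse at the finest precision that validates.

        Returns ``(date, coarsened)`` where ``coarsened`` is True when
        components had to be dropped (e.g. ``"2017-13-40"`` -> year 2017).
        Returns ``(None, False)`` when not even a year can be recovered.
        """
        parts = str(text).strip().split("-")
        if not parts or not parts[0].isdigit():
            return None, False
        nums = []
        for p in parts[:3]:
            if not p.isdigit():
                break
            nums.append(int(p))
        for k in range(len(nums), 0, -1):
            try:
                return cls(*nums[:k]), k < len(parts)
            except ValueError:
                continue
        return None, False

    @classmethod
    def from_date(cls, d: dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    # -- inspection --------------------------------------------------------

    @property
    def precision(self) -> str:
        if self.day is not None:
            return DAY
        if self.month is not None:
            return MONTH
        return YEAR

    def is_day(self) -> bool:
        return self.day is not None

    def as_date(self) -> dt.date:
        """The exact calendar date; only defined at day precision."""
        if self.day is None:
            raise ValueError(f"{self.isoformat()} is not day-precise")
        return dt.date(self.year, self.month, self.day)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()

    # -- comparison at shared precision -----------------------------------

    def compare(self, other: "PartialDate") -> int:
        """Three-way comparison at the precision both sides share."""
        rank = min(_RANK[self.precision], _RANK[other.precision])
        mine = (self.year, self.month, self.day)[: rank + 1]
        theirs = (other.year, other.month, other.day)[: rank + 1]
        return (mine > theirs) - (mine < theirs)

    def __lt__(self, other: "PartialDate") -> bool:
        return self.compare(other) < 0

    def __le__(self, other: "PartialDate") -> bool:
        return self.compare(other) <= 0

    def __gt__(self, other: "PartialDate") -> bool:
        return self.compare(other) > 0

    def __ge__(self, other: "PartialDate") -> bool:
        return self.compare(other) >= 0
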