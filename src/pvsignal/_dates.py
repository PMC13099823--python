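"""FAERS date fields: YYYYMMDD integers, with partial YYYY / YYYYMM forms.

FAERS ASCII archives store dates as bare digit strings.  Partial dates
(year only, or year+month) occur in EVENT_DT / START_DT and must be kept
parseable but distinguishable, because the time-to-onset analysis excludes
reports with incomplete date information.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True, order=True)
class FaersDate:
    """A possibly-partial calendar date as found in FAERS fields.

    ``complete`` is True only for full YYYYMMDD dates; partial dates keep
    the known components and zero-fill the rest for ordering purposes.
    """

    year: int
    month: int = 0
    day: int = 0

    @property
    def complete(self) -> bool:
        return self.month > 0 and self.day > 0

    def to_date(self) -> dt.date:
        if not self.complete:
            raise ValueError(f"incomplete date {self!r} has no calendar day")
        return dt.date(self.year, self.month, self.day)

    def as_int(self) -> int:
        return self.year * 10000 + self.month * 100 + self.day

    def __str__(self) -> str:
        if self.complete:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_faers_date(raw: Optional[str]) -> Optional[FaersDate]:
    """Parse a YYYYMMDD / YYYYMM / YYYY digit string; None/blank -> None.

    Raises ValueError for strings that are not 4, 6 or 8 digits or do not
    form a real calendar date (e.g. month 13, Feb 30).
    """
    if raw is None:
        return None
    s = raw.strip()
    if not s:
        return None
    if not s.isdigit() or len(s) not in (4, 6, 8):
        raise ValueError(f"unparseable FAERS date: {raw!r}")
    year = int(s[:4])
    month = int(s[4:6]) if len(s) >= 6 else 0
    day = int(s[6:8]) if len(s) == 8 else 0
    if year < 1900 or year > 2200:
        raise ValueError(f"implausible year in FAERS date: {raw!r}")
    if len(s) >= 6 and not 1 <= month <= 12:
        raise ValueError(f"bad month in FAERS date: {raw!r}")
    if len(s) == 8:
        try:
            dt.date(year, month, day)
        except ValueError as exc:
            raise ValueError(f"bad day in FAERS date: {raw!r}") from exc
    return FaersDate(year, month, day)


def days_between(start: FaersDate, end: FaersDate) -> int:
    """Whole days from ``start`` to ``end``; both must be complete."""
    return (end.to_date() - start.to_date()).days
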